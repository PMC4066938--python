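"""Asynchronous label-propagation engines: LPA, KBLPA, and NIBLPA.

All three engines share one asynchronous sweep kernel: nodes are visited in
some order and each node immediately adopts the label carried by the
plurality of its neighbours (edge-weight-summed on weighted graphs), so
updates made earlier in a sweep are visible to later nodes.  Asynchronous
updating is what prevents the label oscillation that synchronous updating
exhibits on bipartite graphs.  The engines differ in visit order and in how
plurality ties are broken:

``lpa``
    Classic label propagation: a fresh uniform-random visit order every
    sweep, plurality ties broken uniformly at random.  Stochastic — results
    vary with the seed, which is the instability the other engines address.
``kblpa``
    Visit order fixed for all sweeps by descending k-shell value (ties by
    ascending node id); label ties still random.
``niblpa``
    Visit order fixed by descending node influence NI(i) (ties by node id);
    plurality ties resolved by maximum label influence LI(l), exact LI ties
    by smallest label id.  Fully deterministic — no RNG anywhere.

Convergence: after each mutating sweep, a read-only full pass checks that
every non-isolated node's label would be retained by its own update rule
(plurality membership for the stochastic engines, the exact deterministic
choice for niblpa).  ``iterations`` counts mutating sweeps only.  If the
cap ``max_iter`` is reached first, the partition is still returned with
``converged=False`` and a warning.

Isolated nodes are skipped during sweeps (an update over an empty neighbour
set is undefined) and end up as singleton communities.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import networkx as nx

from .graph import NodeId, edge_weight, is_weighted, node_key, sorted_nodes
from .influence import InfluenceTable, node_influence, update_order
from .kshell import kshell_decompose
from .partition import Labeling, Partition, canonicalize

log = logging.getLogger(__name__)

DEFAULT_MAX_ITER = 100


@dataclass(frozen=True)
class RunResult:
    """Outcome of one propagation run."""

    partition: Partition
    iterations: int
    converged: bool
    algorithm: str
    seed: Optional[int] = None
    alpha: Optional[float] = None

    @property
    def n_communities(self) -> int:
        return len(self.partition)


def neighbor_label_counts(
    G: nx.Graph, labeling: Labeling | Mapping[NodeId, object], node: NodeId
) -> dict:
    """Per-label neighbour support at ``node``: counts on unweighted graphs,
    summed edge weights (w_ij) on weighted ones.  Empty for isolated nodes."""
    labels = labeling.label if isinstance(labeling, Labeling) else labeling
    counts: dict = {}
    if is_weighted(G):
        for j in G[node]:
            counts[labels[j]] = counts.get(labels[j], 0.0) + edge_weight(G, node, j)
    else:
        for j in G[node]:
            counts[labels[j]] = counts.get(labels[j], 0) + 1
    return counts


def _l_max(counts: Mapping) -> list:
    best = max(counts.values())
    return [l for l, c in counts.items() if c == best]


def _sweep(
    G: nx.Graph,
    labels: dict,
    order: list[NodeId],
    choose: Callable[[NodeId, list], object],
) -> int:
    """One asynchronous pass over ``order``; returns the number of label
    changes.  ``choose`` resolves plurality ties (called only when |l_max|>1)."""
    changed = 0
    for v in order:
        counts = neighbor_label_counts(G, labels, v)
        if not counts:
            continue  # isolated node keeps its own label
        lmax = _l_max(counts)
        new = lmax[0] if len(lmax) == 1 else choose(v, lmax)
        if new != labels[v]:
            labels[v] = new
            changed += 1
    return changed


def _stable(
    G: nx.Graph,
    labels: Mapping[NodeId, object],
    deterministic_choice: Optional[Callable[[NodeId, list], object]] = None,
) -> bool:
    """Read-only convergence check.

    Stochastic engines: stable iff every node's label is in its l_max set
    (some tie-break could keep it).  Deterministic engine: stable iff every
    node's label equals the exact choice its update rule would make.
    """
    for v in G.nodes:
        counts = neighbor_label_counts(G, labels, v)
        if not counts:
            continue
        lmax = _l_max(counts)
        if deterministic_choice is None:
            if labels[v] not in lmax:
                return False
        else:
            want = lmax[0] if len(lmax) == 1 else deterministic_choice(v, lmax)
            if labels[v] != want:
                return False
    return True


def _run(
    G: nx.Graph,
    algorithm: str,
    order_for_sweep: Callable[[int], list[NodeId]],
    choose: Callable[[NodeId, list], object],
    max_iter: int,
    deterministic_choice: Optional[Callable[[NodeId, list], object]],
    seed: Optional[int],
    alpha: Optional[float],
) -> RunResult:
    labeling = Labeling.unique(G.nodes)
    converged = False
    t = 0
    while t < max_iter:
        t += 1
        _sweep(G, labeling.label, order_for_sweep(t), choose)
        labeling.iteration = t
        if _stable(G, labeling.label, deterministic_choice):
            converged = True
            break
    if not converged:
        log.warning(
            "%s did not converge within max_iter=%d sweeps", algorithm, max_iter
        )
    partition = canonicalize(labeling, G)
    log.info(
        "%s: %d sweep(s), converged=%s, %d communities",
        algorithm, t, converged, len(partition),
    )
    return RunResult(
        partition=partition,
        iterations=t,
        converged=converged,
        algorithm=algorithm,
        seed=seed,
        alpha=alpha,
    )


def run_lpa(
    G: nx.Graph, seed: Optional[int] = None, max_iter: int = DEFAULT_MAX_ITER
) -> RunResult:
    """Classic asynchronous LPA with seeded randomness.

    Every sweep visits the nodes in a fresh uniform-random order; plurality
    ties are broken uniformly at random among the tied labels.  A fixed seed
    makes the whole run reproducible.
    """
    rng = random.Random(seed)
    base = sorted_nodes(G.nodes)

    def order_for_sweep(_t: int) -> list[NodeId]:
        order = list(base)
        rng.shuffle(order)
        return order

    def choose(_v: NodeId, lmax: list) -> object:
        return rng.choice(sorted(lmax, key=node_key))

    return _run(G, "lpa", order_for_sweep, choose, max_iter, None, seed, None)


def run_kblpa(
    G: nx.Graph, seed: Optional[int] = None, max_iter: int = DEFAULT_MAX_ITER
) -> RunResult:
    """LPA with the visit order fixed by descending k-shell value.

    Order ties break by ascending node id; plurality ties are still broken
    uniformly at random (seeded), which is this baseline's residual
    instability.
    """
    rng = random.Random(seed)
    shells = kshell_decompose(G)
    fixed = sorted(G.nodes, key=lambda v: (-shells.ks[v], node_key(v)))

    def choose(_v: NodeId, lmax: list) -> object:
        return rng.choice(sorted(lmax, key=node_key))

    return _run(G, "kblpa", lambda _t: fixed, choose, max_iter, None, seed, None)


def run_niblpa(
    G: nx.Graph, alpha: float = 1.0, max_iter: int = DEFAULT_MAX_ITER
) -> RunResult:
    """Node-influence based label propagation — fully deterministic.

    Initialization computes the shell index, the influence table NI under
    ``alpha`` and the fixed visit order (NI descending, node-id ties).
    During sweeps a plurality tie among l_max is resolved by the label with
    the greatest label influence LI(l); exact LI ties fall back to the
    smallest label identifier.  The rule is applied strictly: the winning
    label is adopted even when the node's current label is also in l_max.
    """
    if is_weighted(G):
        log.info(
            "weighted graph: weights enter neighbour-label support only; "
            "NI/LI use the unweighted structure"
        )
    shells = kshell_decompose(G)
    table: InfluenceTable = node_influence(G, shells, alpha)
    fixed = update_order(table)

    # LI(l) at v = sum of NI(j)/d(j) over neighbours j holding l; the
    # labeling dict is looked up live so the closure sees async updates.
    labels_ref: dict = {}

    def choose(v: NodeId, lmax: list) -> object:
        li = {l: 0.0 for l in lmax}
        for j in G[v]:
            lab = labels_ref[j]
            if lab in li:
                li[lab] += table.ni[j] / G.degree[j]
        best = max(li.values())
        return min((l for l in lmax if li[l] == best), key=node_key)

    labeling = Labeling.unique(G.nodes)
    labels_ref = labeling.label
    converged = False
    t = 0
    while t < max_iter:
        t += 1
        _sweep(G, labeling.label, fixed, choose)
        labeling.iteration = t
        if _stable(G, labeling.label, choose):
            converged = True
            break
    if not converged:
        log.warning("niblpa did not converge within max_iter=%d sweeps", max_iter)
    partition = canonicalize(labeling, G)
    log.info(
        "niblpa: alpha=%g, %d sweep(s), converged=%s, %d communities",
        alpha, t, converged, len(partition),
    )
    return RunResult(
        partition=partition,
        iterations=t,
        converged=converged,
        algorithm="niblpa",
        seed=None,
        alpha=alpha,
    )


ENGINES = {
    "lpa": run_lpa,
    "kblpa": run_kblpa,
    "niblpa": run_niblpa,
}
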