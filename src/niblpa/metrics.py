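"""Partition-quality and partition-agreement metrics.

Three measures standard in community detection:

* **Modularity Q** — fraction of edges falling inside communities minus the
  expectation under the degree-preserving null model,

      Q = (1/2m) Σ_{i,j} (A_ij − d_i d_j / 2m) δ(c_i, c_j),

  equivalently Σ_c [ L_c/m − (D_c/2m)² ] over communities c with L_c
  internal edges and total degree D_c.  Needs no ground truth; defined here
  for unweighted graphs only.

* **Pair F-measure** — precision/recall over unordered same-cluster node
  pairs: S = pairs co-clustered by the evaluated partition, T = pairs
  co-classed in the truth; Precision = |S∩T|/|S|, Recall = |S∩T|/|T|,
  F = their harmonic mean.

* **NMI** — normalized mutual information between two partitions,
  2·I(X;Y)/(H(X)+H(Y)) computed from the contingency table with natural
  logarithms and the convention 0·log 0 = 0; equals 1 iff the partitions
  are identical up to relabeling.

Degenerate conventions (documented, tested): F with no retrieved pairs is
0, F with neither partition having pairs is 1; NMI of two single-community
partitions is 1, of one trivial vs one non-trivial partition is 0 (the
natural 0/len limit).
"""

from __future__ import annotations

from math import comb, log

import networkx as nx

from .errors import ConsistencyError, UndefinedMetricError
from .partition import Partition


def _check_same_nodes(x: Partition, y: Partition) -> None:
    if x.nodes != y.nodes:
        raise ConsistencyError("partitions are over different node sets")


def modularity(G: nx.Graph, partition: Partition) -> float:
    """Newman modularity Q of ``partition`` on the unweighted graph ``G``.

    Raises :class:`UndefinedMetricError` on edgeless graphs (2m = 0) and
    :class:`ConsistencyError` if the partition does not cover exactly the
    graph's nodes.  Range: −1/2 ≤ Q < 1.
    """
    m = G.number_of_edges()
    if m == 0:
        raise UndefinedMetricError("modularity is undefined on an edgeless graph")
    if partition.nodes != set(G.nodes):
        raise ConsistencyError("partition does not cover exactly the graph's nodes")
    q = 0.0
    for comm in partition.communities:
        internal = G.subgraph(comm).number_of_edges()
        degree_sum = sum(G.degree[v] for v in comm)
        q += internal / m - (degree_sum / (2 * m)) ** 2
    return q


def contingency(x: Partition, y: Partition) -> dict[tuple[int, int], int]:
    """Sparse contingency table {(i, j): |X_i ∩ Y_j|} between two partitions
    of the same node set (zero cells omitted)."""
    _check_same_nodes(x, y)
    counts: dict[tuple[int, int], int] = {}
    for v in x.membership:
        key = (x.membership[v], y.membership[v])
        counts[key] = counts.get(key, 0) + 1
    return counts


def f_measure(pred: Partition, truth: Partition) -> float:
    """Pair-based F-measure of ``pred`` against ``truth`` in [0, 1].

    Computed from the contingency table: |S∩T| = Σ_ij C(n_ij, 2),
    |S| = Σ_i C(|X_i|, 2), |T| = Σ_j C(|Y_j|, 2).
    """
    table = contingency(pred, truth)
    s = sum(comb(len(c), 2) for c in pred.communities)
    t = sum(comb(len(c), 2) for c in truth.communities)
    if s == 0 and t == 0:
        return 1.0
    if s == 0 or t == 0:
        return 0.0
    st = sum(comb(c, 2) for c in table.values())
    precision = st / s
    recall = st / t
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def nmi(x: Partition, y: Partition) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Sum-normalized form 2·I/(H(X)+H(Y)); natural logs; 0·log 0 = 0.  Two
    trivial one-community partitions (both entropies zero) are identical,
    so NMI = 1 by convention.
    """
    table = contingency(x, y)
    n = x.n
    if n == 0:
        raise ConsistencyError("NMI of empty partitions is undefined")
    sizes_x = {i: len(c) for i, c in enumerate(x.communities)}
    sizes_y = {j: len(c) for j, c in enumerate(y.communities)}
    denom = sum(a * log(a / n) for a in sizes_x.values()) + sum(
        b * log(b / n) for b in sizes_y.values()
    )
    if denom == 0.0:
        # both partitions are the single all-nodes community: identical
        return 1.0
    numer = sum(
        nij * log(n * nij / (sizes_x[i] * sizes_y[j]))
        for (i, j), nij in table.items()
    )
    # guard against float spill a hair outside [0, 1]
    return min(1.0, max(0.0, -2.0 * numer / denom))
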