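"""Synthetic benchmark generators with planted ground truth.

Two generators, each returning ``(graph, truth_partition)``:

* :func:`clique_ring` — m complete graphs K_n joined in a ring by single
  bridge edges.  A Clique-Ring with clique size n and m cliques has
  N = m·n nodes and M = m·n·(n−1)/2 + m edges; the planted communities are
  the cliques.  Deterministic, no randomness.  Node naming is ``c{q}_{r}``
  for member r of clique q; the bridge for clique q runs from its last node
  ``c{q}_{n-1}`` to the next clique's first node ``c{q+1}_0`` (indices mod
  m), which realises exactly one bridge per adjacent clique pair.

* :func:`planted_partition` — a planted-partition random graph: nodes are
  split into k near-equal communities; each within-community pair is an
  edge with probability ``p_in``, each between-community pair with
  ``p_out``, independently under a seeded RNG.  This is the in-repo
  stand-in benchmark for mixing-level robustness studies (it lacks the
  power-law degree and community-size heterogeneity of LFR-style
  generators).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .errors import ValidationError
from .partition import Partition


@dataclass(frozen=True)
class CliqueRingSpec:
    """Clique size n (≥3) and number of cliques m (≥2)."""

    n: int
    m_cliques: int


@dataclass(frozen=True)
class PlantedSpec:
    """Planted-partition parameters: node count, community count, and the
    within/between edge probabilities (0 ≤ p_out ≤ p_in ≤ 1)."""

    n_nodes: int
    k_communities: int
    p_in: float
    p_out: float
    seed: int = 0


def clique_ring(n: int, m_cliques: int) -> tuple[nx.Graph, Partition]:
    """Generate a Clique-Ring network and its planted clique partition."""
    if n < 3:
        raise ValidationError(f"clique size must be >= 3, got {n}")
    if m_cliques < 2:
        raise ValidationError(f"number of cliques must be >= 2, got {m_cliques}")
    G = nx.Graph(weighted=False)
    cliques: list[list[str]] = []
    for q in range(m_cliques):
        members = [f"c{q}_{r}" for r in range(n)]
        G.add_edges_from(combinations(members, 2))
        cliques.append(members)
    for q in range(m_cliques):
        G.add_edge(f"c{q}_{n - 1}", f"c{(q + 1) % m_cliques}_0")
    return G, Partition(cliques)


def planted_partition(
    n_nodes: int,
    k_communities: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[nx.Graph, Partition]:
    """Generate a planted-partition graph and its planted communities.

    Community sizes differ by at most one; the same seed reproduces the
    graph bit-for-bit.
    """
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValidationError(
            f"need 0 <= p_out <= p_in <= 1, got p_in={p_in}, p_out={p_out}"
        )
    if n_nodes < k_communities or k_communities < 1:
        raise ValidationError(
            f"need n_nodes >= k_communities >= 1, got {n_nodes}, {k_communities}"
        )
    rng = random.Random(seed)
    base, extra = divmod(n_nodes, k_communities)
    community_of: list[int] = []
    for c in range(k_communities):
        community_of.extend([c] * (base + (1 if c < extra else 0)))
    names = [f"u{i}" for i in range(n_nodes)]
    G = nx.Graph(weighted=False)
    G.add_nodes_from(names)
    for i, j in combinations(range(n_nodes), 2):
        p = p_in if community_of[i] == community_of[j] else p_out
        if rng.random() < p:
            G.add_edge(names[i], names[j])
    groups: dict[int, set] = {}
    for i, c in enumerate(community_of):
        groups.setdefault(c, set()).add(names[i])
    return G, Partition(groups.values())
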