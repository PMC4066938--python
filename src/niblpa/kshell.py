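"""k-shell (k-core) decomposition.

The k-core of a graph is its maximal subgraph of minimum degree k; a node's
shell index Ks(i) is the largest k for which it belongs to the k-core.
Shells are obtained by iterative peeling: repeatedly remove every node whose
remaining degree is ≤ k, assign those nodes shell k, then increment k.
Isolated nodes get shell 0.  The decomposition runs in O(m) and is
deterministic — removal order within a round cannot change the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph import NodeId


@dataclass(frozen=True)
class ShellIndex:
    """Node → shell value Ks(i), plus the largest shell present."""

    ks: dict[NodeId, int]
    max_shell: int

    def __getitem__(self, node: NodeId) -> int:
        return self.ks[node]


def kshell_decompose(G: nx.Graph) -> ShellIndex:
    """Shell index Ks(i) for every node of ``G`` (may be disconnected).

    Delegates to the standard core-number peeling; satisfies
    0 ≤ Ks(i) ≤ d_i and, for every k, {i : Ks(i) ≥ k} induces a subgraph of
    minimum degree ≥ k.
    """
    ks = {v: int(k) for v, k in nx.core_number(G).items()}
    return ShellIndex(ks=ks, max_shell=max(ks.values(), default=0))
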