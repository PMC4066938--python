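"""Node influence, the update order it induces, and label influence.

Node influence combines a node's own core position with the core positions
of its neighbours:

    NI(i) = Ks(i) + α · Σ_{j ∈ N(i)} Ks(j) / d(j)

with α ∈ [0, 1] tuning how much the neighbourhood contributes.  With α = 0
it reduces to the plain shell index; larger α separates nodes that share a
shell by how well-connected their neighbourhoods are.  Sorting nodes by NI
descending (ties broken by ascending node identifier) gives the fixed,
deterministic update order used by the node-influence propagation engine.

Label influence scores a candidate label l at a node i by the influence of
the neighbours carrying it, discounted by their degree:

    LI(l) = Σ_{j ∈ N(i), c_j = l} NI(j) / d(j)

and is used to break plurality ties during label updating.

NI and LI are defined on the unweighted structure only: degrees and shell
values ignore edge weights even on weighted graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Union

import networkx as nx

from .errors import ConsistencyError
from .graph import NodeId, node_key
from .kshell import ShellIndex
from .partition import Labeling

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InfluenceTable:
    """Node → NI(i) under a fixed α."""

    ni: dict[NodeId, float]
    alpha: float

    def __getitem__(self, node: NodeId) -> float:
        return self.ni[node]


def node_influence(G: nx.Graph, shells: ShellIndex, alpha: float = 1.0) -> InfluenceTable:
    """Compute NI(i) = Ks(i) + α·Σ_{j∈N(i)} Ks(j)/d(j) for all nodes.

    Isolated nodes have an empty neighbour sum, so NI = Ks = 0.  α outside
    [0, 1] is allowed but logged as unusual.
    """
    if set(shells.ks) != set(G.nodes):
        raise ConsistencyError("shell index does not cover the graph's node set")
    if not 0.0 <= alpha <= 1.0:
        log.warning("alpha=%g is outside the usual [0, 1] range", alpha)
    ni = {
        i: shells.ks[i] + alpha * sum(shells.ks[j] / G.degree[j] for j in G[i])
        for i in G.nodes
    }
    return InfluenceTable(ni=ni, alpha=alpha)


def update_order(table: InfluenceTable) -> list[NodeId]:
    """Fixed node visit order: NI descending, ties by ascending node id."""
    return sorted(table.ni, key=lambda v: (-table.ni[v], node_key(v)))


def label_influence(
    G: nx.Graph,
    table: InfluenceTable,
    node: NodeId,
    label: object,
    labeling: Union[Labeling, Mapping[NodeId, object]],
) -> float:
    """LI of ``label`` at ``node``: Σ NI(j)/d(j) over neighbours j currently
    holding ``label``; 0.0 when no neighbour does."""
    labels = labeling.label if isinstance(labeling, Labeling) else labeling
    return sum(table.ni[j] / G.degree[j] for j in G[node] if labels[j] == label)
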