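"""Undirected graph model and edge-list I/O.

Graphs are plain :class:`networkx.Graph` objects: simple (no self-loops, no
parallel edges), undirected, with node identifiers kept verbatim as strings.
A graph read with ``weighted=True`` carries a positive ``weight`` attribute
on every edge and ``G.graph["weighted"] is True``.

Node identifiers are opaque strings, but every "by node ID" tie-break in the
package uses :func:`node_key`: identifiers that parse as integers order
numerically (and before all non-numeric identifiers), everything else orders
lexicographically.  This makes ``v2 < v10`` behave as a practitioner expects
on files whose nodes are numbered.
"""

from __future__ import annotations

import logging
from os import PathLike
from typing import Iterable, Union

import networkx as nx

from .errors import EdgeListError, EmptyGraphError, WeightConflictError

log = logging.getLogger(__name__)

NodeId = str


def node_key(node: object) -> tuple:
    """Total-order sort key for node (and label) identifiers.

    Integer-like identifiers sort numerically and precede all others;
    the rest sort lexicographically.
    """
    s = str(node)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


def sorted_nodes(nodes: Iterable[NodeId]) -> list[NodeId]:
    """Nodes in canonical identifier order (see :func:`node_key`)."""
    return sorted(nodes, key=node_key)


def is_weighted(G: nx.Graph) -> bool:
    return bool(G.graph.get("weighted", False))


def edge_weight(G: nx.Graph, u: NodeId, v: NodeId) -> float:
    """Weight of edge (u, v); 1.0 on unweighted graphs."""
    if is_weighted(G):
        return float(G[u][v]["weight"])
    return 1.0


def read_edge_list(path: Union[str, PathLike], weighted: bool = False) -> nx.Graph:
    """Read a whitespace-delimited edge list into a simple undirected graph.

    Each non-blank, non-``#`` line holds ``u v`` (or ``u v w`` when
    ``weighted``).  Self-loops are dropped with a logged warning; reversed
    and repeated edges collapse to one undirected edge.  Node identifiers
    are kept verbatim as strings.

    Raises
    ------
    EdgeListError
        Malformed line (wrong field count, non-positive or unparseable
        weight), with the offending line number in the message.
    WeightConflictError
        The same edge listed twice with different weights.
    EmptyGraphError
        No usable edge survives parsing.
    """
    G = nx.Graph(weighted=weighted)
    want = 3 if weighted else 2
    n_self = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != want:
                raise EdgeListError(
                    f"{path}: line {lineno}: expected {want} fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if u == v:
                n_self += 1
                continue
            if weighted:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise EdgeListError(
                        f"{path}: line {lineno}: weight {fields[2]!r} is not a number"
                    ) from None
                if not w > 0:
                    raise EdgeListError(
                        f"{path}: line {lineno}: weight must be positive, got {w}"
                    )
                if G.has_edge(u, v) and float(G[u][v]["weight"]) != w:
                    raise WeightConflictError(
                        f"{path}: line {lineno}: edge {u}-{v} repeated with "
                        f"conflicting weight ({G[u][v]['weight']} vs {w})"
                    )
                G.add_edge(u, v, weight=w)
            else:
                G.add_edge(u, v)
    if G.number_of_nodes() == 0:
        raise EmptyGraphError(f"{path}: no edges found")
    if n_self:
        log.warning("dropped %d self-loop(s) while reading %s", n_self, path)
    return G


def write_edge_list(G: nx.Graph, path: Union[str, PathLike]) -> None:
    """Write a graph as a tab-delimited edge list, rows in canonical order."""
    weighted = is_weighted(G)
    with open(path, "wt", encoding="utf-8") as fh:
        for u in sorted_nodes(G.nodes):
            for v in sorted_nodes(G[u]):
                if node_key(u) < node_key(v):
                    if weighted:
                        fh.write(f"{u}\t{v}\t{G[u][v]['weight']:g}\n")
                    else:
                        fh.write(f"{u}\t{v}\n")
        # isolated nodes cannot be represented by an edge list; note them
        isolates = [v for v in G.nodes if G.degree[v] == 0]
        if isolates:
            log.warning("%d isolated node(s) not representable in edge list", len(isolates))
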