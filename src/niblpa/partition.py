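"""Partitions, labelings, and membership-file I/O.

A :class:`Partition` is the immutable, canonical end product of community
detection: disjoint non-empty communities covering a node set, numbered
0, 1, 2, ... by each community's smallest member (under :func:`~niblpa.graph.node_key`
order).  Canonical numbering makes partitions comparable with ``==``
regardless of the labels the propagation happened to converge on.

A :class:`Labeling` is the mutable state during propagation: one current
label per node plus a sweep counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Union

import networkx as nx

from .errors import CoverageError, ValidationError
from .graph import NodeId, node_key, sorted_nodes


@dataclass
class Labeling:
    """Mutable node → label map with a sweep counter.

    At iteration 0 every node carries a unique label (its own identifier).
    """

    label: dict[NodeId, NodeId]
    iteration: int = 0

    @classmethod
    def unique(cls, nodes: Iterable[NodeId]) -> "Labeling":
        """Initial labeling: each node labeled by its own identifier."""
        return cls(label={v: v for v in nodes}, iteration=0)


class Partition:
    """Disjoint communities covering a node set, in canonical form.

    Parameters
    ----------
    communities
        Iterable of node collections.  Empty collections are rejected;
        overlapping collections raise :class:`ValidationError`.
    """

    __slots__ = ("communities", "membership")

    def __init__(self, communities: Iterable[Iterable[NodeId]]):
        comms = [frozenset(c) for c in communities]
        if any(not c for c in comms):
            raise ValidationError("communities must be non-empty")
        total = sum(len(c) for c in comms)
        nodes = set().union(*comms) if comms else set()
        if total != len(nodes):
            raise ValidationError("communities must be pairwise disjoint")
        comms.sort(key=lambda c: node_key(min(c, key=node_key)))
        self.communities: tuple[frozenset, ...] = tuple(comms)
        self.membership: dict[NodeId, int] = {
            v: i for i, c in enumerate(self.communities) for v in c
        }

    @classmethod
    def from_membership(cls, membership: Mapping[NodeId, object]) -> "Partition":
        """Group nodes sharing a membership value; the values themselves are
        discarded (only the grouping matters)."""
        groups: dict[object, set] = {}
        for v, c in membership.items():
            groups.setdefault(c, set()).add(v)
        return cls(groups.values())

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.membership)

    @property
    def n(self) -> int:
        return len(self.membership)

    def __len__(self) -> int:
        return len(self.communities)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.communities == other.communities

    def __hash__(self) -> int:
        return hash(self.communities)

    def __repr__(self) -> str:
        return f"Partition({len(self)} communities, {self.n} nodes)"

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities]


def canonicalize(labeling: Union[Labeling, Mapping[NodeId, object]], G: nx.Graph) -> Partition:
    """Group nodes of ``G`` sharing a label into a canonical Partition.

    Raises :class:`CoverageError` if any graph node lacks a label.  Labels
    on nodes outside the graph are ignored.
    """
    labels = labeling.label if isinstance(labeling, Labeling) else labeling
    missing = [v for v in G.nodes if v not in labels]
    if missing:
        raise CoverageError(f"{len(missing)} node(s) missing from labeling, e.g. {missing[0]!r}")
    groups: dict[object, set] = {}
    for v in G.nodes:
        groups.setdefault(labels[v], set()).add(v)
    return Partition(groups.values())


def write_membership(partition: Partition, path: Union[str, PathLike]) -> None:
    """Write a partition as TSV ``node<TAB>community`` with a header row,
    rows sorted by node identifier.  Round-trips via :func:`read_membership`."""
    if partition.n == 0:
        raise ValidationError("cannot write an empty partition")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node\tcommunity\n")
        for v in sorted_nodes(partition.membership):
            fh.write(f"{v}\t{partition.membership[v]}\n")


def read_membership(path: Union[str, PathLike]) -> Partition:
    """Read a TSV membership file (header ``node<TAB>community``) into a
    canonical Partition."""
    membership: dict[NodeId, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValidationError(f"{path}: empty membership file")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"{path}: line {lineno}: expected 2 fields")
            membership[fields[0]] = fields[1]
    if not membership:
        raise ValidationError(f"{path}: no membership rows")
    return Partition.from_membership(membership)
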