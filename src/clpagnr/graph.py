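"""Graph container and plain-text readers/writers.

The detection pipeline is deterministic by construction, so the graph
container fixes a *canonical node order* at build time: numeric when every
identifier parses as an integer, lexicographic otherwise.  All downstream
tie-breaking refers to this order, which makes results invariant to the
line order of the input edge list.

Graphs are undirected, unweighted and simple.  Self-loops and duplicate
edges in the input are dropped with a warning rather than rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

log = logging.getLogger(__name__)

Node = str


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


def _canonical_sort(identifiers: Iterable[Node]) -> list[Node]:
    ids = list(identifiers)
    try:
        return sorted(ids, key=lambda s: int(s))
    except (TypeError, ValueError):
        return sorted(ids, key=str)


@dataclass(frozen=True)
class Graph:
    """Immutable undirected simple graph with a canonical node order."""

    nodes: tuple[Node, ...]
    adj: dict[Node, frozenset[Node]]
    index: dict[Node, int] = field(repr=False)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Node, Node]],
        extra_nodes: Iterable[Node] = (),
        warn: bool = True,
    ) -> "Graph":
        """Build a graph, dropping self-loops and collapsing duplicates."""
        seen: set[frozenset[Node]] = set()
        nodes: set[Node] = set(extra_nodes)
        pairs: list[tuple[Node, Node]] = []
        for u, v in edges:
            u, v = str(u), str(v)
            nodes.update((u, v))
            if u == v:
                if warn:
                    log.warning("dropping self-loop at node %r", u)
                continue
            key = frozenset((u, v))
            if key in seen:
                if warn:
                    log.warning("collapsing duplicate edge %r-%r", u, v)
                continue
            seen.add(key)
            pairs.append((u, v))
        order = tuple(_canonical_sort(nodes))
        index = {v: i for i, v in enumerate(order)}
        neigh: dict[Node, set[Node]] = {v: set() for v in order}
        for u, v in pairs:
            neigh[u].add(v)
            neigh[v].add(u)
        adj = {v: frozenset(neigh[v]) for v in order}
        return cls(nodes=order, adj=adj, index=index)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return sum(len(s) for s in self.adj.values()) // 2

    def degree(self, v: Node) -> int:
        return len(self.adj[v])

    def neighbors(self, v: Node) -> frozenset[Node]:
        return self.adj[v]

    def has_edge(self, u: Node, v: Node) -> bool:
        return v in self.adj[u]

    def edges(self) -> Iterator[tuple[Node, Node]]:
        """Edges in canonical order, lower-index endpoint first."""
        for u in self.nodes:
            iu = self.index[u]
            for v in sorted(self.adj[u], key=self.index.__getitem__):
                if self.index[v] > iu:
                    yield (u, v)

    def sorted_nodes(self, nodes: Iterable[Node]) -> list[Node]:
        return sorted(nodes, key=self.index.__getitem__)

    def induced_subgraph(self, nodes: Iterable[Node]) -> "Graph":
        """Subgraph on ``nodes`` with every edge internal to the set."""
        keep = set(nodes)
        unknown = keep - set(self.adj)
        if unknown:
            raise KeyError(f"unknown nodes: {sorted(unknown)[:5]}")
        edges = [
            (u, v)
            for u in keep
            for v in self.adj[u]
            if v in keep and self.index[u] < self.index[v]
        ]
        return Graph.from_edges(edges, extra_nodes=keep, warn=False)


def induced_subgraph(graph: Graph, nodes: Iterable[Node]) -> Graph:
    return graph.induced_subgraph(nodes)


def read_edge_list(source: TextIO | Iterable[str], comment_prefix: str = "#") -> Graph:
    """Parse a two-column whitespace-separated edge list.

    Blank lines and lines starting with ``comment_prefix`` are skipped.
    A malformed line raises :class:`EdgeListError` naming its line number;
    so does an input containing no nodes at all.
    """
    edges: list[tuple[Node, Node]] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise EdgeListError(
                f"line {lineno}: expected two node identifiers, got {len(tokens)}"
            )
        edges.append((tokens[0], tokens[1]))
    if not edges:
        raise EdgeListError("edge list contains no edges")
    return Graph.from_edges(edges)


# -- partitions ----------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """Total assignment node -> community id, canonically renumbered.

    Community identifiers are renumbered 0,1,2,... by first appearance in
    canonical node order, so two runs that find the same grouping produce
    byte-identical membership tables.
    """

    assignment: dict[Node, int]

    @classmethod
    def from_assignment(cls, assignment: dict[Node, object], graph: Graph) -> "Partition":
        missing = set(graph.nodes) - set(assignment)
        if missing:
            raise ValueError(f"partition not total; missing {sorted(missing)[:5]}")
        renumber: dict[object, int] = {}
        canon: dict[Node, int] = {}
        for v in graph.nodes:
            c = assignment[v]
            if c not in renumber:
                renumber[c] = len(renumber)
            canon[v] = renumber[c]
        return cls(assignment=canon)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> dict[int, set[Node]]:
        out: dict[int, set[Node]] = {}
        for v, c in self.assignment.items():
            out.setdefault(c, set()).add(v)
        return out

    def labels_for(self, nodes: Iterable[Node]) -> list[int]:
        return [self.assignment[v] for v in nodes]


def write_membership(partition: Partition, sink: TextIO, graph: Graph, header: bool = False) -> None:
    """Write a ``node<TAB>community`` table in canonical node order."""
    if header:
        sink.write("node\tcommunity\n")
    for v in graph.nodes:
        sink.write(f"{v}\t{partition.assignment[v]}\n")


def read_membership(source: TextIO | Iterable[str], graph: Graph) -> Partition:
    assignment: dict[Node, str] = {}
    for raw in source:
        line = raw.strip()
        if not line or line.startswith("#") or line == "node\tcommunity":
            continue
        node, comm = line.split("\t")
        assignment[node] = comm
    return Partition.from_assignment(assignment, graph)
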