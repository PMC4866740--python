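"""Mutual-neighbour scores and the initial seeding of communities.

A pair of adjacent nodes that share many neighbours is likely to sit inside
the same community.  The mutual neighbour score MNS(x, y) = |N(x) & N(y)|
drives the first grouping stage of the pipeline: reciprocal-maximum pairs
are fused into seed groups, then remaining nodes adopt the label of their
best-scoring neighbour.
"""

from __future__ import annotations

from collections import Counter

from .community import SOLO, LabelState
from .graph import Graph, Node


def mutual_neighbour_score(graph: Graph, x: Node, y: Node) -> int:
    """Number of common neighbours of two distinct nodes."""
    if x == y:
        raise ValueError("MNS is defined for distinct nodes")
    return len(graph.adj[x] & graph.adj[y])


class MNSTable:
    """MNS values for every *adjacent* pair of a graph.

    Scores are only needed between neighbours (both seeding phases look at
    neighbours), which keeps construction linear in the number of edges
    times the mean degree.
    """

    def __init__(self, graph: Graph):
        self.graph = graph
        self._score: dict[tuple[Node, Node], int] = {}
        for u, v in graph.edges():
            self._score[(u, v)] = len(graph.adj[u] & graph.adj[v])

    def score(self, x: Node, y: Node) -> int:
        ix, iy = self.graph.index[x], self.graph.index[y]
        key = (x, y) if ix < iy else (y, x)
        try:
            return self._score[key]
        except KeyError:
            raise KeyError(f"nodes {x!r} and {y!r} are not adjacent") from None

    def items(self):
        return self._score.items()

    def best(self, x: Node) -> int:
        """Highest score of ``x`` with any neighbour (0 if isolated)."""
        if not self.graph.adj[x]:
            return 0
        return max(self.score(x, y) for y in self.graph.adj[x])


def build_mns_table(graph: Graph) -> MNSTable:
    return MNSTable(graph)


def seed_groups(graph: Graph, mns: MNSTable) -> LabelState:
    """Form initial communities from mutual-neighbour scores.

    Phase 1 (reciprocal maxima): every edge (x, y) whose score is positive
    and is simultaneously x's best and y's best fuses x and y into one
    group; fusion is transitive across such edges.  A zero score groups
    nothing — no shared neighbour is no evidence of co-membership.

    Phase 2 (adoption): still-solo nodes are updated asynchronously in
    ascending-degree order.  Each looks at the neighbours realising its
    highest score; among the labelled ones the most common label wins
    (remaining ties: smallest community identifier).  Nodes with no
    positive score, or whose best-scoring neighbours are all unlabelled,
    stay solo.
    """
    state = LabelState(graph)
    best = {v: mns.best(v) for v in graph.nodes}

    # Phase 1: union of reciprocal-maximum edges.
    parent: dict[Node, Node] = {v: v for v in graph.nodes}

    def find(v: Node) -> Node:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v in graph.edges():
        s = mns.score(u, v)
        if s > 0 and s == best[u] and s == best[v]:
            ru, rv = find(u), find(v)
            if ru != rv:
                # root with the smaller canonical index wins, deterministically
                if graph.index[ru] > graph.index[rv]:
                    ru, rv = rv, ru
                parent[rv] = ru

    groups: dict[Node, set[Node]] = {}
    for v in graph.nodes:
        r = find(v)
        groups.setdefault(r, set()).add(v)
    for r in graph.sorted_nodes(groups):
        members = groups[r]
        if len(members) > 1:
            state.new_community(members)

    # Phase 2: single asynchronous adoption sweep, lowest degree first.
    order = sorted(state.solo_nodes(), key=lambda v: (graph.degree(v), graph.index[v]))
    for v in order:
        if best[v] == 0:
            continue
        tied = [u for u in graph.adj[v] if mns.score(v, u) == best[v]]
        votes = Counter(
            state.label[u] for u in tied if state.label[u] is not SOLO
        )
        if not votes:
            continue
        top = max(votes.values())
        cid = min(c for c, k in votes.items() if k == top)
        state.assign(v, cid)

    return state
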