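"""Community membership state, node capacity, joining conditions, merging.

``LabelState`` is the mutable book-keeping shared by every pipeline stage:
each node is either *solo* (no community) or a member of exactly one
community.  Per-member intra-community link counts are maintained
incrementally so that capacities and the joining conditions are O(degree)
to evaluate.

Links from a member to solo nodes count as inter-community links: a
member's degree decomposes into intra-community links and everything else.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .graph import Graph, Node, Partition

SOLO = None  # label value for nodes outside every community


class LabelState:
    """Node labels plus incrementally maintained community statistics."""

    def __init__(self, graph: Graph):
        self.graph = graph
        self.label: dict[Node, int | None] = {v: SOLO for v in graph.nodes}
        self.communities: dict[int, set[Node]] = {}
        self.member_intra: dict[Node, int] = {}
        self._next_cid = 0

    # -- construction / copying ----------------------------------------
    def copy(self) -> "LabelState":
        other = LabelState.__new__(LabelState)
        other.graph = self.graph
        other.label = dict(self.label)
        other.communities = {c: set(members) for c, members in self.communities.items()}
        other.member_intra = dict(self.member_intra)
        other._next_cid = self._next_cid
        return other

    def new_community(self, members: Iterable[Node]) -> int:
        """Create a community from currently-solo ``members``."""
        cid = self._next_cid
        self._next_cid += 1
        self.communities[cid] = set()
        for v in self.graph.sorted_nodes(members):
            self.assign(v, cid)
        return cid

    # -- membership mutations -------------------------------------------
    def assign(self, v: Node, cid: int) -> None:
        """Solo node ``v`` joins community ``cid``."""
        if self.label[v] is not SOLO:
            raise ValueError(f"node {v!r} is already grouped")
        members = self.communities[cid]
        intra = 0
        for u in self.graph.adj[v]:
            if u in members:
                intra += 1
                self.member_intra[u] += 1
        self.label[v] = cid
        members.add(v)
        self.member_intra[v] = intra

    def remove(self, v: Node) -> None:
        """Member ``v`` becomes solo; empty communities are deleted."""
        cid = self.label[v]
        if cid is SOLO:
            raise ValueError(f"node {v!r} is already solo")
        members = self.communities[cid]
        members.discard(v)
        for u in self.graph.adj[v]:
            if u in members:
                self.member_intra[u] -= 1
        self.label[v] = SOLO
        del self.member_intra[v]
        if not members:
            del self.communities[cid]

    def move(self, v: Node, cid: int) -> None:
        self.remove(v)
        self.assign(v, cid)

    def merge_into(self, a: int, b: int) -> None:
        """All members of community ``a`` adopt label ``b``."""
        movers = self.communities.pop(a)
        target = self.communities[b]
        for v in movers:
            self.label[v] = b
            for u in self.graph.adj[v]:
                if u in target:
                    self.member_intra[v] += 1
                    self.member_intra[u] += 1
        target.update(movers)

    # -- queries ---------------------------------------------------------
    def solo_nodes(self) -> list[Node]:
        return [v for v in self.graph.nodes if self.label[v] is SOLO]

    def n_solo(self) -> int:
        return sum(1 for v in self.graph.nodes if self.label[v] is SOLO)

    def links_into(self, v: Node, cid: int) -> int:
        members = self.communities[cid]
        return sum(1 for u in self.graph.adj[v] if u in members)

    def min_intra(self, cid: int) -> int:
        """q: the observed minimum per-member intra-link count."""
        return min(self.member_intra[u] for u in self.communities[cid])

    def intra_links(self, cid: int) -> int:
        return sum(self.member_intra[u] for u in self.communities[cid]) // 2

    def inter_links(self, cid: int) -> int:
        deg = sum(self.graph.degree(u) for u in self.communities[cid])
        return deg - 2 * self.intra_links(cid)

    def community_of(self, v: Node) -> int | None:
        return self.label[v]

    def sorted_cids(self, key=None) -> list[int]:
        if key is None:
            return sorted(self.communities)
        return sorted(self.communities, key=key)

    def to_partition(self) -> Partition:
        if any(c is SOLO for c in self.label.values()):
            raise ValueError("state has solo nodes; partition would not be total")
        return Partition.from_assignment(self.label, self.graph)

    def check_consistent(self) -> None:
        """Validate all invariants by brute-force recount (for tests)."""
        for cid, members in self.communities.items():
            assert members, f"empty community {cid}"
            for v in members:
                assert self.label[v] == cid
                recount = sum(1 for u in self.graph.adj[v] if u in members)
                assert self.member_intra[v] == recount, (v, cid)
        grouped = {v for ms in self.communities.values() for v in ms}
        for v in self.graph.nodes:
            assert (self.label[v] is SOLO) == (v not in grouped)


@dataclass(frozen=True)
class CommunityStats:
    """Snapshot of one community's link statistics."""

    size: int
    intra_links: int
    inter_links: int
    member_intra: dict[Node, int]


def community_stats(state: LabelState, cid: int) -> CommunityStats:
    members = state.communities[cid]
    return CommunityStats(
        size=len(members),
        intra_links=state.intra_links(cid),
        inter_links=state.inter_links(cid),
        member_intra={v: state.member_intra[v] for v in members},
    )


# -- capacity and joining conditions --------------------------------------


def node_capacity(graph: Graph, state: LabelState, v: Node) -> float:
    """Inter-community links of a grouped node divided by its degree.

    A high capacity means most of the node's links leave its community, so
    the community is "willing" to grow through this node.  Degree-0 nodes
    have capacity 0 by convention.
    """
    if state.label[v] is SOLO:
        raise ValueError(f"capacity is defined for grouped nodes; {v!r} is solo")
    d = graph.degree(v)
    if d == 0:
        return 0.0
    return (d - state.member_intra[v]) / d


def acceptance_capability(graph: Graph, state: LabelState, v: Node, cid: int) -> float:
    """Sum of capacities of v's neighbours that belong to community ``cid``."""
    members = state.communities[cid]
    return sum(node_capacity(graph, state, u) for u in graph.adj[v] if u in members)


def links_into(graph: Graph, state: LabelState, v: Node, cid: int) -> int:
    return state.links_into(v, cid)


def condition_satisfied(
    graph: Graph, state: LabelState, v: Node, cid: int, condition: int
) -> bool:
    """The four progressively relaxed membership tests.

    With l = links from v into the community and q = the community's
    minimum per-member intra-link count:

    1: l > q     2: l >= q     3: l > q/2     4: l >= q/2

    q/2 is compared exactly (2l vs q), never rounded.
    """
    l = state.links_into(v, cid)
    q = state.min_intra(cid)
    if condition == 1:
        return l > q
    if condition == 2:
        return l >= q
    if condition == 3:
        return 2 * l > q
    if condition == 4:
        return 2 * l >= q
    raise ValueError(f"unknown condition {condition}")


# -- merging ---------------------------------------------------------------


@dataclass(frozen=True)
class MergeParams:
    """Merge threshold alpha in (0, 1]; larger alpha = harder to merge."""

    alpha: float = 1.0

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")


def should_merge(
    stats_target: CommunityStats,
    inter_ab: int,
    stats_neighbour: CommunityStats,
    params: MergeParams,
) -> bool:
    """Merge test: inter_AB/n_B > alpha * intra_A/n_A (strict).

    The target A is absorbed into the neighbour B when the per-neighbour-node
    count of links between them exceeds alpha times A's intra-link density.
    Compared exactly through rationals so grid values of alpha (0.1 steps)
    never flip a decision through float rounding.
    """
    if inter_ab < 0:
        raise ValueError("negative inter-community link count")
    alpha = Fraction(params.alpha).limit_denominator(10**6)
    lhs = Fraction(inter_ab, stats_neighbour.size)
    rhs = alpha * Fraction(stats_target.intra_links, stats_target.size)
    return lhs > rhs


def merge_pass(graph: Graph, state: LabelState, params: MergeParams) -> LabelState:
    """Repeatedly absorb communities into denser-connected neighbours.

    Targets are scanned in ascending size (small fragments first); for each
    target its neighbouring communities are tried in descending shared-link
    count.  The first neighbour passing the merge test absorbs the target.
    Scanning repeats until a full scan performs no merge.  Mutates and
    returns ``state``.
    """
    changed = True
    while changed:
        changed = False
        order = state.sorted_cids(key=lambda c: (len(state.communities[c]), c))
        for a in order:
            if a not in state.communities:
                continue
            inter: Counter[int] = Counter()
            for u in state.communities[a]:
                for w in graph.adj[u]:
                    lb = state.label[w]
                    if lb is not SOLO and lb != a:
                        inter[lb] += 1
            if not inter:
                continue
            stats_a = community_stats(state, a)
            for b in sorted(inter, key=lambda c: (-inter[c], c)):
                if should_merge(stats_a, inter[b], community_stats(state, b), params):
                    state.merge_into(a, b)
                    changed = True
                    break
    return state
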