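"""Constrained label propagation (CLPA 1-7) and grouped-node reallocation
(GNR 1-5), plus the classic randomised LPA as a baseline.

Every pass here is deterministic: update sequences are fixed by degree and,
as a final key, by canonical node order; ties between communities are
resolved by acceptance capability and then by smallest community
identifier.  The CLPA passes only ever turn solo nodes into members
(progressively relaxing their admission condition); the GNR passes refine
existing memberships by switching or evicting members.
"""

from __future__ import annotations

import random
import zlib
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .community import (
    SOLO,
    LabelState,
    condition_satisfied,
)
from .graph import Graph, Node, Partition
from .mns import MNSTable, build_mns_table

CLPA_VARIANTS = (1, 2, 3, 4, 5, 6, 7)
GNR_VARIANTS = (1, 2, 3, 4, 5)


class ConvergenceError(RuntimeError):
    """A pass hit its sweep cap without reaching a fixed point."""


@dataclass(frozen=True)
class PassConfig:
    variant: int
    max_sweeps: int = 0  # 0 = derive the default cap from graph size


def _default_cap(graph: Graph, max_sweeps: int | None) -> int:
    if max_sweeps:
        return max_sweeps
    return 100 * max(graph.n, 1)


def _capability(graph: Graph, state: LabelState, v: Node, cid: int) -> Fraction:
    """Acceptance capability as an exact rational, for tie detection."""
    total = Fraction(0)
    members = state.communities[cid]
    for u in graph.adj[v]:
        if u in members:
            d = graph.degree(u)
            total += Fraction(d - state.member_intra[u], d)
    return total


def _grouped_votes(state: LabelState, v: Node) -> Counter:
    votes: Counter[int] = Counter()
    for u in state.graph.adj[v]:
        lb = state.label[u]
        if lb is not SOLO:
            votes[lb] += 1
    return votes


def _solo_neighbours(state: LabelState, cid: int) -> list[Node]:
    graph = state.graph
    seen: set[Node] = set()
    for u in state.communities[cid]:
        for v in graph.adj[u]:
            if state.label[v] is SOLO:
                seen.add(v)
    return sorted(seen, key=lambda v: (-graph.degree(v), graph.index[v]))


def _community_order(state: LabelState) -> list[int]:
    return state.sorted_cids(key=lambda c: (len(state.communities[c]), c))


# -- CLPA ------------------------------------------------------------------


def run_clpa(
    graph: Graph,
    state: LabelState,
    variant: int,
    mns: MNSTable | None = None,
    max_sweeps: int | None = None,
) -> LabelState:
    """One CLPA pass, swept to convergence.  Mutates and returns ``state``.

    Variants 1/2/5 sweep communities smallest-first and consider each
    community's solo neighbours in descending degree; variants 3/4/7 sweep
    solo nodes in descending degree and send each to the community holding
    the plurality of its grouped neighbours; variant 6 sweeps grouped nodes
    by number of solo neighbours and admits positive-MNS solo neighbours.
    The admission conditions tighten or relax per variant (see
    ``condition_satisfied``); variant 5 additionally requires a strict
    modularity gain, treating solo nodes as singleton communities.
    """
    if variant not in CLPA_VARIANTS:
        raise ValueError(f"unknown CLPA variant {variant}")
    cap = _default_cap(graph, max_sweeps)
    if variant == 6 and mns is None:
        mns = build_mns_table(graph)
    m = graph.m

    for _ in range(cap):
        changed = False
        if variant in (1, 2):
            cond = variant  # condition 1 or 2
            for cid in _community_order(state):
                if cid not in state.communities:
                    continue
                for v in _solo_neighbours(state, cid):
                    if state.label[v] is SOLO and condition_satisfied(
                        graph, state, v, cid, cond
                    ):
                        state.assign(v, cid)
                        changed = True
        elif variant in (3, 4, 7):
            cond = 3 if variant in (3, 4) else 4
            order = sorted(
                state.solo_nodes(),
                key=lambda v: (-graph.degree(v), graph.index[v]),
            )
            for v in order:
                if state.label[v] is not SOLO:
                    continue
                votes = _grouped_votes(state, v)
                if not votes:
                    continue
                top = max(votes.values())
                tops = sorted(c for c, k in votes.items() if k == top)
                if len(tops) > 1:
                    if variant == 3:
                        continue  # ties block CLPA3
                    caps = {c: _capability(graph, state, v, c) for c in tops}
                    best = max(caps.values())
                    bests = [c for c in tops if caps[c] == best]
                    if len(bests) > 1:
                        continue
                    cand = bests[0]
                else:
                    cand = tops[0]
                if condition_satisfied(graph, state, v, cand, cond):
                    state.assign(v, cand)
                    changed = True
        elif variant == 5:
            for cid in _community_order(state):
                if cid not in state.communities:
                    continue
                for v in _solo_neighbours(state, cid):
                    if state.label[v] is not SOLO:
                        continue
                    votes = _grouped_votes(state, v)
                    if not votes:
                        continue
                    top = max(votes.values())
                    tops = sorted(c for c, k in votes.items() if k == top)
                    if len(tops) > 1:
                        continue
                    cand = tops[0]
                    if not condition_satisfied(graph, state, v, cand, 3):
                        continue
                    # modularity gain of moving singleton v into cand:
                    # dQ = l/m - d_v * D_c / (2 m^2)  (solo nodes = singletons)
                    links = state.links_into(v, cand)
                    d_c = sum(graph.degree(u) for u in state.communities[cand])
                    gain = Fraction(links, m) - Fraction(
                        graph.degree(v) * d_c, 2 * m * m
                    )
                    if gain > 0:
                        state.assign(v, cand)
                        changed = True
        else:  # variant 6
            order = sorted(
                (g for g in graph.nodes if state.label[g] is not SOLO),
                key=lambda g: (
                    -sum(1 for u in graph.adj[g] if state.label[u] is SOLO),
                    graph.index[g],
                ),
            )
            for g in order:
                cid = state.label[g]
                if cid is SOLO:
                    continue
                solos = sorted(
                    (u for u in graph.adj[g] if state.label[u] is SOLO),
                    key=lambda u: (-graph.degree(u), graph.index[u]),
                )
                for v in solos:
                    if state.label[v] is SOLO and mns.score(g, v) > 0 and (
                        condition_satisfied(graph, state, v, cid, 4)
                    ):
                        state.assign(v, cid)
                        changed = True
        if not changed:
            return state
    raise ConvergenceError(f"CLPA {variant} did not converge within {cap} sweeps")


# -- GNR -------------------------------------------------------------------


def dual_removal(state: LabelState) -> LabelState:
    """Dissolve every two-node community; both members turn solo."""
    for cid in state.sorted_cids():
        members = state.communities.get(cid)
        if members is not None and len(members) == 2:
            for v in state.graph.sorted_nodes(tuple(members)):
                state.remove(v)
    return state


def _quartile_prune(state: LabelState) -> None:
    """Evict members whose intra-link count sits below their community's Q1.

    Decisions use a snapshot of the intra-link multiset taken before any
    eviction in the community, so the pruning is a single one-shot pass.
    """
    graph = state.graph
    for cid in state.sorted_cids():
        members = graph.sorted_nodes(state.communities[cid])
        counts = {v: state.member_intra[v] for v in members}
        q1 = float(np.percentile(list(counts.values()), 25))
        for v in members:
            if counts[v] < q1:
                state.remove(v)


def _reallocate_node(
    graph: Graph,
    state: LabelState,
    v: Node,
    condition: int,
    remove_on_fail: bool,
    allow_tie: bool,
) -> tuple[bool, bool]:
    """Apply the three reallocation situations to one grouped node.

    Returns (changed, deferred): ``deferred`` means the node is in the
    tied-plurality situation and ``allow_tie`` was False.
    """
    own = state.label[v]
    votes = _grouped_votes(state, v)
    if not votes:
        return False, False
    top = max(votes.values())
    tops = sorted(c for c, k in votes.items() if k == top)
    if len(tops) == 1:
        cand = tops[0]
        if cand == own:
            return False, False  # situation 1: plurality agrees with label
        # situation 2: another community holds the plurality
        if condition_satisfied(graph, state, v, cand, condition):
            state.move(v, cand)
            return True, False
        if remove_on_fail:
            state.remove(v)
            return True, False
        return False, False
    # situation 3: tied plurality
    if not allow_tie:
        return False, True
    caps = {c: _capability(graph, state, v, c) for c in tops}
    best = max(caps.values())
    bests = [c for c in tops if caps[c] == best]
    if len(bests) > 1:
        if remove_on_fail:
            state.remove(v)
            return True, False
        return False, False
    cand = bests[0]
    if cand == own:
        return False, False
    if condition_satisfied(graph, state, v, cand, condition):
        state.move(v, cand)
        return True, False
    if remove_on_fail:
        state.remove(v)
        return True, False
    return False, False


def run_gnr(
    graph: Graph,
    state: LabelState,
    variant: int,
    max_sweeps: int | None = None,
) -> LabelState:
    """One GNR pass, swept to convergence.  Mutates and returns ``state``.

    GNR1 first prunes, once, every member whose intra-link count falls
    below its community's first quartile.  All variants then run the
    situation loop: grouped nodes in ascending degree either keep their
    label (their own label is the strict plurality of their grouped
    neighbours), switch to the plurality community if the variant's
    condition holds, or — in the eviction variants 1-3 — are removed to
    solo.  Tied pluralities are settled by acceptance capability and are
    handled only after all untied nodes, each sweep.  Variants 1-4 dissolve
    two-node communities after every sweep; variant 5 leaves them be.
    """
    if variant not in GNR_VARIANTS:
        raise ValueError(f"unknown GNR variant {variant}")
    if variant == 1:
        _quartile_prune(state)
    condition = 1 if variant in (1, 2) else 3
    remove_on_fail = variant <= 3
    dual = variant <= 4
    cap = _default_cap(graph, max_sweeps)

    # Reallocation can enter a short limit cycle (a node, or a few, flipping
    # between equally good placements every sweep).  A repeated label state
    # is detected by fingerprint and treated as convergence: the loop stops
    # at the first revisited state, which is itself deterministic.
    seen: set[int] = set()
    for _ in range(cap):
        fp = zlib.crc32(
            repr(sorted((v, state.label[v]) for v in graph.nodes)).encode()
        )
        if fp in seen:
            return state
        seen.add(fp)
        changed = False
        order = sorted(
            (v for v in graph.nodes if state.label[v] is not SOLO),
            key=lambda v: (graph.degree(v), graph.index[v]),
        )
        deferred: list[Node] = []
        for v in order:
            if state.label[v] is SOLO:
                continue
            did, defer = _reallocate_node(
                graph, state, v, condition, remove_on_fail, allow_tie=False
            )
            changed |= did
            if defer:
                deferred.append(v)
        for v in deferred:
            if state.label[v] is SOLO:
                continue
            did, _ = _reallocate_node(
                graph, state, v, condition, remove_on_fail, allow_tie=True
            )
            changed |= did
        if dual:
            before = len(state.communities)
            dual_removal(state)
            changed |= len(state.communities) != before
        if not changed:
            return state
    raise ConvergenceError(f"GNR {variant} did not converge within {cap} sweeps")


# -- baseline randomised LPA ----------------------------------------------


def run_simple_lpa(graph: Graph, seed: int, max_sweeps: int | None = None) -> Partition:
    """Classic asynchronous label propagation with seeded randomness.

    Update order is reshuffled each sweep and ties between equally frequent
    neighbour labels are broken uniformly at random.  Stops once every
    node's label is among its neighbours' most frequent labels.  Distinct
    seeds generally give distinct partitions — this is the instability the
    constrained pipeline is designed to remove, kept here for comparison.
    """
    rng = random.Random(seed)
    label: dict[Node, int] = {v: i for i, v in enumerate(graph.nodes)}
    cap = _default_cap(graph, max_sweeps)
    for _ in range(cap):
        order = list(graph.nodes)
        rng.shuffle(order)
        changed = False
        for v in order:
            if not graph.adj[v]:
                continue
            votes = Counter(label[u] for u in graph.adj[v])
            top = max(votes.values())
            tops = sorted(c for c, k in votes.items() if k == top)
            if label[v] not in tops:
                label[v] = rng.choice(tops)
                changed = True
        if not changed:
            return Partition.from_assignment(label, graph)
    raise ConvergenceError(f"simple LPA did not converge within {cap} sweeps")
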