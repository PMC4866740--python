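"""End-to-end deterministic community detection.

The pipeline has six parts:

1. every node starts solo (a unique latent label);
2. seed groups from mutual-neighbour scores, merge them at alpha = 1 and
   refine with GNR 1;
3. admit solo nodes through CLPA 1, 2 and 3, each followed by a
   reallocation pass (GNR 2 on the first execution, GNR 3 after part 4);
4. if at least ``subgraph_threshold`` solo nodes remain, run parts 1-3 on
   the subgraph they induce, import the communities found there, and
   repeat part 3 on the full graph;
5. admit stragglers with the relaxed passes CLPA 4, 5, 6, 7 (each followed
   by GNR 4); any node still solo joins the adjacent community with the
   highest acceptance capability, or becomes a singleton community;
6. merge communities at alpha descending from 1.0 to 0.1, refining with
   the final GNR after each step, and keep the best-modularity state seen.

Every stage is deterministic, so identical graphs — regardless of edge
list order — yield byte-identical membership tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .community import SOLO, LabelState, MergeParams, merge_pass
from .community import acceptance_capability
from .graph import Graph, Partition
from .metrics import modularity
from .mns import build_mns_table, seed_groups
from .propagation import run_clpa, run_gnr


@dataclass(frozen=True)
class PipelineOptions:
    """Tunable pipeline parameters (defaults reproduce the reference setup)."""

    subgraph_threshold: int = 10
    alpha_grid: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)
    final_gnr_variant: int = 5
    part5_clpa_sequence: tuple[int, ...] = (4, 5, 6, 7)

    def __post_init__(self):
        if self.subgraph_threshold < 1:
            raise ValueError("subgraph_threshold must be >= 1")
        grid = self.alpha_grid
        if any(not (0 < a <= 1) for a in grid) or any(
            a2 >= a1 for a1, a2 in zip(grid, grid[1:])
        ):
            raise ValueError("alpha_grid must be strictly decreasing within (0, 1]")
        if self.final_gnr_variant not in (4, 5):
            raise ValueError("final GNR must be a non-evicting variant (4 or 5)")


@dataclass(frozen=True)
class StageSnapshot:
    stage: str
    n_communities: int
    n_solo: int
    q: float


@dataclass(frozen=True)
class PipelineResult:
    partition: Partition
    modularity: float
    trace: tuple[StageSnapshot, ...] = field(repr=False)

    @property
    def n_communities(self) -> int:
        return self.partition.n_communities


def trivial_detection(partition: Partition) -> bool:
    """True when the whole network collapsed into a single community."""
    return partition.n_communities == 1


def _interim_q(graph: Graph, state: LabelState) -> float:
    """Modularity of the current state, solo nodes as singleton communities."""
    assignment: dict = {}
    for v in graph.nodes:
        c = state.label[v]
        assignment[v] = ("c", c) if c is not SOLO else ("s", v)
    return modularity(graph, Partition.from_assignment(assignment, graph))


def _part_3(graph: Graph, state: LabelState, gnr_variant: int) -> None:
    for clpa_variant in (1, 2, 3):
        run_clpa(graph, state, clpa_variant)
        run_gnr(graph, state, gnr_variant)


def _parts_1_3(graph: Graph) -> LabelState:
    # part 1 (all nodes solo) is the initial LabelState inside seed_groups
    state = seed_groups(graph, build_mns_table(graph))
    merge_pass(graph, state, MergeParams(alpha=1.0))
    run_gnr(graph, state, 1)
    _part_3(graph, state, gnr_variant=2)
    return state


def detect_communities(
    graph: Graph, options: PipelineOptions | None = None
) -> PipelineResult:
    """Run the full six-part pipeline and return the best partition found."""
    if graph.n == 0:
        raise ValueError("cannot detect communities in an empty graph")
    opts = options or PipelineOptions()
    trace: list[StageSnapshot] = []

    def snap(stage: str, state: LabelState) -> None:
        trace.append(
            StageSnapshot(
                stage=stage,
                n_communities=len(state.communities),
                n_solo=state.n_solo(),
                q=_interim_q(graph, state),
            )
        )

    # parts 1-3
    state = _parts_1_3(graph)
    snap("parts1-3", state)

    # part 4: recurse on the solo subgraph once, then repeat part 3
    solo = state.solo_nodes()
    if len(solo) >= opts.subgraph_threshold:
        sub = graph.induced_subgraph(solo)
        sub_state = _parts_1_3(sub)
        for cid in sub_state.sorted_cids():
            members = sub_state.communities[cid]
            state.new_community(members)
        _part_3(graph, state, gnr_variant=3)
        snap("part4", state)

    # part 5: relaxed admission, then capability fallback
    if state.n_solo():
        mns = build_mns_table(graph)
        for clpa_variant in opts.part5_clpa_sequence:
            run_clpa(graph, state, clpa_variant, mns=mns)
            run_gnr(graph, state, 4)
        for v in state.solo_nodes():
            if state.label[v] is not SOLO:
                continue
            cids = sorted(
                {
                    state.label[u]
                    for u in graph.adj[v]
                    if state.label[u] is not SOLO
                }
            )
            if not cids:
                state.new_community([v])
                continue
            caps = {c: acceptance_capability(graph, state, v, c) for c in cids}
            best = max(caps.values())
            chosen = min(c for c in cids if caps[c] == best)
            state.assign(v, chosen)
        snap("part5", state)

    # safety: any remaining solo node (isolated nodes) becomes a singleton
    for v in state.solo_nodes():
        state.new_community([v])

    # part 6: descending-alpha merge sweep, keep the best-Q state
    best_state = state.copy()
    best_q = modularity(graph, state.to_partition())
    snap("pre-part6", state)
    for alpha in opts.alpha_grid:
        merge_pass(graph, state, MergeParams(alpha=alpha))
        run_gnr(graph, state, opts.final_gnr_variant)
        for v in state.solo_nodes():  # final GNR variant 4 may evict via duals
            state.new_community([v])
        q = modularity(graph, state.to_partition())
        snap(f"part6 alpha={alpha:.1f}", state)
        if q < best_q:
            state = best_state
            break
        best_q = q
        best_state = state.copy()

    partition = best_state.to_partition()
    q_final = modularity(graph, partition)
    trace.append(
        StageSnapshot(
            stage="final",
            n_communities=partition.n_communities,
            n_solo=0,
            q=q_final,
        )
    )
    return PipelineResult(partition=partition, modularity=q_final, trace=tuple(trace))
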