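import random

import pytest
from hypothesis import given, settings, strategies as st

from clpagnr.community import (
    LabelState,
    MergeParams,
    acceptance_capability,
    community_stats,
    condition_satisfied,
    merge_pass,
    node_capacity,
    should_merge,
)
from clpagnr.examples import capacity_example, merge_example
from clpagnr.graph import Graph
from .conftest import random_graph


class TestLabelState:
    def test_assign_remove_move_keep_stats_consistent(self, two_cliques):
        state = LabelState(two_cliques)
        c1 = state.new_community(list("abcd"))
        c2 = state.new_community(list("efg"))
        state.check_consistent()
        state.remove("d")
        state.check_consistent()
        state.assign("d", c2)
        state.check_consistent()
        state.move("d", c1)
        state.check_consistent()
        assert state.label["d"] == c1

    def test_empty_community_deleted_on_last_removal(self, triangle):
        state = LabelState(triangle)
        c = state.new_community(["a", "b"])
        state.remove("a")
        state.remove("b")
        assert c not in state.communities

    def test_merge_into_updates_member_intra(self, two_cliques):
        state = LabelState(two_cliques)
        a = state.new_community(list("abcd"))
        b = state.new_community(list("efgh"))
        state.merge_into(a, b)
        state.check_consistent()
        assert len(state.communities) == 1
        # bridge d-e became intra after the merge
        assert state.member_intra["d"] == 4

    def test_stats_equal_recount_after_random_mutations(self):
        g = random_graph(30, 0.25, seed=2)
        state = LabelState(g)
        rng = random.Random(9)
        cids = [state.new_community([str(i), str(i + 1)]) for i in (0, 2, 4, 6)]
        for _ in range(200):
            v = str(rng.randrange(30))
            if state.label[v] is None:
                state.assign(v, rng.choice(cids))
            elif rng.random() < 0.5:
                state.remove(v)
            else:
                target = rng.choice(cids)
                if target in state.communities and state.label[v] != target:
                    state.move(v, target)
            cids = [c for c in cids if c in state.communities]
            if not cids:
                cids = [state.new_community([v])] if state.label[v] is None else cids
            state.check_consistent()


class TestCapacity:
    def test_worked_capacities(self):
        graph, state, j, c1, c2 = capacity_example()
        assert node_capacity(graph, state, "K") == pytest.approx(0.500)
        assert node_capacity(graph, state, "N") == pytest.approx(4 / 12)
        assert acceptance_capability(graph, state, j, c1) == pytest.approx(1.0625)
        assert acceptance_capability(graph, state, j, c2) == pytest.approx(0.9583, abs=1e-4)

    def test_fully_internal_node_has_zero_capacity(self, triangle):
        state = LabelState(triangle)
        state.new_community(["a", "b", "c"])
        assert node_capacity(triangle, state, "a") == 0.0

    def test_capability_zero_without_neighbours_in_community(self):
        g = Graph.from_edges([("a", "b"), ("c", "d")])
        state = LabelState(g)
        c = state.new_community(["c", "d"])
        assert acceptance_capability(g, state, "a", c) == 0.0

    def test_capacity_bounded_in_unit_interval(self):
        g = random_graph(25, 0.3, seed=4)
        state = LabelState(g)
        state.new_community([str(i) for i in range(10)])
        for i in range(10):
            assert 0.0 <= node_capacity(g, state, str(i)) <= 1.0


class TestConditions:
    def test_triangle_q2(self, triangle):
        g = Graph.from_edges(
            [("a", "b"), ("b", "c"), ("c", "a"), ("s", "a"), ("s", "b")]
        )
        state = LabelState(g)
        c = state.new_community(["a", "b", "c"])
        # l = 2 against q = 2
        assert not condition_satisfied(g, state, "s", c, 1)
        assert condition_satisfied(g, state, "s", c, 2)
        assert condition_satisfied(g, state, "s", c, 3)
        assert condition_satisfied(g, state, "s", c, 4)

    def test_no_links_fails_everything(self):
        g = Graph.from_edges([("a", "b"), ("x", "y"), ("a", "x")])
        state = LabelState(g)
        c = state.new_community(["a", "b"])
        for cond in (1, 2, 3, 4):
            assert not condition_satisfied(g, state, "y", c, cond)

    def test_seeded_pair_q1(self):
        g = Graph.from_edges([("a", "b"), ("s", "a")])
        state = LabelState(g)
        c = state.new_community(["a", "b"])
        # l = 1 against q = 1: exact halving, no rounding
        assert not condition_satisfied(g, state, "s", c, 1)
        assert condition_satisfied(g, state, "s", c, 2)
        assert condition_satisfied(g, state, "s", c, 3)
        assert condition_satisfied(g, state, "s", c, 4)

    def test_unknown_condition_rejected(self, triangle):
        state = LabelState(triangle)
        c = state.new_community(["a", "b", "c"])
        with pytest.raises(ValueError):
            condition_satisfied(triangle, state, "a", c, 5)


class TestShouldMerge:
    def test_worked_ratio_triggers_merge(self):
        graph, state, a, b = merge_example()
        stats_a = community_stats(state, a)
        stats_b = community_stats(state, b)
        assert 16 / 7 == pytest.approx(2.286, abs=5e-4)
        assert should_merge(stats_a, 16, stats_b, MergeParams(alpha=1.0))

    def test_equal_densities_do_not_merge(self):
        graph, state, a, b = merge_example()
        stats_a = community_stats(state, a)
        # inter/size_b == intra_a/size_a == 2 exactly: strict inequality
        assert not should_merge(stats_a, 14, community_stats(state, b), MergeParams(1.0))

    def test_zero_inter_links_never_merge(self):
        graph, state, a, b = merge_example()
        assert not should_merge(
            community_stats(state, a), 0, community_stats(state, b), MergeParams(0.1)
        )

    @given(st.integers(0, 40), st.sampled_from([0.1, 0.3, 0.5, 0.7, 0.9, 1.0]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_alpha(self, inter, alpha):
        graph, state, a, b = merge_example()
        stats_a = community_stats(state, a)
        stats_b = community_stats(state, b)
        if should_merge(stats_a, inter, stats_b, MergeParams(alpha)):
            for lower in (0.05, alpha / 2, alpha * 0.9):
                assert should_merge(stats_a, inter, stats_b, MergeParams(lower))


class TestMergePass:
    def test_worked_pair_is_absorbed(self):
        graph, state, a, b = merge_example()
        merge_pass(graph, state, MergeParams(alpha=1.0))
        state.check_consistent()
        assert len(state.communities) == 1

    def test_bridged_cliques_stay_separate(self, two_cliques):
        state = LabelState(two_cliques)
        state.new_community(list("abcd"))
        state.new_community(list("efgh"))
        merge_pass(two_cliques, state, MergeParams(alpha=1.0))
        assert len(state.communities) == 2

    def test_single_community_unchanged(self, triangle):
        state = LabelState(triangle)
        state.new_community(["a", "b", "c"])
        merge_pass(triangle, state, MergeParams(alpha=0.5))
        assert len(state.communities) == 1

    def test_deterministic(self):
        g = random_graph(40, 0.15, seed=6)
        runs = []
        for _ in range(2):
            state = LabelState(g)
            for i in range(0, 40, 5):
                state.new_community([str(i + k) for k in range(5)])
            merge_pass(g, state, MergeParams(alpha=0.5))
            runs.append(dict(state.label))
        assert runs[0] == runs[1]
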