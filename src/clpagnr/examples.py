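"""Small hand-constructed scenarios used in documentation and tests."""

from __future__ import annotations

from .community import LabelState
from .graph import Graph, Node


def capacity_example() -> tuple[Graph, LabelState, Node, int, int]:
    """The four-neighbour capacity scenario.

    A solo node J touches two communities through two members each:
    C1 via K (5 of 10 links inter-community) and L (9 of 16), C2 via
    M (5 of 8) and N (4 of 12).  The acceptance capabilities work out to
    0.5 + 0.5625 = 1.0625 for C1 and 0.625 + 0.333... = 0.9583 for C2,
    so a capability tie-break sends J into C1.

    Returns (graph, state, "J", c1, c2).
    """
    edges: list[tuple[str, str]] = []
    # C1 members: K, L, P1..P6.  K intra = 5 (L, P1..P4); L intra = 7.
    c1_members = ["K", "L"] + [f"P{i}" for i in range(1, 7)]
    edges.append(("K", "L"))
    edges += [("K", f"P{i}") for i in range(1, 5)]
    edges += [("L", f"P{i}") for i in range(1, 7)]
    # K degree 10: 5 inter (J plus 4 solo fillers)
    edges.append(("K", "J"))
    edges += [("K", f"X{i}") for i in range(1, 5)]
    # L degree 16: 9 inter (J plus 8 solo fillers)
    edges.append(("L", "J"))
    edges += [("L", f"Y{i}") for i in range(1, 9)]
    # C2 members: M, N, Q1..Q7.  M intra = 3 (N, Q1, Q2); N intra = 8.
    c2_members = ["M", "N"] + [f"Q{i}" for i in range(1, 8)]
    edges.append(("M", "N"))
    edges += [("M", f"Q{i}") for i in range(1, 3)]
    edges += [("N", f"Q{i}") for i in range(1, 8)]
    # M degree 8: 5 inter; N degree 12: 4 inter
    edges.append(("M", "J"))
    edges += [("M", f"Z{i}") for i in range(1, 5)]
    edges.append(("N", "J"))
    edges += [("N", f"W{i}") for i in range(1, 4)]

    graph = Graph.from_edges(edges)
    state = LabelState(graph)
    c1 = state.new_community(c1_members)
    c2 = state.new_community(c2_members)

    assert graph.degree("K") == 10 and state.member_intra["K"] == 5
    assert graph.degree("L") == 16 and state.member_intra["L"] == 7
    assert graph.degree("M") == 8 and state.member_intra["M"] == 3
    assert graph.degree("N") == 12 and state.member_intra["N"] == 8
    return graph, state, "J", c1, c2


def merge_example() -> tuple[Graph, LabelState, int, int]:
    """Two groups with the worked merge ratio 16/7 = 2.286 > 10/5 = 2.

    Group A: 5 nodes, 10 intra links (the 5-clique).  Group B: 7 nodes,
    10 intra links.  16 links run between them, so at alpha = 1 group A
    is absorbed into group B.  Returns (graph, state, a, b).
    """
    a_members = [f"a{i}" for i in range(5)]
    b_members = [f"b{i}" for i in range(7)]
    edges = [
        (a_members[i], a_members[j])
        for i in range(5)
        for j in range(i + 1, 5)
    ]
    b_pairs = [
        (b_members[i], b_members[j]) for i in range(7) for j in range(i + 1, 7)
    ]
    edges += b_pairs[:10]
    cross = [(x, y) for x in a_members for y in b_members]
    edges += cross[:16]
    graph = Graph.from_edges(edges)
    state = LabelState(graph)
    a = state.new_community(a_members)
    b = state.new_community(b_members)
    assert state.intra_links(a) == 10 and state.intra_links(b) == 10
    return graph, state, a, b
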