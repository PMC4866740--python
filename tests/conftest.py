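import io
import random
from pathlib import Path

import pytest

from clpagnr.graph import Graph, read_edge_list

DATA = Path(__file__).parent / "data"


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def two_cliques() -> Graph:
    """Two 4-cliques joined by a single bridge edge d-e."""
    abcd = [(u, v) for u in "abcd" for v in "abcd" if u < v]
    efgh = [(u, v) for u in "efgh" for v in "efgh" if u < v]
    return Graph.from_edges(abcd + efgh + [("d", "e")])


@pytest.fixture(scope="session")
def karate() -> Graph:
    with open(DATA / "karate.edgelist") as fh:
        return read_edge_list(fh)


def random_graph(n: int, p: float, seed: int) -> Graph:
    """Erdos-Renyi graph used as an unstructured test input."""
    rng = random.Random(seed)
    edges = [
        (str(i), str(j))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Graph.from_edges(edges, extra_nodes=[str(i) for i in range(n)])


@pytest.fixture
def er_graph() -> Graph:
    return random_graph(20, 0.3, seed=7)


def as_stream(lines) -> io.StringIO:
    return io.StringIO("\n".join(lines) + "\n")
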