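import itertools
import random

import pytest

from structent import WeightedGraph


def make_path_abc() -> WeightedGraph:
    g = WeightedGraph()
    g.add_edge("a", "b", 1.0)
    g.add_edge("b", "c", 1.0)
    return g


def make_k4() -> WeightedGraph:
    g = WeightedGraph()
    for u, v in itertools.combinations("abcd", 2):
        g.add_edge(u, v, 1.0)
    return g


def make_bridged_triangles() -> WeightedGraph:
    """Two unit triangles a-b-c and d-e-f joined by the bridge c-d."""
    g = WeightedGraph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]:
        g.add_edge(u, v, 1.0)
    g.add_edge("c", "d", 1.0)
    return g


def make_bridged_cliques(size: int = 5) -> WeightedGraph:
    """Two unit cliques of ``size`` vertices joined by the bridge a0-b0."""
    g = WeightedGraph()
    for i, j in itertools.combinations(range(size), 2):
        g.add_edge(f"a{i}", f"a{j}", 1.0)
    for i, j in itertools.combinations(range(size), 2):
        g.add_edge(f"b{i}", f"b{j}", 1.0)
    g.add_edge("a0", "b0", 1.0)
    return g


def make_triangle_pendant() -> WeightedGraph:
    """Unit triangle a-b-c with a pendant vertex d attached to c."""
    g = WeightedGraph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]:
        g.add_edge(u, v, 1.0)
    return g


def random_connected_graph(rng: random.Random, n: int, p: float = 0.5) -> WeightedGraph:
    """Random weighted graph with a random spanning tree forced in."""
    labels = [f"v{i}" for i in range(n)]
    g = WeightedGraph(labels)
    present = set()
    order = list(range(1, n))
    rng.shuffle(order)
    for i in order:
        j = rng.randrange(i)
        present.add((j, i))
    for i, j in itertools.combinations(range(n), 2):
        if (i, j) not in present and rng.random() < p:
            present.add((i, j))
    for i, j in sorted(present):
        g.add_edge(labels[i], labels[j], rng.uniform(0.2, 2.0))
    return g


@pytest.fixture
def path_abc():
    return make_path_abc()


@pytest.fixture
def k4():
    return make_k4()


@pytest.fixture
def bridged_triangles():
    return make_bridged_triangles()


@pytest.fixture
def triangle_pendant():
    return make_triangle_pendant()
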