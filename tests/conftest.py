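import numpy as np
import pytest

from focs.graph import BipartiteCommunity, Community, Graph


@pytest.fixture
def five_cycle():
    """Cycle 1-2-3-4-5-1."""
    return Graph([("1", "2"), ("2", "3"), ("3", "4"), ("4", "5"), ("5", "1")])


@pytest.fixture
def clique_plus_clique():
    """Two disconnected 4-cliques."""
    edges = []
    for block in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((block[i], block[j]))
    return Graph(edges)


@pytest.fixture
def toy_graph():
    """Small irregular multigraph used across modules."""
    return Graph([
        ("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"),
        ("e", "f"), ("f", "d"), ("b", "e"), ("a", "f", 2),
    ])


@pytest.fixture
def random_graph_20():
    """Fixed 20-node Erdos-Renyi-ish multigraph (seeded)."""
    rng = np.random.default_rng(7)
    nodes = [f"v{i:02d}" for i in range(20)]
    edges = []
    for i in range(20):
        for j in range(i + 1, 20):
            if rng.random() < 0.25:
                edges.append((nodes[i], nodes[j], int(rng.integers(1, 3))))
    return Graph(edges, nodes=nodes)


@pytest.fixture
def bipartite_graph():
    """Small two-sided graph: u-side u0..u4, v-side w0..w3."""
    edges = [
        ("u0", "w0"), ("u0", "w1"), ("u1", "w0"), ("u1", "w1"),
        ("u2", "w1"), ("u2", "w2"), ("u3", "w2"), ("u3", "w3"),
        ("u4", "w3"), ("u4", "w0", 2),
    ]
    side = {f"u{i}": "U" for i in range(5)} | {f"w{i}": "V" for i in range(4)}
    return Graph(edges, side=side)


def random_small_graph(rng, n_max=12):
    n = int(rng.integers(4, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                edges.append((nodes[i], nodes[j], int(rng.integers(1, 4))))
    return Graph(edges, nodes=nodes)


def random_community(graph, rng):
    nodes = sorted(graph.nodes)
    k = int(rng.integers(2, len(nodes)))
    members = rng.choice(nodes, size=k, replace=False)
    return Community(frozenset(members.tolist()), id="rand")
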