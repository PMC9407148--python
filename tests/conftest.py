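import numpy as np
import pytest

from zonebreak.network import Network


def network_from_edges(n_nodes, edges):
    return Network.from_edges(n_nodes, edges)


def random_small_network(rng: np.random.Generator, n_max: int = 50) -> Network:
    """A random G(n, p) graph with n in [2, n_max], for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.0, 0.6))
    adjacency = [[] for _ in range(n)]
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                adjacency[a].append(b)
                adjacency[b].append(a)
    return Network(n_nodes=n, adjacency=adjacency)


@pytest.fixture
def triangle():
    return network_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def triangle_with_pendant():
    return network_from_edges(4, [(0, 1), (1, 2), (0, 2), (2, 3)])


@pytest.fixture
def star_k13():
    return network_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def path5():
    return network_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
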