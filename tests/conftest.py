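import numpy as np
import pytest

from brainpred.types import BrainNetwork


def network_from_edges(n, edges, labels=None):
    labels = labels or [f"n{i}" for i in range(n)]
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BrainNetwork(labels=labels, adjacency=a)


def random_network(n, p, seed):
    """Erdos-Renyi G(n, p) as a BrainNetwork."""
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    a = a + a.T
    return BrainNetwork(labels=[f"n{i}" for i in range(n)], adjacency=a)


@pytest.fixture
def four_cycle():
    """a-b-c-d-a ring; nodes 0=a, 1=b, 2=c, 3=d."""
    return network_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def star4():
    """Star on 4 nodes: node 0 is the centre."""
    return network_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def path3():
    """Path a-b-c; nodes 0=a, 1=b, 2=c."""
    return network_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k4():
    return network_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def two_triangles():
    return network_from_edges(
        6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
    )
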