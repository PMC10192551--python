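import numpy as np
import pytest

from modcog.connectivity import ConnectivityMatrix


@pytest.fixture
def two_triangles() -> ConnectivityMatrix:
    """Two disjoint unweighted triangles: unique optimum at gamma=1, Q*=0.5."""
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return ConnectivityMatrix(a)


@pytest.fixture
def bridged_triangles() -> ConnectivityMatrix:
    """Two triangles joined by one bridge edge (connected graph)."""
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
        a[i, j] = a[j, i] = 1.0
    return ConnectivityMatrix(a)


def random_weighted_graph(rng, n_max=8, density=0.6):
    """Random small non-negative weighted graph with at least one edge."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), 1)
        w = w + w.T
        if w.sum() > 0:
            return ConnectivityMatrix(w)
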