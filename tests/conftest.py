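import numpy as np
import pytest

from adnetworks.netbuild import BrainNetwork


def net_from_edges(n, edges, prefix="R"):
    """BrainNetwork with n nodes and the given (i, j) edge list."""
    A = np.zeros((n, n), dtype=int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return BrainNetwork(A, [f"{prefix}{k:03d}" for k in range(n)])


def random_net(rng, n=None, p=None):
    """Random Erdos-Renyi BrainNetwork (possibly disconnected)."""
    n = n if n is not None else int(rng.integers(4, 9))
    p = p if p is not None else float(rng.uniform(0.2, 0.8))
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, k=1)
    A = A + A.T
    return BrainNetwork(A, [f"R{k:03d}" for k in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def path3():
    """a - b - c."""
    return net_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def star4():
    """Hub 0 with 4 spokes (K_{1,4})."""
    return net_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def complete5():
    return net_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
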