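import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_adjacency(rng, n, p=0.3):
    """Random symmetric binary adjacency with zero diagonal."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T


def random_distance(rng, n, box=100.0):
    """Euclidean distance matrix of n random points in a box (mm)."""
    X = rng.uniform(0, box, size=(n, 3))
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_geometry():
    """Static 30-node geometry shared by engine/evaluation tests."""
    from connectogen import DistanceSet

    r = np.random.default_rng(7)
    D = random_distance(r, 30)
    return DistanceSet.static(D)
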