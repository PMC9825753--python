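import numpy as np
import pytest

from phclust import CountMatrix, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_counts():
    """6 features x 6 samples (2 treatments x 3 replicates), mixed zeros."""
    counts = np.array([
        [5, 3, 4, 9, 12, 7],
        [0, 1, 0, 2, 0, 1],
        [10, 8, 14, 3, 2, 4],
        [0, 0, 0, 0, 0, 1],
        [2, 2, 3, 2, 3, 2],
        [7, 0, 5, 0, 6, 8],
    ])
    return CountMatrix(counts, np.array(["A", "A", "A", "B", "B", "B"]))


@pytest.fixture(scope="session")
def separated_dataset():
    """Strongly separated small benchmark: 3 clusters, no zero inflation."""
    cfg = SimulationConfig(n_features=150, n_clusters=3, eta_mu=3.0,
                           beta=0.0, scenario=2, phi=1.0, depth=10.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_small_dataset():
    """Default-style setting at reduced size for fast fitting tests."""
    cfg = SimulationConfig(n_features=150, seed=11)
    return simulate_dataset(cfg)


def random_instance(seed, G=6, I=2, J=3, zero_frac=0.35):
    """A small arbitrary count matrix plus random valid mixture weights."""
    r = np.random.default_rng(seed)
    N = I * J
    counts = r.poisson(5.0, size=(G, N))
    counts[r.random((G, N)) < zero_frac] = 0
    if not counts.any(axis=1).all():  # keep every sample/feature usable
        counts[~counts.any(axis=1), 0] = 1
    for n in range(N):
        if counts[:, n].sum() == 0:
            counts[0, n] = 2
    labels = np.repeat([chr(65 + i) for i in range(I)], J)
    return CountMatrix(counts, np.array(labels))
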