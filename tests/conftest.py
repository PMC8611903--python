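import numpy as np
import pytest

import geosurr as gs


@pytest.fixture(scope="session")
def benchmark():
    """Default 286-node purely geometric benchmark (fixed seed)."""
    g, truth = gs.make_benchmark(gs.SyntheticSpec(seed=42))
    return g, truth


@pytest.fixture(scope="session")
def planted_benchmark():
    """286-node benchmark with planted modules and peripheral hubs."""
    spec = gs.SyntheticSpec(
        seed=42,
        n_planted_modules=4,
        module_boost=1.0,
        hub_fraction=0.15,
        hub_boost=1.0,
    )
    return gs.make_benchmark(spec)


@pytest.fixture(scope="session")
def small_benchmark():
    """Fast 60-node benchmark for pipeline-level tests."""
    g, truth = gs.make_benchmark(gs.SyntheticSpec(n_nodes=60, seed=3))
    return g, truth


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 0.7) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.triu(W, k=1)
    return W + W.T
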