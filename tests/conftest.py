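import numpy as np
import pytest

from finehic import ReadCountMatrix, SimulationParams, simulate_true_if


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_rc(rng):
    """Small random symmetric count matrix."""
    n = 25
    upper = rng.poisson(2.0, size=(n, n))
    v = np.triu(upper) + np.triu(upper, 1).T
    return ReadCountMatrix(v)


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic chromosome shared across read-only tests."""
    return simulate_true_if(SimulationParams(n_fragments=120, seed=7))
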