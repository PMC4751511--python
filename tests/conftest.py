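import numpy as np
import pytest

from hdmice.data import IncompleteMatrix
from hdmice.simulation import SimConfig, calibrate_missingness


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_incomplete(rng):
    """A 30x5 matrix with missing cells scattered in the first two columns."""
    X = rng.standard_normal((30, 5))
    mask = np.ones_like(X, dtype=bool)
    mask[[0, 3, 7], 0] = False
    mask[[2, 5], 1] = False
    return IncompleteMatrix(np.where(mask, X, np.nan), mask)


@pytest.fixture(scope="session")
def calibrated_cfg():
    """Default scenario (n=100, p=200, q=4, rho=0.1) with calibrated logits."""
    return calibrate_missingness(SimConfig(seed=99))
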