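import numpy as np
import pytest

from motiondecomp import TrialMatrix, PerformanceVector, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def standardized_instance(rng):
    """A generic standardized 30x6 design with a planted linear signal."""
    x = rng.normal(size=(30, 6))
    w_true = rng.normal(size=6)
    d = x @ w_true + 0.1 * rng.normal(size=30)
    z, zd, xp, dp = standardize(TrialMatrix(x), PerformanceVector(d))
    return z, zd, xp, dp
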