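import numpy as np
import pytest

from palpkf.hc_model import STATE_DIM
from palpkf.ukf import ut_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def weights7():
    """Default unscented-transform weights for the 7-state contact filter."""
    return ut_weights(STATE_DIM)


def random_spd(rng, n, scale=1.0):
    """A random symmetric positive-definite matrix for covariance fixtures."""
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))
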