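import numpy as np
import pytest

from copulachain import BinomialSeries, MarginModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_series():
    """Hand-built 3-point series with n_t = 3 and two covariates."""
    return BinomialSeries(
        y=np.array([1, 2, 0]),
        n=np.array([3, 3, 3]),
        X=np.array([[1.0, 2.0], [1.0, 5.0], [1.0, 1.0]]),
    )


@pytest.fixture
def tiny_margin():
    return MarginModel([0.2, -0.1])


def make_series(y, n, X=None):
    y = np.asarray(y)
    n = np.asarray(n)
    if X is None:
        X = np.ones((y.size, 1))
    return BinomialSeries(y=y, n=n, X=np.asarray(X, dtype=float))
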