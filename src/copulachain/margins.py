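"""Binomial-logistic marginal model.

Linear predictor, success probability, pmf/CDF/quantile of the binomial
margin with heterogeneous trial counts. The CDF is computed through the
regularized incomplete beta function and the pmf through log-gamma
binomial coefficients, so trial counts of several hundred cost the same
as small ones.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "MarginModel",
    "BinomialSeries",
    "success_prob",
    "binom_pmf",
    "binom_cdf",
    "binom_ppf",
    "binom_logpmf",
]


@dataclasses.dataclass(frozen=True)
class MarginModel:
    """Logistic-regression coefficients (intercept first)."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if beta.ndim != 1 or beta.size < 1:
            raise ValueError("beta must be a 1-d vector with an intercept entry")
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta entries must be finite")
        object.__setattr__(self, "beta", beta)

    @property
    def n_covariates(self) -> int:
        return self.beta.size - 1

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.beta.size:
            raise ValueError(
                f"design has {X.shape[-1]} columns but beta has {self.beta.size} entries"
            )
        return X @ self.beta

    def probs(self, X) -> np.ndarray:
        """Success probability for each row of the design matrix."""
        return special.expit(self.linear_predictor(X))


@dataclasses.dataclass
class BinomialSeries:
    """Aligned observation vectors of a binomial time series.

    ``y[t]`` successes out of ``n[t]`` trials at time t, with design
    matrix ``X`` whose first column is the intercept.
    """

    y: np.ndarray
    n: np.ndarray
    X: np.ndarray
    covariate_names: tuple = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        n = np.asarray(self.n)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if np.any(y != np.floor(y)) or np.any(n != np.floor(n)):
            raise ValueError("y and n must be integer-valued")
        y = y.astype(np.int64)
        n = n.astype(np.int64)
        if y.shape != n.shape or y.ndim != 1:
            raise ValueError("y and n must be 1-d vectors of equal length")
        if y.size < 2:
            raise ValueError("a series needs at least T=2 time points")
        if X.shape[0] != y.size:
            raise ValueError("X must have one row per time point")
        if np.any(n < 1):
            raise ValueError("trial counts n must be >= 1")
        if np.any(y < 0) or np.any(y > n):
            bad = int(np.argmax((y < 0) | (y > n)))
            raise ValueError(f"y outside [0, n] at row {bad}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        if not self.covariate_names:
            self.covariate_names = tuple(f"x{j}" for j in range(1, X.shape[1]))
        self.y, self.n, self.X = y, n, X

    @property
    def T(self) -> int:
        return self.y.size

    @property
    def d(self) -> int:
        return self.X.shape[1] - 1

    def to_frame(self) -> pd.DataFrame:
        data = {"y": self.y, "n": self.n}
        for j, name in enumerate(self.covariate_names, start=1):
            data[name] = self.X[:, j]
        return pd.DataFrame(data)


def success_prob(margin: MarginModel, X_row) -> "float | np.ndarray":
    """Logistic success probability pi = expit(X beta); stable for |Xb| up to ~700."""
    out = margin.probs(X_row)
    return float(out) if np.ndim(out) == 0 else out


def binom_logpmf(y, n, pi) -> np.ndarray:
    """Log binomial pmf via log-gamma; vectorized, tolerant of y outside [0, n]."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    pi = np.asarray(pi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            special.gammaln(n + 1.0)
            - special.gammaln(y + 1.0)
            - special.gammaln(n - y + 1.0)
            + special.xlogy(y, pi)
            + special.xlog1py(n - y, -pi)
        )
    return np.where((y < 0) | (y > n) | (y != np.floor(y)), -np.inf, out)


def binom_pmf(y, n, pi) -> "float | np.ndarray":
    """Binomial pmf P(Y = y | n, pi)."""
    ya = np.asarray(y)
    na = np.asarray(n)
    if np.any(ya < 0) or np.any(ya > na):
        raise ValueError("y must lie in [0, n]")
    out = np.exp(binom_logpmf(ya, na, pi))
    return float(out) if np.ndim(out) == 0 else out


def binom_cdf(y, n, pi) -> "float | np.ndarray":
    """Binomial CDF with the conventions F(-1) = 0 and F(y >= n) = 1.

    The empty-sum convention at y = -1 is what makes the lower PIT bound
    of a zero count collapse to 0 in the rectangle probability.
    """
    scalar = np.ndim(y) == 0 and np.ndim(n) == 0 and np.ndim(pi) == 0
    y, n, pi = np.broadcast_arrays(
        np.atleast_1d(np.floor(np.asarray(y, dtype=float))),
        np.atleast_1d(np.asarray(n, dtype=float)),
        np.atleast_1d(np.asarray(pi, dtype=float)),
    )
    out = np.empty(y.shape, dtype=float)
    below = y < 0
    above = y >= n
    mid = ~(below | above)
    out[below] = 0.0
    out[above] = 1.0
    if np.any(mid):
        ym, nm, pm = y[mid], n[mid], pi[mid]
        # F(y) = I_{1-pi}(n - y, y + 1)
        out[mid] = special.betainc(nm - ym, ym + 1.0, 1.0 - pm)
    return float(out[0]) if scalar else out


def binom_ppf(p, n, pi) -> "int | np.ndarray":
    """Smallest integer y with F(y) >= p (generalized inverse CDF)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("binom_ppf requires 0 < p < 1")
    from scipy import stats

    out = stats.binom.ppf(p, np.asarray(n), np.asarray(pi)).astype(np.int64)
    return int(out) if np.ndim(out) == 0 else out
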