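"""Bivariate Archimedean copulas: Clayton, Gumbel and Frank.

Implements the closed-form CDF, density, conditional distribution
(h-function), inverse conditional distribution, Kendall-tau conversions
and tail-dependence coefficients for the three one-parameter families
used by the Markov-chain likelihood.

Conventions
-----------
* ``copula_hfun(spec, u, v)`` returns ``P(U <= u | V = v)``, i.e. the
  partial derivative of the CDF with respect to its second argument.
* Dependence parameters near the independence member (``alpha`` within
  ``1e-6`` of 0 for Clayton/Frank, of 1 for Gumbel) are evaluated as the
  product copula so that every formula degenerates cleanly instead of
  hitting 0/0.
* Potentially overflowing expressions (Gumbel powers, Frank
  exponentials) are evaluated in log space.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Tuple

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "CLAYTON",
    "GUMBEL",
    "FRANK",
    "FAMILIES",
    "CopulaSpec",
    "copula_cdf",
    "copula_density",
    "copula_hfun",
    "copula_hinv",
    "tau_to_param",
    "param_to_tau",
    "tail_dependence",
    "debye1",
]

CLAYTON = "clayton"
GUMBEL = "gumbel"
FRANK = "frank"
FAMILIES = (CLAYTON, GUMBEL, FRANK)

#: parameters closer than this to the independence member are treated as
#: exactly independent (product copula)
INDEPENDENCE_TOL = 1e-6


def _check_family(family: str) -> str:
    if family not in FAMILIES:
        raise ValueError(f"unknown copula family {family!r}; expected one of {FAMILIES}")
    return family


@dataclasses.dataclass(frozen=True)
class CopulaSpec:
    """A copula family tag plus its dependence parameter.

    Parameter domains: Clayton ``alpha > 0`` (positive-dependence
    branch), Gumbel ``alpha >= 1``, Frank any finite ``alpha`` with
    ``alpha -> 0`` the explicit independence limit.
    """

    family: str
    alpha: float

    def __post_init__(self) -> None:
        _check_family(self.family)
        alpha = float(self.alpha)
        if not math.isfinite(alpha):
            raise ValueError(f"copula parameter must be finite, got {alpha}")
        if self.family == CLAYTON and alpha <= 0 and abs(alpha) > INDEPENDENCE_TOL:
            raise ValueError(f"Clayton parameter must be > 0, got {alpha}")
        if self.family == GUMBEL and alpha < 1:
            raise ValueError(f"Gumbel parameter must be >= 1, got {alpha}")
        object.__setattr__(self, "alpha", alpha)

    @property
    def independent(self) -> bool:
        """True when the spec denotes (numerically) the product copula."""
        if self.family == GUMBEL:
            return self.alpha - 1.0 < INDEPENDENCE_TOL
        return abs(self.alpha) < INDEPENDENCE_TOL


# ---------------------------------------------------------------------------
# low-level numerics helpers
# ---------------------------------------------------------------------------


def _log_expm1(x: np.ndarray) -> np.ndarray:
    """log(e^x - 1) for x > 0 without overflow."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        small = np.log(np.expm1(np.minimum(x, 33.0)))
    return np.where(x > 33.0, x, small)


def _log_nexpm1(x: np.ndarray) -> np.ndarray:
    """log(1 - e^x) for x < 0, accurate for both tiny and large |x|."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        near = np.log(-np.expm1(np.maximum(x, -0.693)))
        far = np.log1p(-np.exp(np.minimum(x, -0.693)))
    return np.where(x > -0.693, near, far)


def _as_prob(x, name: str, *, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi) or np.any(np.isnan(arr)):
        raise ValueError(f"{name} must lie in [{lo}, {hi}]")
    return arr


def _maybe_scalar(out: np.ndarray, *inputs) -> "np.ndarray | float":
    if all(np.ndim(i) == 0 for i in inputs):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# CDF
# ---------------------------------------------------------------------------


def _clayton_logs(alpha: float, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """log(u^-a + v^-a - 1) computed stably (interior u, v)."""
    x1 = -alpha * np.log(u)
    x2 = -alpha * np.log(v)
    m = np.maximum(np.maximum(x1, x2), 0.0)
    return m + np.log(np.exp(x1 - m) + np.exp(x2 - m) - np.exp(-m))


def _gumbel_log_s(alpha: float, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """log[(-ln u)^a + (-ln v)^a] (interior u, v)."""
    lx = alpha * np.log(-np.log(u))
    ly = alpha * np.log(-np.log(v))
    return np.logaddexp(lx, ly)


def _frank_log_arg(alpha: float, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """log of the Frank CDF argument (e^-aC in essence), stable for all alpha.

    Writes the argument of the log in the Frank CDF as
    ``[e^a(1-e^b) + e^b(1-e^{c-b})] / (1-e^c)`` with ``a=-alpha*u``,
    ``b=-alpha*v``, ``c=-alpha``; both bracketed terms are positive, so
    there is no catastrophic cancellation for strong dependence.
    """
    a = -alpha * u
    b = -alpha * v
    c = -alpha
    if alpha > 0:
        log_num = np.logaddexp(a + _log_nexpm1(b), b + _log_nexpm1(c - b))
        log_den = _log_nexpm1(np.asarray(c))
    else:
        log_num = np.logaddexp(a + _log_expm1(b), b + _log_expm1(c - b))
        log_den = _log_expm1(np.asarray(c))
    return log_num - log_den


def copula_cdf(spec: CopulaSpec, u, v):
    """Evaluate C(u, v; alpha) with exact boundary handling."""
    uu = _as_prob(u, "u")
    vv = _as_prob(v, "v")
    uu, vv = np.broadcast_arrays(uu, vv)
    out = np.empty(uu.shape, dtype=float)

    zero = (uu == 0.0) | (vv == 0.0)
    u_one = (uu == 1.0) & ~zero
    v_one = (vv == 1.0) & ~zero
    interior = ~(zero | u_one | v_one)

    out[zero] = 0.0
    out[u_one] = vv[u_one]
    out[v_one] = uu[v_one]  # overrides u_one where both are 1 -> 1

    if np.any(interior):
        ui, vi = uu[interior], vv[interior]
        alpha = spec.alpha
        if spec.independent:
            ci = ui * vi
        elif spec.family == CLAYTON:
            ci = np.exp(-_clayton_logs(alpha, ui, vi) / alpha)
        elif spec.family == GUMBEL:
            ci = np.exp(-np.exp(_gumbel_log_s(alpha, ui, vi) / alpha))
        else:  # frank
            ci = -_frank_log_arg(alpha, ui, vi) / alpha
        out[interior] = ci
    return _maybe_scalar(out, u, v)


# ---------------------------------------------------------------------------
# density (diagnostics only; the discrete likelihood never needs it)
# ---------------------------------------------------------------------------


def copula_density(spec: CopulaSpec, u, v):
    """Copula density c(u, v; alpha) on the open unit square."""
    uu = _as_prob(u, "u")
    vv = _as_prob(v, "v")
    if np.any(uu <= 0.0) or np.any(uu >= 1.0) or np.any(vv <= 0.0) or np.any(vv >= 1.0):
        raise ValueError("copula_density requires 0 < u < 1 and 0 < v < 1")
    uu, vv = np.broadcast_arrays(uu, vv)
    alpha = spec.alpha

    if spec.independent:
        out = np.ones(uu.shape, dtype=float)
    elif spec.family == CLAYTON:
        logs = _clayton_logs(alpha, uu, vv)
        log_c = (
            np.log(alpha + 1.0)
            - (alpha + 1.0) * (np.log(uu) + np.log(vv))
            - (2.0 * alpha + 1.0) / alpha * logs
        )
        out = np.exp(log_c)
    elif spec.family == GUMBEL:
        log_s = _gumbel_log_s(alpha, uu, vv)
        w = np.exp(log_s / alpha)  # = S^(1/a)
        log_c = (
            -w
            - np.log(uu)
            - np.log(vv)
            + (alpha - 1.0) * (np.log(-np.log(uu)) + np.log(-np.log(vv)))
            + (2.0 / alpha - 2.0) * log_s
            + np.log1p((alpha - 1.0) / w)
        )
        out = np.exp(log_c)
    else:  # frank
        d = np.expm1(-alpha)
        num = alpha * (-d) * np.exp(-alpha * (uu + vv))
        den = -d - np.expm1(-alpha * uu) * np.expm1(-alpha * vv)
        out = num / den**2
    return _maybe_scalar(out, u, v)


# ---------------------------------------------------------------------------
# conditional distribution h(u|v) = dC/dv and its inverse in u
# ---------------------------------------------------------------------------


def copula_hfun(spec: CopulaSpec, u, v):
    """Conditional distribution P(U <= u | V = v) = dC(u, v)/dv."""
    uu = _as_prob(u, "u")
    vv = _as_prob(v, "v")
    if np.any(vv <= 0.0) or np.any(vv >= 1.0):
        raise ValueError("copula_hfun requires 0 < v < 1")
    uu, vv = np.broadcast_arrays(uu, vv)
    out = np.empty(uu.shape, dtype=float)

    lo = uu == 0.0
    hi = uu == 1.0
    interior = ~(lo | hi)
    out[lo] = 0.0
    out[hi] = 1.0

    if np.any(interior):
        ui, vi = uu[interior], vv[interior]
        alpha = spec.alpha
        if spec.independent:
            hi_val = ui
        elif spec.family == CLAYTON:
            logs = _clayton_logs(alpha, ui, vi)
            hi_val = np.exp(-(alpha + 1.0) * np.log(vi) - (alpha + 1.0) / alpha * logs)
        elif spec.family == GUMBEL:
            log_s = _gumbel_log_s(alpha, ui, vi)
            log_c = -np.exp(log_s / alpha)
            hi_val = np.exp(
                log_c
                + (1.0 / alpha - 1.0) * log_s
                + (alpha - 1.0) * np.log(-np.log(vi))
                - np.log(vi)
            )
        else:  # frank
            a = -alpha * ui
            b = -alpha * vi
            c = -alpha
            if alpha > 0:
                log_num = np.logaddexp(a + _log_nexpm1(b), b + _log_nexpm1(c - b))
                hi_val = np.exp(b + _log_nexpm1(a) - log_num)
            else:
                log_num = np.logaddexp(a + _log_expm1(b), b + _log_expm1(c - b))
                hi_val = np.exp(b + _log_expm1(a) - log_num)
        out[interior] = np.clip(hi_val, 0.0, 1.0)
    return _maybe_scalar(out, u, v)


def _gumbel_hinv_scalar(alpha: float, p: float, v: float) -> float:
    spec = CopulaSpec(GUMBEL, alpha)
    lo, hi = 1e-12, 1.0 - 1e-12
    f = lambda x: copula_hfun(spec, x, v) - p
    flo, fhi = f(lo), f(hi)
    if flo > 0.0:
        return lo
    if fhi < 0.0:
        return hi
    try:
        return float(optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200))
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"Gumbel h-inverse failed to converge (alpha={alpha}, p={p}, v={v})"
        ) from exc


def copula_hinv(spec: CopulaSpec, p, v):
    """Inverse of :func:`copula_hfun` in its first argument.

    Returns ``u`` such that ``copula_hfun(spec, u, v) == p``. Closed form
    for Clayton and Frank; bracketed root-finding for Gumbel.
    """
    pp = _as_prob(p, "p")
    vv = _as_prob(v, "v")
    if np.any(pp <= 0.0) or np.any(pp >= 1.0) or np.any(vv <= 0.0) or np.any(vv >= 1.0):
        raise ValueError("copula_hinv requires 0 < p < 1 and 0 < v < 1")
    pp, vv = np.broadcast_arrays(pp, vv)
    alpha = spec.alpha

    if spec.independent:
        out = pp.copy()
    elif spec.family == CLAYTON:
        # u = [(p v^(a+1))^(-a/(a+1)) - v^-a + 1]^(-1/a)
        with np.errstate(over="ignore"):
            log_w = -(alpha / (alpha + 1.0)) * (np.log(pp) + (alpha + 1.0) * np.log(vv))
            w = np.exp(log_w)
            s = w - np.exp(-alpha * np.log(vv)) + 1.0
            out = np.exp(-np.log(s) / alpha)
        out = np.clip(out, 0.0, 1.0)
    elif spec.family == FRANK:
        # solve p = e^b A / (D + A B) for A = expm1(-alpha u)
        b = -alpha * vv
        big_b = np.expm1(b)
        big_d = np.expm1(-alpha)
        a_val = pp * big_d / (np.exp(b) - pp * big_b)
        out = -np.log1p(a_val) / alpha
        out = np.clip(out, 0.0, 1.0)
    else:  # gumbel
        flat_p = pp.ravel()
        flat_v = vv.ravel()
        res = np.fromiter(
            (_gumbel_hinv_scalar(alpha, pi, vi) for pi, vi in zip(flat_p, flat_v)),
            dtype=float,
            count=flat_p.size,
        )
        out = res.reshape(pp.shape)
    return _maybe_scalar(out, p, v)


# ---------------------------------------------------------------------------
# Kendall's tau and tail dependence
# ---------------------------------------------------------------------------


def debye1(x: float) -> float:
    """First-order Debye function D1(x) = (1/x) * int_0^x t/(e^t - 1) dt.

    Negative arguments use D1(-x) = D1(x) + x/2.
    """
    x = float(x)
    if x == 0.0:
        return 1.0
    ax = abs(x)
    # t/(e^t - 1) written as t e^-t / (1 - e^-t) to stay finite for large t
    val, _ = integrate.quad(
        lambda t: t * np.exp(-t) / -np.expm1(-t), 0.0, ax, epsabs=1e-12, limit=200
    )
    d1 = val / ax
    if x < 0:
        d1 += ax / 2.0
    return d1


def param_to_tau(spec: CopulaSpec) -> float:
    """Kendall's tau implied by a copula spec."""
    if spec.independent:
        return 0.0
    alpha = spec.alpha
    if spec.family == CLAYTON:
        return alpha / (alpha + 2.0)
    if spec.family == GUMBEL:
        return 1.0 - 1.0 / alpha
    return 1.0 - (4.0 / alpha) * (1.0 - debye1(alpha))


def tau_to_param(family: str, tau: float) -> float:
    """Dependence parameter whose Kendall's tau equals ``tau``.

    Closed form for Clayton and Gumbel; root-finding on the Debye
    relation for Frank (negative tau handled by antisymmetry).
    """
    _check_family(family)
    tau = float(tau)
    if family in (CLAYTON, GUMBEL):
        if not 0.0 < tau < 1.0:
            raise ValueError(f"{family} requires Kendall tau in (0, 1), got {tau}")
        if family == CLAYTON:
            return 2.0 * tau / (1.0 - tau)
        return 1.0 / (1.0 - tau)
    if tau == 0.0 or not -1.0 < tau < 1.0:
        raise ValueError(f"frank requires Kendall tau in (-1, 1) excluding 0, got {tau}")
    sign = 1.0 if tau > 0 else -1.0
    target = abs(tau)

    def f(a: float) -> float:
        return param_to_tau(CopulaSpec(FRANK, a)) - target

    alpha = optimize.brentq(f, 1e-5, 1e5, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    return sign * float(alpha)


def tail_dependence(spec: CopulaSpec) -> Tuple[float, float]:
    """(lower, upper) tail-dependence coefficients of the family."""
    if spec.independent:
        return (0.0, 0.0)
    if spec.family == CLAYTON:
        return (2.0 ** (-1.0 / spec.alpha), 0.0)
    if spec.family == GUMBEL:
        return (0.0, 2.0 - 2.0 ** (1.0 / spec.alpha))
    return (0.0, 0.0)
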