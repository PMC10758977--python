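"""Monte-Carlo parameter-recovery study harness.

Generates B independent series from a design, fits each one, and
aggregates replicate means and dispersions in the shape of the
reference recovery tables ("mean (MSE)" per parameter, rows indexed by
series length and dependence parameter).

Two dispersion measures are reported: ``mse_estimates`` is the spread
about the replicate mean (the tabulated convention, i.e. a Monte-Carlo
variance) and ``mse_true`` is the conventional mean squared error about
the generating truth.
"""

from __future__ import annotations

import dataclasses
import re
from typing import List, Optional

import numpy as np
import pandas as pd

from . import model as _model
from .simulate import SimDesign, generate_series

__all__ = ["StudyResult", "run_study", "study_table", "parse_cell"]


@dataclasses.dataclass
class StudyResult:
    family: str
    T: int
    alpha_true: float
    beta_true: np.ndarray
    B: int
    mean_estimates: np.ndarray  # (beta..., alpha)
    mse_estimates: np.ndarray  # dispersion about the replicate mean
    mse_true: np.ndarray  # dispersion about the generating truth
    n_failed: int
    seed: Optional[int]
    valid: bool
    estimates: Optional[np.ndarray] = None  # (B_converged, d+2) raw draws

    @property
    def mc_se(self) -> np.ndarray:
        """Monte-Carlo standard error of each mean estimate."""
        b = self.B - self.n_failed
        return np.sqrt(self.mse_estimates / max(b - 1, 1))

    def param_names(self) -> List[str]:
        return [f"beta{j}" for j in range(len(self.beta_true))] + ["alpha"]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "T": self.T,
            "alpha_true": float(self.alpha_true),
            "beta_true": [float(b) for b in self.beta_true],
            "B": self.B,
            "mean_estimates": [float(x) for x in self.mean_estimates],
            "mse_estimates": [float(x) for x in self.mse_estimates],
            "mse_true": [float(x) for x in self.mse_true],
            "n_failed": self.n_failed,
            "seed": self.seed,
            "valid": self.valid,
        }


def run_study(
    design: SimDesign,
    B: int,
    seed: Optional[int] = None,
    *,
    keep_estimates: bool = True,
    include_first: bool = True,
) -> StudyResult:
    """Replicate generate-and-fit B times and aggregate.

    Per-replicate seeds are spawned deterministically from the study
    seed; non-converged fits are dropped from the statistics and
    counted, and a study with more than 20% failures is flagged invalid.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    root = np.random.SeedSequence(design.seed if seed is None else seed)
    children = root.spawn(B)

    draws = []
    n_failed = 0
    for child in children:
        series = generate_series(design, seed=child)
        try:
            res = _model.fit(
                series, design.family, include_first=include_first, compute_se=False
            )
        except (ValueError, FloatingPointError):
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        draws.append(np.append(res.beta_hat, res.alpha_hat))

    truth = np.append(np.asarray(design.beta), design.alpha)
    if draws:
        est = np.vstack(draws)
        mean = est.mean(axis=0)
        mse_mean = np.mean((est - mean) ** 2, axis=0)
        mse_true = np.mean((est - truth) ** 2, axis=0)
    else:
        est = np.empty((0, truth.size))
        mean = np.full(truth.size, np.nan)
        mse_mean = np.full(truth.size, np.nan)
        mse_true = np.full(truth.size, np.nan)

    return StudyResult(
        family=design.family,
        T=design.T,
        alpha_true=design.alpha,
        beta_true=np.asarray(design.beta),
        B=B,
        mean_estimates=mean,
        mse_estimates=mse_mean,
        mse_true=mse_true,
        n_failed=n_failed,
        seed=seed if seed is not None else design.seed,
        valid=n_failed <= 0.2 * B,
        estimates=est if keep_estimates else None,
    )


_CELL_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*\((-?\d+(?:\.\d+)?)\)\s*$")


def _format_cell(mean: float, mse: float, decimals: int = 3) -> str:
    if not np.isfinite(mean):
        raise ValueError("cannot format an empty (all-failed) parameter cell")
    return f"{mean:.{decimals}f} ({mse:.{decimals}f})"


def parse_cell(cell: str) -> "tuple[float, float]":
    """Inverse of the 'mean (MSE)' cell format."""
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"unparseable table cell {cell!r}")
    return float(m.group(1)), float(m.group(2))


def study_table(results: List[StudyResult], decimals: int = 3) -> pd.DataFrame:
    """Render studies as a 'mean (MSE)' table indexed by (T, alpha)."""
    if not results:
        raise ValueError("no study results to tabulate")
    families = {r.family for r in results}
    dims = {len(r.beta_true) for r in results}
    if len(families) > 1 or len(dims) > 1:
        raise ValueError("cannot mix copula families or covariate dimensions in one table")
    rows = []
    for r in sorted(results, key=lambda r: (r.T, r.alpha_true)):
        row = {"T": r.T, "alpha_true": r.alpha_true}
        for name, mean, mse in zip(r.param_names(), r.mean_estimates, r.mse_estimates):
            row[name] = _format_cell(mean, mse, decimals)
        row["n_failed"] = r.n_failed
        rows.append(row)
    return pd.DataFrame(rows)
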