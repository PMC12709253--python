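"""Nonparametric comparison of length–wavelength curves, and regression rules.

Two preparations are compared by a zero-crossing test: one preparation's
(L, λ) points are interpolated into a reference curve, the other's points
are reduced to residual signs against it, and the number of sign changes
``n`` along increasing length is counted.  Under the null (same underlying
curve, independent noise) consecutive signs flip with probability 1/2, so
n has mean ≈ N/2 and SD ≈ √N/2 for N points; the statistic
t = |n − N/2| / (√N/2) is referred to a t distribution with N/2 degrees of
freedom.  Too few crossings mean one curve sits systematically above the
other; too many mean over-dispersion around the reference.  Bonferroni
correction handles families of pairwise comparisons.

Regression slopes are called significant when they differ from zero by at
least two standard errors (the 95% confidence rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputDataError, ParameterError

__all__ = [
    "LengthWavelengthDataset",
    "CrossingTestResult",
    "RegressionResult",
    "crossing_test",
    "bonferroni",
    "slope_significance",
]


@dataclass
class LengthWavelengthDataset:
    """(length, wavelength) points of one preparation/strain/condition."""

    length_um: np.ndarray
    lambda_um: np.ndarray
    sem_um: np.ndarray | None = None
    group: str = ""

    def __post_init__(self):
        self.length_um = np.asarray(self.length_um, dtype=float)
        self.lambda_um = np.asarray(self.lambda_um, dtype=float)
        if self.length_um.shape != self.lambda_um.shape or self.length_um.ndim != 1:
            raise InputDataError("length_um and lambda_um must be matching 1-D arrays")
        if np.any(self.length_um <= 0):
            raise InputDataError("lengths must be positive")
        if self.sem_um is not None:
            self.sem_um = np.asarray(self.sem_um, dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group: str | None = None):
        """Build from a summary table with columns group, length_um, lambda_um[, sem_um]."""
        if group is not None:
            df = df[df["group"] == group]
        return cls(
            length_um=df["length_um"].to_numpy(),
            lambda_um=df["lambda_um"].to_numpy(),
            sem_um=df["sem_um"].to_numpy() if "sem_um" in df else None,
            group=group or (str(df["group"].iloc[0]) if "group" in df and len(df) else ""),
        )

    @property
    def n(self) -> int:
        return self.length_um.size


@dataclass
class CrossingTestResult:
    n_crossings: int
    N: int
    se: float
    t_stat: float
    df: int
    p_value: float
    p_adjusted: float | None = None
    flags: list[str] = dc_field(default_factory=list)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    significant: bool


def crossing_test(
    dataset_a: LengthWavelengthDataset, dataset_b: LengthWavelengthDataset
) -> CrossingTestResult:
    """Zero-crossing comparison of two length–wavelength curves.

    ``dataset_b`` is linearly interpolated over length into the reference
    curve; ``dataset_a``'s points inside b's length range are reduced to
    residual signs, ordered by length, and n counts the sign changes.
    A residual of exactly zero inherits the previous sign (flagged).

    Raises
    ------
    InputDataError : fewer than 3 usable points after range restriction.
    """
    if dataset_a.n < 3 or dataset_b.n < 3:
        raise InputDataError("each dataset needs at least 3 points")
    order_b = np.argsort(dataset_b.length_um)
    xb = dataset_b.length_um[order_b]
    yb = dataset_b.lambda_um[order_b]

    in_range = (dataset_a.length_um >= xb[0]) & (dataset_a.length_um <= xb[-1])
    if in_range.sum() < 3:
        raise InputDataError(
            "fewer than 3 points of dataset_a fall inside dataset_b's length range"
        )
    order_a = np.argsort(dataset_a.length_um[in_range])
    xa = dataset_a.length_um[in_range][order_a]
    ya = dataset_a.lambda_um[in_range][order_a]

    resid = ya - np.interp(xa, xb, yb)
    flags: list[str] = []
    signs = np.sign(resid)
    for i in range(signs.size):
        if signs[i] == 0:
            signs[i] = signs[i - 1] if i > 0 else 1.0
            if "zero_residual" not in flags:
                flags.append("zero_residual")

    n = int(np.sum(signs[1:] != signs[:-1]))
    N = int(xa.size)
    se = np.sqrt(N) / 2.0
    t_stat = abs(n - N / 2.0) / se
    df = N // 2
    p = float(2.0 * sps.t.sf(t_stat, df))
    return CrossingTestResult(
        n_crossings=n, N=N, se=se, t_stat=t_stat, df=df, p_value=min(p, 1.0), flags=flags
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p → min(1, m·p), with m ≥ len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p_values", "must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ParameterError("m", "must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def slope_significance(x, y) -> RegressionResult:
    """OLS fit y = mx + b; the slope is significant iff |m| ≥ 2·SE(m)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InputDataError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise InputDataError("x values are all equal (degenerate regression)")
    fit = sps.linregress(x, y)
    se = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=se,
        significant=bool(abs(fit.slope) >= 2 * se),
    )
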