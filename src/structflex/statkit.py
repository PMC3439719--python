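"""Small statistics toolkit: Pearson correlation, 2x2 chi-square, least squares.

Thin, validated wrappers around scipy/numpy so every pipeline stage draws its
statistics from one place with consistent conventions (two-sided p-values,
Yates continuity correction on by default for 2x2 tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class FitResult:
    """Ordinary least-squares line fit.

    ``intercept`` is 0.0 when the fit was forced through the origin.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    through_origin: bool = False


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    continuity_corrected: bool


def pearson_cc(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value (t-distribution, n-2 df).

    Raises ``ValueError`` on length mismatch, n < 3 or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("pearson_cc requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def chi_square_2x2(table, yates: bool = True) -> ChiSquareResult:
    """Chi-square test of homogeneity on a 2x2 count table.

    With ``yates`` (the default, matching R's ``chisq.test``) the statistic is
    sum((|O - E| - 0.5)^2 / E), with the correction capped so it cannot
    overshoot the observed deviation.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal")
    expected = row @ col / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic, 1, p, expected, yates)


def linear_fit(x, y, through_origin: bool = False) -> FitResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if through_origin:
        if n < 1 or np.all(x == 0):
            raise ValueError("degenerate x for through-origin fit")
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        resid = y - slope * x
        # r^2 about the origin model: 1 - SS_res / SS_tot(uncentred)
        ss_tot = float(np.dot(y, y))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    else:
        if n < 2 or np.ptp(x) == 0:
            raise ValueError("degenerate x")
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(float(slope), float(intercept), max(0.0, min(1.0, r2)), n, through_origin)
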