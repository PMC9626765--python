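"""Regression and rank-based two-sample inference.

Two analyses accompany the risk pipeline: a per-crop ordinary
least-squares regression of grain F concentration on Cd (with Pearson r
and its two-sided t-test on n-2 degrees of freedom), and a Mann-Whitney U
comparison of per-sample risk values between populations (adults vs
children).  The U test is exact (full enumeration of labelings) for small
tie-free samples and otherwise uses the normal approximation with midrank
tie correction and continuity correction; p-values are two-sided
throughout.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, EmptyGroupError

#: largest combined sample size for which the exact null distribution is used
EXACT_MAX_N = 12


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with Pearson correlation and its p-value."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    stderr: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class TestResult:
    """Mann-Whitney U result: U of the first sample and two-sided p."""

    statistic: float
    p_value: float
    method: str  # "exact_enumeration" or "normal_approx"
    n1: int
    n2: int


def fit_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Simple linear regression of y on x (for the F-on-Cd analysis, x = Cd).

    Pearson r's significance is the two-sided t-test with
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"regression needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(n),
        stderr=float(res.stderr),
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test with automatic method choice.

    Exact enumeration of the null distribution when the combined sample is
    small (n1 + n2 <= 12) and tie-free; otherwise the normal approximation
    with midrank tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroupError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and a.size + b.size <= EXACT_MAX_N:
        method, scipy_method = "exact_enumeration", "exact"
    else:
        method, scipy_method = "normal_approx", "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method=scipy_method, use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n1=int(a.size),
        n2=int(b.size),
    )


def annotate_significance(p: float) -> str:
    """Figure-style significance annotation: ns / star / double_star."""
    if not 0 < p <= 1:
        raise DegenerateInputError(f"p-value must be in (0, 1], got {p}")
    if p < 0.01:
        return "double_star"
    if p < 0.05:
        return "star"
    return "ns"
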