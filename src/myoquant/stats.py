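"""Group-comparison statistics: normality-gated two-sample tests,
effect sizes, and gated correlations.

The procedure mirrors common practice in clinical physiology: each
sample is screened with the D'Agostino-Pearson omnibus K^2 test; when
both arms look normal the comparison is an unpaired pooled-variance
Student's t with mean +/- SD summaries, otherwise a two-sided
Mann-Whitney U with median (IQR) summaries.  Cohen's d uses the
unweighted mean of the two SDs as denominator, d = |m1 - m2| / ((s1 +
s2)/2), and is reported unsigned with direction carried by the percent
difference.  Correlations are Pearson when both variables pass the gate
and Spearman otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "SmallSampleWarning",
    "GroupComparison",
    "normality_gate",
    "cohens_d",
    "mann_whitney",
    "compare_groups",
    "correlate",
    "percent_difference",
]

ALPHA = 0.05
#: below this size the omnibus normality test is undefined
_MIN_NORMALITY_N = 8
#: largest min(n1, n2) for which the Mann-Whitney p is exact by enumeration
_EXACT_MW_MAX_N = 8


class SmallSampleWarning(UserWarning):
    """Sample too small for the requested distributional test."""


def normality_gate(sample: Sequence[float], alpha: float = ALPHA) -> str:
    """Classify a sample as 'normal' or 'non_normal'.

    Uses the D'Agostino-Pearson omnibus test (K^2 from transformed
    skewness and kurtosis); 'normal' iff p >= alpha.  Samples with n < 8
    are forced 'non_normal' with a warning, since the test statistic is
    undefined there.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample must be 1-D")
    if x.size < _MIN_NORMALITY_N:
        warnings.warn(
            f"n={x.size} < {_MIN_NORMALITY_N}: omnibus normality test undefined; "
            "treating sample as non-normal",
            SmallSampleWarning,
            stacklevel=2,
        )
        return "non_normal"
    with warnings.catch_warnings():
        # scipy warns for 8 <= n < 20; the gate still applies there
        warnings.simplefilter("ignore")
        _, p = sps.normaltest(x)
    return "normal" if p >= alpha else "non_normal"


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Unsigned Cohen's d with the mean-of-SDs denominator.

    d = |mean_a - mean_b| / ((sd_a + sd_b)/2).  Thresholds 0.2/0.5/0.8
    conventionally mark small/medium/large effects.
    """
    if not (sd_a > 0 and sd_b > 0):
        raise ValueError("both SDs must be strictly positive")
    return abs(mean_a - mean_b) / ((sd_a + sd_b) / 2.0)


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating rank assignments.

    Enumerates all C(n1+n2, n1) assignments of the pooled mid-ranks to
    group A; ties are handled exactly through the mid-ranks.  Two-sided
    p = P(|U - n1*n2/2| >= |U_obs - n1*n2/2|) under the permutation null.
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2.0
    centre = n1 * n2 / 2.0
    dev_obs = abs(u_obs - centre)
    hits = 0
    idx = range(n1 + n2)
    for pick in combinations(idx, n1):
        u = ranks[list(pick)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - centre) >= dev_obs - 1e-12:
            hits += 1
    return float(u_obs), hits / comb(n1 + n2, n1)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U_a, p).

    Exact permutation enumeration when min(n1, n2) <= 8 (correct under
    ties); otherwise the normal approximation with continuity and tie
    correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if min(x.size, y.size) <= _EXACT_MW_MAX_N:
        return _mann_whitney_exact(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """One two-group comparison row of the report."""

    variable: str
    n_a: int
    n_b: int
    summary_a: tuple[float, float]  # (mean, SD) or (median, IQR)
    summary_b: tuple[float, float]
    summary_style: str  # 'mean_sd' | 'median_iqr'
    test_used: str  # 'student_t' | 'mann_whitney'
    statistic: float
    p_value: float
    cohens_d: float
    percent_diff: float
    significant: bool


def _summaries(x: np.ndarray, style: str) -> tuple[float, float]:
    if style == "mean_sd":
        return float(x.mean()), float(x.std(ddof=1))
    q1, q3 = np.percentile(x, [25, 75])
    return float(np.median(x)), float(q3 - q1)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    variable: str = "",
    alpha: float = ALPHA,
    force_test: str = "auto",
) -> GroupComparison:
    """Normality-gated unpaired two-group comparison.

    Student's t (pooled variance) with mean +/- SD summaries when both
    samples pass the gate, otherwise Mann-Whitney U with median (IQR)
    summaries.  ``force_test`` in {'auto', 't', 'mw'} overrides the gate.
    Cohen's d is always computed from the sample means/SDs; the percent
    difference uses the central values of the chosen summary style.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    if force_test not in ("auto", "t", "mw"):
        raise ValueError("force_test must be 'auto', 't' or 'mw'")

    if force_test == "auto":
        gate = normality_gate(x, alpha) == "normal" and normality_gate(y, alpha) == "normal"
        use_t = gate
    else:
        use_t = force_test == "t"

    if use_t:
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            raise ValueError("degenerate zero-variance samples under Student's t")
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        style, test = "mean_sd", "student_t"
    else:
        stat, p = mann_whitney(x, y)
        style, test = "median_iqr", "mann_whitney"

    sa = _summaries(x, style)
    sb = _summaries(y, style)
    d = cohens_d(float(x.mean()), float(x.std(ddof=1)), float(y.mean()), float(y.std(ddof=1)))
    return GroupComparison(
        variable=variable,
        n_a=int(x.size),
        n_b=int(y.size),
        summary_a=sa,
        summary_b=sb,
        summary_style=style,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        cohens_d=d,
        percent_diff=percent_difference(sa[0], sb[0]),
        significant=bool(p < alpha),
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = ALPHA,
    force_method: str = "auto",
) -> tuple[float, float, str]:
    """Gated bivariate correlation; returns (r, p, method).

    Pearson's r (t-distributed p) when both variables pass the normality
    gate, Spearman's rank correlation otherwise.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must be paired")
    if xv.size < 3:
        raise ValueError("correlation needs n >= 3")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("constant input vector")
    if force_method == "auto":
        method = (
            "pearson"
            if normality_gate(xv, alpha) == "normal" and normality_gate(yv, alpha) == "normal"
            else "spearman"
        )
    elif force_method in ("pearson", "spearman"):
        method = force_method
    else:
        raise ValueError("force_method must be 'auto', 'pearson' or 'spearman'")
    if method == "pearson":
        r, p = sps.pearsonr(xv, yv)
    else:
        r, p = sps.spearmanr(xv, yv)
    return float(r), float(p), method


def percent_difference(value_a: float, value_b: float) -> float:
    """Percent difference of a relative to the reference b: 100*(a - b)/b."""
    if value_b == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (value_a - value_b) / value_b
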