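"""Shared inferential statistics.

Every group-level inference in the package funnels through this module:
Welch and paired t-tests with Cohen's d / dz effect sizes, the Fisher
r-to-z transform, the two-sample correlation comparison, Benjamini-Hochberg
FDR adjustment, and a balanced two-way factorial ANOVA with partial eta
squared.  All p-values are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "TestResult",
    "welch_t",
    "paired_t",
    "fisher_z",
    "compare_correlations",
    "bh_fdr",
    "factorial_anova",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single two-tailed hypothesis test."""

    statistic: float
    df: float
    p: float
    effect_size: float
    effect_size_name: str = "d"
    tails: str = "two"

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1 or np.isnan(self.p)):
            raise ValidationError(f"p must lie in (0, 1], got {self.p}")
        if not (self.df > 0):
            raise ValidationError(f"df must be positive, got {self.df}")


def _as_clean_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError(f"{name}: empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite values")
    return arr


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Effect size is Cohen's d using the pooled standard deviation
    (df-weighted across the two groups).
    """
    a = _as_clean_array(a, "a")
    b = _as_clean_array(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t requires n >= 2 in each sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateDataError("welch_t: zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    pooled_sd = np.sqrt(
        ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
    )
    d = (a.mean() - b.mean()) / pooled_sd
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), float(d))


def paired_t(diffs: Sequence[float]) -> TestResult:
    """One-sample t-test on paired differences; effect size dz = mean/SD."""
    diffs = _as_clean_array(diffs, "diffs")
    if diffs.size < 2:
        raise ValidationError("paired_t requires n >= 2 differences")
    sd = diffs.std(ddof=1)
    n = diffs.size
    if sd == 0:
        if diffs.mean() == 0:
            return TestResult(0.0, float(n - 1), 1.0, 0.0, "dz")
        raise DegenerateDataError("paired_t: zero variance in nonzero differences")
    t = diffs.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    dz = diffs.mean() / sd
    return TestResult(float(t), float(n - 1), float(p), float(dz), "dz")


def fisher_z(r: float) -> float:
    """Fisher r-to-z transform, atanh(r); defined only for |r| < 1."""
    if not np.isfinite(r) or abs(r) >= 1:
        raise ValidationError(f"fisher_z unbounded at |r| >= 1 (got r={r})")
    return float(np.arctanh(r))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Two-sample z test for independent Pearson correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the reference
    distribution is standard normal, so df is reported as +inf.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValidationError("compare_correlations requires n > 3 per sample")
    z = (fisher_z(r1) - fisher_z(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    q = fisher_z(r1) - fisher_z(r2)  # difference of z-transforms as effect size
    return TestResult(float(z), np.inf, float(p), float(q), "delta_z")


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = _as_clean_array(pvals, "pvals")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("pvals must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def factorial_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> dict[str, TestResult]:
    """Balanced two-way between-subjects ANOVA via partitioned sums of squares.

    Returns F tests for the main effects and the interaction with partial
    eta-squared (SS_effect / (SS_effect + SS_error)) as the effect size.
    Requires every cell of the A x B design to hold the same number (>= 2)
    of observations; unbalanced designs are rejected.
    """
    y = _as_clean_array(values, "values")
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValidationError("values and factors must have equal length")
    levels_a = list(dict.fromkeys(fa.tolist()))
    levels_b = list(dict.fromkeys(fb.tolist()))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValidationError("each factor needs >= 2 levels")

    counts = {
        (la, lb): int(np.sum((fa == la) & (fb == lb)))
        for la in levels_a
        for lb in levels_b
    }
    n_cell = counts[(levels_a[0], levels_b[0])]
    if n_cell < 2 or any(c != n_cell for c in counts.values()):
        raise ValidationError("factorial_anova requires a balanced design with >= 2 per cell")

    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    nb = len(levels_b) * n_cell
    na = len(levels_a) * n_cell
    ss_a = sum(nb * (y[fa == la].mean() - grand) ** 2 for la in levels_a)
    ss_b = sum(na * (y[fb == lb].mean() - grand) ** 2 for lb in levels_b)
    ss_cells = sum(
        n_cell * (y[(fa == la) & (fb == lb)].mean() - grand) ** 2
        for la in levels_a
        for lb in levels_b
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells
    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    df_err = y.size - len(levels_a) * len(levels_b)

    def _effect(ss: float, df: float) -> TestResult:
        ss = max(ss, 0.0)  # guard tiny negative rounding
        if ss == 0.0:
            return TestResult(0.0, df, 1.0, 0.0, "partial_eta_sq")
        if ss_err == 0.0:
            raise DegenerateDataError("factorial_anova: zero error sum of squares")
        f = (ss / df) / (ss_err / df_err)
        p = stats.f.sf(f, df, df_err)
        eta = ss / (ss + ss_err)
        return TestResult(float(f), float(df), float(p), float(eta), "partial_eta_sq")

    return {"a": _effect(ss_a, df_a), "b": _effect(ss_b, df_b), "interaction": _effect(ss_ab, df_ab)}
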