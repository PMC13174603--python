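"""Quantitative-MRI trajectory analyses and gene-set normalization.

R1 (longitudinal relaxation rate, 1/s) tracks myelin and macromolecular
content; MTV (macromolecular tissue volume) is 1 minus the water volume
fraction, so 1/WVF = 1/(1 - MTV) is the regressor in the linearity
analysis.  Subjects are binned into four developmental age groups and
compared across lobes and hemispheres with the balanced factorial ANOVA
from :mod:`devgeom.statcore`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .statcore import TestResult, factorial_anova, welch_t
from .synthgen import TissueSample

__all__ = [
    "AGE_GROUPS",
    "MYELIN_GENES",
    "assign_age_group",
    "roi_mean",
    "r1_vs_invwvf_fit",
    "slope_contrast",
    "heterogeneity_vs_age",
    "normalize_gene_sets",
    "lobe_age_anova",
]

# Developmental bins (years, inclusive integer ranges): disjoint, exhaustive
# over [5, 54]; older adults are excluded as aging is distinct from development.
AGE_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("kids", 5, 10),
    ("teens", 11, 17),
    ("young_adults", 18, 24),
    ("adults", 25, 54),
)

# Genes directly involved in the structure and maintenance of the human
# myelin sheath (deduplicated).
MYELIN_GENES: tuple[str, ...] = (
    "PLP1", "PLLP", "MAG", "MBP", "CA2", "PMP22", "MAL", "ERMN", "OMG",
)


def assign_age_group(age: float) -> str:
    """Deterministic bin per the inclusive ranges 5-10, 11-17, 18-24, 25-54."""
    if not 5 <= age <= 54:
        raise ValidationError(f"age {age} outside the developmental range [5, 54]")
    for name, lo, hi in AGE_GROUPS:
        if age < hi + 1:
            return name
    return AGE_GROUPS[-1][0]  # age == 54 lands here via the loop; keep explicit


def roi_mean(sample: TissueSample, metric: str) -> float:
    """Arithmetic mean over voxels of R1 or MTV."""
    if metric not in ("R1", "MTV"):
        raise ValidationError("metric must be 'R1' or 'MTV'")
    values = sample.r1 if metric == "R1" else sample.mtv
    if values.size == 0:
        raise ValidationError("empty voxel set")
    return float(values.mean())


def r1_vs_invwvf_fit(sample: TissueSample) -> dict[str, float]:
    """Per-subject OLS fit of R1 on 1/WVF = 1/(1 - MTV) across voxels."""
    if sample.r1.size < 3:
        raise ValidationError("need >= 3 voxels for the R1 vs 1/WVF fit")
    invwvf = 1.0 / (1.0 - sample.mtv)
    if np.var(invwvf) == 0:
        raise ValidationError("zero variance in 1/WVF")
    res = stats.linregress(invwvf, sample.r1)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
    }


def slope_contrast(
    child_samples: Sequence[TissueSample],
    adult_samples: Sequence[TissueSample],
) -> TestResult:
    """Welch t-test contrasting per-subject R1-vs-1/WVF slopes across groups."""
    child = [r1_vs_invwvf_fit(s)["slope"] for s in child_samples]
    adult = [r1_vs_invwvf_fit(s)["slope"] for s in adult_samples]
    return welch_t(child, adult)


def heterogeneity_vs_age(samples: Sequence[TissueSample]) -> dict[str, float]:
    """OLS regression of per-subject inter-voxel R1 SD on age."""
    ages = np.array([s.age for s in samples])
    if len(set(np.round(ages, 9))) < 3:
        raise ValidationError("need >= 3 subjects with distinct ages")
    sds = np.array([s.r1.std(ddof=1) for s in samples])
    res = stats.linregress(ages, sds)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p": float(res.pvalue),
        "stderr": float(res.stderr),
    }


def lobe_age_anova(samples: Sequence[TissueSample], metric: str = "R1") -> dict[str, TestResult]:
    """Lobe x age-group factorial ANOVA on per-subject ROI means.

    Requires a balanced design (same number of subjects per lobe x age-group
    cell); the interaction term tests for divergent tissue trajectories.
    """
    values = [roi_mean(s, metric) for s in samples]
    lobes = [s.lobe for s in samples]
    groups = [assign_age_group(s.age) for s in samples]
    return factorial_anova(values, lobes, groups)


def normalize_gene_sets(
    expr: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    window: tuple[float, float] = (11.0, 20.0),
) -> pd.DataFrame:
    """Normalize each gene to its mean over the adolescence window, then
    average across genes within each set.

    ``expr`` is gene x age (columns are ages in years); the window is the
    open interval (11, 20) by default.  Returns a set x age table in which
    each gene's window mean maps to 1 before set-averaging.
    """
    ages = np.asarray(expr.columns, dtype=float)
    lo, hi = window
    in_window = (ages > lo) & (ages < hi)
    if not in_window.any():
        raise ValidationError("no age columns inside the adolescence window")
    if (expr.to_numpy() < 0).any():
        raise ValidationError("expression values must be >= 0")
    rows = {}
    for set_name, genes in sets.items():
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise ValidationError(f"genes missing from table: {missing}")
        normalized = []
        for g in genes:
            values = expr.loc[g].to_numpy(dtype=float)
            wmean = values[in_window].mean()
            if wmean == 0:
                raise ValidationError(f"gene {g!r} has zero mean in the window")
            normalized.append(values / wmean)
        rows[set_name] = np.mean(normalized, axis=0)
    return pd.DataFrame(rows, index=expr.columns).T
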