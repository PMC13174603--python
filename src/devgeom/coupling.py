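"""Stability-versus-coupling coordinates and developmental displacement.

For each subject and hemisphere, *stability* is the split-half reliability
of the prefrontal similarity structure (mean Pearson correlation between
the unique cells of every unordered pair of per-fold LORO matrices) and
*coupling* is the mean correlation between prefrontal and posterior
per-fold matrices over all cross-region split combinations.  The signed
distance to the identity line, (stability - coupling) / sqrt(2), is
positive when internal prefrontal coherence dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rsm import SimilarityMatrix, _pearson
from .synthgen import CATEGORIES

__all__ = [
    "CouplingPoint",
    "DisplacementVector",
    "stability",
    "coupling",
    "signed_distance",
    "coupling_point",
    "category_coordinates",
    "displacement",
]

SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class CouplingPoint:
    """One subject's (coupling, stability) coordinate for one hemisphere."""

    subject_id: str
    hemisphere: str
    coupling: float
    stability: float

    def __post_init__(self) -> None:
        for name in ("coupling", "stability"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValidationError(f"{name} must lie in [-1, 1], got {v}")

    @property
    def signed_distance(self) -> float:
        return signed_distance(self.stability, self.coupling)


@dataclass(frozen=True)
class DisplacementVector:
    """Child-to-adult movement of one category in stability-coupling space."""

    category: str
    delta_coupling: float
    delta_stability: float
    p_value: float | None = None

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.delta_coupling, self.delta_stability))


def signed_distance(stability_value: float, coupling_value: float) -> float:
    """Perpendicular distance to the identity line; positive = stability dominance."""
    return float((stability_value - coupling_value) / SQRT2)


def _cells(sm: SimilarityMatrix, row: int | None = None) -> np.ndarray:
    v = sm.values
    if row is None:
        iu = np.triu_indices(v.shape[0], k=0)
        return v[iu]
    return v[row]  # the category's diagonal cell + its 4 between-category cells


def stability(split_matrices: Sequence[SimilarityMatrix], row: int | None = None) -> float:
    """Split-half reliability: mean correlation over unordered split pairs."""
    if len(split_matrices) < 2:
        raise ValidationError("stability needs >= 2 split matrices")
    vals = [
        _pearson(_cells(a, row), _cells(b, row))
        for a, b in combinations(split_matrices, 2)
    ]
    return float(np.mean(vals))


def coupling(
    pfc_splits: Sequence[SimilarityMatrix],
    vtc_splits: Sequence[SimilarityMatrix],
    row: int | None = None,
) -> float:
    """Cross-region similarity: mean correlation over all split combinations."""
    if not pfc_splits or not vtc_splits:
        raise ValidationError("coupling needs non-empty split lists")
    vals = [
        _pearson(_cells(a, row), _cells(b, row))
        for a, b in product(pfc_splits, vtc_splits)
    ]
    return float(np.mean(vals))


def coupling_point(
    subject_id: str,
    hemisphere: str,
    pfc_splits: Sequence[SimilarityMatrix],
    vtc_splits: Sequence[SimilarityMatrix],
) -> CouplingPoint:
    return CouplingPoint(
        subject_id=subject_id,
        hemisphere=hemisphere,
        coupling=np.clip(coupling(pfc_splits, vtc_splits), -1, 1),
        stability=np.clip(stability(pfc_splits), -1, 1),
    )


def category_coordinates(
    pfc_splits: Sequence[SimilarityMatrix],
    vtc_splits: Sequence[SimilarityMatrix],
) -> pd.DataFrame:
    """Per-category (coupling, stability), restricted to each category's row cells."""
    rows = []
    for i, cat in enumerate(CATEGORIES):
        rows.append(
            {
                "category": cat,
                "coupling": coupling(pfc_splits, vtc_splits, row=i),
                "stability": stability(pfc_splits, row=i),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def displacement(
    child_points: pd.DataFrame,
    adult_points: pd.DataFrame,
    null_permutations: int = 0,
    seed: int = 0,
) -> list[DisplacementVector]:
    """Adult-minus-child group-mean displacement per category.

    ``child_points`` / ``adult_points`` are long tables with columns
    (subject_id, category, coupling, stability), one row per subject and
    category.  With ``null_permutations`` > 0, significance of each
    category's displacement magnitude is assessed by shuffling subjects'
    group labels and recomputing the magnitude (add-one p-value).
    """
    for df in (child_points, adult_points):
        missing = {"subject_id", "category", "coupling", "stability"} - set(df.columns)
        if missing:
            raise ValidationError(f"points table missing columns {missing}")
    cats = sorted(set(child_points["category"]))
    if cats != sorted(set(adult_points["category"])):
        raise ValidationError("both groups must cover the same categories")

    def group_means(df: pd.DataFrame) -> pd.DataFrame:
        return df.groupby("category")[["coupling", "stability"]].mean()

    cm, am = group_means(child_points), group_means(adult_points)
    deltas = am - cm

    p_values: dict[str, float | None] = {c: None for c in cats}
    if null_permutations > 0:
        n_child = child_points["subject_id"].nunique()
        n_adult = adult_points["subject_id"].nunique()
        if n_child < 2 or n_adult < 2:
            raise ValidationError("permutation null needs >= 2 subjects per group")
        pooled = pd.concat(
            [child_points.assign(_g="child"), adult_points.assign(_g="adult")],
            ignore_index=True,
        )
        subjects = pooled[["subject_id", "_g"]].drop_duplicates().reset_index(drop=True)
        true_mag = np.hypot(deltas["coupling"], deltas["stability"])
        rng = np.random.default_rng(seed)
        exceed = pd.Series(0, index=true_mag.index, dtype=int)
        for _ in range(null_permutations):
            perm = rng.permutation(len(subjects))
            relabeled = dict(zip(subjects["subject_id"].iloc[perm], subjects["_g"]))
            g = pooled["subject_id"].map(relabeled)
            pm_c = group_means(pooled[g == "child"])
            pm_a = group_means(pooled[g == "adult"])
            d = pm_a - pm_c
            mag = np.hypot(d["coupling"], d["stability"])
            exceed += (mag >= true_mag).astype(int)
        for c in cats:
            p_values[c] = float((1 + exceed[c]) / (1 + null_permutations))

    return [
        DisplacementVector(
            category=c,
            delta_coupling=float(deltas.loc[c, "coupling"]),
            delta_stability=float(deltas.loc[c, "stability"]),
            p_value=p_values[c],
        )
        for c in cats
    ]
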