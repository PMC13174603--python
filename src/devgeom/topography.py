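"""Suprathreshold topography: counts, area shares, laterality, profiles.

A selectivity map holds per-vertex t-values for one category-versus-rest
contrast; vertices with t strictly above the threshold (default 2.5) count
as suprathreshold.  The laterality index LI = RH / (RH + LH) is 0.5 for a
symmetric map.  Response-profile vectors concatenate mean per-ROI contrast
values across categories and are compared across groups by Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .rsm import _pearson
from .synthgen import CATEGORIES, PatternArchive

__all__ = [
    "SelectivityMap",
    "ProfileVector",
    "selectivity_map",
    "suprathreshold_count",
    "laterality_index",
    "area_share",
    "percent_change",
    "profile_vector",
    "profile_correlation",
]


@dataclass(frozen=True)
class SelectivityMap:
    """Per-vertex t-values for one category > all-others contrast."""

    t_values: np.ndarray
    category: str
    hemisphere: str
    roi_labels: np.ndarray | None = None
    threshold: float = 2.5

    def __post_init__(self) -> None:
        t = np.asarray(self.t_values, dtype=float)
        object.__setattr__(self, "t_values", t)
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if not np.all(np.isfinite(t)):
            raise ValidationError("t-values must be finite")


@dataclass(frozen=True)
class ProfileVector:
    """Concatenated ROI x category mean t-values with ordering metadata."""

    values: np.ndarray
    roi_order: tuple[str, ...]
    category_order: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size != len(self.roi_order) * len(self.category_order):
            raise ValidationError("length must equal n_rois * n_categories")


def selectivity_map(
    archive: PatternArchive, category: str, threshold: float = 2.5
) -> SelectivityMap:
    """Category-versus-rest contrast map, averaged over runs."""
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    runs = archive.runs
    contrasts = []
    others = [c for c in CATEGORIES if c != category]
    for r in runs:
        own = archive.pattern(r, category)
        rest = np.mean([archive.pattern(r, c) for c in others], axis=0)
        contrasts.append(own - rest)
    return SelectivityMap(
        t_values=np.mean(contrasts, axis=0),
        category=category,
        hemisphere=archive.hemisphere,
        roi_labels=archive.roi_labels,
        threshold=threshold,
    )


def suprathreshold_count(sel_map: SelectivityMap) -> int:
    """Number of vertices with t strictly greater than the threshold."""
    return int(np.sum(sel_map.t_values > sel_map.threshold))


def laterality_index(rh_count: int, lh_count: int) -> float:
    """LI = RH / (RH + LH); 0.5 symmetric, > 0.5 right-dominant."""
    if rh_count < 0 or lh_count < 0:
        raise ValidationError("counts must be non-negative")
    total = rh_count + lh_count
    if total == 0:
        raise ValidationError("no suprathreshold activity in either hemisphere")
    return rh_count / total


def area_share(counts: Mapping[str, int]) -> dict[str, float]:
    """Per-category share of the total suprathreshold territory.

    A vertex may be suprathreshold for several category contrasts; shares
    use per-category counts over the summed counts (not winner-take-all).
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError("zero total suprathreshold count")
    return {c: counts[c] / total for c in counts}


def percent_change(child_share: float, adult_share: float) -> float:
    """(adult - child) / child x 100."""
    if child_share == 0:
        raise ValidationError("child share is zero; percent change undefined")
    return (adult_share - child_share) / child_share * 100.0


def profile_vector(
    archive: PatternArchive,
    roi_order: Sequence[str] | None = None,
) -> ProfileVector:
    """Mean per-ROI contrast value per category, concatenated ROI-major."""
    rois = tuple(roi_order) if roi_order is not None else tuple(
        dict.fromkeys(archive.roi_labels.tolist())
    )
    maps = {c: selectivity_map(archive, c).t_values for c in CATEGORIES}
    values = [
        maps[c][archive.roi_labels == roi].mean()
        for roi in rois
        for c in CATEGORIES
    ]
    return ProfileVector(values=np.array(values), roi_order=rois)


def profile_correlation(a: ProfileVector, b: ProfileVector) -> float:
    """Pearson correlation of two profile vectors with identical ordering."""
    if a.roi_order != b.roi_order or a.category_order != b.category_order:
        raise ValidationError("profile orderings differ; refusing to reorder")
    return _pearson(a.values, b.values)
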