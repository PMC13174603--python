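"""Cross-validated representational similarity matrices.

Leave-one-run-out (LORO) scheme: for each fold, the held-out-run pattern of
category i is Pearson-correlated with the mean over the remaining runs of
category j; the 5x5 matrix of fold-averaged correlations is then
symmetrized as (M + M') / 2.  The diagonal indexes within-category
reliability, the off-diagonal cross-category similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ValidationError
from .synthgen import CATEGORIES, ANIMATE, INANIMATE, PatternArchive

__all__ = [
    "SimilarityMatrix",
    "BlockScheme",
    "ANIMATE_INANIMATE",
    "TRIPARTITE",
    "loro_similarity",
    "loro_fold_matrices",
    "within_between_category",
    "block_contrast",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Category x category correlation matrix with fold provenance."""

    values: np.ndarray
    categories: tuple[str, ...] = CATEGORIES
    fold_scheme: str = "loro"
    symmetrized: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.categories)
        if v.shape != (n, n):
            raise ValidationError(f"values must be {n}x{n}")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValidationError("correlations must lie in [-1, 1]")
        if self.symmetrized and not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("symmetrized matrix must equal its transpose")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.categories, columns=self.categories)


@dataclass(frozen=True)
class BlockScheme:
    """A grouping of the five categories into labeled blocks."""

    name: str
    blocks: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        flat = [c for b in self.blocks for c in b]
        if sorted(flat) != sorted(CATEGORIES):
            raise ValidationError("blocks must be disjoint and cover all 5 categories")

    def block_of(self, category: str) -> int:
        for i, b in enumerate(self.blocks):
            if category in b:
                return i
        raise ValidationError(f"category {category!r} not in scheme")


ANIMATE_INANIMATE = BlockScheme(
    "animate_inanimate", (ANIMATE, ("pseudowords",) + INANIMATE)
)
TRIPARTITE = BlockScheme("tripartite", (ANIMATE, ("pseudowords",), INANIMATE))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    nx, ny = np.linalg.norm(xm), np.linalg.norm(ym)
    if nx == 0 or ny == 0:
        raise DegenerateDataError("zero-variance vector in Pearson correlation")
    return float(np.clip(xm @ ym / (nx * ny), -1.0, 1.0))


def _check_patterns(archive: PatternArchive, level: str) -> list[int]:
    runs = archive.runs
    if len(runs) < 2:
        raise ValidationError("LORO requires >= 2 runs")
    if archive.n_vertices < 3:
        raise ValidationError("LORO requires >= 3 vertices")
    for r in runs:
        mat = archive.condition_matrix(r, level)
        for cond, row in mat.iterrows():
            if np.std(row.to_numpy()) == 0:
                raise DegenerateDataError(
                    f"zero-variance pattern: run {r}, condition {cond!r}"
                )
    return runs


def loro_fold_matrices(
    archive: PatternArchive,
    level: str = "category",
    symmetrize_folds: bool = True,
) -> list[SimilarityMatrix]:
    """One similarity matrix per held-out run (fold).

    Each fold correlates the held-out run's patterns against the mean of
    the remaining runs; per-fold matrices are symmetrized by default so the
    stability/coupling analyses can consume them directly.
    """
    runs = _check_patterns(archive, level)
    items = list(archive.condition_matrix(runs[0], level).index)
    out = []
    for held in runs:
        test = archive.condition_matrix(held, level).to_numpy()
        train = np.mean(
            [archive.condition_matrix(r, level).to_numpy() for r in runs if r != held],
            axis=0,
        )
        m = np.empty((len(items), len(items)))
        for i in range(len(items)):
            for j in range(len(items)):
                m[i, j] = _pearson(test[i], train[j])
        if symmetrize_folds:
            m = (m + m.T) / 2
        out.append(
            SimilarityMatrix(
                values=m,
                categories=tuple(items),
                fold_scheme=f"loro_holdout_run{held}",
                symmetrized=symmetrize_folds,
            )
        )
    return out


def loro_similarity(
    archive: PatternArchive,
    level: str = "category",
    fisher_average: bool = False,
    pairwise_runs: bool = False,
) -> SimilarityMatrix:
    """Fold-averaged, symmetrized LORO similarity matrix.

    ``fisher_average`` averages fold correlations in Fisher-z space;
    ``pairwise_runs`` switches to run-vs-run correlation over all ordered
    run pairs (sensitivity-check mode) instead of held-out-vs-mean.
    """
    runs = _check_patterns(archive, level)
    items = list(archive.condition_matrix(runs[0], level).index)
    n = len(items)
    folds = []
    if pairwise_runs:
        for ra, rb in combinations(runs, 2):
            a = archive.condition_matrix(ra, level).to_numpy()
            b = archive.condition_matrix(rb, level).to_numpy()
            m = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    m[i, j] = _pearson(a[i], b[j])
            folds.append(m)
    else:
        folds = [
            sm.values
            for sm in loro_fold_matrices(archive, level, symmetrize_folds=False)
        ]
    stacked = np.stack(folds)
    if fisher_average:
        clipped = np.clip(stacked, -1 + 1e-12, 1 - 1e-12)
        mean = np.tanh(np.arctanh(clipped).mean(axis=0))
    else:
        mean = stacked.mean(axis=0)
    sym = (mean + mean.T) / 2
    scheme = "pairwise_runs" if pairwise_runs else "loro_holdout_vs_mean"
    return SimilarityMatrix(values=sym, categories=tuple(items), fold_scheme=scheme)


def within_between_category(sm: SimilarityMatrix) -> dict[str, float]:
    """Mean diagonal (within-category) vs mean unique off-diagonal cells."""
    v = sm.values
    n = v.shape[0]
    iu = np.triu_indices(n, k=1)
    return {
        "within_mean": float(np.diag(v).mean()),
        "between_mean": float(v[iu].mean()),
    }


def block_contrast(sm: SimilarityMatrix, scheme: BlockScheme) -> dict[str, float]:
    """Within-block vs between-block mean similarity (diagonal excluded)."""
    cats = sm.categories
    within, between = [], []
    for i, j in combinations(range(len(cats)), 2):
        pair = sm.values[i, j]
        if scheme.block_of(cats[i]) == scheme.block_of(cats[j]):
            within.append(pair)
        else:
            between.append(pair)
    if not within:
        raise ValidationError("no within-block pairs in scheme")
    return {
        "within_block_mean": float(np.mean(within)),
        "between_block_mean": float(np.mean(between)),
    }
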