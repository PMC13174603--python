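"""Representational geometry: PCA embeddings, distances, Procrustes, hulls.

Category (or subcategory) response patterns are z-scored across vertices,
embedded with PCA, and compared across subjects and groups through full
Procrustes alignment (translation, uniform scale, rotation with reflection
permitted).  The group template is a generalized-Procrustes mean; the
dispersion of a cohort is the mean Procrustes distance of its members to
that template.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateDataError, ValidationError
from .rsm import BlockScheme, _pearson
from .synthgen import PatternArchive

__all__ = [
    "EmbeddingConfiguration",
    "AlignmentReport",
    "embed_patterns",
    "pairwise_distances",
    "axis_contrast",
    "procrustes_align",
    "group_template",
    "dispersion",
    "convex_hull_area",
    "clusters_from_scheme",
]


@dataclass(frozen=True)
class EmbeddingConfiguration:
    """Item coordinates in a low-dimensional component space."""

    points: np.ndarray
    item_labels: tuple[str, ...]
    owner: str = ""
    n_components: int = 2

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[0] != len(self.item_labels):
            raise ValidationError("points must be items x components")
        if pts.shape[1] != self.n_components or self.n_components < 2:
            raise ValidationError("n_components must be >= 2 and match points")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("coordinates must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points,
            index=self.item_labels,
            columns=[f"pc{i + 1}" for i in range(self.n_components)],
        )


@dataclass(frozen=True)
class AlignmentReport:
    """Residual misfit and similarity after full Procrustes alignment."""

    procrustes_distance: float
    template_similarity: float
    transform: dict

    def __post_init__(self) -> None:
        if self.procrustes_distance < -1e-12:
            raise ValidationError("procrustes_distance must be >= 0")
        if self.procrustes_distance <= 1e-9 and abs(self.template_similarity - 1) > 1e-6:
            raise ValidationError("zero distance must imply similarity 1")


def embed_patterns(
    archive_or_matrix: PatternArchive | pd.DataFrame,
    n_components: int = 2,
    level: str = "subcategory",
    owner: str | None = None,
) -> EmbeddingConfiguration:
    """PCA embedding of run-averaged item patterns.

    Each item pattern is z-scored across vertices, items are centered, and
    projected onto the leading principal components.  Component sign is
    fixed by making the largest-magnitude vertex loading positive.
    """
    if isinstance(archive_or_matrix, PatternArchive):
        mat = archive_or_matrix.mean_patterns(level)
        owner = owner or archive_or_matrix.subject_id
    else:
        mat = archive_or_matrix
        owner = owner or "matrix"
    items = tuple(mat.index)
    X = mat.to_numpy(dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValidationError("need items >= n_components + 1")
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateDataError("zero-variance item pattern; cannot z-score")
    X = (X - X.mean(axis=1, keepdims=True)) / sd
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    if rank < n_components:
        raise DegenerateDataError(
            f"input rank {rank} below requested {n_components} components"
        )
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return EmbeddingConfiguration(
        points=scores, item_labels=items, owner=owner, n_components=n_components
    )


def pairwise_distances(cfg: EmbeddingConfiguration) -> pd.DataFrame:
    """Symmetric Euclidean distance table over item pairs."""
    if len(cfg.item_labels) < 2:
        raise ValidationError("need >= 2 items for distances")
    d = squareform(pdist(cfg.points))
    return pd.DataFrame(d, index=cfg.item_labels, columns=cfg.item_labels)


def clusters_from_scheme(
    items: Sequence[str], scheme: BlockScheme
) -> dict[str, int]:
    """Map items (categories or 'category-subcategory' labels) to scheme blocks."""
    out = {}
    for it in items:
        cat = it.split("-", 1)[0]
        out[it] = scheme.block_of(cat)
    return out


def axis_contrast(
    cfg: EmbeddingConfiguration,
    clusters: Mapping[str, object],
) -> dict[str, float]:
    """Mean within-cluster item distance and between-centroid distance.

    Clusters with a single item contribute nothing to the within term; the
    between term is the mean Euclidean distance between cluster centroids
    in the embedding space (pairwise-averaged when there are > 2 clusters).
    """
    labels = list(cfg.item_labels)
    groups: dict[object, list[int]] = {}
    for i, it in enumerate(labels):
        if it not in clusters:
            raise ValidationError(f"item {it!r} missing from cluster mapping")
        groups.setdefault(clusters[it], []).append(i)
    if len(groups) < 2:
        raise ValidationError("between-centroid distance needs >= 2 clusters")
    within = []
    for ids in groups.values():
        for i, j in combinations(ids, 2):
            within.append(np.linalg.norm(cfg.points[i] - cfg.points[j]))
    if not within:
        raise ValidationError("all clusters singleton; within distance undefined")
    centroids = [cfg.points[ids].mean(axis=0) for ids in groups.values()]
    between = [
        np.linalg.norm(a - b) for a, b in combinations(centroids, 2)
    ]
    return {
        "within_cluster_mean": float(np.mean(within)),
        "between_centroid_distance": float(np.mean(between)),
    }


def _centered(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    mean = points.mean(axis=0)
    c = points - mean
    norm = np.linalg.norm(c)
    if norm == 0:
        raise DegenerateDataError("all points coincident; Procrustes undefined")
    return c, mean, norm


def procrustes_align(
    source: EmbeddingConfiguration,
    target: EmbeddingConfiguration,
) -> tuple[EmbeddingConfiguration, AlignmentReport]:
    """Full Procrustes: translate, uniformly scale, rotate (reflection allowed).

    ``procrustes_distance`` is the normalized residual 1 - (sum of the
    cross-covariance singular values)^2, identical to the classical
    disparity between unit-norm centered configurations.
    ``template_similarity`` is the Pearson correlation between flattened
    aligned-source and target coordinates.
    """
    if source.item_labels != target.item_labels:
        raise ValidationError("source and target must share item labels")
    if source.n_components != target.n_components:
        raise ValidationError("source and target must share n_components")
    X, _, nx = _centered(source.points)
    Y, y_mean, ny = _centered(target.points)
    X0, Y0 = X / nx, Y / ny
    U, S, Vt = np.linalg.svd(X0.T @ Y0)
    R = U @ Vt
    trace = S.sum()
    scale = trace * ny / nx
    aligned_pts = scale * (X @ R) + y_mean
    distance = max(0.0, 1.0 - trace**2)
    similarity = _pearson(aligned_pts.ravel(), target.points.ravel())
    aligned = EmbeddingConfiguration(
        points=aligned_pts,
        item_labels=source.item_labels,
        owner=source.owner,
        n_components=source.n_components,
    )
    report = AlignmentReport(
        procrustes_distance=float(distance),
        template_similarity=float(similarity),
        transform={
            "rotation": R.tolist(),
            "scale": float(scale),
            "translation": y_mean.tolist(),
            "reflection": bool(np.linalg.det(R) < 0),
        },
    )
    return aligned, report


def group_template(
    cfgs: Sequence[EmbeddingConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> EmbeddingConfiguration:
    """Generalized-Procrustes mean configuration (unit-norm, centered).

    Iteratively aligns every configuration to the current mean and
    re-averages until the mean moves by less than ``tol`` (Frobenius) or
    ``max_iter`` iterations.
    """
    if len(cfgs) < 2:
        raise ValidationError("group template needs >= 2 configurations")
    labels = cfgs[0].item_labels
    if any(c.item_labels != labels for c in cfgs):
        raise ValidationError("configurations must share item labels")

    def normalize(p: np.ndarray) -> np.ndarray:
        c, _, n = _centered(p)
        return c / n

    ref = normalize(cfgs[0].points)
    ref_cfg = EmbeddingConfiguration(ref, labels, "template", cfgs[0].n_components)
    for _ in range(max_iter):
        aligned = [procrustes_align(c, ref_cfg)[0].points for c in cfgs]
        new = normalize(np.mean(aligned, axis=0))
        moved = np.linalg.norm(new - ref)
        ref = new
        ref_cfg = EmbeddingConfiguration(ref, labels, "template", cfgs[0].n_components)
        if moved < tol:
            break
    return ref_cfg


def dispersion(
    cfgs: Sequence[EmbeddingConfiguration],
    template: EmbeddingConfiguration | None = None,
) -> float:
    """Mean Procrustes distance of each configuration to the group template."""
    if template is None:
        template = group_template(cfgs)
    return float(
        np.mean([procrustes_align(c, template)[1].procrustes_distance for c in cfgs])
    )


def convex_hull_area(cfg: EmbeddingConfiguration) -> float:
    """Area of the minimal polygon enclosing all items (first two components)."""
    pts = cfg.points[:, :2]
    if pts.shape[0] < 3:
        raise ValidationError("convex hull needs >= 3 points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-12) < 2:
        raise DegenerateDataError("zero-area hull: points are collinear")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise DegenerateDataError("zero-area hull") from exc
    return float(hull.volume)  # in 2-D, .volume is the polygon area
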