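"""Binary partition models: enumeration, scoring, ranking.

A partition model assigns categories to two labeled groups and is encoded
as a symmetric 5x5 binary matrix with 1 where two categories share a group
(diagonal cell 1 iff the category belongs to either group).  Models are
scored by Pearson-correlating the 15 unique cells (5 diagonal + 10 upper
off-diagonal) of the model matrix against a symmetrized similarity matrix,
then ranked by descending score with percentile = rank / N.

Enumeration modes over the five categories:

- ``full_bipartition``: unordered splits into two non-empty groups covering
  every category (15 models).
- ``disjoint_pairs``: all unordered pairs of disjoint non-empty subsets,
  partial coverage allowed (90 models).
- ``partial_pairs``: disjoint pairs whose union leaves at least one
  category unassigned (75 models) — the candidate-family size used when a
  fixed 75-model ranking is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ValidationError
from .rsm import SimilarityMatrix, _pearson

__all__ = [
    "PartitionModel",
    "PartitionRanking",
    "enumerate_partitions",
    "score_partition",
    "rank_partitions",
    "FB_WPO",
    "W_FBPO",
]

_INITIALS = {"faces": "F", "bodies": "B", "pseudowords": "W", "places": "P", "objects": "O"}


@dataclass(frozen=True)
class PartitionModel:
    """Two disjoint, non-empty groups of categories plus the binary model matrix."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b:
            raise ValidationError("both groups must be non-empty")
        if a & b:
            raise ValidationError("groups must be disjoint")
        if not (a | b) <= set(self.categories):
            raise ValidationError("groups must draw from the category list")
        # canonical order: group containing the earliest category first
        order = {c: i for i, c in enumerate(self.categories)}
        ga = tuple(sorted(self.group_a, key=order.get))
        gb = tuple(sorted(self.group_b, key=order.get))
        if order[gb[0]] < order[ga[0]]:
            ga, gb = gb, ga
        object.__setattr__(self, "group_a", ga)
        object.__setattr__(self, "group_b", gb)

    @property
    def name(self) -> str:
        def tag(grp: tuple[str, ...]) -> str:
            return "".join(_INITIALS.get(c, c[0].upper()) for c in grp)

        return f"{tag(self.group_a)}_{tag(self.group_b)}"

    @property
    def model_matrix(self) -> np.ndarray:
        n = len(self.categories)
        m = np.zeros((n, n))
        idx = {c: i for i, c in enumerate(self.categories)}
        for grp in (self.group_a, self.group_b):
            ids = [idx[c] for c in grp]
            for i in ids:
                for j in ids:
                    m[i, j] = 1.0
        return m


@dataclass(frozen=True)
class PartitionRanking:
    """Descending-score ranking with percentile = rank / N."""

    entries: tuple[dict, ...]

    def __post_init__(self) -> None:
        n = len(self.entries)
        scores = [e["score"] for e in self.entries]
        if any(self.entries[i]["rank"] != i + 1 for i in range(n)):
            raise ValidationError("ranks must be 1..N without gaps")
        if any(scores[i] < scores[i + 1] - 1e-12 for i in range(n - 1)):
            raise ValidationError("scores must be non-increasing in rank")

    def percentile_at(self, rank: int) -> float:
        return self.entries[rank - 1]["percentile"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": e["model"].name,
                    "group_a": "+".join(e["model"].group_a),
                    "group_b": "+".join(e["model"].group_b),
                    "score": e["score"],
                    "rank": e["rank"],
                    "percentile": e["percentile"],
                }
                for e in self.entries
            ]
        )


def enumerate_partitions(
    categories: tuple[str, ...],
    mode: str = "full_bipartition",
) -> list[PartitionModel]:
    """Enumerate candidate two-group models in a canonical deterministic order."""
    categories = tuple(categories)
    if len(categories) < 2:
        raise ValidationError("need >= 2 categories to partition")
    if mode not in ("full_bipartition", "disjoint_pairs", "partial_pairs"):
        raise ValidationError(f"unknown enumeration mode {mode!r}")
    seen: set[frozenset] = set()
    models: list[PartitionModel] = []
    # brute force over all assignments of each category to group a / b / neither
    for assign in product((0, 1, 2), repeat=len(categories)):
        ga = tuple(c for c, k in zip(categories, assign) if k == 0)
        gb = tuple(c for c, k in zip(categories, assign) if k == 1)
        if not ga or not gb:
            continue
        covered = len(ga) + len(gb) == len(categories)
        if mode == "full_bipartition" and not covered:
            continue
        if mode == "partial_pairs" and covered:
            continue
        key = frozenset((frozenset(ga), frozenset(gb)))
        if key in seen:
            continue
        seen.add(key)
        models.append(PartitionModel(ga, gb, categories))
    order = {c: i for i, c in enumerate(categories)}

    def sort_key(m: PartitionModel):
        return (
            len(m.group_a) + len(m.group_b),
            tuple(order[c] for c in m.group_a),
            tuple(order[c] for c in m.group_b),
        )

    models.sort(key=sort_key)
    return models


def _unique_cells(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    iu = np.triu_indices(n, k=0)  # diagonal + unique off-diagonal
    return m[iu]


def score_partition(
    model: PartitionModel,
    sm: SimilarityMatrix,
    include_diagonal: bool = True,
) -> float:
    """Pearson correlation between model-matrix cells and similarity cells."""
    if not sm.symmetrized:
        raise ValidationError("score_partition requires a symmetrized matrix")
    if tuple(sm.categories) != tuple(model.categories):
        raise ValidationError("model and matrix category orders differ")
    mm, vv = model.model_matrix, sm.values
    if include_diagonal:
        x, y = _unique_cells(mm), _unique_cells(vv)
    else:
        iu = np.triu_indices(mm.shape[0], k=1)
        x, y = mm[iu], vv[iu]
    try:
        return _pearson(x, y)
    except DegenerateDataError as exc:
        raise DegenerateDataError("degenerate model or matrix") from exc


def rank_partitions(
    models: list[PartitionModel],
    sm: SimilarityMatrix,
    include_diagonal: bool = True,
) -> PartitionRanking:
    """Score all models against ``sm`` and rank them by descending score.

    Ties break by the canonical enumeration order of the model list;
    percentile = rank / N.
    """
    if len(models) < 2:
        raise ValidationError("ranking needs >= 2 models")
    scored = []
    n_degenerate = 0
    for pos, m in enumerate(models):
        try:
            s = score_partition(m, sm, include_diagonal)
        except DegenerateDataError:
            n_degenerate += 1
            continue
        scored.append((s, pos, m))
    if not scored:
        raise DegenerateDataError("all models degenerate against this matrix")
    scored.sort(key=lambda t: (-t[0], t[1]))
    n = len(scored)
    entries = tuple(
        {
            "model": m,
            "score": float(s),
            "rank": r + 1,
            "percentile": (r + 1) / n,
        }
        for r, (s, _, m) in enumerate(scored)
    )
    return PartitionRanking(entries)


# Named reference models: the animate-inanimate axis and the word axis.
from .synthgen import CATEGORIES as _CATS  # noqa: E402

FB_WPO = PartitionModel(("faces", "bodies"), ("pseudowords", "places", "objects"), _CATS)
W_FBPO = PartitionModel(("pseudowords",), ("faces", "bodies", "places", "objects"), _CATS)
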