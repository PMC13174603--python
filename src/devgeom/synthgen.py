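"""Synthetic cohorts of category-selective response patterns and tissue data.

The generator emulates the statistical structure of a developmental
category-localizer study: two age groups viewing five stimulus categories
(faces, bodies, pseudowords, places, objects, each with two subcategories)
over three runs, measured in two regions (VLPFC, VTC) of both hemispheres.

Signal model, per subject s, run r, subcategory u of category c::

    pattern = T[hemi, region]                        (shared visual template)
            + s_anim * A          if c in {faces, bodies}
            + s_anim * I          if c in {places, objects}
            + s_word * W          if c == pseudowords
            + bump_c              (category-selective vertices, lateralized)
            + jitter * strength_c * D[u]              (subcategory identity)
            + E[s, u]             (subject idiosyncrasy, SD subject_noise_sd)
            + N(0, run_noise_sd)  (independent run noise)

A, I, W and the subcategory directions D are unit-variance patterns drawn
once per hemisphere x region; s_anim and s_word are the per
group x hemisphere x region structure strengths.  Every category-specific
term scales with the category's block strength, so a cohort with all
strengths at zero is exactly structureless: within-category and
between-category cross-run correlations then share the same expectation.

Synthetic "t-values" are the pattern values themselves; no GLM is
simulated, since all downstream statistics consume t-maps as given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "CATEGORIES",
    "SUBCATEGORIES",
    "ANIMATE",
    "INANIMATE",
    "GROUPS",
    "HEMISPHERES",
    "REGIONS",
    "VLPFC_ROIS",
    "VTC_ROIS",
    "CohortSpec",
    "PatternArchive",
    "TissueSample",
    "generate_cohort",
    "generate_tissue",
    "generate_expression",
    "write_cohort",
    "read_cohort",
    "read_archive",
]

CATEGORIES: tuple[str, ...] = ("faces", "bodies", "pseudowords", "places", "objects")
SUBCATEGORIES: dict[str, tuple[str, str]] = {
    "faces": ("faces-child", "faces-adult"),
    "bodies": ("bodies-whole", "bodies-limbs"),
    "pseudowords": ("pseudowords-words", "pseudowords-numbers"),
    "places": ("places-corridors", "places-houses"),
    "objects": ("objects-cars", "objects-guitars"),
}
ANIMATE: tuple[str, ...] = ("faces", "bodies")
INANIMATE: tuple[str, ...] = ("places", "objects")
GROUPS: tuple[str, ...] = ("child", "adult")
HEMISPHERES: tuple[str, ...] = ("LH", "RH")
REGIONS: tuple[str, ...] = ("VLPFC", "VTC")

VLPFC_ROIS: tuple[str, ...] = (
    "IFJ", "pIFS", "mIFS", "aIFS", "SPCS", "s-IPCS", "i-IPCS", "op", "tr", "or",
)
VTC_ROIS: tuple[str, ...] = (
    "FG1", "FG2", "FG3", "FG4", "hOc3v", "hOc4v", "hOc3vla", "hOc4vlp",
)

StrengthSpec = float | Mapping[tuple[str, str, str], float]

# Study-like default structure strengths per (group, hemisphere, region):
# VTC carries strong bilateral animate-inanimate structure in both groups;
# right VLPFC animacy sharpens from childhood to adulthood; left VLPFC
# carries an early, strong word axis.
DEFAULT_ANIMACY: dict[tuple[str, str, str], float] = {
    **{(g, h, "VTC"): 1.0 for g in GROUPS for h in HEMISPHERES},
    ("child", "LH", "VLPFC"): 0.3,
    ("adult", "LH", "VLPFC"): 0.4,
    ("child", "RH", "VLPFC"): 0.5,
    ("adult", "RH", "VLPFC"): 1.0,
}
DEFAULT_WORD: dict[tuple[str, str, str], float] = {
    **{(g, h, "VTC"): 0.5 for g in GROUPS for h in HEMISPHERES},
    ("child", "LH", "VLPFC"): 0.8,
    ("adult", "LH", "VLPFC"): 1.0,
    ("child", "RH", "VLPFC"): 0.2,
    ("adult", "RH", "VLPFC"): 0.2,
}
# Fraction of each category's suprathreshold activity placed in the right
# hemisphere: pseudowords left-lateralized; faces/bodies/objects rightward.
DEFAULT_RH_BIAS: dict[str, float] = {
    "faces": 0.62,
    "bodies": 0.58,
    "pseudowords": 0.35,
    "places": 0.52,
    "objects": 0.55,
}


def _resolve(strength: StrengthSpec, group: str, hemi: str, region: str) -> float:
    if isinstance(strength, Mapping):
        try:
            return float(strength[(group, hemi, region)])
        except KeyError as exc:
            raise ValidationError(
                f"strength mapping missing key {(group, hemi, region)}"
            ) from exc
    return float(strength)


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of one synthetic localizer cohort."""

    n_children: int = 30
    n_adults: int = 30
    n_runs: int = 3
    categories: tuple[str, ...] = CATEGORIES
    subcats_per_category: int = 2
    n_vertices: int = 500
    regions: tuple[str, ...] = REGIONS
    hemispheres: tuple[str, ...] = HEMISPHERES
    animacy_strength: StrengthSpec = field(default_factory=lambda: dict(DEFAULT_ANIMACY))
    word_axis_strength: StrengthSpec = field(default_factory=lambda: dict(DEFAULT_WORD))
    run_noise_sd: float = 1.0
    subject_noise_sd: float = 0.3
    selectivity_amplitude: float = 3.0
    selective_fraction: float = 0.08
    subcat_jitter: float = 0.25
    rh_bias: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RH_BIAS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_children < 1 or self.n_adults < 1:
            raise ValidationError("n_children/n_adults must be >= 1")
        if self.n_runs < 2:
            raise ValidationError("n_runs must be >= 2 (cross-validation needs >= 2 folds)")
        if tuple(self.categories) != CATEGORIES:
            raise ValidationError(
                f"categories must be {CATEGORIES} in fixed order, got {self.categories}"
            )
        if self.subcats_per_category != 2:
            raise ValidationError("subcats_per_category must be 2")
        if self.n_vertices < 3:
            raise ValidationError("n_vertices must be >= 3")
        for name in ("run_noise_sd",):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v}")
        for name in ("subject_noise_sd", "selectivity_amplitude", "subcat_jitter"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if not (0 <= self.selective_fraction < 1):
            raise ValidationError("selective_fraction must lie in [0, 1)")
        for g in GROUPS:
            for h in self.hemispheres:
                for r in self.regions:
                    for name, spec in (
                        ("animacy_strength", self.animacy_strength),
                        ("word_axis_strength", self.word_axis_strength),
                    ):
                        v = _resolve(spec, g, h, r)
                        if not (np.isfinite(v) and v >= 0):
                            raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        for c, b in self.rh_bias.items():
            if c not in CATEGORIES or not (0 <= b <= 1):
                raise ValidationError(f"rh_bias: bad entry {c}={b}")

    def to_json(self) -> str:
        def _enc(v):
            if isinstance(v, Mapping):
                return {"|".join(map(str, k)) if isinstance(k, tuple) else k: v[k] for k in v}
            return v

        return json.dumps(
            {k: _enc(getattr(self, k)) for k in self.__dataclass_fields__},
            indent=1,
            sort_keys=True,
        )


@dataclass
class PatternArchive:
    """Response patterns for one subject x hemisphere x region.

    ``data`` holds synthetic t-values with one row per vertex and one
    column per run x subcategory, named ``run<r>_<subcategory>``.
    Category-level patterns are the mean of the two subcategory patterns.
    """

    subject_id: str
    group: str
    age: float
    hemisphere: str
    region: str
    roi_labels: np.ndarray
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if self.hemisphere not in HEMISPHERES or self.region not in REGIONS:
            raise ValidationError("bad hemisphere/region label")
        if len(self.roi_labels) != len(self.data):
            raise ValidationError("roi_labels must match the vertex count")
        if self.data.isna().any().any():
            raise ValidationError("pattern data contains missing values")
        expected = {
            f"run{r}_{sub}"
            for r in self.runs
            for subs in SUBCATEGORIES.values()
            for sub in subs
        }
        if set(self.data.columns) != expected:
            raise ValidationError("every (run, subcategory) pair must appear exactly once")

    @property
    def n_vertices(self) -> int:
        return len(self.data)

    @property
    def runs(self) -> list[int]:
        return sorted({int(c.split("_", 1)[0][3:]) for c in self.data.columns})

    def pattern(self, run: int, condition: str) -> np.ndarray:
        """Pattern vector for one run and one category or subcategory."""
        if condition in SUBCATEGORIES:  # category: mean of its subcategories
            cols = [f"run{run}_{sub}" for sub in SUBCATEGORIES[condition]]
            return self.data[cols].to_numpy().mean(axis=1)
        col = f"run{run}_{condition}"
        if col not in self.data.columns:
            raise ValidationError(f"unknown run/condition {col!r}")
        return self.data[col].to_numpy()

    def condition_matrix(self, run: int, level: str = "category") -> pd.DataFrame:
        """Conditions x vertices matrix for one run at category or subcategory level."""
        if level == "category":
            items = list(CATEGORIES)
        elif level == "subcategory":
            items = [s for c in CATEGORIES for s in SUBCATEGORIES[c]]
        else:
            raise ValidationError("level must be 'category' or 'subcategory'")
        return pd.DataFrame(
            [self.pattern(run, it) for it in items], index=items
        )

    def mean_patterns(self, level: str = "category") -> pd.DataFrame:
        """Conditions x vertices matrix averaged over all runs."""
        mats = [self.condition_matrix(r, level) for r in self.runs]
        return sum(mats) / len(mats)


def _orthogonalize_components(
    raw: list[np.ndarray], masks: list[np.ndarray], n_v: int
) -> list[np.ndarray]:
    """Make the shared signal components exactly orthogonal.

    Each Gaussian component is centered, projected orthogonal to the
    (centered) selective-vertex masks and to all previously processed
    components, and rescaled to unit SD.  The realized inter-component
    geometry is then a deterministic function of the strengths alone, so
    two regions generated with equal strengths share the same expected
    similarity structure (the generating partition is the analytic
    optimum).  Skipped when there are too few vertices for a full basis.
    """
    basis: list[np.ndarray] = []
    for m in masks:
        mc = m - m.mean()
        for b in basis:
            mc = mc - (mc @ b) * b
        norm = np.linalg.norm(mc)
        if norm > 1e-12:
            basis.append(mc / norm)
    if n_v < len(raw) + len(basis) + 2:
        return [v - v.mean() for v in raw]  # degrade gracefully at tiny sizes
    out = []
    for v in raw:
        vc = v - v.mean()
        for b in basis:
            vc = vc - (vc @ b) * b
        sd = vc.std()
        vc = vc / sd
        basis.append(vc / np.linalg.norm(vc))
        out.append(vc)
    return out


def _roi_assignment(region: str, n_vertices: int) -> np.ndarray:
    rois = VLPFC_ROIS if region == "VLPFC" else VTC_ROIS
    labels = np.empty(n_vertices, dtype=object)
    for roi, idx in zip(rois, np.array_split(np.arange(n_vertices), len(rois))):
        labels[idx] = roi
    return labels


def generate_cohort(spec: CohortSpec) -> list[PatternArchive]:
    """Generate one cohort; deterministic given ``spec`` (incl. its seed)."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_shared, ss_subjects, ss_ages = root.spawn(3)

    # Shared structure per hemisphere x region: template, block components,
    # subcategory directions, selective vertex sets.
    shared: dict[tuple[str, str], dict] = {}
    rng_shared = np.random.default_rng(ss_shared)
    n_v = spec.n_vertices
    subcats = [s for c in CATEGORIES for s in SUBCATEGORIES[c]]
    n_sel = int(round(spec.selective_fraction * n_v))
    for h in spec.hemispheres:
        for reg in spec.regions:
            order = rng_shared.permutation(n_v)
            sel = {}
            for i, c in enumerate(CATEGORIES):
                mask = np.zeros(n_v)
                mask[order[i * n_sel : (i + 1) * n_sel]] = 1.0
                sel[c] = mask
            names = ["template", "animate", "inanimate", "word", *subcats]
            raw = [rng_shared.standard_normal(n_v) for _ in names]
            vecs = _orthogonalize_components(raw, list(sel.values()), n_v)
            comp = dict(zip(names, vecs))
            comp = {
                "template": comp["template"],
                "animate": comp["animate"],
                "inanimate": comp["inanimate"],
                "word": comp["word"],
                "subcat_dirs": {s: comp[s] for s in subcats},
                "selective": sel,
            }
            shared[(h, reg)] = comp

    rng_ages = np.random.default_rng(ss_ages)
    ages = {
        "child": rng_ages.uniform(5, 12, size=spec.n_children),
        "adult": rng_ages.uniform(20, 29, size=spec.n_adults),
    }

    block_of = {c: "animate" for c in ANIMATE}
    block_of.update({c: "inanimate" for c in INANIMATE})
    block_of["pseudowords"] = "word"

    archives: list[PatternArchive] = []
    subject_seeds = iter(ss_subjects.spawn(spec.n_children + spec.n_adults))
    index = 0
    for group, n_group in (("child", spec.n_children), ("adult", spec.n_adults)):
        for i in range(n_group):
            index += 1
            sid = f"sub-{index:03d}"
            rng = np.random.default_rng(next(subject_seeds))
            for h in spec.hemispheres:
                for reg in spec.regions:
                    comp = shared[(h, reg)]
                    s_anim = _resolve(spec.animacy_strength, group, h, reg)
                    s_word = _resolve(spec.word_axis_strength, group, h, reg)
                    strength = {
                        c: (s_word if c == "pseudowords" else s_anim)
                        for c in CATEGORIES
                    }
                    cols = {}
                    idio = {
                        s: spec.subject_noise_sd * rng.standard_normal(n_v)
                        for s in subcats
                    }
                    for c in CATEGORIES:
                        hemi_mult = (
                            2 * spec.rh_bias.get(c, 0.5)
                            if h == "RH"
                            else 2 * (1 - spec.rh_bias.get(c, 0.5))
                        )
                        base = (
                            comp["template"]
                            + strength[c] * comp[block_of[c]]
                            + spec.selectivity_amplitude
                            * strength[c]
                            * hemi_mult
                            * comp["selective"][c]
                        )
                        for sub in SUBCATEGORIES[c]:
                            fixed = (
                                base
                                + spec.subcat_jitter
                                * strength[c]
                                * comp["subcat_dirs"][sub]
                                + idio[sub]
                            )
                            for r in range(1, spec.n_runs + 1):
                                cols[f"run{r}_{sub}"] = (
                                    fixed
                                    + spec.run_noise_sd * rng.standard_normal(n_v)
                                )
                    data = pd.DataFrame(cols)
                    archives.append(
                        PatternArchive(
                            subject_id=sid,
                            group=group,
                            age=float(ages[group][i]),
                            hemisphere=h,
                            region=reg,
                            roi_labels=_roi_assignment(reg, n_v),
                            data=data,
                        )
                    )
    return archives


# ---------------------------------------------------------------------------
# Tissue (quantitative MRI) generator
# ---------------------------------------------------------------------------


@dataclass
class TissueSample:
    """Per-voxel R1 (1/s) and MTV (fraction) for one subject x hemisphere x lobe."""

    subject_id: str
    age: float
    hemisphere: str
    lobe: str
    r1: np.ndarray
    mtv: np.ndarray

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=float)
        self.mtv = np.asarray(self.mtv, dtype=float)
        if self.r1.shape != self.mtv.shape or self.r1.size == 0:
            raise ValidationError("r1 and mtv must be non-empty and equal-length")
        if np.any(self.r1 <= 0):
            raise ValidationError("R1 must be positive")
        if np.any((self.mtv <= 0) | (self.mtv >= 1)):
            raise ValidationError("MTV must lie strictly in (0, 1)")


def _quantile_grid(n: int) -> np.ndarray:
    """Deterministic standardized grid (mean exactly 0, SD exactly 1)."""
    z = stats.norm.ppf((np.arange(n) + 0.5) / n)
    z -= z.mean()
    return z / z.std()


def generate_tissue(
    n_subjects: int,
    age_range: tuple[float, float] = (5.0, 54.0),
    trajectory: str = "linear",
    n_voxels: int = 120,
    seed: int = 0,
    *,
    hemisphere: str = "RH",
    lobe: str = "VTC",
    ages: Sequence[float] | None = None,
    r1_base: float = 0.62,
    r1_range: float = 0.13,
    r1_tau: float = 8.0,
    dip_age: float = 18.0,
    dip_width: float = 2.5,
    dip_depth: float = 0.05,
    het_sd0: float = 0.02,
    het_slope: float = 0.0008,
    r1_mtv_slope_child: float = 1.0,
    r1_mtv_slope_adult: float = 0.7,
    subject_sd: float = 0.01,
    voxel_noise_sd: float = 0.005,
) -> list[TissueSample]:
    """Generate per-voxel R1/MTV samples around an age trajectory.

    ``trajectory='linear'`` yields a monotone increase with age (VTC-like,
    saturating-exponential growth that plateaus in adulthood, the standard
    lifespan-maturation shape); ``'dip'`` adds a Gaussian-shaped adolescent
    dip centred at ``dip_age`` (right-VLPFC-like).  Inter-voxel R1 SD grows
    linearly with age at ``het_slope`` per year.  Voxel deviations follow a
    fixed standardized quantile grid, so noiseless ROI means track the
    trajectory exactly.
    """
    lo, hi = float(age_range[0]), float(age_range[1])
    if not (5.0 <= lo < hi <= 54.0):
        raise ValidationError("age_range must be a non-empty interval within [5, 54]")
    if trajectory not in ("linear", "dip"):
        raise ValidationError("trajectory must be 'linear' or 'dip'")
    if n_voxels < 10:
        raise ValidationError("n_voxels must be >= 10")
    rng = np.random.default_rng(seed)
    if ages is None:
        ages_arr = rng.uniform(lo, hi, size=n_subjects)
    else:
        ages_arr = np.asarray(ages, dtype=float)
        if ages_arr.size != n_subjects:
            raise ValidationError("ages must have length n_subjects")
    z = _quantile_grid(n_voxels)
    samples = []
    for i, age in enumerate(ages_arr):
        dip = (
            dip_depth * np.exp(-0.5 * ((age - dip_age) / dip_width) ** 2)
            if trajectory == "dip"
            else 0.0
        )
        growth = r1_range * (1.0 - np.exp(-(age - 5.0) / r1_tau))
        r1_mean = r1_base + growth - dip + subject_sd * rng.standard_normal()
        # MTV mean through a logistic squash so values stay in (0, 1)
        mtv_latent = -1.0 + 0.02 * (age - 5.0) - 10.0 * dip + subject_sd * rng.standard_normal()
        mtv_mean = 1.0 / (1.0 + np.exp(-mtv_latent))
        slope = r1_mtv_slope_child if age < 18 else r1_mtv_slope_adult
        target_sd = het_sd0 + het_slope * (age - 5.0)
        invwvf_mean = 1.0 / (1.0 - mtv_mean)
        invwvf = invwvf_mean + z * (target_sd / slope)
        invwvf = np.maximum(invwvf, 1.0 + 1e-6)
        mtv = 1.0 - 1.0 / invwvf
        r1 = (
            r1_mean
            + slope * (invwvf - invwvf.mean())
            + voxel_noise_sd * rng.standard_normal(n_voxels)
        )
        samples.append(
            TissueSample(
                subject_id=f"tis-{i + 1:03d}",
                age=float(age),
                hemisphere=hemisphere,
                lobe=lobe,
                r1=r1,
                mtv=mtv,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Developmental gene-expression generator
# ---------------------------------------------------------------------------


def generate_expression(
    genes: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    ages: Sequence[float],
    recovery: Mapping[str, bool],
    seed: int = 0,
    *,
    window: tuple[float, float] = (11.0, 20.0),
    decline: float = 0.6,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Gene x age expression table (RPKM-like) with an adolescent decline.

    Every set declines to ``decline`` of baseline across the adolescence
    window; sets flagged ``recovery=True`` ramp back to baseline after the
    window, the rest stay suppressed.  Each gene must belong to exactly one
    set.
    """
    genes = list(genes)
    ages_arr = np.asarray(ages, dtype=float)
    if ages_arr.size == 0:
        raise ValidationError("ages must be non-empty")
    membership: dict[str, str] = {}
    for set_name, members in sets.items():
        for g in members:
            if g in membership:
                raise ValidationError(f"gene {g!r} appears in two sets")
            membership[g] = set_name
    for g in genes:
        if g not in membership:
            raise ValidationError(f"gene {g!r} belongs to zero sets")
    for set_name in sets:
        if set_name not in recovery:
            raise ValidationError(f"recovery flag missing for set {set_name!r}")
    lo, hi = window
    if not np.any((ages_arr > lo) & (ages_arr < hi)):
        raise ValidationError("ages must span the adolescence window")

    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        base = 8.0 + 4.0 * rng.random()
        rec = recovery[membership[g]]
        values = []
        for age in ages_arr:
            if age <= lo:
                m = 1.0
            elif age < hi:  # linear decline across the window
                m = 1.0 - (1.0 - decline) * (age - lo) / (hi - lo)
            elif rec:
                # ramp back to baseline over 5 years, then flat
                m = min(1.0, decline + (1.0 - decline) * (age - hi) / 5.0)
            else:
                m = decline
            v = base * m
            if noise_sd > 0:
                v *= np.exp(noise_sd * rng.standard_normal())
            values.append(v)
        rows.append(values)
    return pd.DataFrame(rows, index=genes, columns=ages_arr)


# ---------------------------------------------------------------------------
# Archive I/O: one wide TSV per subject x hemisphere x region + manifest
# ---------------------------------------------------------------------------


def _archive_filename(a: PatternArchive) -> str:
    return f"{a.subject_id}_{a.hemisphere}_{a.region}.tsv"


def write_cohort(archives: Sequence[PatternArchive], outdir: str | Path, spec: CohortSpec | None = None) -> Path:
    """Write archives as TSVs plus a manifest and a JSON sidecar; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for a in archives:
        fname = _archive_filename(a)
        df = a.data.copy()
        df.insert(0, "roi", a.roi_labels)
        df.to_csv(outdir / fname, sep="\t", index_label="vertex", float_format="%.6f")
        rows.append(
            {
                "subject_id": a.subject_id,
                "group": a.group,
                "age": round(a.age, 3),
                "hemisphere": a.hemisphere,
                "region": a.region,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    if spec is not None:
        (outdir / "cohort.json").write_text(spec.to_json())
    return outdir


def read_archive(path: str | Path, subject_id: str, group: str, age: float, hemisphere: str, region: str) -> PatternArchive:
    df = pd.read_csv(path, sep="\t", index_col="vertex")
    roi = df.pop("roi").to_numpy()
    return PatternArchive(
        subject_id=subject_id,
        group=group,
        age=age,
        hemisphere=hemisphere,
        region=region,
        roi_labels=roi,
        data=df,
    )


def read_cohort(outdir: str | Path) -> list[PatternArchive]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    return [
        read_archive(
            outdir / row.file,
            row.subject_id,
            row.group,
            float(row.age),
            row.hemisphere,
            row.region,
        )
        for row in manifest.itertuples()
    ]


def subset(
    archives: Sequence[PatternArchive],
    group: str | None = None,
    hemisphere: str | None = None,
    region: str | None = None,
) -> list[PatternArchive]:
    """Filter a cohort by group / hemisphere / region."""
    out = []
    for a in archives:
        if group is not None and a.group != group:
            continue
        if hemisphere is not None and a.hemisphere != hemisphere:
            continue
        if region is not None and a.region != region:
            continue
        out.append(a)
    return out
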