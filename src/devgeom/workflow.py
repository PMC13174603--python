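"""End-to-end orchestration of the analysis graph on a synthetic cohort.

Stages (in dependency order): simulate -> rsm -> partitions -> geometry ->
decode -> coupling -> topography -> tissue.  Each stage writes TSV/JSON
under ``out/<stage>/``; a provenance record carries the config hash and
seed so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as coupling_mod
from . import decoding, geometry, partitions, topography
from . import rsm as rsm_mod
from . import synthgen
from . import tissue as tissue_mod
from .exceptions import ValidationError
from .statcore import compare_correlations, paired_t

log = logging.getLogger("devgeom")

STAGES = (
    "simulate",
    "rsm",
    "partitions",
    "geometry",
    "decode",
    "coupling",
    "topography",
    "tissue",
)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (see the TOML template in README)."""

    n_children: int = 10
    n_adults: int = 10
    n_runs: int = 3
    n_vertices: int = 200
    run_noise_sd: float = 1.0
    subject_noise_sd: float = 0.3
    seed: int = 0
    threshold: float = 2.5
    decode_permutations: int = 100
    displacement_permutations: int = 200
    tissue_subjects_per_group: int = 8
    tissue_voxels: int = 60
    stages: tuple[str, ...] = STAGES
    out_dir: str = "out"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        for s in cfg.stages:
            if s not in STAGES:
                raise ValidationError(f"unknown stage {s!r}")
        return cfg

    def cohort_spec(self) -> synthgen.CohortSpec:
        return synthgen.CohortSpec(
            n_children=self.n_children,
            n_adults=self.n_adults,
            n_runs=self.n_runs,
            n_vertices=self.n_vertices,
            run_noise_sd=self.run_noise_sd,
            subject_noise_sd=self.subject_noise_sd,
            seed=self.seed,
        )

    def identity(self) -> dict:
        """Config fields that determine the outputs (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def digest(self) -> str:
        blob = json.dumps(self.identity(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _cells_of(cfg: RunConfig):
    for g in synthgen.GROUPS:
        for h in synthgen.HEMISPHERES:
            for reg in synthgen.REGIONS:
                yield g, h, reg


def _load_cohort(cfg: RunConfig) -> list[synthgen.PatternArchive]:
    path = Path(cfg.out_dir) / "simulate"
    if not (path / "manifest.tsv").exists():
        raise ValidationError("missing upstream output: run the 'simulate' stage first")
    return synthgen.read_cohort(path)


def stage_simulate(cfg: RunConfig) -> list[synthgen.PatternArchive]:
    spec = cfg.cohort_spec()
    cohort = synthgen.generate_cohort(spec)
    synthgen.write_cohort(cohort, _stage_dir(cfg, "simulate"), spec)
    return cohort


def stage_rsm(cfg: RunConfig, cohort) -> pd.DataFrame:
    out = _stage_dir(cfg, "rsm")
    rows = []
    for a in cohort:
        sm = rsm_mod.loro_similarity(a)
        sm.to_frame().to_csv(
            out / f"{a.subject_id}_{a.hemisphere}_{a.region}_rsm.tsv", sep="\t"
        )
        wb = rsm_mod.within_between_category(sm)
        bc = rsm_mod.block_contrast(sm, rsm_mod.ANIMATE_INANIMATE)
        tc = rsm_mod.block_contrast(sm, rsm_mod.TRIPARTITE)
        base = dict(
            subject=a.subject_id, group=a.group, hemisphere=a.hemisphere, region=a.region
        )
        for stat, value in {**wb,
                            "animate_within": bc["within_block_mean"],
                            "animate_between": bc["between_block_mean"],
                            "tripartite_within": tc["within_block_mean"],
                            "tripartite_between": tc["between_block_mean"]}.items():
            rows.append({**base, "statistic": stat, "value": value})
    table = pd.DataFrame(rows)
    table.to_csv(out / "rsm_statistics.tsv", sep="\t", index=False)
    return table


def _group_mean_rsm(cohort, group, hemi, region) -> rsm_mod.SimilarityMatrix:
    mats = [
        rsm_mod.loro_similarity(a).values
        for a in synthgen.subset(cohort, group, hemi, region)
    ]
    return rsm_mod.SimilarityMatrix(values=np.mean(mats, axis=0), fold_scheme="group_mean")


def stage_partitions(cfg: RunConfig, cohort) -> pd.DataFrame:
    out = _stage_dir(cfg, "partitions")
    models = partitions.enumerate_partitions(synthgen.CATEGORIES, "full_bipartition")
    frames = []
    for g, h, reg in _cells_of(cfg):
        sm = _group_mean_rsm(cohort, g, h, reg)
        ranking = partitions.rank_partitions(models, sm)
        df = ranking.to_frame()
        df.insert(0, "group", g)
        df.insert(1, "hemisphere", h)
        df.insert(2, "region", reg)
        df.to_csv(out / f"{g}_{h}_{reg}_ranking.tsv", sep="\t", index=False)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "rankings.tsv", sep="\t", index=False)
    return table


def stage_geometry(cfg: RunConfig, cohort) -> dict:
    out = _stage_dir(cfg, "geometry")
    report: dict = {}
    rows = []
    for g, h, reg in _cells_of(cfg):
        members = synthgen.subset(cohort, g, h, reg)
        cfgs = [geometry.embed_patterns(a) for a in members]
        template = geometry.group_template(cfgs)
        disp = geometry.dispersion(cfgs, template)
        sims = [
            geometry.procrustes_align(c, template)[1].template_similarity for c in cfgs
        ]
        group_embed = geometry.embed_patterns(
            sum(a.mean_patterns("subcategory") for a in members) / len(members),
            owner=f"{g}_{h}_{reg}",
        )
        hull = geometry.convex_hull_area(group_embed)
        contrast = geometry.axis_contrast(
            group_embed,
            geometry.clusters_from_scheme(group_embed.item_labels, rsm_mod.ANIMATE_INANIMATE),
        )
        key = f"{g}_{h}_{reg}"
        report[key] = {
            "dispersion": disp,
            "template_similarity_mean": float(np.mean(sims)),
            "convex_hull_area": hull,
            **contrast,
        }
        for c in cfgs:
            df = c.to_frame()
            df.insert(0, "owner", c.owner)
            rows.append(df.assign(group=g, hemisphere=h, region=reg))
    pd.concat(rows).to_csv(out / "embeddings.tsv", sep="\t", index_label="item")
    (out / "geometry.json").write_text(json.dumps(report, indent=1))
    return report


def stage_decode(cfg: RunConfig, cohort) -> dict:
    out = _stage_dir(cfg, "decode")
    report: dict = {}
    for g in synthgen.GROUPS:
        for h in synthgen.HEMISPHERES:
            members = synthgen.subset(cohort, g, h, "VLPFC")
            key = f"{g}_{h}_VLPFC"
            report[key] = {}
            for gran, kwargs in [("category", {}), *[
                (f"cluster_k{k}", {"k": k}) for k in (2, 3, 4, 5)
            ]]:
                res = decoding.decode_with_null(
                    members,
                    n_permutations=cfg.decode_permutations,
                    seed=cfg.seed,
                    **kwargs,
                )
                report[key][gran] = {
                    "true_accuracy": res.true_accuracy,
                    "null_mean": res.null_mean,
                    "null_sd": float(np.std(res.shuffled_accuracies)),
                    "true_minus_shuffled": res.true_minus_shuffled,
                    "p_value": res.p_value,
                    "seed": res.seed,
                }
    (out / "decoding.json").write_text(json.dumps(report, indent=1))
    return report


def stage_coupling(cfg: RunConfig, cohort) -> dict:
    out = _stage_dir(cfg, "coupling")
    points = []
    cat_rows = {"child": [], "adult": []}
    for g in synthgen.GROUPS:
        for h in synthgen.HEMISPHERES:
            pfc = synthgen.subset(cohort, g, h, "VLPFC")
            vtc = synthgen.subset(cohort, g, h, "VTC")
            for a_pfc, a_vtc in zip(pfc, vtc):
                splits_p = rsm_mod.loro_fold_matrices(a_pfc)
                splits_v = rsm_mod.loro_fold_matrices(a_vtc)
                pt = coupling_mod.coupling_point(a_pfc.subject_id, h, splits_p, splits_v)
                points.append(
                    dict(
                        subject_id=pt.subject_id,
                        group=g,
                        hemisphere=h,
                        coupling=pt.coupling,
                        stability=pt.stability,
                        signed_distance=pt.signed_distance,
                    )
                )
                coords = coupling_mod.category_coordinates(splits_p, splits_v)
                for cat, row in coords.iterrows():
                    cat_rows[g].append(
                        dict(
                            subject_id=pt.subject_id,
                            hemisphere=h,
                            category=cat,
                            coupling=row["coupling"],
                            stability=row["stability"],
                        )
                    )
    table = pd.DataFrame(points)
    table.to_csv(out / "coupling_points.tsv", sep="\t", index=False)
    report = {}
    for g in synthgen.GROUPS:
        sd = table.query("group == @g")["signed_distance"]
        t = paired_t(sd)
        report[f"{g}_signed_distance"] = {
            "mean": float(sd.mean()), "t": t.statistic, "p": t.p, "dz": t.effect_size
        }
    disp = {}
    for h in synthgen.HEMISPHERES:
        child = pd.DataFrame([r for r in cat_rows["child"] if r["hemisphere"] == h])
        adult = pd.DataFrame([r for r in cat_rows["adult"] if r["hemisphere"] == h])
        vectors = coupling_mod.displacement(
            child, adult, cfg.displacement_permutations, cfg.seed
        )
        disp[h] = [
            dict(
                category=v.category,
                delta_coupling=v.delta_coupling,
                delta_stability=v.delta_stability,
                magnitude=v.magnitude,
                p_value=v.p_value,
            )
            for v in vectors
        ]
    report["displacement"] = disp
    (out / "coupling.json").write_text(json.dumps(report, indent=1))
    return report


def stage_topography(cfg: RunConfig, cohort) -> pd.DataFrame:
    out = _stage_dir(cfg, "topography")
    rows = []
    for a in cohort:
        for c in synthgen.CATEGORIES:
            rows.append(
                dict(
                    subject=a.subject_id,
                    group=a.group,
                    hemisphere=a.hemisphere,
                    region=a.region,
                    category=c,
                    count=topography.suprathreshold_count(
                        topography.selectivity_map(a, c, cfg.threshold)
                    ),
                )
            )
    counts = pd.DataFrame(rows)
    counts.to_csv(out / "suprathreshold_counts.tsv", sep="\t", index=False)

    li_rows = []
    wide = counts.pivot_table(
        index=["subject", "group", "region", "category"],
        columns="hemisphere",
        values="count",
    ).reset_index()
    for row in wide.itertuples():
        total = row.RH + row.LH
        if total == 0:
            continue
        li_rows.append(
            dict(
                subject=row.subject, group=row.group, region=row.region,
                category=row.category, li=topography.laterality_index(row.RH, row.LH),
            )
        )
    li = pd.DataFrame(li_rows)
    li.to_csv(out / "laterality.tsv", sep="\t", index=False)

    # group response-profile correlations, child vs adult, per hemisphere/region
    profile_stats = []
    for h in synthgen.HEMISPHERES:
        for reg in synthgen.REGIONS:
            vecs = {}
            ns = {}
            for g in synthgen.GROUPS:
                members = synthgen.subset(cohort, g, h, reg)
                pvs = [topography.profile_vector(a) for a in members]
                vecs[g] = topography.ProfileVector(
                    np.mean([p.values for p in pvs], axis=0), pvs[0].roi_order
                )
                ns[g] = len(vecs[g].values)
            r = topography.profile_correlation(vecs["child"], vecs["adult"])
            profile_stats.append(
                dict(hemisphere=h, region=reg, child_adult_r=r, n=ns["child"])
            )
    prof = pd.DataFrame(profile_stats)
    # z test contrasting the VLPFC vs VTC child-adult correlations per hemisphere
    z_rows = []
    for h in synthgen.HEMISPHERES:
        sub = prof.query("hemisphere == @h").set_index("region")
        res = compare_correlations(
            sub.loc["VTC", "child_adult_r"], int(sub.loc["VTC", "n"]),
            sub.loc["VLPFC", "child_adult_r"], int(sub.loc["VLPFC", "n"]),
        )
        z_rows.append(dict(hemisphere=h, z=res.statistic, p=res.p))
    prof.to_csv(out / "profile_correlations.tsv", sep="\t", index=False)
    pd.DataFrame(z_rows).to_csv(out / "profile_z.tsv", sep="\t", index=False)
    return counts


def stage_tissue(cfg: RunConfig) -> dict:
    out = _stage_dir(cfg, "tissue")
    n_per = cfg.tissue_subjects_per_group
    rng = np.random.default_rng(cfg.seed + 7)
    ages = np.concatenate(
        [rng.uniform(lo, hi, n_per) for _, lo, hi in tissue_mod.AGE_GROUPS]
    )
    n = ages.size
    vtc = synthgen.generate_tissue(
        n, trajectory="linear", n_voxels=cfg.tissue_voxels, seed=cfg.seed + 11,
        lobe="VTC", ages=ages,
    )
    vlpfc = synthgen.generate_tissue(
        n, trajectory="dip", n_voxels=cfg.tissue_voxels, seed=cfg.seed + 13,
        lobe="VLPFC", ages=ages,
    )
    rows = []
    for s in vtc + vlpfc:
        rows.append(
            dict(
                subject=s.subject_id, age=round(s.age, 2), lobe=s.lobe,
                age_group=tissue_mod.assign_age_group(s.age),
                r1_mean=tissue_mod.roi_mean(s, "R1"),
                mtv_mean=tissue_mod.roi_mean(s, "MTV"),
                r1_sd=float(s.r1.std(ddof=1)),
            )
        )
    pd.DataFrame(rows).to_csv(out / "tissue_means.tsv", sep="\t", index=False)

    anova = tissue_mod.lobe_age_anova(vtc + vlpfc, "R1")
    child = [s for s in vlpfc if s.age < 18]
    adult = [s for s in vlpfc if s.age >= 18]
    slopes = tissue_mod.slope_contrast(child, adult)
    het = tissue_mod.heterogeneity_vs_age(vlpfc)

    genes = list(tissue_mod.MYELIN_GENES) + ["SYN1", "SYP", "DLG4", "SHANK3", "HOMER1"]
    sets = {
        "myelin": list(tissue_mod.MYELIN_GENES),
        "synapse": ["SYN1", "SYP", "DLG4", "SHANK3", "HOMER1"],
    }
    expr_ages = list(range(6, 41, 2))
    expr = synthgen.generate_expression(
        genes, sets, expr_ages, {"myelin": True, "synapse": False},
        seed=cfg.seed + 17, noise_sd=0.05,
    )
    curves = tissue_mod.normalize_gene_sets(expr, sets)
    curves.to_csv(out / "gene_set_curves.tsv", sep="\t")

    report = {
        "lobe_age_interaction": {
            "F": anova["interaction"].statistic,
            "p": anova["interaction"].p,
            "partial_eta_sq": anova["interaction"].effect_size,
        },
        "r1_invwvf_slope_contrast": {
            "t": slopes.statistic, "df": slopes.df, "p": slopes.p, "d": slopes.effect_size
        },
        "heterogeneity_vs_age": het,
    }
    (out / "tissue.json").write_text(json.dumps(report, indent=1))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns a results bundle."""
    logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    results: dict = {}
    cohort = None
    needs_cohort = {"rsm", "partitions", "geometry", "decode", "coupling", "topography"}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.monotonic()
        if stage == "simulate":
            cohort = stage_simulate(config)
            results["simulate"] = f"{len(cohort)} archives"
        elif stage in needs_cohort:
            if cohort is None:
                cohort = _load_cohort(config)
            fn = {
                "rsm": stage_rsm,
                "partitions": stage_partitions,
                "geometry": stage_geometry,
                "decode": stage_decode,
                "coupling": stage_coupling,
                "topography": stage_topography,
            }[stage]
            results[stage] = fn(config, cohort)
        elif stage == "tissue":
            results["tissue"] = stage_tissue(config)
        log.info("stage %-10s %.1fs", stage, time.monotonic() - t0)
    provenance = {
        "config": config.identity(),
        "config_hash": config.digest(),
        "seed": config.seed,
    }
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1, default=list))
    return results
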