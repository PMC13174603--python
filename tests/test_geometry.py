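"""Embeddings, Procrustes alignment, templates, hulls — with SVD and
brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from devgeom import synthgen
from devgeom.exceptions import DegenerateDataError, ValidationError
from devgeom.geometry import (
    EmbeddingConfiguration,
    axis_contrast,
    clusters_from_scheme,
    convex_hull_area,
    dispersion,
    embed_patterns,
    group_template,
    pairwise_distances,
    procrustes_align,
)
from devgeom.rsm import ANIMATE_INANIMATE
from conftest import tiny_spec


def _cfg(points, labels=None, owner="t"):
    points = np.asarray(points, dtype=float)
    labels = tuple(labels or [f"i{k}" for k in range(points.shape[0])])
    return EmbeddingConfiguration(points=points, item_labels=labels, owner=owner,
                                  n_components=points.shape[1])


def _matrix(items, n_vertices, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.standard_normal((items, n_vertices)),
                        index=[f"i{k}" for k in range(items)])


class TestEmbedPatterns:
    def test_two_points_symmetric_about_origin(self):
        mat = _matrix(3, 30, 0).iloc[:3]
        cfg = embed_patterns(mat, n_components=2)
        # after item-centering, coordinates sum to ~0 on every component
        np.testing.assert_allclose(cfg.points.sum(axis=0), 0, atol=1e-9)

    def test_exact_planar_data_has_zero_reconstruction_error(self):
        rng = np.random.default_rng(1)
        basis = rng.standard_normal((2, 40))
        coeffs = rng.standard_normal((5, 2))
        raw = coeffs @ basis
        # undo the z-scoring inside embed_patterns so the rank-2 structure
        # survives: feed patterns that are already zero-mean unit-SD rows
        raw = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)
        mat = pd.DataFrame(raw, index=[f"i{k}" for k in range(5)])
        cfg = embed_patterns(mat, n_components=2)
        X = mat.to_numpy()
        Xc = X - X.mean(axis=0)
        # distances in the embedding reproduce distances in pattern space
        d_embed = pairwise_distances(cfg).to_numpy()
        d_full = np.linalg.norm(Xc[:, None] - Xc[None, :], axis=2)
        # rank <= 3 after centering rank-2-mixture rows; allow 2 components
        # to capture everything only if centered rank <= 2
        if np.linalg.matrix_rank(Xc, tol=1e-8) <= 2:
            np.testing.assert_allclose(d_embed, d_full, atol=1e-9)
        else:
            assert np.all(d_embed <= d_full + 1e-9)

    def test_component_variances_match_eigendecomposition(self):
        mat = _matrix(5, 100, 7)
        X = mat.to_numpy()
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
        cfg = embed_patterns(mat, n_components=4)
        comp_ss = (cfg.points**2).sum(axis=0)
        np.testing.assert_allclose(comp_ss, evals[:4], atol=1e-8)

    def test_rank_deficient_rejected(self):
        mat = _matrix(3, 20, 3)
        mat.iloc[1] = mat.iloc[0]  # duplicate row: centered rank 1
        with pytest.raises(DegenerateDataError, match="rank"):
            embed_patterns(mat, n_components=2)

    def test_deterministic_sign_convention(self, rh_vlpfc_adults):
        a = rh_vlpfc_adults[0]
        c1 = embed_patterns(a)
        c2 = embed_patterns(a)
        np.testing.assert_array_equal(c1.points, c2.points)


class TestDistances:
    def test_three_four_five(self):
        cfg = _cfg([[0, 0], [3, 4]])
        assert pairwise_distances(cfg).iloc[0, 1] == 5.0

    def test_coincident_points_zero(self):
        cfg = _cfg([[1, 1], [1, 1]])
        assert pairwise_distances(cfg).iloc[0, 1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((6, 3))
        d = pairwise_distances(_cfg(pts)).to_numpy()
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((pts[i] - pts[j]) ** 2).sum()), abs=1e-12
                )


class TestAxisContrast:
    def test_two_tight_clusters(self):
        cfg = _cfg([[0, 0], [0, 0], [1, 0], [1, 0]])
        clusters = {"i0": "a", "i1": "a", "i2": "b", "i3": "b"}
        res = axis_contrast(cfg, clusters)
        assert res["within_cluster_mean"] == 0.0
        assert res["between_centroid_distance"] == 1.0

    def test_constructed_animate_inanimate(self):
        cfg = _cfg([[-1, 0], [1, 0], [3, 0], [5, 0]])
        clusters = {"i0": "a", "i1": "a", "i2": "b", "i3": "b"}
        res = axis_contrast(cfg, clusters)
        assert res["within_cluster_mean"] == pytest.approx(2.0)
        assert res["between_centroid_distance"] == pytest.approx(4.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        pts = rng.standard_normal((10, 2))
        labels = [f"i{k}" for k in range(10)]
        clusters = {l: k % 3 for k, l in enumerate(labels)}
        res = axis_contrast(_cfg(pts, labels), clusters)
        within = []
        for g in set(clusters.values()):
            ids = [k for k, l in enumerate(labels) if clusters[l] == g]
            within += [np.linalg.norm(pts[i] - pts[j]) for i, j in combinations(ids, 2)]
        cents = [pts[[k for k, l in enumerate(labels) if clusters[l] == g]].mean(axis=0)
                 for g in sorted(set(clusters.values()))]
        between = [np.linalg.norm(a - b) for a, b in combinations(cents, 2)]
        assert res["within_cluster_mean"] == pytest.approx(np.mean(within))
        assert res["between_centroid_distance"] == pytest.approx(np.mean(between))

    def test_all_singletons_rejected(self):
        cfg = _cfg([[0, 0], [1, 0], [2, 2]])
        with pytest.raises(ValidationError, match="singleton"):
            axis_contrast(cfg, {"i0": 0, "i1": 1, "i2": 2})

    def test_scheme_helper_maps_subcategories(self):
        items = ["faces-child", "bodies-whole", "places-houses"]
        m = clusters_from_scheme(items, ANIMATE_INANIMATE)
        assert m["faces-child"] == m["bodies-whole"] != m["places-houses"]


class TestProcrustes:
    def test_identity_alignment(self):
        cfg = _cfg(np.random.default_rng(0).standard_normal((5, 2)))
        _, rep = procrustes_align(cfg, cfg)
        assert rep.procrustes_distance == pytest.approx(0.0, abs=1e-12)
        assert rep.template_similarity == pytest.approx(1.0, abs=1e-9)

    def test_similarity_transform_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((5, 2))
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = 3.0 * pts @ rot + np.array([5.0, -2.0])
        _, rep = procrustes_align(_cfg(moved), _cfg(pts))
        assert rep.procrustes_distance <= 1e-9

    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((6, 2)), rng.standard_normal((6, 2))
        _, rep = procrustes_align(_cfg(a), _cfg(b))
        # independent oracle: scipy's classical procrustes disparity
        from scipy.spatial import procrustes as scipy_procrustes

        _, _, disparity = scipy_procrustes(b, a)
        assert rep.procrustes_distance == pytest.approx(disparity, abs=1e-10)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(DegenerateDataError, match="coincident"):
            procrustes_align(_cfg([[1, 1], [1, 1], [1, 1]]),
                             _cfg([[0, 0], [1, 0], [0, 1]]))


class TestGroupTemplate:
    def test_identical_configurations(self):
        pts = np.random.default_rng(5).standard_normal((5, 2))
        cfgs = [_cfg(pts, owner=f"s{i}") for i in range(4)]
        template = group_template(cfgs)
        assert dispersion(cfgs, template) == pytest.approx(0.0, abs=1e-12)

    def test_rotated_copies_recover_shape(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((5, 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        cfgs = [_cfg(pts), _cfg(pts @ rot)]
        template = group_template(cfgs)
        _, rep = procrustes_align(_cfg(pts), template)
        assert rep.procrustes_distance <= 1e-9

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        cfgs = [_cfg(rng.standard_normal((5, 2)), owner=f"s{i}") for i in range(5)]
        t1 = group_template(cfgs)
        t2 = group_template(cfgs[::-1])
        _, rep = procrustes_align(t1, t2)
        assert rep.procrustes_distance <= 1e-6

    def test_dispersion_increases_with_subject_noise(self):
        from scipy.stats import spearmanr

        grid = [0.0, 0.5, 1.0, 2.0, 4.0]
        disps = []
        for s in grid:
            spec = tiny_spec(
                n_children=1, n_adults=50, n_vertices=60,
                subject_noise_sd=s, seed=71,
                hemispheres=("RH",), regions=("VLPFC",),
            )
            cohort = synthgen.subset(
                synthgen.generate_cohort(spec), "adult", "RH", "VLPFC"
            )
            cfgs = [embed_patterns(a) for a in cohort]
            disps.append(dispersion(cfgs))
        assert spearmanr(grid, disps).statistic > 0.9


class TestConvexHull:
    def test_unit_square(self):
        cfg = _cfg([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert convex_hull_area(cfg) == pytest.approx(1.0)

    def test_triangle_shoelace(self):
        cfg = _cfg([[0, 0], [1, 0], [0, 1]])
        assert convex_hull_area(cfg) == pytest.approx(0.5)

    def test_matches_brute_force_shoelace_maximum(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((12, 2))

        def shoelace(poly):
            x, y = poly[:, 0], poly[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

        # brute force: the hull area is the max shoelace area over all
        # subsets ordered by angle around their centroid
        best = 0.0
        from itertools import combinations as combs

        idx = range(len(pts))
        for k in range(3, len(pts) + 1):
            for sub in combs(idx, k):
                poly = pts[list(sub)]
                c = poly.mean(axis=0)
                ang = np.arctan2(poly[:, 1] - c[1], poly[:, 0] - c[0])
                best = max(best, shoelace(poly[np.argsort(ang)]))
        assert convex_hull_area(_cfg(pts)) == pytest.approx(best, abs=1e-9)

    def test_collinear_rejected(self):
        cfg = _cfg([[0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(DegenerateDataError, match="zero-area"):
            convex_hull_area(cfg)
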