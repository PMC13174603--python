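"""Cross-validated similarity: oracle checks, symmetry, group-level signal."""

import numpy as np
import pandas as pd
import pytest

from devgeom import synthgen
from devgeom.exceptions import DegenerateDataError, ValidationError
from devgeom.rsm import (
    ANIMATE_INANIMATE,
    TRIPARTITE,
    BlockScheme,
    SimilarityMatrix,
    block_contrast,
    loro_fold_matrices,
    loro_similarity,
    within_between_category,
)
from devgeom.statcore import paired_t
from conftest import null_spec, random_symmetric_sm, tiny_spec


def _archive_from_columns(cols: dict, n_runs: int) -> synthgen.PatternArchive:
    """Build a PatternArchive from explicit per-(run, category) vectors.

    ``cols`` maps (run, category) -> vertex vector; both subcategories of a
    category are set to the same vector so the category pattern equals it.
    """
    data = {}
    for (run, cat), vec in cols.items():
        for sub in synthgen.SUBCATEGORIES[cat]:
            data[f"run{run}_{sub}"] = np.asarray(vec, dtype=float)
    n_vertices = len(next(iter(cols.values())))
    return synthgen.PatternArchive(
        subject_id="sub-test",
        group="adult",
        age=25.0,
        hemisphere="RH",
        region="VLPFC",
        roi_labels=np.array(["IFJ"] * n_vertices, dtype=object),
        data=pd.DataFrame(data),
    )


def _mutually_uncorrelated_templates(n=64, seed=0, k=5):
    """k orthogonal zero-mean vectors: exact pairwise Pearson 0 (needs k < n)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, k + 2))
    x -= x.mean(axis=0)
    q, _ = np.linalg.qr(x)
    return [q[:, i] for i in range(k)]


class TestLoroSimilarity:
    def test_noiseless_identity(self):
        templates = _mutually_uncorrelated_templates()
        cols = {
            (r, c): templates[i]
            for r in (1, 2, 3)
            for i, c in enumerate(synthgen.CATEGORIES)
        }
        sm = loro_similarity(_archive_from_columns(cols, 3))
        np.testing.assert_allclose(np.diag(sm.values), 1.0, atol=1e-12)
        off = sm.values[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-9)

    def test_hand_computed_two_run_entries(self):
        # 2 runs x 2 distinct categories over 4 vertices; remaining
        # categories held fixed at orthogonal fillers
        f_r1, f_r2 = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
        b_r1, b_r2 = [4.0, 3.0, 1.0, 2.0], [1.0, 3.0, 2.0, 4.0]
        fillers = _mutually_uncorrelated_templates(n=4, seed=1, k=3)
        cols = {}
        for r, f, b in ((1, f_r1, b_r1), (2, f_r2, b_r2)):
            cols[(r, "faces")] = f
            cols[(r, "bodies")] = b
            for i, c in enumerate(("pseudowords", "places", "objects")):
                cols[(r, c)] = fillers[i]
        sm = loro_similarity(_archive_from_columns(cols, 2))

        def pearson(x, y):
            x, y = np.asarray(x), np.asarray(y)
            return np.corrcoef(x, y)[0, 1]

        # with 2 runs, the train side is the single other run; fold average
        # then symmetrization reproduces plain pairwise correlations
        expected_ff = np.mean([pearson(f_r1, f_r2), pearson(f_r2, f_r1)])
        # faces-bodies entry: average of fold matrix (f_test vs b_train) and
        # its transpose cell (b_test vs f_train) across both folds
        m = np.mean(
            [pearson(f_r2, b_r1), pearson(f_r1, b_r2)]
        )
        mt = np.mean([pearson(b_r2, f_r1), pearson(b_r1, f_r2)])
        expected_fb = (m + mt) / 2
        assert sm.values[0, 0] == pytest.approx(expected_ff, abs=1e-12)
        assert sm.values[0, 1] == pytest.approx(expected_fb, abs=1e-12)

    def test_white_noise_null_diagonal(self):
        # structureless patterns: mean within-category reliability ~ 0
        rng = np.random.default_rng(4)
        diags = []
        for _ in range(100):
            cols = {
                (r, c): rng.standard_normal(60)
                for r in (1, 2)
                for c in synthgen.CATEGORIES
            }
            sm = loro_similarity(_archive_from_columns(cols, 2))
            diags.append(np.diag(sm.values).mean())
        diags = np.asarray(diags)
        sem = diags.std(ddof=1) / np.sqrt(len(diags))
        assert abs(diags.mean()) < 3 * sem

    def test_fold_count_invariance_on_noiseless_data(self):
        rng = np.random.default_rng(3)
        mix = [rng.standard_normal(64) for _ in range(5)]
        for n_runs in (2, 3):
            cols = {
                (r, c): mix[i]
                for r in range(1, n_runs + 1)
                for i, c in enumerate(synthgen.CATEGORIES)
            }
            sm = loro_similarity(_archive_from_columns(cols, n_runs))
            if n_runs == 2:
                ref = sm.values
        np.testing.assert_allclose(sm.values, ref, atol=1e-12)

    def test_symmetry_exact(self, rh_vlpfc_adults):
        sm = loro_similarity(rh_vlpfc_adults[0])
        np.testing.assert_array_equal(sm.values, sm.values.T)

    def test_single_run_rejected(self):
        cols = {(1, c): np.arange(5.0) + i for i, c in enumerate(synthgen.CATEGORIES)}
        with pytest.raises(ValidationError, match="2 runs"):
            loro_similarity(_archive_from_columns(cols, 1))

    def test_zero_variance_pattern_identified(self):
        templates = _mutually_uncorrelated_templates()
        cols = {
            (r, c): templates[i]
            for r in (1, 2)
            for i, c in enumerate(synthgen.CATEGORIES)
        }
        cols[(2, "places")] = np.zeros(64)
        with pytest.raises(DegenerateDataError, match="run 2.*places"):
            loro_similarity(_archive_from_columns(cols, 2))

    def test_fold_matrices_average_to_similarity(self, rh_vlpfc_adults):
        a = rh_vlpfc_adults[0]
        folds = loro_fold_matrices(a)
        sm = loro_similarity(a)
        np.testing.assert_allclose(
            np.mean([f.values for f in folds], axis=0), sm.values, atol=1e-12
        )


class TestWithinBetween:
    def test_identity_like(self):
        sm = SimilarityMatrix(values=np.eye(5))
        stats = within_between_category(sm)
        assert stats == {"within_mean": 1.0, "between_mean": 0.0}

    def test_constant_matrix(self):
        sm = SimilarityMatrix(values=np.full((5, 5), 0.3))
        stats = within_between_category(sm)
        assert stats["within_mean"] == pytest.approx(0.3)
        assert stats["between_mean"] == pytest.approx(0.3)

    def test_matches_brute_force_cells(self):
        sm = random_symmetric_sm(7)
        stats = within_between_category(sm)
        cells_within = [sm.values[i, i] for i in range(5)]
        cells_between = [sm.values[i, j] for i in range(5) for j in range(i + 1, 5)]
        assert stats["within_mean"] == pytest.approx(np.mean(cells_within))
        assert stats["between_mean"] == pytest.approx(np.mean(cells_between))


class TestBlockContrast:
    def test_constant_off_diagonal(self):
        v = np.full((5, 5), 0.2)
        np.fill_diagonal(v, 0.9)
        stats = block_contrast(SimilarityMatrix(values=v), ANIMATE_INANIMATE)
        assert stats["within_block_mean"] == pytest.approx(0.2)
        assert stats["between_block_mean"] == pytest.approx(0.2)

    def test_constructed_block_matrix(self):
        cats = synthgen.CATEGORIES
        v = np.full((5, 5), -0.5)
        for i, a in enumerate(cats):
            for j, b in enumerate(cats):
                same = ANIMATE_INANIMATE.block_of(a) == ANIMATE_INANIMATE.block_of(b)
                if same:
                    v[i, j] = 0.5
        stats = block_contrast(SimilarityMatrix(values=v), ANIMATE_INANIMATE)
        assert stats["within_block_mean"] == 0.5
        assert stats["between_block_mean"] == -0.5

    def test_tripartite_matches_brute_force(self):
        sm = random_symmetric_sm(13)
        stats = block_contrast(sm, TRIPARTITE)
        idx = {c: i for i, c in enumerate(synthgen.CATEGORIES)}
        within = [sm.values[idx["faces"], idx["bodies"]],
                  sm.values[idx["places"], idx["objects"]]]
        between = [
            sm.values[i, j]
            for i in range(5)
            for j in range(i + 1, 5)
            if sm.values[i, j] not in within
        ]
        assert len(between) == 8
        assert stats["within_block_mean"] == pytest.approx(np.mean(within))
        assert stats["between_block_mean"] == pytest.approx(np.mean(between))

    def test_all_singleton_blocks_rejected(self):
        scheme = BlockScheme("singletons", tuple((c,) for c in synthgen.CATEGORIES))
        with pytest.raises(ValidationError, match="no within-block pairs"):
            block_contrast(random_symmetric_sm(1), scheme)


class TestGroupLevelSignal:
    def test_within_exceeds_between_across_replicates(self):
        hits = 0
        n_reps = 25
        for rep in range(n_reps):
            spec = tiny_spec(n_children=3, n_adults=3, n_vertices=50,
                             seed=9000 + rep)
            cohort = synthgen.subset(
                synthgen.generate_cohort(spec), hemisphere="RH", region="VLPFC"
            )
            diffs = []
            for a in cohort:
                s = within_between_category(loro_similarity(a))
                diffs.append(s["within_mean"] - s["between_mean"])
            if paired_t(diffs).statistic > 0:
                hits += 1
        assert hits / n_reps >= 0.95
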