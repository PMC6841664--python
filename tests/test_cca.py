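"""Canonical correlation analysis against a generalized-eigenvalue oracle,
plus the behaviour-correlation operations."""

import numpy as np
import pytest
from scipy import linalg, stats

from affectlink.cca import (block_permutation_pvalue, cca_fit,
                            loading_weight_share, paired_band_ttest,
                            project_and_correlate, regress_emotions,
                            standardize, top_loadings)


def oracle_canonical_correlations(x, y):
    """Brute-force generalized eigenvalue solve on the full block covariance."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    p, q = x.shape[1], y.shape[1]
    c = np.cov(np.hstack([xc, yc]).T)
    cxx, cyy = c[:p, :p], c[p:, p:]
    cxy = c[:p, p:]
    a = np.zeros((p + q, p + q))
    a[:p, p:] = cxy
    a[p:, :p] = cxy.T
    b = linalg.block_diag(cxx, cyy)
    evals = linalg.eigh(a, b, eigvals_only=True)
    rho = np.sort(evals[evals > 1e-10])[::-1]
    return rho[: min(p, q)]


def planted_pair(n, rho=0.8, p=5, q=4, seed=0):
    """x0 and y0 share a factor giving population correlation ``rho``."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    x = rng.standard_normal((n, p))
    y = rng.standard_normal((n, q))
    a = np.sqrt(rho / (1 - rho))
    x[:, 0] = a * f + rng.standard_normal(n)
    y[:, 0] = a * f + rng.standard_normal(n)
    return standardize(x)[0], standardize(y)[0]


class TestStandardize:
    def test_closed_form_column(self):
        z, names = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z[:, 0], [-1.224744871, 0.0, 1.224744871],
                                   atol=1e-9)

    def test_constant_column_dropped_with_warning(self, caplog):
        m = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with caplog.at_level("WARNING"):
            z, names = standardize(m, ["a", "b"])
        assert names == ["a"] and z.shape == (5, 1)
        assert "b" in caplog.text

    def test_idempotent(self, rng):
        m = rng.standard_normal((50, 4))
        once, _ = standardize(m)
        twice, _ = standardize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)


class TestCCAFit:
    def test_identical_matrices_give_unit_correlations(self, rng):
        z, _ = standardize(rng.standard_normal((100, 4)))
        res = cca_fit(z, z.copy(), ridge=0.0)
        np.testing.assert_allclose(res.canonical_correlations, 1.0, atol=1e-8)

    def test_matches_generalized_eigenvalue_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(50, 500))
            p, q = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            x = rng.standard_normal((n, p))
            y = 0.3 * x[:, :1] + rng.standard_normal((n, q))
            res = cca_fit(x, y, ridge=0.0)
            np.testing.assert_allclose(res.canonical_correlations,
                                       oracle_canonical_correlations(x, y),
                                       atol=1e-8)

    def test_independent_gaussians_have_near_zero_first_correlation(self, rng):
        x = rng.standard_normal((5000, 3))
        y = rng.standard_normal((5000, 3))
        res = cca_fit(x, y, ridge=0.0)
        assert res.canonical_correlations[0] < 0.1

    def test_planted_factor_is_recovered(self):
        x, y = planted_pair(2000, rho=0.8, seed=42)
        res = cca_fit(x, y, ridge=0.0, x_names=[f"x{i}" for i in range(5)])
        assert 0.75 <= res.canonical_correlations[0] <= 0.85
        assert top_loadings(res, "x", 1)[0][0] == "x0"

    def test_affine_recoding_leaves_correlations_unchanged(self, rng):
        x, y = planted_pair(800, seed=3)
        t_x = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        t_y = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        base = cca_fit(x, y, ridge=0.0).canonical_correlations
        recoded = cca_fit(x @ t_x + 1.0, y @ t_y - 2.0, ridge=0.0)
        np.testing.assert_allclose(recoded.canonical_correlations, base, atol=1e-8)

    def test_successive_variates_are_uncorrelated(self, rng):
        x = rng.standard_normal((600, 5))
        y = 0.4 * x[:, :2] @ rng.standard_normal((2, 4)) + rng.standard_normal((600, 4))
        res = cca_fit(x, y, ridge=0.0)
        ux, uy = res.variates(x, y)
        for a in range(ux.shape[1]):
            for b in range(a):
                assert abs(np.corrcoef(ux[:, a], ux[:, b])[0, 1]) < 1e-6
                assert abs(np.corrcoef(uy[:, a], uy[:, b])[0, 1]) < 1e-6

    def test_rank_deficiency_demands_ridge(self, rng):
        x = rng.standard_normal((30, 3))
        x = np.column_stack([x, x[:, 0]])          # duplicated column
        y = rng.standard_normal((30, 2))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            cca_fit(x, y, ridge=0.0)
        cca_fit(x, y, ridge=1e-3)                  # regularized fit succeeds

    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cca_fit(rng.standard_normal((10, 2)), rng.standard_normal((11, 2)))


class TestTopLoadings:
    def test_full_k_is_a_permutation_of_names(self):
        x, y = planted_pair(500, seed=9)
        res = cca_fit(x, y, ridge=0.0, x_names=list("abcde"))
        ranked = top_loadings(res, "x", 5)
        assert sorted(n for n, _ in ranked) == list("abcde")

    def test_weight_share_is_a_proper_fraction(self):
        x, y = planted_pair(500, seed=10)
        res = cca_fit(x, y, ridge=0.0)
        share = loading_weight_share(res, "x", k=2)
        assert 0.0 <= share <= 1.0
        assert loading_weight_share(res, "x", k=5) == pytest.approx(1.0)

    def test_oversized_k_rejected(self):
        x, y = planted_pair(200, seed=1)
        res = cca_fit(x, y, ridge=0.0)
        with pytest.raises(ValueError):
            top_loadings(res, "x", 99)


class TestProjectAndCorrelate:
    def test_affine_labels_give_perfect_correlation(self):
        x, y = planted_pair(400, seed=5)
        res = cca_fit(x, y, ridge=0.0)
        ux, _ = res.variates(x, y)
        labels = 3.0 * ux[:, 0] + 1.0
        out = project_and_correlate(res, x, y, labels, labels)
        assert abs(out["x"]["valence"]["r"]) == pytest.approx(1.0, abs=1e-9)

    def test_independent_labels_give_near_zero_correlation(self, rng):
        x, y = planted_pair(1000, seed=6)
        res = cca_fit(x, y, ridge=0.0)
        labels = rng.integers(1, 10, size=1000)
        out = project_and_correlate(res, x, y, labels, labels)
        assert abs(out["x"]["valence"]["r"]) < 0.1

    def test_reports_a_best_cue_per_side_and_label(self):
        x, y = planted_pair(300, seed=7)
        res = cca_fit(x, y, ridge=0.0, x_names=list("abcde"), y_names=list("wxyz"))
        out = project_and_correlate(res, x, y, np.arange(300), np.arange(300))
        assert out["x"]["arousal"]["best_cue"] in list("abcde")
        assert out["y"]["valence"]["best_cue"] in list("wxyz")


class TestRegressEmotions:
    def test_balanced_two_level_variate_yields_class_mean_deviation(self):
        emotions = np.array(["joy"] * 50 + ["fear"] * 50 + ["sadness"] * 50)
        scores = np.where(emotions == "joy", 1.0, -1.0)
        out = regress_emotions(scores, emotions)
        assert out["max_class"] == "joy"
        grand = scores.mean()
        assert out["max_coefficient"] == pytest.approx(1.0 - grand)

    def test_frequency_weighted_coefficients_sum_to_zero(self, rng):
        emotions = rng.choice(["joy", "fear", "calmness"], size=300, p=[0.5, 0.3, 0.2])
        scores = rng.standard_normal(300)
        out = regress_emotions(scores, emotions)
        weighted = sum((emotions == c).mean() * v
                       for c, v in out["coefficients"].items())
        assert weighted == pytest.approx(0.0, abs=1e-12)

    def test_null_coefficients_shrink_with_sample_size(self, rng):
        def max_coef(n, seed):
            r = np.random.default_rng(seed)
            emotions = r.choice(["a", "b", "c", "d"], size=n)
            return abs(regress_emotions(r.standard_normal(n), emotions)
                       ["max_coefficient"])
        small = np.mean([max_coef(200, s) for s in range(10)])
        large = np.mean([max_coef(2000, s) for s in range(10, 20)])
        assert large < small

    def test_sparse_class_excluded_with_log(self, caplog):
        emotions = np.array(["joy"] * 20 + ["fear"] * 20 + ["anger"])
        with caplog.at_level("WARNING"):
            out = regress_emotions(np.arange(41.0), emotions)
        assert "anger" not in out["coefficients"]


class TestPairedTTest:
    def test_consistent_sign_differences_are_significant(self, rng):
        a = rng.standard_normal(6)
        coefs = np.column_stack([a + 1.0 + 0.01 * rng.standard_normal(6), a])
        t, p = paired_band_ttest(coefs, 0, 1)
        assert p < 0.01

    def test_identical_bands_sentinel(self):
        coefs = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert paired_band_ttest(coefs, 0, 1) == (0.0, 1.0)

    def test_matches_textbook_formula(self):
        a = np.array([3.1, 2.7, 4.0, 3.3, 2.9])
        b = np.array([2.5, 2.9, 3.1, 2.8, 2.6])
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p = paired_band_ttest(np.column_stack([a, b]), 0, 1)
        assert t == pytest.approx(expected_t, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), len(d) - 1), abs=1e-9)


def test_block_permutation_respects_clip_structure(rng):
    # windows inherit their clip's label; a clip-level signal must survive
    blocks = np.repeat(np.arange(20), 10)
    clip_vals = rng.standard_normal(20)
    scores = np.repeat(clip_vals, 10) + 0.1 * rng.standard_normal(200)
    labels = np.repeat(clip_vals, 10)
    p = block_permutation_pvalue(scores, labels, blocks, n_perm=199, seed=0)
    assert p < 0.05
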