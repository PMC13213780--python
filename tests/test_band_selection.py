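"""Tests of KMO/Bartlett, PCA, composite scoring and backward stepwise."""

import numpy as np
import pytest
from scipy import stats

from chilispec import (
    backward_stepwise,
    bartlett_sphericity,
    composite_score,
    kmo_measure,
    pca_decompose,
    select_bands,
)

from oracles import bartlett_bruteforce, exact_correlation_data, kmo_bruteforce


class TestKMO:
    def test_matches_bruteforce_partial_correlations(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.standard_normal((80, 2))
            X = np.column_stack([
                base[:, 0], base[:, 0] + 0.3 * rng.standard_normal(80),
                base[:, 1], base[:, 1] + 0.5 * rng.standard_normal(80),
                rng.standard_normal(80),
            ])
            assert kmo_measure(X) == pytest.approx(kmo_bruteforce(X), abs=1e-8)

    def test_equicorrelated_closed_form(self):
        rho, p = 0.5, 3
        R = (1 - rho) * np.eye(p) + rho * np.ones((p, p))
        X = exact_correlation_data(R, n=500, seed=0)
        # analytic inverse of the equicorrelation matrix
        a = 1 / (1 - rho) - rho / ((1 - rho) * (1 + (p - 1) * rho))
        b = -rho / ((1 - rho) * (1 + (p - 1) * rho))
        q = -b / a
        expected = (p * (p - 1) * rho**2) / (p * (p - 1) * rho**2 + p * (p - 1) * q**2)
        assert kmo_measure(X) == pytest.approx(expected, abs=1e-6)

    def test_whitened_data_far_from_adequacy(self):
        # uncorrelated features sit at the uninformative ~0.5 limit, well
        # below the 0.7 adequacy bar and far below collinear spectra
        X = exact_correlation_data(np.eye(4), n=300, seed=1)
        assert kmo_measure(X) < 0.55
        rng = np.random.default_rng(2)
        base = rng.standard_normal(200)
        collinear = np.column_stack(
            [base + 0.2 * rng.standard_normal(200) for _ in range(5)])
        assert kmo_measure(collinear) > 0.7 > kmo_measure(X)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(50), np.random.random(50), np.random.random(50)])
        with pytest.raises(ValueError, match="zero variance feature"):
            kmo_measure(X)


class TestBartlett:
    def test_identity_correlation_gives_zero(self):
        X = exact_correlation_data(np.eye(5), n=200, seed=2)
        chi2, df, p = bartlett_sphericity(X)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_two_feature_hand_formula(self):
        r = 0.6
        R = np.array([[1, r], [r, 1.0]])
        X = exact_correlation_data(R, n=100, seed=3)
        chi2, df, p = bartlett_sphericity(X)
        expected = -(100 - 1 - 9 / 6) * np.log(1 - r**2)
        assert chi2 == pytest.approx(expected, rel=1e-9)
        assert df == 1

    def test_df_for_19_bands(self):
        X = np.random.default_rng(4).standard_normal((40, 19))
        _, df, _ = bartlett_sphericity(X)
        assert df == 171

    def test_matches_bruteforce(self):
        X = np.random.default_rng(5).standard_normal((60, 6))
        mine = bartlett_sphericity(X)
        ref = bartlett_bruteforce(X)
        assert mine[0] == pytest.approx(ref[0], rel=1e-10)
        assert mine[2] == pytest.approx(ref[2], abs=1e-12)

    def test_singular_correlation_rejected(self):
        x = np.random.default_rng(6).standard_normal(30)
        X = np.column_stack([x, x, np.random.default_rng(7).standard_normal(30)])
        with pytest.raises(ValueError, match="singular|ridge"):
            bartlett_sphericity(X)


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(8)
        X = np.outer(rng.standard_normal(50), [1.0, 2.0, -1.0])
        loadings, scores, ratios = pca_decompose(X, 2)
        assert ratios[0] == pytest.approx(1.0, abs=1e-6)

    def test_scores_uncorrelated(self):
        X = np.random.default_rng(9).standard_normal((100, 5))
        _, scores, _ = pca_decompose(X, 3)
        c = np.corrcoef(scores, rowvar=False)
        assert abs(c[0, 1]) < 1e-8 and abs(c[0, 2]) < 1e-8

    def test_two_feature_closed_form_eigenvalues(self):
        r = 0.7
        X = exact_correlation_data(np.array([[1, r], [r, 1.0]]), n=150, seed=10)
        _, _, ratios = pca_decompose(X, 2)
        assert ratios[0] == pytest.approx((1 + r) / 2, abs=1e-9)
        assert ratios[1] == pytest.approx((1 - r) / 2, abs=1e-9)

    def test_sign_convention_deterministic(self):
        X = np.random.default_rng(11).standard_normal((60, 4))
        l1, s1, _ = pca_decompose(X, 2)
        l2, s2, _ = pca_decompose(X.copy(), 2)
        assert np.allclose(l1, l2)
        for j in range(2):
            assert l1[np.argmax(np.abs(l1[:, j])), j] > 0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            pca_decompose(np.random.random((10, 3)), 0)


class TestCompositeScore:
    def test_k1_equals_pc1(self):
        scores = np.random.default_rng(12).standard_normal((30, 2))
        F = composite_score(scores, np.array([0.6, 0.3]), k=1)
        assert np.allclose(F, scores[:, 0])

    def test_equal_ratios_give_mean(self):
        scores = np.random.default_rng(13).standard_normal((30, 2))
        F = composite_score(scores, np.array([0.4, 0.4]), k=2)
        assert np.allclose(F, scores.mean(axis=1))

    def test_weighted_mean_of_equal_scores(self):
        F = composite_score(np.ones((5, 2)), np.array([0.676, 0.244]), k=2)
        assert np.allclose(F, 1.0)

    def test_zero_ratio_sum_rejected(self):
        with pytest.raises(ValueError):
            composite_score(np.ones((5, 2)), np.array([0.0, 0.0]), k=2)


class TestBackwardStepwise:
    def test_planted_model_recovery(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((200, 12))
        wl = np.arange(400, 400 + 12 * 10, 10.0)
        F = 2 * X[:, 3] + 1 * X[:, 7] + 1e-4 * rng.standard_normal(200)
        sel, r, r2, pv = backward_stepwise(F, X, wl)
        assert set(sel) == {wl[3], wl[7]}
        assert r2 > 0.99

    def test_single_exact_predictor(self):
        x = np.random.default_rng(15).standard_normal(50)
        sel, r, r2, _ = backward_stepwise(x, x[:, None], [500.0])
        assert sel == [500.0]
        assert r2 == pytest.approx(1.0)

    def test_pure_noise_gives_empty_model_error(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 5))
        F = rng.standard_normal(100)
        with pytest.raises(ValueError, match="empty model"):
            backward_stepwise(F, X, np.arange(5, dtype=float))

    def test_survivors_exceed_f_to_remove(self):
        """Every surviving predictor's removal must raise RSS beyond the
        partial-F threshold implied by alpha (brute-force lstsq check)."""
        rng = np.random.default_rng(16)
        n, p, alpha = 120, 8, 0.05
        X = rng.standard_normal((n, p))
        F = X[:, 1] - 0.8 * X[:, 4] + 0.3 * rng.standard_normal(n)
        wl = np.arange(p, dtype=float)
        sel, _, _, _ = backward_stepwise(F, X, wl, alpha_remove=alpha)
        keep = [int(w) for w in sel]

        def rss(cols):
            A = np.column_stack([np.ones(n), X[:, cols]])
            beta, *_ = np.linalg.lstsq(A, F, rcond=None)
            return float(np.sum((F - A @ beta) ** 2))

        full = rss(keep)
        dof = n - len(keep) - 1
        f_crit = stats.f.ppf(1 - alpha, 1, dof)
        for drop in keep:
            reduced = rss([c for c in keep if c != drop])
            f_stat = (reduced - full) / (full / dof)
            assert f_stat > f_crit


class TestSelectBandsPipeline:
    def test_on_synthetic_population(self, default_dataset):
        res = select_bands(default_dataset.spectra)
        wl = default_dataset.spectra.wavelengths_nm
        assert set(res.selected_wavelengths_nm) <= set(wl)
        assert 0 <= res.kmo <= 1
        assert res.bartlett_p < 0.001
        assert np.all(res.explained_variance_ratio <= 1)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-12
        assert res.stepwise_r2 <= 1

    def test_max_bands_cap(self, default_dataset):
        res = select_bands(default_dataset.spectra, max_bands=5)
        assert len(res.selected_wavelengths_nm) <= 5

    def test_reproducible(self, default_dataset):
        a = select_bands(default_dataset.spectra)
        b = select_bands(default_dataset.spectra)
        assert a.selected_wavelengths_nm == b.selected_wavelengths_nm
        assert a.kmo == b.kmo
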