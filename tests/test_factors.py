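"""Psychometrics: z-scoring, outlier screens, maximum-likelihood EFA,
parallel analysis, fit indices, factor scores, and residualization."""

import numpy as np
import pandas as pd
import pytest

from efficog import (
    MLFactorAnalysis,
    factor_scores,
    fit_indices,
    ml_efa,
    parallel_analysis,
    residualize,
    screen_outliers,
    zscore,
)
from conftest import COG_LOADINGS, one_factor_data


def implied_corr(loadings) -> np.ndarray:
    lam = np.asarray(loadings)
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return r


class TestZscore:
    def test_symmetric_column(self):
        out = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["a"], [-1, 0, 1])

    def test_idempotent(self):
        z = zscore(pd.DataFrame({"a": np.random.default_rng(0).normal(size=50)}))
        np.testing.assert_allclose(zscore(z), z, atol=1e-12)

    def test_hand_computed_column(self):
        col = [2.0, 4, 4, 4, 5, 5, 7, 9]
        out = zscore(pd.DataFrame({"a": col}))
        sd = np.std(col, ddof=1)
        assert sd == pytest.approx(2.138, abs=1e-3)
        assert out["a"].iloc[0] == pytest.approx((2 - 5) / sd)
        assert out["a"].iloc[0] == pytest.approx(-1.403, abs=1e-3)

    def test_rejects_constant_column_by_name(self):
        with pytest.raises(ValueError, match="flat"):
            zscore(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


class TestOutlierScreen:
    def test_clean_data_unflagged(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(np.clip(rng.standard_normal((200, 3)), -1.9, 1.9))
        uni, multi = screen_outliers(z)
        assert not uni.any()

    def test_univariate_flag_at_z5(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame(rng.standard_normal((100, 2)) * 0.5)
        z.iloc[7, 0] = 5.0
        uni, _ = screen_outliers(z)
        assert uni.iloc[7] and uni.sum() == 1

    def test_multivariate_flag_under_near_identity(self):
        rng = np.random.default_rng(3)
        z = pd.DataFrame(rng.standard_normal((500, 2)))
        z.iloc[0] = [3.5, -3.5]  # squared Mahalanobis ~ 24.5 under identity cov
        _, multi = screen_outliers(z)
        assert multi.iloc[0]

    def test_rejects_singular_covariance(self):
        x = np.random.default_rng(4).standard_normal(50)
        with pytest.raises(ValueError, match="collinear"):
            screen_outliers(pd.DataFrame({"a": x, "b": 2 * x}))


class TestMlEfa:
    def test_recovers_loadings_from_noiseless_matrix(self):
        sol = ml_efa(implied_corr(COG_LOADINGS), 1, n_obs=139)
        np.testing.assert_allclose(sol.loadings[:, 0], COG_LOADINGS, atol=1e-4)
        assert sol.rmsr < 1e-5

    def test_uniqueness_identity(self):
        sol = ml_efa(implied_corr(COG_LOADINGS), 1, n_obs=139)
        np.testing.assert_allclose(
            sol.uniquenesses, 1 - np.sum(sol.loadings**2, axis=1), atol=1e-4
        )

    def test_identity_matrix_gives_no_common_variance(self):
        sol = ml_efa(np.eye(5), 1, n_obs=200)
        assert np.all(np.abs(sol.loadings) < 1e-3)
        assert sol.var_explained < 1e-4

    def test_var_explained_is_mean_squared_loading(self):
        sol = ml_efa(implied_corr(COG_LOADINGS), 1, n_obs=139)
        assert sol.var_explained == pytest.approx(np.mean(np.sum(sol.loadings**2, axis=1)))
        assert round(sol.var_explained, 2) == 0.48

    def test_sign_convention_largest_loading_positive(self):
        sol = ml_efa(implied_corr(COG_LOADINGS), 1, n_obs=100)
        j = np.argmax(np.abs(sol.loadings[:, 0]))
        assert sol.loadings[j, 0] > 0

    def test_two_factor_recovery(self):
        lam = np.zeros((6, 2))
        lam[:3, 0] = (0.8, 0.7, 0.75)
        lam[3:, 1] = (0.7, 0.8, 0.65)
        r = lam @ lam.T
        np.fill_diagonal(r, 1.0)
        sol = ml_efa(r, 2, n_obs=500)
        comm = np.sum(sol.loadings**2, axis=1)
        np.testing.assert_allclose(comm, np.sum(lam**2, axis=1), atol=1e-3)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            ml_efa(np.ones((3, 4)), 1, 100)
        with pytest.raises(ValueError):
            ml_efa(np.eye(4), 4, 100)

    def test_matches_sklearn_ml_factor_analysis(self):
        """Independent check: sklearn's EM-based ML FA on raw data agrees."""
        from sklearn.decomposition import FactorAnalysis

        x, _ = one_factor_data(np.random.default_rng(8), 3000)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        ours = ml_efa(np.corrcoef(z, rowvar=False), 1, n_obs=3000)
        fa = FactorAnalysis(n_components=1, tol=1e-6, max_iter=5000).fit(z)
        ref = np.abs(fa.components_[0]) * np.sqrt((3000 - 1) / 3000)  # sklearn uses 1/n cov
        np.testing.assert_allclose(np.abs(ours.loadings[:, 0]), ref, atol=0.02)


class TestParallelAnalysis:
    def test_one_factor_data_retains_one(self):
        x, _ = one_factor_data(np.random.default_rng(10), 500, (0.7,) * 5)
        assert parallel_analysis(x, 200, seed=1) == 1

    def test_two_factor_data_retains_two(self):
        rng = np.random.default_rng(12)
        g = rng.standard_normal((500, 2))
        lam = np.zeros((6, 2))
        lam[:3, 0] = 0.8
        lam[3:, 1] = 0.8
        x = g @ lam.T + np.sqrt(1 - (lam**2).sum(1)) * rng.standard_normal((500, 6))
        assert parallel_analysis(x, 200, seed=2) == 2

    def test_independent_columns_retain_zero_with_percentile_null(self):
        x = np.random.default_rng(14).standard_normal((500, 6))
        assert parallel_analysis(x, 300, seed=3, null_summary="p95") == 0

    def test_invariant_to_column_order_and_monotone_rescaling(self):
        rng = np.random.default_rng(16)
        x, _ = one_factor_data(rng, 300)
        base = parallel_analysis(x, 150, seed=5)
        shuffled = x[:, ::-1].copy()
        assert parallel_analysis(shuffled, 150, seed=5) == base
        rescaled = x.copy()
        rescaled[:, 0] = 3.0 * rescaled[:, 0] - 7.0
        assert parallel_analysis(rescaled, 150, seed=5) == base

    def test_rejects_wide_data_and_few_permutations(self):
        with pytest.raises(ValueError):
            parallel_analysis(np.random.default_rng(0).standard_normal((4, 6)), 200)
        with pytest.raises(ValueError):
            parallel_analysis(np.random.default_rng(0).standard_normal((50, 3)), 50)


class TestFitIndices:
    def test_perfect_fit(self):
        rmsr, rmsea, _ = fit_indices(5.0, 5, 139, np.zeros((5, 5)))
        assert rmsr == 0.0 and rmsea == 0.0

    def test_rmsea_plug_in(self):
        df = 5
        _, rmsea, _ = fit_indices(2 * df, df, 139, np.zeros((5, 5)))
        assert rmsea == pytest.approx(1 / np.sqrt(138))

    def test_tli_zero_when_model_equals_null(self):
        r = implied_corr((0.6, 0.6, 0.6, 0.6))
        sign, logdet = np.linalg.slogdet(r)
        null_chi2 = -(139 - 1 - (2 * 4 + 5) / 6) * logdet
        null_df = 6
        chi2 = null_chi2 * 5 / null_df  # same chi2/df ratio as the null at df=5
        _, _, tli = fit_indices(chi2, 5, 139, np.zeros((4, 4)), corr=r)
        assert tli == pytest.approx(0.0, abs=1e-10)

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            fit_indices(1.0, 0, 100, np.zeros((3, 3)))


class TestFactorScores:
    def test_single_unit_loading_reproduces_measure(self):
        z = np.random.default_rng(20).standard_normal((50, 1))
        z = (z - z.mean()) / z.std(ddof=1)
        s = factor_scores(np.array([[1.0]]), np.eye(1), z)
        np.testing.assert_allclose(s[:, 0], z[:, 0], atol=1e-10)

    def test_near_noiseless_recovery_of_latent(self):
        rng = np.random.default_rng(21)
        lam = np.full(5, 0.999)
        x, g = one_factor_data(rng, 400, lam)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        corr = np.corrcoef(z, rowvar=False)
        s = factor_scores(lam[:, None], corr, z)
        assert abs(np.corrcoef(s[:, 0], g)[0, 1]) > 0.999

    def test_equal_loadings_give_row_mean_scores(self):
        # with exchangeable measures (compound-symmetric R, equal loadings)
        # the regression weights are equal, so scores ~ row mean of z-scores
        rng = np.random.default_rng(22)
        x, _ = one_factor_data(rng, 300, (0.7,) * 4)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        corr = implied_corr((0.7,) * 4)
        s = factor_scores(np.full((4, 1), 0.7), corr, z)
        r = np.corrcoef(s[:, 0], z.mean(axis=1))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)


class TestResidualize:
    def test_unrelated_covariates_leave_scores(self):
        rng = np.random.default_rng(30)
        scores = rng.standard_normal(500)
        age = rng.uniform(7, 12, 500)
        sex = rng.integers(0, 2, 500).astype(float)
        resid = residualize(scores, age, sex)
        assert np.corrcoef(resid, (scores - scores.mean()) / scores.std(ddof=1))[0, 1] > 0.99

    def test_pure_age_effect_removed(self):
        age = np.linspace(7, 12, 100)
        sex = np.tile([0.0, 1.0], 50)
        resid = residualize(2 * age, age, sex, standardize=False)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_quadratic_age_effect_needs_quadratic_term(self):
        rng = np.random.default_rng(31)
        age = rng.uniform(7, 12, 400)
        sex = rng.integers(0, 2, 400).astype(float)
        scores = (age - age.mean()) ** 2 + 0.5 * rng.standard_normal(400)
        resid = residualize(scores, age, sex)
        a2 = age**2 - np.polyval(np.polyfit(age, age**2, 1), age)  # age^2 | age
        assert abs(np.corrcoef(resid, a2)[0, 1]) < 1e-8

    def test_orthogonal_to_all_covariates(self):
        rng = np.random.default_rng(32)
        scores = rng.standard_normal(200)
        age = rng.uniform(7, 12, 200)
        sex = rng.integers(0, 2, 200).astype(float)
        resid = residualize(scores, age, sex)
        for cov in (age, age**2, sex):
            assert abs(np.corrcoef(resid, cov)[0, 1]) < 1e-10

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(33)
        with pytest.warns(UserWarning, match="sex"):
            residualize(rng.standard_normal(50), rng.uniform(7, 12, 50), np.zeros(50))


class TestMLFactorAnalysisEstimator:
    def test_fit_recovers_structure_and_transform_scores(self):
        rng = np.random.default_rng(40)
        x, g = one_factor_data(rng, 1500)
        model = MLFactorAnalysis(n_factors="parallel", n_permutations=150, random_state=0)
        model.fit(pd.DataFrame(x))
        assert model.n_factors_ == 1
        np.testing.assert_allclose(model.loadings_[:, 0], COG_LOADINGS, atol=0.08)
        scores = model.transform(pd.DataFrame(x))
        assert abs(np.corrcoef(scores[:, 0], g)[0, 1]) > 0.85

    def test_bootstrap_ci_covers_generating_loadings(self):
        rng = np.random.default_rng(41)
        x, _ = one_factor_data(rng, 139)
        model = MLFactorAnalysis(
            n_factors=1, n_bootstrap=200, random_state=1
        ).fit(pd.DataFrame(x))
        lo, hi = model.loading_ci_[..., 0], model.loading_ci_[..., 1]
        covered = (lo[:, 0] <= np.asarray(COG_LOADINGS)) & (np.asarray(COG_LOADINGS) <= hi[:, 0])
        assert covered.sum() >= 4  # 5-95% bounds should capture nearly all

    def test_missing_values_rejected(self):
        x = pd.DataFrame(np.random.default_rng(42).standard_normal((30, 4)))
        x.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            MLFactorAnalysis(n_factors=1).fit(x)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = MLFactorAnalysis(n_factors=1, n_permutations=200)
        assert clone(model).get_params() == model.get_params()
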