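"""OLS engine: fits, statistics, VIF, leverages."""

import numpy as np
import pytest

import rmqsar as rq
from rmqsar.data import DataError, LinearModel
from rmqsar.mlr import (fit_ols, leverages_for, max_pairwise_r2, predict,
                        subset_stats, vif_and_corr)

from conftest import clean_spec


def exact_correlated(rng, n, target_corr):
    """Columns whose *sample* correlation matrix equals target_corr exactly."""
    d = target_corr.shape[0]
    Z = rng.normal(size=(n, d))
    Z -= Z.mean(axis=0)
    cov = Z.T @ Z / n
    W = np.linalg.cholesky(np.linalg.inv(cov))
    L = np.linalg.cholesky(target_corr)
    return Z @ W @ L.T


class TestFitOls:
    def test_exact_linear_response(self, rng):
        X = rng.normal(size=(30, 4))
        y = 2.0 + X @ np.array([1.0, -2.0, 0.5, 3.0])
        model, stats = fit_ols(X, y)
        assert stats.r2 == pytest.approx(1.0)
        assert stats.s == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(stats.residuals, 0, atol=1e-10)
        assert model.intercept == pytest.approx(2.0)

    def test_intercept_only(self, rng):
        y = rng.normal(size=25)
        model, stats = fit_ols(np.empty((25, 0)), y)
        assert model.intercept == pytest.approx(y.mean())
        assert stats.r2 == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_names_offenders(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, 2 * x, rng.normal(size=40)])
        with pytest.raises(DataError, match="dup"):
            fit_ols(X, rng.normal(size=40), names=["dup1", "dup2", "ok"])

    def test_n_too_small_rejected(self, rng):
        with pytest.raises(DataError):
            fit_ols(rng.normal(size=(4, 3)), rng.normal(size=4))

    def test_coefficient_recovery_within_3_se(self):
        """Planted 8-descriptor model at noise 0.8, n = 265: across 100
        seeds, at least 95% of (seed, coefficient) draws land within 3
        standard errors of the generating coefficients."""
        hits = total = 0
        for seed in range(100):
            spec = clean_spec(n_compounds=265, n_descriptors=20, n_signal=8,
                              noise_sd=0.8, seed=seed)
            dm, act, truth = rq.generate(spec)
            model, stats = fit_ols(dm.matrix(truth.signal_names),
                                   act.log10_ic50, names=truth.signal_names)
            se = stats.coef_se[:8]
            for k, name in enumerate(truth.signal_names):
                total += 1
                hits += abs(model.coefficients[k] - truth.beta[name]) <= 3 * se[k]
        assert hits / total >= 0.95


class TestPredict:
    def test_zero_row_gives_intercept(self):
        model = LinearModel(["a", "b"], [1.5, -2.0], 4.37)
        out = predict(model, np.zeros((3, 2)), names=["a", "b"])
        np.testing.assert_allclose(out, 4.37)

    def test_matches_fitted_values(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + rng.normal(size=40) * 0.1
        model, stats = fit_ols(X, y, names=["a", "b", "c"])
        np.testing.assert_allclose(predict(model, X, names=["a", "b", "c"]),
                                   y - stats.residuals, atol=1e-10)

    def test_column_matching_by_name_not_position(self, rng):
        X = rng.normal(size=(20, 2))
        y = 1.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1]
        model, _ = fit_ols(X, y, names=["a", "b"])
        shuffled = X[:, [1, 0]]
        np.testing.assert_allclose(
            predict(model, shuffled, names=["b", "a"]), y, atol=1e-10)

    def test_missing_column_rejected(self, rng):
        model = LinearModel(["a"], [1.0], 0.0)
        with pytest.raises(DataError):
            predict(model, rng.normal(size=(5, 1)), names=["z"])


class TestSubsetStats:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=20)
        r2, s = subset_stats(y, y, d=3)
        assert r2 == pytest.approx(1.0) and s == 0.0

    def test_constant_shift_closed_form(self, rng):
        y = rng.normal(size=50)
        r2, s = subset_stats(y, y + 1.0, d=4)
        assert r2 == pytest.approx(1.0)
        assert s == pytest.approx(np.sqrt(50 / (50 - 4 - 1)))

    def test_random_predictions_near_zero_r2(self, rng):
        y = rng.normal(size=1000)
        r2, _ = subset_stats(y, rng.normal(size=1000), d=2)
        assert r2 < 0.02

    def test_zero_variance_flagged(self):
        r2, s = subset_stats(np.ones(10), np.arange(10.0), d=1)
        assert np.isnan(r2) and s > 0

    def test_training_stats_coincide_with_fit(self, rng):
        """On training data the Pearson-squared and 1 - RSS/TSS definitions
        of R2 coincide for OLS with intercept."""
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1, -1, 2, 0.5]) + rng.normal(size=60)
        model, stats = fit_ols(X, y)
        r2, s = subset_stats(y, y - stats.residuals, d=4)
        assert r2 == pytest.approx(stats.r2, abs=1e-10)
        assert s == pytest.approx(stats.s, abs=1e-10)


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        X = np.column_stack([np.r_[np.ones(10), -np.ones(10)],
                             np.r_[np.ones(5), -np.ones(10), np.ones(5)]])
        vifs, _ = vif_and_corr(X)
        np.testing.assert_allclose(vifs, 1.0, atol=1e-10)

    def test_duplicated_column_infinite(self, rng):
        x = rng.normal(size=30)
        vifs, _ = vif_and_corr(np.column_stack([x, x]))
        assert np.isinf(vifs).all()

    def test_equicorrelated_half_gives_1_5(self, rng):
        target = np.full((3, 3), 0.5)
        np.fill_diagonal(target, 1.0)
        X = exact_correlated(rng, 200, target)
        vifs, r2m = vif_and_corr(X)
        np.testing.assert_allclose(vifs, 1.5, atol=1e-8)
        assert max_pairwise_r2(X) == pytest.approx(0.25, abs=1e-8)

    def test_vif_at_least_one(self, rng):
        for _ in range(20):
            X = rng.normal(size=(40, 4))
            vifs, _ = vif_and_corr(X)
            assert (vifs >= 1.0 - 1e-12).all()


class TestHatMatrix:
    def test_leverage_identities(self, rng):
        X = rng.normal(size=(50, 6))
        y = rng.normal(size=50)
        _, stats = fit_ols(X, y)
        assert stats.leverages.sum() == pytest.approx(7.0, abs=1e-8)
        assert (stats.leverages >= 1 / 50 - 1e-12).all()
        assert (stats.leverages <= 1.0 + 1e-12).all()

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        _, stats = fit_ols(X, y)
        A = np.hstack([X, np.ones((50, 1))])
        assert np.abs(A.T @ stats.residuals).max() < 1e-6

    def test_query_leverages_match_training(self, rng):
        X = rng.normal(size=(30, 3))
        _, stats = fit_ols(X, rng.normal(size=30))
        np.testing.assert_allclose(leverages_for(X, X), stats.leverages,
                                   atol=1e-10)
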