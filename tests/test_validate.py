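"""Validation battery: cross-validation, Y-randomization, external criteria."""

import numpy as np
import pytest

import rmqsar as rq
from rmqsar.data import DataError
from rmqsar.mlr import fit_ols
from rmqsar.validate import (count_outliers, golbraikh_tropsha, leave_n_pct_out,
                             loo_cv, loo_cv_naive, rm_squared, y_randomization)

from conftest import clean_spec


class TestLoo:
    def test_shortcut_equals_naive_refits(self, rng):
        """The hat-matrix identity must reproduce the n-refit procedure
        exactly, across several random fixtures."""
        for _ in range(5):
            n, d = 30, 3
            X = rng.normal(size=(n, d))
            y = X @ rng.normal(size=d) + rng.normal(size=n) * 0.5
            r2_fast, s_fast = loo_cv(X, y)
            r2_slow, s_slow = loo_cv_naive(X, y)
            assert r2_fast == pytest.approx(r2_slow, abs=1e-8)
            assert s_fast == pytest.approx(s_slow, abs=1e-8)

    def test_noiseless_model_perfect(self, planted_noiseless):
        dm, act, truth = planted_noiseless
        r2, s = loo_cv(dm.matrix(truth.signal_names), act.log10_ic50)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert s == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_predicts_mean_of_others(self, rng):
        y = rng.normal(size=12)
        X = np.empty((12, 0))
        _, stats = fit_ols(X, y)
        e_loo = stats.residuals / (1 - stats.leverages)
        pred = y - e_loo
        for i in range(12):
            others = np.delete(y, i).mean()
            assert pred[i] == pytest.approx(others, abs=1e-10)

    def test_loo_never_beats_training_r2(self, rng):
        """Shrinkage: cross-validated R2 stays below the training R2 on
        fixtures with genuine signal."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 3))
            y = X @ np.array([1.0, -0.8, 0.6]) + r.normal(size=40)
            _, stats = fit_ols(X, y)
            r2_loo, _ = loo_cv(X, y)
            assert r2_loo <= stats.r2 + 1e-10

    def test_too_small_rejected(self, rng):
        with pytest.raises(DataError):
            loo_cv(rng.normal(size=(5, 3)), rng.normal(size=5))


class TestLeaveNPctOut:
    def test_noiseless_perfect_any_pct(self, planted_noiseless):
        dm, act, truth = planted_noiseless
        r2, s = leave_n_pct_out(dm.matrix(truth.signal_names), act.log10_ic50,
                                pct=0.3, n_cases=200, seed=0)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_holdout_limit_matches_loo(self, rng):
        n = 30
        X = rng.normal(size=(n, 2))
        y = X @ np.array([1.0, -1.0]) + rng.normal(size=n) * 0.5
        r2_loo, s_loo = loo_cv(X, y)
        r2_lno, s_lno = leave_n_pct_out(X, y, pct=1 / n, n_cases=4000, seed=1)
        assert r2_lno == pytest.approx(r2_loo, abs=0.05)
        assert s_lno == pytest.approx(s_loo, abs=0.05)

    def test_holdout_block_size(self):
        assert round(0.30 * 265) == 80  # 80 compounds per case at study scale

    def test_remainder_too_small_rejected(self, rng):
        with pytest.raises(DataError):
            leave_n_pct_out(rng.normal(size=(12, 6)), rng.normal(size=12),
                            pct=0.4, n_cases=100)


class TestYRandomization:
    def test_strong_signal_degrades_under_scrambling(self):
        dm, act, truth = rq.generate(clean_spec(
            n_compounds=200, n_descriptors=30, n_signal=5, noise_sd=0.3,
            seed=2))
        X = dm.matrix(truth.signal_names)
        y = act.log10_ic50
        _, stats = fit_ols(X, y)
        _, s_rand, ok = y_randomization(X, y, n_permutations=300, seed=0,
                                        s_train=stats.s)
        assert ok and s_rand > 1.5 * stats.s

    def test_pure_noise_ratio_near_one(self, rng):
        n = 400
        X = rng.normal(size=(n, 5))
        y = rng.normal(size=n)  # no relationship at all
        _, stats = fit_ols(X, y)
        _, s_rand, _ = y_randomization(X, y, n_permutations=300, seed=0,
                                       s_train=stats.s)
        assert 0.95 < s_rand / stats.s < 1.05

    def test_permutation_is_never_identity(self, rng):
        # scrambling with the identity would silently copy the real fit
        X = rng.normal(size=(3, 1))
        y = np.array([1.0, 2.0, 4.0])
        r2_rand, _, _ = y_randomization(X, y, n_permutations=50, seed=0)
        assert np.isfinite(r2_rand)


class TestGolbraikhTropsha:
    def test_identity_passes_everything(self, rng):
        y = rng.normal(size=30) + 3
        gt = golbraikh_tropsha(y, y)
        assert gt.k == pytest.approx(1.0) and gt.k_prime == pytest.approx(1.0)
        assert gt.r2 == pytest.approx(1.0) and gt.r0sq == pytest.approx(1.0)
        assert gt.rm2 == pytest.approx(1.0)
        assert gt.passes

    def test_doubled_slope_fails_k_window(self, rng):
        y = np.abs(rng.normal(size=50)) + 1.0
        gt = golbraikh_tropsha(y, 2 * y)
        assert gt.k == pytest.approx(2.0)
        assert not (0.85 <= gt.k <= 1.15)

    def test_swap_symmetry(self, rng):
        y = rng.normal(size=40) + 5
        p = y + rng.normal(size=40) * 0.3
        gt = golbraikh_tropsha(y, p)
        gt_swapped = golbraikh_tropsha(p, y)
        assert gt_swapped.k == pytest.approx(gt.k_prime)
        assert gt_swapped.k_prime == pytest.approx(gt.k)
        assert gt_swapped.r0sq == pytest.approx(gt.r0sq_prime)
        assert gt_swapped.r0sq_prime == pytest.approx(gt.r0sq)

    def test_published_triplet_is_internally_consistent(self):
        """R2 = 0.69 with 1 - R0^2/R2 = 1.18e-3 implies Rm^2 = 0.67, the
        value printed alongside them."""
        r2 = 0.69
        r0sq = r2 * (1 - 1.18e-3)
        assert rm_squared(r2, r0sq) == pytest.approx(0.67, abs=0.005)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DataError):
            golbraikh_tropsha(np.ones(10), np.arange(10.0))


class TestOutliers:
    def test_zero_residuals_no_outliers(self):
        count, ids = count_outliers(np.zeros(10), s_train=0.5)
        assert count == 0 and ids == []

    def test_boundary_just_above_three_s(self):
        res = np.zeros(20)
        res[7] = 3.01 * 0.8
        count, ids = count_outliers(res, s_train=0.8,
                                    ids=[f"c{i}" for i in range(20)])
        assert count == 1 and ids == ["c7"]

    def test_exactly_three_s_not_an_outlier(self):
        res = np.array([3.0 * 0.5, 0.0])
        count, _ = count_outliers(res, s_train=0.5)
        assert count == 0

    def test_gaussian_rate_matches_normal_tail(self):
        """With Gaussian residuals at n = 265 the expected o3 count is
        roughly 265 * P(|Z| > 3) ~ 0.7; the 50-seed mean must sit in
        [0.3, 1.3]."""
        counts = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = r.normal(size=(265, 8))
            y = X @ r.normal(size=8) + r.normal(size=265) * 0.8
            _, stats = fit_ols(X, y)
            c, _ = count_outliers(stats.residuals, stats.s)
            counts.append(c)
        assert 0.3 <= np.mean(counts) <= 1.3
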