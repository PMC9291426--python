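import numpy as np
import pytest

from seqreach import (
    DataError,
    GroupSeries,
    LearningModel,
    ParameterError,
    baseline_correct,
    bootstrap_fit,
    compare_families,
    early_training_mean,
    group_contrast,
    simulate_mt_series,
)


def _series(values, group="g"):
    return GroupSeries(np.asarray(values, float), group=group)


class TestBootstrapFit:
    def test_noiseless_identical_participants_recover_exactly(self):
        x = np.arange(1, 101)
        vals = np.tile(5.0 - 0.002 * x, (6, 1))
        res = bootstrap_fit(_series(vals), "poly1", n_boot=50, seed=0)
        assert res.point.params[0] == pytest.approx(-0.002, abs=1e-12)
        assert res.point.params[1] == pytest.approx(5.0, abs=1e-9)
        lo, hi = res.ci["p1"]
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_slope_ci_contains_zero(self):
        rng = np.random.default_rng(0)
        vals = 4.0 + rng.normal(0, 0.1, size=(8, 60))
        res = bootstrap_fit(_series(vals), "poly1", n_boot=300, seed=1)
        lo, hi = res.ci["p1"]
        assert lo <= 0.0 <= hi

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        vals = 5 - 0.003 * np.arange(1, 81) + rng.normal(0, 0.2, (10, 80))
        a = bootstrap_fit(_series(vals), "poly1", n_boot=200, seed=11)
        b = bootstrap_fit(_series(vals), "poly1", n_boot=200, seed=11)
        np.testing.assert_array_equal(a.param_draws, b.param_draws)
        assert a.ci == b.ci

    def test_ci_width_shrinks_with_noise(self):
        x = np.arange(1, 121)
        rng = np.random.default_rng(9)
        widths = []
        for sd in (0.5, 0.05, 0.005):
            offs = rng.normal(0, sd, size=(12, 1))
            vals = 5 - 0.002 * x + offs + rng.normal(0, sd, (12, 120))
            res = bootstrap_fit(_series(vals), "poly1", n_boot=300, seed=2)
            lo, hi = res.ci["p2"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_parameter_recovery_within_ci(self):
        """Downstream fit recovers the generative intercept and slope."""
        model = LearningModel(intercept=5.0, slope=-0.002, participant_sd=0.3, trial_sd=0.2)
        vals = simulate_mt_series(model, 15, 200, np.random.default_rng(21))
        res = bootstrap_fit(_series(vals), "poly1", n_boot=500, seed=3)
        lo, hi = res.ci["p1"]
        assert lo <= -0.002 <= hi
        lo, hi = res.ci["p2"]
        assert lo <= 5.0 <= hi

    def test_nonlinear_families_fit_exponential_truth(self):
        x = np.arange(1, 151)
        truth = 5.0 * np.exp(-0.01 * x)
        rng = np.random.default_rng(1)
        vals = truth + rng.normal(0, 0.05, (10, 150))
        res = bootstrap_fit(_series(vals), "exp1", n_boot=100, seed=4)
        assert res.point.params[0] == pytest.approx(5.0, rel=0.05)
        assert res.point.params[1] == pytest.approx(-0.01, rel=0.1)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ParameterError):
            bootstrap_fit(_series(np.ones((1, 10))), "poly1")

    def test_unknown_family_rejected(self):
        with pytest.raises(ParameterError):
            bootstrap_fit(_series(np.ones((3, 10))), "spline9")


class TestCompareFamilies:
    def test_linear_truth_ranks_poly_first(self):
        # the decline must be steep enough that exponential convexity
        # misfits; a shallow line is locally indistinguishable from exp
        x = np.arange(1, 201)
        rng = np.random.default_rng(6)
        vals = 5.0 - 0.015 * x + rng.normal(0, 0.3, (12, 1)) + rng.normal(0, 0.2, (12, 200))
        rep = compare_families(_series(vals), n_boot=150, seed=5)
        assert rep["ranking"][0]["family"] == "poly1"

    def test_exponential_truth_ranks_exp_first(self):
        x = np.arange(1, 201)
        rng = np.random.default_rng(7)
        truth = 4.0 * np.exp(-0.015 * x)
        vals = truth + rng.normal(0, 0.05, (12, 200))
        rep = compare_families(_series(vals), n_boot=150, seed=6)
        assert rep["ranking"][0]["family"] == "exp1"

    def test_pure_noise_r_squared_near_zero_and_overlapping(self):
        rng = np.random.default_rng(8)
        vals = 5.0 + rng.normal(0, 0.2, (10, 120))
        rep = compare_families(_series(vals), families=("poly1", "exp1"), n_boot=150, seed=7)
        assert all(abs(row["mean_r_squared"]) < 0.2 for row in rep["ranking"])
        assert rep["top_two_cis_overlap"]


class TestGroupContrast:
    @staticmethod
    def _group(slope, seed, n=12):
        x = np.arange(1, 201)
        rng = np.random.default_rng(seed)
        vals = 5.0 + slope * x + rng.normal(0, 0.3, (n, 1)) + rng.normal(0, 0.2, (n, 200))
        return _series(vals)

    def test_separated_slopes_detected(self):
        a = bootstrap_fit(self._group(-0.006, 1), "poly1", n_boot=400, seed=10)
        b = bootstrap_fit(self._group(-0.002, 2), "poly1", n_boot=400, seed=11)
        rep = group_contrast(a, b, "p1")
        assert rep.significant
        assert rep.diff_ci[1] < 0.0

    def test_self_contrast_is_identically_zero(self):
        a = bootstrap_fit(self._group(-0.004, 3), "poly1", n_boot=200, seed=12)
        rep = group_contrast(a, a, "p1")
        assert rep.diff_ci == (0.0, 0.0)
        assert not rep.significant

    def test_null_contrast_usually_not_significant(self):
        a = bootstrap_fit(self._group(-0.004, 4), "poly1", n_boot=400, seed=13)
        b = bootstrap_fit(self._group(-0.004, 5), "poly1", n_boot=400, seed=14)
        rep = group_contrast(a, b, "p1")
        assert rep.diff_ci[0] <= 0.0 <= rep.diff_ci[1]

    def test_mismatched_families_rejected(self):
        a = bootstrap_fit(self._group(-0.004, 6), "poly1", n_boot=50, seed=15)
        b = bootstrap_fit(self._group(-0.004, 7), "exp1", n_boot=50, seed=16)
        with pytest.raises(ParameterError):
            group_contrast(a, b, "p1")


class TestBaselineAndEarlyMeans:
    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        vals = 5 + rng.normal(0, 0.2, (5, 30))
        base = vals[:, 0].copy()
        corrected = baseline_correct(_series(vals), base)
        shifted = vals.copy()
        shifted[2] += 3.0
        base2 = base.copy()
        base2[2] += 3.0
        corrected2 = baseline_correct(_series(shifted), base2)
        np.testing.assert_allclose(corrected.values, corrected2.values)

    def test_first_trial_baseline_zeroes_start(self):
        vals = np.array([[4.0, 4.1, 4.2], [5.0, 5.2, 5.4]])
        corrected = baseline_correct(_series(vals), vals[:, 0])
        np.testing.assert_allclose(corrected.values[:, 0], 0.0)

    def test_offsets_removed_shrinks_between_participant_variance(self):
        """Removing generative offsets leaves only trial noise at trial 1."""
        model = LearningModel(intercept=5.0, slope=0.0, participant_sd=0.5, trial_sd=0.1)
        vals = simulate_mt_series(model, 200, 30, np.random.default_rng(2))
        offsets = vals.mean(axis=1) - vals.mean()
        corrected = baseline_correct(_series(vals), offsets)
        var_before = vals[:, 0].var()
        var_after = corrected.values[:, 0].var()
        assert var_after < var_before
        assert var_after == pytest.approx(0.1**2, rel=0.5)

    def test_missing_baseline_rejected(self):
        with pytest.raises(DataError):
            baseline_correct(_series(np.ones((3, 5))), {1: 0.0, 2: 0.0})

    @pytest.mark.parametrize("first5,expected", [([5, 5, 5, 5, 5], 5.0), ([1, 2, 3, 4, 5], 3.0)])
    def test_early_training_mean_values(self, first5, expected):
        vals = np.array([first5 + [9, 9]], dtype=float)
        assert early_training_mean(_series(vals))[0] == pytest.approx(expected)

    def test_early_mean_recovers_intercept_shift(self):
        m1 = LearningModel(intercept=5.0, slope=-0.002, participant_sd=0.2, trial_sd=0.15)
        m2 = LearningModel(intercept=4.2, slope=-0.002, participant_sd=0.2, trial_sd=0.15)
        rng = np.random.default_rng(3)
        a = early_training_mean(_series(simulate_mt_series(m1, 40, 20, rng)))
        b = early_training_mean(_series(simulate_mt_series(m2, 40, 20, rng)))
        assert b.mean() - a.mean() == pytest.approx(-0.8, abs=0.15)

    def test_insufficient_trials_rejected(self):
        with pytest.raises(DataError):
            early_training_mean(_series(np.ones((2, 3))))
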