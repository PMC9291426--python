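import numpy as np
import pytest

from seqreach import (
    ParameterError,
    SimulationConfig,
    fusion_index,
    piecewise_fit,
    radial_distance,
    radial_percent,
    simulate_trial,
    trial_fusion,
)
from seqreach.fusion import _confidence_ellipse


class TestFusionIndex:
    def test_fully_coarticulated_transition_scores_one(self):
        assert fusion_index(20.0, 20.0, 20.0) == 1.0

    def test_full_stop_scores_zero(self):
        assert fusion_index(20.0, 30.0, 0.0) == 0.0

    def test_hand_computed_value(self):
        # m = 25, fi = 1 - (25 - 10)/25 = 0.4
        assert fusion_index(20.0, 30.0, 10.0) == pytest.approx(0.4)

    def test_scale_invariance(self):
        base = fusion_index(18.0, 26.0, 7.0)
        for c in (0.1, 3.0, 250.0):
            assert fusion_index(18.0 * c, 26.0 * c, 7.0 * c) == pytest.approx(base)

    def test_clamped_with_warning_when_vmin_exceeds_mean_peak(self):
        with pytest.warns(RuntimeWarning):
            assert fusion_index(10.0, 10.0, 15.0) == 1.0

    @pytest.mark.parametrize("bad", [(0.0, 10.0, 1.0), (10.0, -1.0, 1.0), (10.0, 10.0, -0.1)])
    def test_invalid_speeds_rejected(self, bad):
        with pytest.raises(ParameterError):
            fusion_index(*bad)


class TestTrialFusion:
    def test_all_fused_trial_sums_to_seven(self, clean_trial):
        m = clean_trial.metrics
        m2 = type(m)(
            movement_time=m.movement_time,
            reaction_time=m.reaction_time,
            vmax_per_segment=np.full(8, 20.0),
            vmin_per_transition=np.full(7, 20.0),
        )
        assert trial_fusion(m2).fi_trial == 7.0

    def test_all_stopped_trial_sums_to_zero(self, clean_trial):
        m = clean_trial.metrics
        m2 = type(m)(
            movement_time=m.movement_time,
            reaction_time=m.reaction_time,
            vmax_per_segment=np.full(8, 20.0),
            vmin_per_transition=np.zeros(7),
        )
        assert trial_fusion(m2).fi_trial == 0.0

    def test_mixed_triplets_sum_of_hand_values(self, clean_trial):
        m = clean_trial.metrics
        vmax = np.array([20, 30, 20, 25, 25, 40, 10, 20], dtype=float)
        vmin = np.array([10, 0, 9, 25, 13, 5, 15], dtype=float)
        m2 = type(m)(
            movement_time=m.movement_time,
            reaction_time=m.reaction_time,
            vmax_per_segment=vmax,
            vmin_per_transition=vmin,
        )
        expected = sum(
            min(1.0, vmin[k] / (0.5 * (vmax[k] + vmax[k + 1]))) for k in range(7)
        )
        assert trial_fusion(m2).fi_trial == pytest.approx(expected)


class TestRadialDistance:
    def test_centroid_on_via_scores_100(self, geometry):
        assert radial_percent(geometry.via_center, geometry.via_center, [0.0, 10.0]) == 100.0

    def test_hand_computed_value(self):
        # d = 2.5 on an L = 10 segment -> 75%
        assert radial_percent([0.0, 2.5], [0.0, 0.0], [0.0, 10.0]) == pytest.approx(75.0)

    def test_zero_fusion_trials_score_in_discrete_band(self, clean_trial, geometry):
        series = radial_distance([clean_trial] * 10, geometry, window=10)
        assert len(series) == 1
        assert 45.0 <= series[0].rd_mean <= 55.0

    def test_window_slides_with_stride_one(self, clean_trial, geometry):
        series = radial_distance([clean_trial] * 13, geometry, window=10)
        assert [s.window_start_trial for s in series] == [0, 1, 2, 3]

    def test_window_larger_than_data_rejected(self, clean_trial, geometry):
        with pytest.raises(ParameterError):
            radial_distance([clean_trial] * 5, geometry, window=10)

    def test_rd_invariant_under_rigid_motion(self, geometry, clean_trial, analyze_one):
        import seqreach

        th = np.deg2rad(52.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([-4.0, 2.5])
        geo2 = geometry.transformed(rotation_deg=52.0, translation=shift)
        traj2 = seqreach.Trajectory(
            clean_trial.trajectory.sample_times,
            clean_trial.trajectory.positions @ R.T + shift,
        )
        prof2 = seqreach.compute_velocity(traj2)
        seg2 = seqreach.segment_trial(prof2, traj2, geo2)
        from seqreach.pipeline import AnalyzedTrial

        t2 = AnalyzedTrial(traj2, prof2, seg2, None)
        a = radial_distance([clean_trial] * 10, geometry, window=10)[0]
        b = radial_distance([t2] * 10, geo2, window=10)[0]
        np.testing.assert_allclose(a.rd_percent, b.rd_percent, atol=1e-8)

    def test_degenerate_scatter_gives_zero_axes(self):
        c, axes, ang = _confidence_ellipse(np.tile([1.0, 2.0], (10, 1)), 0.95)
        np.testing.assert_allclose(c, [1.0, 2.0])
        np.testing.assert_allclose(axes, 0.0, atol=1e-12)

    def test_ellipse_covers_95_percent_of_bivariate_normal(self):
        rng = np.random.default_rng(2)
        pts = rng.multivariate_normal([0, 0], [[4.0, 1.2], [1.2, 1.0]], size=20000)
        c, axes, ang = _confidence_ellipse(pts, 0.95)
        th = np.deg2rad(ang)
        R = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        local = (pts - c) @ R.T
        inside = (local[:, 0] / axes[0]) ** 2 + (local[:, 1] / axes[1]) ** 2 <= 1.0
        assert np.mean(inside) == pytest.approx(0.95, abs=0.01)


class TestPiecewiseFit:
    @staticmethod
    def _hinge(x, knot, s1, s2, b=0.0):
        return np.where(x <= knot, b + s1 * x, b + s1 * knot + s2 * (x - knot))

    def test_noiseless_hinge_identified_exactly(self):
        x = np.linspace(0.0, 4.0, 300)
        y = self._hinge(x, 1.6, -0.1, 0.9, b=50.0)
        fit = piecewise_fit(x, y)
        assert fit.interior_knot == pytest.approx(1.6, abs=1e-3)
        assert fit.slopes[0] == pytest.approx(-0.1, abs=1e-6)
        assert fit.slopes[1] == pytest.approx(0.9, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_noisy_hinge_recovered(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0.0, 4.0, 500)
        y = self._hinge(x, 1.6, -0.1, 0.9, b=50.0) + rng.normal(0, 0.5, 500)
        fit = piecewise_fit(x, y)
        assert fit.interior_knot == pytest.approx(1.6, abs=0.15)

    def test_nested_in_single_line(self):
        x = np.linspace(0.0, 10.0, 120)
        y = 2.0 + 0.3 * x
        fit = piecewise_fit(x, y)
        A = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse_line = float(np.sum((y - A @ beta) ** 2))
        assert fit.sse <= sse_line + 1e-9
        assert fit.slopes[0] == pytest.approx(0.3, abs=1e-6)
        assert fit.slopes[1] == pytest.approx(0.3, abs=1e-4)

    def test_two_segment_sse_never_exceeds_single_line(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0.0, 10.0, 120)
        y = 2.0 + 0.3 * x + rng.normal(0, 0.05, 120)
        fit = piecewise_fit(x, y)
        A = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse_line = float(np.sum((y - A @ beta) ** 2))
        assert fit.sse <= sse_line + 1e-9

    def test_continuity_at_interior_knot(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 5, 200)
        y = self._hinge(x, 2.0, 1.0, -2.0) + rng.normal(0, 0.3, 200)
        fit = piecewise_fit(x, y)
        k = fit.interior_knot
        left = fit.intercepts[0] + fit.slopes[0] * k
        right = fit.intercepts[1] + fit.slopes[1] * k
        assert left == pytest.approx(right, abs=1e-9)

    def test_insufficient_data_rejected(self):
        from seqreach import FitError

        with pytest.raises(FitError):
            piecewise_fit([1, 2, 3], [1, 2, 3])
        with pytest.raises(FitError):
            piecewise_fit(np.ones(10), np.arange(10))


def test_fi_and_rd_positively_associated_at_high_fusion(geometry, analyze_one):
    """Above drift onset, spatial reorganization tracks the fusion index."""
    from seqreach import radial_distance, trial_fusion

    fis, rds = [], []
    for f in (0.6, 0.7, 0.8, 0.9, 1.0):
        a = analyze_one(fusion=f)
        fis.append(trial_fusion(a.metrics).fi_trial)
        rds.append(radial_distance([a] * 10, geometry, window=10)[0].rd_mean)
    from scipy.stats import spearmanr

    assert spearmanr(fis, rds).statistic > 0.9
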