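"""Correlation tests, Fisher combination and bootstrap angle estimation."""

import math

import numpy as np
import pytest
from scipy import stats

import spikepairs as sp
from spikepairs.geometry import angle_significance_two_sided


def _cloud_at(angle_deg, n, rng, sds=(3.0, 0.5), centre=(20.0, 20.0)):
    phi = np.deg2rad(angle_deg)
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    cov = R @ np.diag(np.square(sds)) @ R.T
    return rng.multivariate_normal(centre, cov, size=n)


class TestLinearCorrelation:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = sp.linear_correlation(np.column_stack([x, 2 * x + 1]))
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_zero_x_variance_rejected(self):
        pts = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError):
            sp.linear_correlation(pts)

    def test_symmetric_in_axis_swap(self, rng):
        pts = rng.normal(size=(50, 2))
        assert sp.linear_correlation(pts).r == pytest.approx(
            sp.linear_correlation(pts[:, ::-1]).r)

    def test_type_one_error_rate_at_strict_threshold(self, rng):
        # 2000 independent bivariate samples, n=500: rejections at
        # alpha=0.005 should occur at the nominal rate
        n_rep, n = 2000, 500
        x = rng.standard_normal((n_rep, n))
        y = rng.standard_normal((n_rep, n))
        xm = x - x.mean(1, keepdims=True)
        ym = y - y.mean(1, keepdims=True)
        r = (xm * ym).sum(1) / np.sqrt((xm**2).sum(1) * (ym**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        rate = np.mean(p < 0.005)
        assert 0.0003 <= rate <= 0.0105


class TestFisherCombine:
    def test_closed_form_half(self):
        n = 100
        chi2, df, p = sp.fisher_combine([0.5] * n)
        assert chi2 == pytest.approx(-2 * n * math.log(0.5))
        assert df == 2 * n

    def test_all_ones_give_zero(self):
        chi2, df, _ = sp.fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == pytest.approx(0.0)
        assert df == 6

    def test_df_is_twice_count(self, rng):
        p = rng.uniform(0.01, 1, size=3929)
        assert sp.fisher_combine(p)[1] == 7858

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            sp.fisher_combine([0.5, 0.0])
        with pytest.raises(ValueError):
            sp.fisher_combine([0.5, 1.2])


class TestBootstrapAngle:
    def test_exact_diagonal(self):
        x = np.linspace(0, 10, 50)
        est = sp.bootstrap_angle(np.column_stack([x, x]), n_boot=500, seed=0)
        assert est.theta == pytest.approx(45.0)
        assert est.theta45 == pytest.approx(45.0)
        assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_slope_two_line(self):
        x = np.linspace(0, 10, 50)
        est = sp.bootstrap_angle(np.column_stack([x, 2 * x]), n_boot=500, seed=0)
        assert est.theta == pytest.approx(math.degrees(math.atan(2)), abs=1e-6)
        assert est.theta45 == pytest.approx(90 - math.degrees(math.atan(2)), abs=1e-6)

    def test_degenerate_isotropic_rejected(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])  # exact isotropy
        with pytest.raises(ValueError):
            sp.bootstrap_angle(pts, n_boot=100, seed=0)

    @pytest.mark.parametrize("angle", [5, 15, 25, 35, 45, 55, 65, 75, 85])
    def test_doubling_roundtrip_no_discontinuity(self, angle, rng):
        pts = _cloud_at(angle, 500, rng, sds=(3.0, 0.3))
        est = sp.bootstrap_angle(pts, n_boot=1000, seed=rng)
        assert abs(est.theta - angle) < 1.0

    def test_near_zero_angle_wraparound(self, rng):
        pts = _cloud_at(1.0, 500, rng, sds=(3.0, 0.3))
        est = sp.bootstrap_angle(pts, n_boot=1000, seed=rng)
        delta = min(abs(est.theta - 1.0), abs(est.theta - 181.0), abs(est.theta + 179.0))
        assert delta < 1.0

    def test_axis_swap_maps_theta_to_complement(self, rng):
        pts = _cloud_at(30, 200, rng)
        a = sp.bootstrap_angle(pts, n_boot=1000, seed=7)
        b = sp.bootstrap_angle(pts[:, ::-1], n_boot=1000, seed=7)
        assert b.theta == pytest.approx(90 - a.theta, abs=1e-9)
        assert b.theta45 == pytest.approx(a.theta45, abs=1e-9)

    def test_ci_brackets_estimate(self, rng):
        pts = _cloud_at(60, 100, rng)
        est = sp.bootstrap_angle(pts, n_boot=2000, seed=rng)
        assert est.ci_low <= est.theta <= est.ci_high


class TestAngleSignificance:
    def test_tight_cluster_inside_range_has_zero_tails(self, rng):
        pts = _cloud_at(25, 400, rng, sds=(3.0, 0.2))
        est = sp.bootstrap_angle(pts, n_boot=2000, seed=rng)
        assert sp.angle_significance(est, 0.0) == 0.0
        assert sp.angle_significance(est, 45.0) == 0.0

    def test_cloud_on_45_has_half_tail(self, rng):
        pts = _cloud_at(45, 300, rng, sds=(3.0, 1.0))
        est = sp.bootstrap_angle(pts, n_boot=4000, seed=rng)
        assert 0.25 <= sp.angle_significance(est, 45.0) <= 0.75
        assert angle_significance_two_sided(est) >= 0.5

    def test_shallow_noisy_cloud_not_significant_vs_zero(self, rng):
        pts = _cloud_at(1.0, 40, rng, sds=(2.0, 1.5))
        est = sp.bootstrap_angle(pts, n_boot=2000, seed=rng)
        if 0 < est.theta < 90:
            assert sp.angle_significance(est, 0.0) > 0.025

    def test_negative_correlation_rejected(self, rng):
        pts = _cloud_at(135, 100, rng)
        est = sp.bootstrap_angle(pts, n_boot=500, seed=rng)
        with pytest.raises(ValueError):
            sp.angle_significance(est, 45.0)


class TestHenzeZirkler:
    def test_null_calibration(self, rng):
        rejections = sum(sp.henze_zirkler(rng.normal(size=(100, 2))) < 0.05
                         for _ in range(400))
        assert 0.02 <= rejections / 400 <= 0.09

    def test_power_on_two_blob_mixture(self, rng):
        rej = 0
        for _ in range(50):
            a = rng.normal(0, 1, size=(50, 2))
            b = rng.normal(8, 1, size=(50, 2))
            rej += sp.henze_zirkler(np.vstack([a, b])) < 0.05
        assert rej / 50 > 0.9

    def test_degenerate_input_rejected(self):
        pts = np.tile([[1.0, 2.0]], (20, 1))
        with pytest.raises(ValueError):
            sp.henze_zirkler(pts)

    def test_small_sample_not_assessable(self, rng):
        with pytest.raises(ValueError):
            sp.henze_zirkler(rng.normal(size=(5, 2)))


class TestTrendAndLagged:
    def test_trial_regression_extremes(self, rng):
        t = np.arange(100)
        flat = rng.normal(size=(100, 2))
        _, r2 = sp.trial_regressions(flat, t)
        assert r2 < 0.1
        exact = np.column_stack([2.0 * t + 1, -0.5 * t + 3])
        _, r2 = sp.trial_regressions(exact, t)
        assert r2 == pytest.approx(1.0)

    def test_trial_r2_grows_with_drift_amplitude(self, rng):
        t = np.arange(200)
        r2s = []
        for amp in (0.0, 1.0, 2.0, 4.0):
            vals = []
            for _ in range(20):
                drift = amp * (t / t.max())
                pts = rng.normal(size=(200, 2)) + drift[:, None]
                vals.append(sp.trial_regressions(pts, t)[1])
            r2s.append(np.mean(vals))
        assert all(np.diff(r2s) > 0)

    def test_constant_trial_vector_rejected(self, rng):
        with pytest.raises(ValueError):
            sp.trial_regressions(rng.normal(size=(10, 2)), np.ones(10))

    def test_fixed_difference_null(self):
        x = np.linspace(5, 15, 30)
        res = sp.diff_vs_first_spike(np.column_stack([x, x + 3.0]))
        assert res.r == 0.0 and res.p == 1.0

    def test_difference_equals_x_on_slope_two(self):
        x = np.linspace(5, 15, 30)
        res = sp.diff_vs_first_spike(np.column_stack([x, 2 * x]))
        assert res.r == pytest.approx(1.0)

    def test_diff_regression_nominal_rate_under_fixed_difference_null(self, rng):
        # null model: s1 = s0 + d + independent noise, so the difference
        # carries no information about s0 and rejections are nominal
        sig = 0
        for _ in range(300):
            s0 = rng.normal(12.0, 2.0, 60)
            s1 = s0 + 3.0 + rng.normal(0.0, 0.8, 60)
            sig += sp.diff_vs_first_spike(np.column_stack([s0, s1])).p < 0.05
        assert 0.01 <= sig / 300 <= 0.10

    def test_cross_correlation_identity_and_null(self, rng):
        t = np.arange(100)
        s = rng.normal(size=100)
        res = sp.cross_correlation(s, t, s, t, lag=0)
        assert res.r == pytest.approx(1.0)
        sig = 0
        for _ in range(200):
            a, b = rng.normal(size=(2, 200))
            sig += sp.cross_correlation(a, np.arange(200), b, np.arange(200), lag=1).p < 0.05
        assert 0.01 <= sig / 200 <= 0.10

    def test_cross_correlation_shared_state_positive(self):
        d = sp.sample_pair_distribution(55, n_trials=200)
        res = sp.cross_correlation(d.x, d.trials, d.y, d.trials, lag=0)
        assert res.r > 0.5

    def test_overlap_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            sp.cross_correlation([1, 2], [0, 1], [3, 4], [5, 6], lag=0)
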