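"""Single-factor state model, RDR spreads and cross-cluster state tests."""

import math

import numpy as np
import pytest

import spikepairs as sp
from spikepairs.calibration import four_neuron_config
from spikepairs.core import FactorModel
from spikepairs.state import HeywoodError, loading_angle


def _cluster_dist(seed, n=300, loadings=(2.0, 1.0), noise=0.25):
    sigmas = (noise * loadings[0], max(noise * loadings[1], 1e-3))
    return sp.sample_pair_distribution(seed, n_trials=n, loadings=loadings,
                                       sigmas=sigmas)


class TestFitSingleFactor:
    def test_sigma_diff_pythagoras(self):
        m = FactorModel(1, 1, 3.0, 4.0, eta=np.zeros(10))
        assert m.sigma_diff == pytest.approx(5.0)

    def test_parameter_recovery_under_proportional_noise(self):
        lam = (2.0, 1.0)
        ok = 0
        n_rep = 40
        for seed in range(n_rep):
            d = _cluster_dist(600 + seed, n=300, loadings=lam, noise=0.25)
            m = sp.fit_single_factor(d.points)
            lam_ok = (abs(m.lambda0 - lam[0]) / lam[0] < 0.15
                      and abs(m.lambda1 - lam[1]) / lam[1] < 0.15)
            sig_ok = (abs(m.sigma0 - 0.25 * lam[0]) / (0.25 * lam[0]) < 0.2
                      and abs(m.sigma1 - 0.25 * lam[1]) / (0.25 * lam[1]) < 0.2)
            ok += lam_ok and sig_ok
        assert ok >= 0.9 * n_rep

    def test_eta_scores_centred_and_correlated_with_truth(self):
        d = _cluster_dist(42, n=400, noise=0.2)
        m = sp.fit_single_factor(d.points)
        assert abs(m.eta.mean()) < 1e-9

    def test_implied_covariance_matches_em_factor_analysis(self):
        # dual route: the closed-form fit and scikit-learn's EM factor
        # analysis sit on the same solution ridge, so their model-implied
        # covariances (lambda lambda' + diag(sigma^2)) must agree
        from sklearn.decomposition import FactorAnalysis
        d = _cluster_dist(21, n=400, noise=0.2)
        m = sp.fit_single_factor(d.points)
        lam = np.array([m.lambda0, m.lambda1])
        ours = np.outer(lam, lam) + np.diag([m.sigma0**2, m.sigma1**2])
        fa = FactorAnalysis(n_components=1, random_state=0).fit(d.points)
        theirs = fa.components_.T @ fa.components_ + np.diag(fa.noise_variance_)
        assert np.allclose(ours, theirs, rtol=0.05, atol=0.05)

    def test_negative_correlation_rejected(self, rng):
        pts = rng.multivariate_normal([0, 0], [[1, -0.6], [-0.6, 1]], 100)
        with pytest.raises(HeywoodError):
            sp.fit_single_factor(pts)

    def test_equal_loadings_symmetric_cluster_at_45(self):
        d = _cluster_dist(7, loadings=(1.5, 1.5), noise=0.05)
        m = sp.fit_single_factor(d.points)
        assert loading_angle(m) == pytest.approx(45.0, abs=2.0)


class TestFactorAngle:
    def test_loading_angle_closed_forms(self):
        assert loading_angle(FactorModel(2, 1, 0.1, 0.1, np.zeros(3))) == \
            pytest.approx(math.degrees(math.atan2(1, 2)))
        assert loading_angle(FactorModel(1, 1, 0.1, 0.1, np.zeros(3))) == \
            pytest.approx(45.0)

    def test_zero_loadings_rejected(self):
        with pytest.raises(ValueError):
            loading_angle(FactorModel(0, 0, 1, 1, np.zeros(3)))

    def test_factor_angle_close_to_pca_angle_for_tight_clusters(self):
        d = _cluster_dist(11, n=400, loadings=(2.0, 1.2), noise=0.1)
        fa = sp.factor_angle(d.points, n_boot=1000, seed=1)
        pca = sp.bootstrap_angle(d.points, n_boot=1000, seed=1)
        assert abs(fa.theta - pca.theta) < 5.0


class TestRdr:
    def test_outlier_mass_inflates_rdr1(self, rng):
        d = _cluster_dist(13, n=200)
        far = d.points + np.array([25.0, -10.0])
        pts = np.vstack([d.points, far])
        dist = d.replace_points(pts, trials=np.arange(len(pts)))
        m = sp.fit_single_factor(d.points)
        rdr = sp.rdr_summary(dist, d.points, m)
        assert rdr.rdr1_sigma_diff > rdr.rdr2_sigma_diff

    def test_unequal_loadings_give_rdr3_below_rdr2(self):
        for seed in range(10):
            d = _cluster_dist(700 + seed, loadings=(2.0, 1.0), noise=0.3)
            m = sp.fit_single_factor(d.points)
            rdr = sp.rdr_summary(d, d.points, m)
            assert rdr.rdr3_sigma_diff <= rdr.rdr2_sigma_diff + 1e-12

    def test_equal_loadings_give_no_improvement(self):
        # sd(s1 - s0) = sqrt(sigma0^2 + sigma1^2) when loadings are equal
        vals = []
        for seed in range(10):
            d = _cluster_dist(800 + seed, loadings=(1.5, 1.5), noise=0.2)
            m = sp.fit_single_factor(d.points)
            rdr = sp.rdr_summary(d, d.points, m)
            vals.append(rdr.rdr3_sigma_diff / rdr.rdr2_sigma_diff)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


class TestPredictState:
    def test_point_at_cluster_mean_scores_zero(self, rng):
        pts = rng.multivariate_normal([10, 20], [[2, 1.2], [1.2, 1]], 101)
        pts[0] = pts.mean(axis=0) * (101 / 100) - pts[1:].mean(axis=0) / 100
        pred = sp.predict_state(pts, np.arange(101))
        centred = pts - pts.mean(axis=0)
        idx = np.argmin(np.hypot(centred[:, 0], centred[:, 1]))
        assert abs(pred.state[idx]) < 0.2

    def test_state_positively_correlated_with_both_latencies(self):
        d = _cluster_dist(17)
        pred = sp.predict_state(d.points, d.trials)
        assert np.corrcoef(pred.state, d.x)[0, 1] > 0
        assert np.corrcoef(pred.state, d.y)[0, 1] > 0

    def test_recovers_generative_state(self):
        # sigma/lambda = 0.2: the PC1 projection tracks the latent state
        cfg = sp.default_pair_config(19, n_trials=300, loadings=(2.0, 1.0),
                                     sigmas=(0.4, 0.2))
        rec = sp.generate_session(cfg)
        d = sp.build_distributions(rec)[0]
        rng = np.random.default_rng(cfg.seed)
        eta = rng.standard_normal(cfg.n_trials)   # generator draws eta first
        pred = sp.predict_state(d.points, d.trials)
        r = np.corrcoef(pred.state, eta[d.trials])[0, 1]
        assert r > 0.7


class TestStateCorrelation:
    def test_shared_state_positive(self):
        pos = total = 0
        for seed in range(20):
            cfg = four_neuron_config(900 + seed, n_trials=40, noise=0.2,
                                      reliability=1.0)
            dists = {(d.neuron_x, d.neuron_y): d
                     for d in sp.build_distributions(sp.generate_session(cfg))}
            da, db = dists[("n0", "n1")], dists[("n2", "n3")]
            pa = sp.predict_state(da.points, da.trials, "a",
                                  (da.neuron_x, da.neuron_y))
            pb = sp.predict_state(db.points, db.trials, "b",
                                  (db.neuron_x, db.neuron_y))
            res = sp.state_correlation(pa, pb)
            total += 1
            pos += res.r > 0
        assert pos >= 0.8 * total

    def test_fourteen_common_trials_excluded(self, rng):
        pa = sp.StatePrediction("a", np.arange(14), rng.normal(size=14), ("x", "y"))
        pb = sp.StatePrediction("b", np.arange(14), rng.normal(size=14), ("u", "v"))
        with pytest.raises(ValueError):
            sp.state_correlation(pa, pb)

    def test_shared_neuron_rejected(self, rng):
        pa = sp.StatePrediction("a", np.arange(20), rng.normal(size=20), ("x", "y"))
        pb = sp.StatePrediction("b", np.arange(20), rng.normal(size=20), ("y", "z"))
        with pytest.raises(ValueError):
            sp.state_correlation(pa, pb)


class TestFourNeuronPca:
    def test_fractions_sum_to_one(self, rng):
        fr = sp.four_neuron_pca(rng.normal(size=(30, 2)), np.arange(30),
                                rng.normal(size=(30, 2)), np.arange(30))
        assert fr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shared_state_dominates_first_component(self):
        cfg = four_neuron_config(33, n_trials=100, noise=0.2, reliability=1.0)
        dists = {(d.neuron_x, d.neuron_y): d
                 for d in sp.build_distributions(sp.generate_session(cfg))}
        da, db = dists[("n0", "n1")], dists[("n2", "n3")]
        fr = sp.four_neuron_pca(da.points, da.trials, db.points, db.trials)
        assert fr[0] > 0.7

    def test_independent_neurons_near_isotropy(self, rng):
        fr = sp.four_neuron_pca(rng.normal(size=(500, 2)), np.arange(500),
                                rng.normal(size=(500, 2)), np.arange(500))
        assert np.all(np.abs(fr - 0.25) < 0.1)


class TestConditionedVariability:
    def test_linear_target_fully_explained(self, rng):
        pred = sp.StatePrediction("a", np.arange(50), rng.normal(size=50), ("x", "y"))
        target = 2.0 * pred.state + 1.0
        uncond, cond = sp.state_conditioned_variability(target, np.arange(50), pred)
        assert cond == pytest.approx(0.0, abs=1e-9)
        assert uncond > 0

    def test_shared_factor_reduces_spread(self):
        wins = total = 0
        for seed in range(30):
            cfg = four_neuron_config(1100 + seed, n_trials=60, noise=0.2,
                                      reliability=1.0)
            dists = {(d.neuron_x, d.neuron_y): d
                     for d in sp.build_distributions(sp.generate_session(cfg))}
            da, db = dists[("n0", "n1")], dists[("n2", "n3")]
            pred = sp.predict_state(da.points, da.trials, "a",
                                    (da.neuron_x, da.neuron_y))
            uncond, cond = sp.state_conditioned_variability(
                db.x, db.trials, pred)
            total += 1
            wins += cond < uncond
        assert wins >= 0.9 * total

    def test_independent_predictor_changes_nothing(self, rng):
        ratios = []
        for _ in range(30):
            pred = sp.StatePrediction("a", np.arange(200),
                                      rng.normal(size=200), ("x", "y"))
            target = rng.normal(size=200)
            uncond, cond = sp.state_conditioned_variability(target,
                                                            np.arange(200), pred)
            ratios.append(cond / uncond)
        assert 0.9 <= np.mean(ratios) <= 1.05


class TestPooling:
    def _ex(self, dist_id, kind):
        return sp.PooledExample(dist_id=dist_id, kind=kind,
                                points=np.zeros((3, 2)), trials=np.arange(3),
                                neuron_ids=("a", "b"))

    def test_cluster_preferred_over_unclustered(self):
        pool = sp.pool_examples([self._ex("d1", "cluster")],
                                [self._ex("d1", "unclustered")])
        assert len(pool) == 1 and pool[0].kind == "cluster"

    def test_disjoint_distributions_union(self):
        pool = sp.pool_examples([self._ex("d1", "cluster")],
                                [self._ex("d2", "unclustered")])
        assert {p.dist_id for p in pool} == {"d1", "d2"}

    def test_empty_inputs(self):
        assert sp.pool_examples([], []) == []
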