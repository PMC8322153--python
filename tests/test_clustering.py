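"""Two-stage cluster extraction: sweep, isolation, expansion, bootstrap
refinement, similarity filtering and the GMM comparison variants."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN

import spikepairs as sp
from spikepairs.clustering import (CandidateCluster, DegenerateClusterError,
                                   _intersection_ellipse, angled_ellipse,
                                   dbscan_labels, ellipses_intersect)
from spikepairs.core import ClusterStage2, Ellipse


def _blob(rng, centre, n, sd=0.5):
    return rng.normal(centre, sd, size=(n, 2))


class TestDbscanLabels:
    def test_matches_reference_implementation(self, rng):
        """Partition-equivalence with scikit-learn's DBSCAN; differences are
        permitted only for border points reachable from several clusters."""
        for _ in range(25):
            pts = rng.normal(size=(int(rng.integers(20, 150)), 2)) * rng.uniform(0.5, 3)
            dmat = squareform(pdist(pts))
            for eps in (0.4, 0.9, 1.8):
                mine = dbscan_labels(dmat, eps, 5)
                ref = DBSCAN(eps=eps, min_samples=5,
                             metric="precomputed").fit_predict(dmat)
                if (mine == ref).all():
                    continue
                mism = np.flatnonzero(mine != ref)
                core = (dmat <= eps).sum(1) >= 5
                assert not core[mism].any()

    def test_all_noise_when_sparse(self, rng):
        pts = rng.uniform(0, 100, size=(40, 2))
        assert (dbscan_labels(squareform(pdist(pts)), 0.1, 5) == -1).all()


class TestSweep:
    def test_two_separated_blobs_give_two_candidates(self, rng):
        pts = np.vstack([_blob(rng, (10, 10), 60), _blob(rng, (30, 30), 60)])
        cands = sp.dbscan_sweep(pts, epsilons=np.array([1.5]))
        assert len(cands) == 2
        # cross-check against the reference density-based implementation
        ref = DBSCAN(eps=1.5, min_samples=5).fit_predict(pts)
        ref_sets = {frozenset(np.flatnonzero(ref == k).tolist())
                    for k in np.unique(ref) if k >= 0}
        assert {frozenset(c.members.tolist()) for c in cands} == ref_sets

    def test_small_blob_discarded(self, rng):
        pts = _blob(rng, (10, 10), 25)
        assert sp.dbscan_sweep(pts, epsilons=np.array([1.5])) == []

    def test_identical_partition_discarded_at_next_epsilon(self, rng):
        pts = _blob(rng, (10, 10), 60)
        cands = sp.dbscan_sweep(pts, epsilons=np.array([1.0, 1.05]))
        assert all(c.epsilon == 1.0 for c in cands)
        assert len(cands) == 1

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            sp.dbscan_sweep(np.empty((0, 2)))


class TestIsolation:
    def test_intersection_ellipse_widths_floor(self, rng):
        pts = _blob(rng, (5, 5), 200, sd=0.3)
        ell = _intersection_ellipse(pts)
        # semi-axes 3 * max(0.5, sigma) with sigma ~ 0.3 -> floor at 1.5
        assert ell.semi_axes[0] == pytest.approx(1.5, abs=0.15)
        assert ell.semi_axes[1] == pytest.approx(1.5, abs=0.15)

    def test_distant_candidates_both_retained(self, rng):
        pts = np.vstack([_blob(rng, (10, 10), 60, 1.0), _blob(rng, (110, 110), 60, 1.0)])
        cands = sp.dbscan_sweep(pts, epsilons=np.array([2.0]))
        assert len(sp.isolation_test(cands, pts)) == 2

    def test_contained_cluster_excluded(self, rng):
        # a dense blob inside the middle of a wide cloud: both flagged
        wide = _blob(rng, (20, 20), 120, sd=4.0)
        dense = _blob(rng, (20, 20), 60, sd=0.4)
        pts = np.vstack([wide, dense])
        cands = sp.dbscan_sweep(pts, epsilons=np.array([0.5, 3.0]))
        kept = sp.isolation_test(cands, pts)
        eps_with_two = [c for c in cands if len(c.siblings) >= 1]
        if eps_with_two:   # partitions with >= 2 clusters must lose both
            kept_keys = {frozenset(c.members.tolist()) for c in kept}
            for c in eps_with_two:
                assert frozenset(c.members.tolist()) not in kept_keys

    def test_ellipse_intersection_is_symmetric(self):
        a = Ellipse((0, 0), (2, 1))
        b = Ellipse((2.5, 0), (1, 1))
        c = Ellipse((10, 10), (1, 1))
        assert ellipses_intersect(a, b) and ellipses_intersect(b, a)
        assert not ellipses_intersect(a, c)


class TestExpandStage1:
    def test_boundary_membership_arithmetic(self):
        ell = Ellipse(centre=(10, 12), semi_axes=(8, 4))
        assert ell.contains(np.array([[18.0, 12.0]]))[0]
        assert not ell.contains(np.array([[18.01, 12.0]]))[0]

    def test_candidate_members_contained_and_stragglers_absorbed(self, rng):
        core = _blob(rng, (10, 10), 80, sd=1.0)
        stragglers = np.array([[12.5, 10.0], [10.0, 7.5]])   # inside 4 sigma
        far = np.array([[40.0, 40.0]])
        pts = np.vstack([core, stragglers, far])
        cands = sp.dbscan_sweep(pts, epsilons=np.array([1.0]))
        s1 = sp.expand_stage1(cands[0], pts)
        members = set(s1.members.tolist())
        assert set(cands[0].members.tolist()) <= members
        assert {80, 81} <= members
        assert 82 not in members

    def test_zero_variance_rejected(self):
        pts = np.tile([[5.0, 5.0]], (40, 1))
        cand = CandidateCluster(members=np.arange(40), epsilon=1.0)
        with pytest.raises(DegenerateClusterError):
            sp.expand_stage1(cand, pts)


class TestBootstrapEllipse:
    def test_deterministic_given_seed(self, elongated_cloud):
        a = sp.bootstrap_ellipse(elongated_cloud, n_boot=500, seed=3)
        b = sp.bootstrap_ellipse(elongated_cloud, n_boot=500, seed=3)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.cov, b.cov)
        assert np.array_equal(a.thetas, b.thetas)

    def test_collinear_data_has_vanishing_second_eigenvalue(self):
        x = np.linspace(0, 10, 40)
        boot = sp.bootstrap_ellipse(np.column_stack([x, x]), n_boot=300, seed=0)
        eig = np.sort(np.linalg.eigvalsh(boot.cov))
        assert eig[0] == pytest.approx(0.0, abs=1e-9)

    def test_consistency_with_sample_covariance(self, rng):
        pts = rng.normal(size=(500, 2))
        boot = sp.bootstrap_ellipse(pts, n_boot=2000, seed=rng)
        sample = np.cov(pts.T)
        assert np.allclose(boot.cov, sample, rtol=0.1, atol=0.02)


class TestStage2:
    def test_recovers_generative_rotation(self):
        cover = 0
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            phi = np.deg2rad(30.0)
            R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            cov = R @ np.diag([9.0, 1.0]) @ R.T
            pts = rng.multivariate_normal([20.0, 25.0], cov, size=300)
            cands = sp.dbscan_sweep(pts, epsilons=np.array([1.5]))
            s1 = sp.expand_stage1(cands[0], pts)
            s2 = sp.stage2_cluster(s1, pts, n_boot=2000, seed=5)
            cover += s2.angle.ci_low <= 30.0 <= s2.angle.ci_high
        assert cover >= 4   # 95% CI covers the generative rotation

    def test_isolated_cluster_membership_stable(self, correlated_dist):
        ext = sp.extract_clusters(correlated_dist, n_boot=1000, seed=2)
        s2 = ext.stage2
        assert s2 is not None
        # nothing beyond the Stage 1 cluster to absorb: memberships agree
        s1_sets = [set(s.members.tolist()) for s in ext.stage1]
        assert set(s2.members.tolist()) in s1_sets or \
            any(set(s2.members.tolist()) >= s for s in s1_sets)

    def test_semi_axes_are_four_sigma_of_averaged_covariance(self, elongated_cloud):
        boot = sp.bootstrap_ellipse(elongated_cloud, n_boot=1000, seed=9)
        ell = angled_ellipse(boot, k=4.0)
        eig = np.sort(np.linalg.eigvalsh(boot.cov))[::-1]
        assert ell.semi_axes[0] == pytest.approx(4 * np.sqrt(eig[0]))
        assert ell.semi_axes[1] == pytest.approx(4 * np.sqrt(eig[1]))

    def test_members_inside_reported_ellipse(self, correlated_dist):
        ext = sp.extract_clusters(correlated_dist, n_boot=1000, seed=2)
        s2 = ext.stage2
        inside = s2.ellipse.contains(correlated_dist.points[s2.members])
        assert inside.all()


class TestSimilarityFilter:
    def _fake(self, members, eps):
        return ClusterStage2(members=np.asarray(members),
                             ellipse=Ellipse((0, 0), (1, 1)), epsilon=eps)

    def test_fifteen_shared_members_drop_later_cluster(self):
        a = self._fake(range(30), 0.5)
        b = self._fake(range(15, 45), 1.0)   # shares exactly 15
        kept = sp.similarity_filter([a, b])
        assert kept == [a]

    def test_fourteen_shared_members_keep_both(self):
        a = self._fake(range(30), 0.5)
        b = self._fake(range(16, 46), 1.0)   # shares exactly 14
        kept = sp.similarity_filter([a, b])
        assert kept == [a, b]

    def test_single_cluster_retained(self):
        a = self._fake(range(30), 0.5)
        assert sp.similarity_filter([a]) == [a]


class TestGmmVariants:
    def test_bic_selects_one_component_for_single_gaussian(self, rng):
        pts = rng.normal((10, 10), 1.0, size=(200, 2))
        groups = sp.gmm_cluster(pts, "standard", seed=0)
        assert len(groups) == 1

    def test_bic_selects_two_for_separated_blobs(self, rng):
        pts = np.vstack([_blob(rng, (5, 5), 100), _blob(rng, (25, 25), 100)])
        groups = sp.gmm_cluster(pts, "standard", seed=0)
        assert len(groups) == 2

    def test_custom_variant_unique_per_distribution(self, correlated_dist):
        res = sp.gmm_cluster(correlated_dist, "custom", seed=0, n_boot=500)
        assert res.stage2 is None or isinstance(res.stage2, ClusterStage2)
        assert len(sp.similarity_filter(res.stage2_all)) <= max(1, len(res.stage2_all))


class TestPipelineInvariants:
    def test_stage2_count_monotonicity(self, correlated_dist):
        ext = sp.extract_clusters(correlated_dist, n_boot=1000, seed=4)
        assert len(ext.stage1_correlated) <= len(ext.stage1)
        assert len(ext.stage2_all) <= len(ext.stage1_correlated)
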