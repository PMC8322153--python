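"""Two-stage extraction of isolated clusters from pairwise response
distributions.

Stage 1 sweeps DBSCAN over a grid of epsilon values, discards clusterings
identical to the previous epsilon's and clusters below a minimum size,
removes non-isolated clusters (intersection-ellipse test), and expands each
survivor to a flat (axis-aligned) 4-sigma bounding ellipse so that the
subsequent correlation test is unbiased by the density-based selection.

Stage 2 refines each correlated Stage 1 cluster with three successive
bootstrap rounds: resampled means/covariances are averaged into an angled
4-sigma ellipse whose membership is re-selected from the full distribution,
and the round-3 bootstrap principal components double as the cluster's
angle estimate. A similarity filter then drops angled clusters sharing at
least 15 members with one produced at a lower epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.mixture import GaussianMixture

from .core import AngleEstimate, ClusterStage1, ClusterStage2, Ellipse, PairDistribution
from .geometry import angle_from_bootstrap, linear_correlation, _pc1_angles_deg

DEFAULT_EPSILONS = np.round(np.arange(0.4, 5.0 + 1e-9, 0.05), 10)
MIN_CLUSTER_SIZE = 30
SIMILARITY_THRESHOLD = 15


class DegenerateClusterError(ValueError):
    """Raised when a cluster has zero variance on an axis."""


@dataclass
class CandidateCluster:
    """A DBSCAN cluster surviving the size filter, with sweep provenance."""

    members: np.ndarray
    epsilon: float
    siblings: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.members)


def dbscan_labels(dmat: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN cluster labels from a precomputed distance matrix.

    Standard density-based labelling: core points have at least
    ``min_samples`` neighbours within ``eps`` (the point itself included);
    clusters are the connected components of the core-point adjacency, and
    each border point (a non-core point within ``eps`` of a core point)
    joins the cluster of its nearest core point. Identical to the reference
    scikit-learn implementation up to the assignment of border points that
    are reachable from more than one cluster (asserted in the test suite);
    run on the precomputed matrix so the epsilon sweep costs one distance
    computation per distribution.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(dmat)
    within = dmat <= eps
    is_core = within.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    cores = np.flatnonzero(is_core)
    if len(cores) == 0:
        return labels
    sub = within[np.ix_(cores, cores)]
    _, comp = connected_components(csr_matrix(sub), directed=False)
    # component ids are assigned in order of first core occurrence, matching
    # the reference implementation's label numbering
    labels[cores] = comp
    border = np.flatnonzero(~is_core & within[:, cores].any(axis=1))
    if len(border):
        d = np.where(within[np.ix_(border, cores)], dmat[np.ix_(border, cores)],
                     np.inf)
        labels[border] = comp[np.argmin(d, axis=1)]
    return labels


def _partition_key(labels: np.ndarray) -> frozenset:
    """Label-invariant representation of a clustering (noise excluded)."""
    return frozenset(
        frozenset(np.flatnonzero(labels == lab).tolist())
        for lab in np.unique(labels) if lab != -1
    )


def dbscan_sweep(dist: PairDistribution | np.ndarray,
                 epsilons: np.ndarray | None = None,
                 min_cluster_size: int = MIN_CLUSTER_SIZE,
                 min_samples: int = 5) -> list[CandidateCluster]:
    """Sequential DBSCAN over the epsilon grid.

    A clustering identical (as a set partition of the points) to the
    previous epsilon's is discarded, as are clusters with fewer than
    ``min_cluster_size`` members. Each returned candidate records the other
    clusters of its own partition (``siblings``) for the isolation test.
    """
    pts = dist.points if isinstance(dist, PairDistribution) else np.asarray(dist, float)
    if len(pts) == 0:
        raise ValueError("empty distribution")
    if epsilons is None:
        epsilons = DEFAULT_EPSILONS
    dmat = squareform(pdist(pts))
    candidates: list[CandidateCluster] = []
    prev_key = None
    for eps in epsilons:
        labels = dbscan_labels(dmat, float(eps), min_samples)
        key = _partition_key(labels)
        if key == prev_key:
            continue
        prev_key = key
        groups = [np.flatnonzero(labels == lab) for lab in np.unique(labels) if lab != -1]
        for g in groups:
            if len(g) >= min_cluster_size:
                sibs = [h for h in groups if h is not g]
                candidates.append(CandidateCluster(members=g, epsilon=float(eps),
                                                   siblings=sibs))
    return candidates


def _intersection_ellipse(points: np.ndarray) -> Ellipse:
    """Axis-aligned ellipse with semi-axes w_i = 3 * max(0.5, sigma_i)."""
    mean = points.mean(axis=0)
    sds = points.std(axis=0, ddof=1) if len(points) > 1 else np.zeros(2)
    w = 3.0 * np.maximum(0.5, sds)
    return Ellipse(centre=tuple(mean), semi_axes=tuple(w), rotation=0.0)


def ellipses_intersect(a: Ellipse, b: Ellipse, n_boundary: int = 720) -> bool:
    """Conservative intersection/containment test between two ellipses:
    boundary-point sampling plus mutual centre containment."""
    if bool(b.contains(np.array([a.centre]))[0]) or bool(a.contains(np.array([b.centre]))[0]):
        return True
    if a.contains(b.boundary(n_boundary)).any():
        return True
    return bool(b.contains(a.boundary(n_boundary)).any())


def isolation_test(candidates: list[CandidateCluster],
                   dist: PairDistribution | np.ndarray) -> list[CandidateCluster]:
    """Drop candidates whose intersection ellipse touches that of any other
    cluster in the same partition (same epsilon)."""
    pts = dist.points if isinstance(dist, PairDistribution) else np.asarray(dist, float)
    kept = []
    for cand in candidates:
        own = _intersection_ellipse(pts[cand.members])
        isolated = True
        for sib in cand.siblings:
            if len(sib) < 2:
                continue
            if ellipses_intersect(own, _intersection_ellipse(pts[sib])):
                isolated = False
                break
        if isolated:
            kept.append(cand)
    return kept


def expand_stage1(candidate: CandidateCluster,
                  dist: PairDistribution | np.ndarray) -> ClusterStage1:
    """Flat 4-sigma bounding ellipse around the candidate; every
    distribution point inside it becomes a Stage 1 member."""
    pts = dist.points if isinstance(dist, PairDistribution) else np.asarray(dist, float)
    cpts = pts[candidate.members]
    sds = cpts.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise DegenerateClusterError("zero variance on an axis")
    ell = Ellipse(centre=tuple(cpts.mean(axis=0)), semi_axes=tuple(4.0 * sds),
                  rotation=0.0)
    members = np.flatnonzero(ell.contains(pts))
    return ClusterStage1(members=members, ellipse=ell, epsilon=candidate.epsilon,
                         core_members=candidate.members)


# ---------------------------------------------------------------------------
# Stage 2: bootstrap-averaged angled ellipses
# ---------------------------------------------------------------------------

@dataclass
class BootstrapEllipse:
    """Averaged bootstrap mean/covariance plus the per-resample PC1 angles."""

    mean: np.ndarray
    cov: np.ndarray
    thetas: np.ndarray   # degrees in [0, 180), one per resample


def bootstrap_ellipse(points: np.ndarray, n_boot: int = 10_000,
                      seed: int | np.random.Generator = 0) -> BootstrapEllipse:
    """Average of sample means and covariance matrices over with-replacement
    resamples of the points (element-wise averages)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    n = len(pts)
    idx = rng.integers(0, n, size=(n_boot, n))
    x, y = pts[idx, 0], pts[idx, 1]                       # (B, n) each
    mx, my = x.mean(axis=1), y.mean(axis=1)
    sxx = ((x * x).sum(axis=1) - n * mx * mx) / (n - 1)
    syy = ((y * y).sum(axis=1) - n * my * my) / (n - 1)
    sxy = ((x * y).sum(axis=1) - n * mx * my) / (n - 1)
    avg_cov = np.array([[sxx.mean(), sxy.mean()], [sxy.mean(), syy.mean()]])
    if np.linalg.eigvalsh(avg_cov)[1] <= 0:
        raise DegenerateClusterError("degenerate averaged covariance")
    thetas = np.rad2deg(0.5 * np.arctan2(2.0 * sxy, sxx - syy)) % 180.0
    return BootstrapEllipse(mean=np.array([mx.mean(), my.mean()]), cov=avg_cov,
                            thetas=thetas)


def angled_ellipse(boot: BootstrapEllipse, k: float = 4.0) -> Ellipse:
    """Angled ellipse from an averaged covariance: rotation = PC1 angle,
    semi-axes k * sqrt(explained variance per component)."""
    eigvals, eigvecs = np.linalg.eigh(boot.cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.maximum(eigvals, 0.0)
    if eigvals[1] <= 0:
        raise DegenerateClusterError("rank-deficient covariance")
    v = eigvecs[:, 0]
    rot = float(np.rad2deg(np.arctan2(v[1], v[0])) % 180.0)
    return Ellipse(centre=tuple(boot.mean),
                   semi_axes=(k * float(np.sqrt(eigvals[0])),
                              k * float(np.sqrt(eigvals[1]))),
                   rotation=rot)


def stage2_cluster(stage1: ClusterStage1, dist: PairDistribution | np.ndarray,
                   n_boot: int = 10_000,
                   seed: int | np.random.Generator = 0) -> ClusterStage2:
    """Three successive bootstrap rounds refining a Stage 1 cluster.

    Each round averages resampled means/covariances into an angled 4-sigma
    ellipse and re-selects members from the full distribution inside it; the
    round-3 resampled PC1 angles provide the cluster's angle estimate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = dist.points if isinstance(dist, PairDistribution) else np.asarray(dist, float)
    members = stage1.members
    boot = None
    for _ in range(3):
        if len(members) < 3:
            raise DegenerateClusterError("intermediate membership below 3")
        boot = bootstrap_ellipse(pts[members], n_boot=n_boot, seed=rng)
        ell = angled_ellipse(boot)
        members = np.flatnonzero(ell.contains(pts))
    if len(members) < 3:
        raise DegenerateClusterError("final membership below 3")
    angle = angle_from_bootstrap(boot.thetas)
    dist_id = dist.dist_id if isinstance(dist, PairDistribution) else ""
    return ClusterStage2(members=members, ellipse=angled_ellipse(boot),
                         epsilon=stage1.epsilon, dist_id=dist_id, angle=angle)


def similarity_filter(clusters: list[ClusterStage2],
                      threshold: int = SIMILARITY_THRESHOLD) -> list[ClusterStage2]:
    """Drop angled clusters sharing >= ``threshold`` members with any angled
    cluster produced at a lower epsilon for the same distribution."""
    ordered = sorted(clusters, key=lambda c: c.epsilon)
    kept: list[ClusterStage2] = []
    seen: list[set] = []
    for c in ordered:
        mem = set(c.members.tolist())
        if not any(len(mem & s) >= threshold for s in seen):
            kept.append(c)
        seen.append(mem)
    return kept


# ---------------------------------------------------------------------------
# end-to-end extraction and GMM comparison variants
# ---------------------------------------------------------------------------

@dataclass
class ExtractionResult:
    """Everything the two-stage algorithm produced for one distribution."""

    stage1: list[ClusterStage1]
    stage1_correlated: list[ClusterStage1]
    stage2_all: list[ClusterStage2]
    stage2: ClusterStage2 | None    # unique surviving cluster, if any


def extract_clusters(dist: PairDistribution | np.ndarray,
                     epsilons: np.ndarray | None = None,
                     min_cluster_size: int = MIN_CLUSTER_SIZE,
                     min_samples: int = 5,
                     n_boot: int = 10_000,
                     p_threshold: float = 0.005,
                     seed: int | np.random.Generator = 0) -> ExtractionResult:
    """Run the full two-stage pipeline on one pair distribution.

    Stage 2 is computed only for Stage 1 clusters correlated at
    ``p < p_threshold``; after the similarity filter, the lowest-epsilon
    survivor is the distribution's unique Stage 2 cluster.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = dist.points if isinstance(dist, PairDistribution) else np.asarray(dist, float)
    candidates = dbscan_sweep(dist, epsilons=epsilons,
                              min_cluster_size=min_cluster_size,
                              min_samples=min_samples)
    candidates = isolation_test(candidates, dist)
    stage1: list[ClusterStage1] = []
    for cand in candidates:
        try:
            stage1.append(expand_stage1(cand, dist))
        except DegenerateClusterError:
            continue
    correlated = []
    for s1 in stage1:
        if s1.n < 3:
            continue
        try:
            res = linear_correlation(pts[s1.members])
        except ValueError:
            continue
        if res.p < p_threshold:
            correlated.append(s1)
    stage2_all = []
    cache: dict[frozenset, ClusterStage2 | None] = {}
    for s1 in correlated:
        key = frozenset(s1.members.tolist())
        if key in cache:   # identical Stage 1 member sets refine identically
            prev = cache[key]
            if prev is not None:
                stage2_all.append(ClusterStage2(members=prev.members,
                                                ellipse=prev.ellipse,
                                                epsilon=s1.epsilon,
                                                dist_id=prev.dist_id,
                                                angle=prev.angle))
            continue
        try:
            s2 = stage2_cluster(s1, dist, n_boot=n_boot, seed=rng)
        except DegenerateClusterError:
            cache[key] = None
            continue
        cache[key] = s2
        stage2_all.append(s2)
    survivors = similarity_filter(stage2_all)
    unique = min(survivors, key=lambda c: c.epsilon) if survivors else None
    return ExtractionResult(stage1=stage1, stage1_correlated=correlated,
                            stage2_all=stage2_all, stage2=unique)


def gmm_cluster(dist: PairDistribution | np.ndarray, variant: str = "standard",
                seed: int | np.random.Generator = 0,
                max_components: int = 10,
                n_boot: int = 10_000) -> list[np.ndarray] | ExtractionResult:
    """Gaussian-mixture comparison clusterings.

    ``standard``: BIC selects the component count (1..10); each component's
    members form a cluster. ``custom``: the isolation test, Stage 1
    expansion and Stage 2 bootstrap steps are additionally applied to the
    mixture components, with the same per-distribution uniqueness rule.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = dist.points if isinstance(dist, PairDistribution) else np.asarray(dist, float)
    best_labels, best_bic = None, np.inf
    rs = int(rng.integers(0, 2**31 - 1))
    for k in range(1, min(max_components, len(pts) // 2) + 1):
        try:
            gm = GaussianMixture(n_components=k, random_state=rs, n_init=1).fit(pts)
        except ValueError:
            continue
        bic = gm.bic(pts)
        if bic < best_bic:
            best_bic, best_labels = bic, gm.predict(pts)
    if best_labels is None:
        raise RuntimeError("GMM fit failed at all component counts")
    groups = [np.flatnonzero(best_labels == lab) for lab in np.unique(best_labels)]
    if variant == "standard":
        return groups
    if variant != "custom":
        raise ValueError("variant must be 'standard' or 'custom'")
    candidates = [CandidateCluster(members=g, epsilon=0.0,
                                   siblings=[h for h in groups if h is not g])
                  for g in groups if len(g) >= 3]
    candidates = isolation_test(candidates, pts)
    stage1 = []
    for cand in candidates:
        try:
            stage1.append(expand_stage1(cand, pts))
        except DegenerateClusterError:
            continue
    correlated = []
    for s1 in stage1:
        try:
            if linear_correlation(pts[s1.members]).p < 0.005:
                correlated.append(s1)
        except ValueError:
            continue
    stage2_all = []
    for s1 in correlated:
        try:
            stage2_all.append(stage2_cluster(s1, pts, n_boot=n_boot, seed=rng))
        except DegenerateClusterError:
            continue
    survivors = similarity_filter(stage2_all)
    unique = survivors[0] if survivors else None
    return ExtractionResult(stage1=stage1, stage1_correlated=correlated,
                            stage2_all=stage2_all, stage2=unique)
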