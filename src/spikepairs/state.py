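"""Single-factor state model, relative-difference regimes and cross-cluster
state structure.

Each stationary (or made-stationary) cluster is modelled as
``s_i = lambda_i * eta + sigma_i`` for the two neurons ``i in {0, 1}``: a
shared per-trial excitability ``eta`` moves both latencies with
neuron-specific gains, leaving independent Gaussian residuals. The
state-conditioned spread of the spike-time difference,
``sigma_diff = sqrt(sigma_0^2 + sigma_1^2)``, quantifies the potential
encoding capacity of relative differences under state-dependent decoding
(RDR 3), compared with the within-cluster spread (RDR 2) and the
whole-distribution spread (RDR 1).

With only two observed variables the factor decomposition is identified
only up to a one-parameter ridge; the canonical maximum-likelihood
solution used here takes standardized loadings sqrt(r) for both neurons,
which is exact whenever the residual sds are proportional to the gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (AngleEstimate, CorrelationResult, FactorModel,
                   PairDistribution, RDRSummary, StatePrediction)
from .geometry import angle_from_bootstrap


class HeywoodError(ValueError):
    """Raised when the factor solution implies non-positive residual variance."""


def fit_single_factor(points: np.ndarray, trials: np.ndarray | None = None) -> FactorModel:
    """Maximum-likelihood single-factor fit of a zero-centred 2-D cluster.

    Loadings are ``lambda_i = sd_i * sqrt(r)`` and residual sds
    ``sigma_i = sd_i * sqrt(1 - r)`` (the canonical two-variable solution);
    per-trial factor scores use the regression method,
    ``eta = sqrt(r) * (z0 + z1) / (1 + r)`` on standardized data.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 cluster trials")
    mean = pts.mean(axis=0)
    sds = pts.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError("degenerate cluster")
    r = float(np.corrcoef(pts.T)[0, 1])
    if r <= 0:
        raise HeywoodError("non-positive correlation: single-factor model rejected")
    if r >= 1:
        raise HeywoodError("perfect correlation: zero residual variance")
    lam = sds * np.sqrt(r)
    sig = sds * np.sqrt(1.0 - r)
    z = (pts - mean) / sds
    eta = np.sqrt(r) * (z[:, 0] + z[:, 1]) / (1.0 + r)
    return FactorModel(lambda0=float(lam[0]), lambda1=float(lam[1]),
                       sigma0=float(sig[0]), sigma1=float(sig[1]),
                       eta=eta, mean=(float(mean[0]), float(mean[1])))


def factor_angle(points: np.ndarray, n_boot: int = 10_000,
                 seed: int | np.random.Generator = 0) -> AngleEstimate:
    """Angle of the factor loading direction, bootstrapped over cluster
    resamples with the same doubled-angle convention as the PCA angle.

    The loading direction of the closed-form fit is (sd0, sd1) (both
    non-negative), so its angle is arctan(sd1 / sd0) mapped to [0, 180).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = pts[idx]
    sds = samples.std(axis=1, ddof=1)
    if np.any(sds <= 0):
        sds = np.maximum(sds, 1e-12)
    thetas = np.rad2deg(np.arctan2(sds[:, 1], sds[:, 0])) % 180.0
    est = angle_from_bootstrap(thetas)
    return est


def loading_angle(model: FactorModel) -> float:
    """Point estimate of the loading angle (degrees in [0, 180))."""
    if model.lambda0 == 0 and model.lambda1 == 0:
        raise ValueError("both loadings are zero")
    return float(np.rad2deg(np.arctan2(model.lambda1, model.lambda0)) % 180.0)


def rdr_summary(dist: PairDistribution, cluster_points: np.ndarray,
                model: FactorModel) -> RDRSummary:
    """The three relative-difference spreads.

    RDR 1: sd of (s1 - s0) over all conjunctive pairs of the distribution.
    RDR 2: sd of (s1 - s0) within the (detrended) cluster samples.
    RDR 3: state-conditioned spread sqrt(sigma0^2 + sigma1^2) from the
    factor model fitted to the same samples.
    """
    cpts = np.asarray(cluster_points, dtype=float)
    if len(cpts) < 3:
        raise ValueError("cluster below minimum size")
    rdr1 = float(np.std(dist.y - dist.x, ddof=1))
    rdr2 = float(np.std(cpts[:, 1] - cpts[:, 0], ddof=1))
    return RDRSummary(rdr1_sigma_diff=rdr1, rdr2_sigma_diff=rdr2,
                      rdr3_sigma_diff=model.sigma_diff)


def predict_state(points: np.ndarray, trials: np.ndarray,
                  cluster_id: str = "", neuron_ids: tuple[str, str] = ("", "")
                  ) -> StatePrediction:
    """Per-trial state prediction: signed projection of each zero-centred
    pair onto PC1, with PC1 oriented so both component loadings are
    non-negative (higher excitability moves both latencies the same way)."""
    pts = np.asarray(points, dtype=float)
    t = np.asarray(trials, dtype=int)
    cov = np.cov(pts.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 0:
        raise ValueError("degenerate covariance")
    v = eigvecs[:, -1]
    if v.sum() < 0:   # both loadings non-negative for correlated clouds
        v = -v
    proj = (pts - pts.mean(axis=0)) @ v
    return StatePrediction(cluster_id=cluster_id, trials=t, state=proj,
                           neuron_ids=neuron_ids)


def state_correlation(pred_a: StatePrediction, pred_b: StatePrediction,
                      min_conjunctive: int = 15) -> CorrelationResult:
    """Pearson correlation of two clusters' predicted states over common
    trials. The clusters must share no neuron (4 distinct neurons) and at
    least ``min_conjunctive`` common trials; otherwise the pair is excluded.
    """
    ids_a = set(filter(None, pred_a.neuron_ids))
    ids_b = set(filter(None, pred_b.neuron_ids))
    if ids_a & ids_b:
        raise ValueError("clusters share a neuron")
    common, ia, ib = np.intersect1d(pred_a.trials, pred_b.trials,
                                    return_indices=True)
    if len(common) < min_conjunctive:
        raise ValueError(f"only {len(common)} common trials "
                         f"(inclusion threshold {min_conjunctive})")
    r, p = stats.pearsonr(pred_a.state[ia], pred_b.state[ib])
    return CorrelationResult(r=float(r), p=float(p), n=len(common))


def four_neuron_pca(points_a: np.ndarray, trials_a: np.ndarray,
                    points_b: np.ndarray, trials_b: np.ndarray) -> np.ndarray:
    """Variance-explained fractions of the PCA of the joint 4-neuron latency
    matrix on trials where all four neurons spiked. Fractions sum to 1."""
    common, ia, ib = np.intersect1d(np.asarray(trials_a, int),
                                    np.asarray(trials_b, int),
                                    return_indices=True)
    if len(common) < 5:
        raise ValueError("fewer than 5 common trials")
    mat = np.hstack([np.asarray(points_a, float)[ia],
                     np.asarray(points_b, float)[ib]])
    cov = np.cov(mat.T)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.maximum(eigvals, 0.0)
    return eigvals / eigvals.sum()


def state_conditioned_variability(target: np.ndarray, target_trials: np.ndarray,
                                  predictor: StatePrediction
                                  ) -> tuple[float, float]:
    """Spread of a target series before and after conditioning on another
    pair's predicted state.

    The conditioned sd is the residual sd of the least-squares regression of
    the target on the predictor state over common trials.
    """
    common, it, ip = np.intersect1d(np.asarray(target_trials, int),
                                    predictor.trials, return_indices=True)
    if len(common) < 10:
        raise ValueError("fewer than 10 common trials")
    y = np.asarray(target, float)[it]
    x = predictor.state[ip]
    uncond = float(np.std(y, ddof=1))
    if np.ptp(x) == 0:
        return uncond, uncond
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return uncond, float(np.std(resid, ddof=1))


@dataclass
class PooledExample:
    """One entry of the pooled stationary/made-stationary example set."""

    dist_id: str
    kind: str                 # "cluster" or "unclustered"
    points: np.ndarray
    trials: np.ndarray
    neuron_ids: tuple[str, str]


def pool_examples(clusters: list[PooledExample],
                  unclustered: list[PooledExample]) -> list[PooledExample]:
    """Pool Stage 2 clusters with correlated unclustered distributions,
    keeping exactly one entry per response distribution (cluster preferred).
    """
    by_dist: dict[str, PooledExample] = {}
    for ex in unclustered:
        by_dist[ex.dist_id] = ex
    for ex in clusters:
        by_dist[ex.dist_id] = ex   # cluster overrides unclustered
    return list(by_dist.values())
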