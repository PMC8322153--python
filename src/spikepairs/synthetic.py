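"""Synthetic first-spike sessions and surrogate control datasets.

The generator emulates the statistical structure the downstream analysis
assumes: on each trial a session-wide latent excitability ``eta ~ N(0, 1)``
shifts both neurons' first-spike latencies with neuron-specific gains
(``s_i = mean_i + lambda_i * eta + noise``), spiking is unreliable (0/1
spikes per trial), rapid stimulation adds a depressive latency drift and
count depression concentrated in the early trials, and a pair's response
distribution can mix several clusters.

Four surrogate constructions reproduce the control datasets used to
calibrate the cluster/angle statistics: margin shuffling (derangement),
an independent bivariate Gaussian match, a 45-degree cluster replacement,
and a two-cluster "distractor" layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NeuronMeta, PairDistribution, ClusterStage2

#: stimulation frequencies used in the recordings (Hz)
FREQUENCIES_HZ = (0.066, 0.1, 0.2, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)

RECORD_COLUMNS = [
    "session", "whisker", "frequency_hz", "trial", "neuron_id",
    "layer", "ei_type", "column", "septum", "first_spike_ms",
]


@dataclass
class ClusterSpec:
    """One mixture component of a pair's response distribution."""

    prob: float                      # membership probability
    means: tuple[float, float]       # mean latencies (ms)
    loadings: tuple[float, float]    # lambda_i, ms per unit of state
    sigmas: tuple[float, float]      # residual sds (ms)

    def __post_init__(self) -> None:
        if not 0 < self.prob <= 1:
            raise ValueError("membership probability must be in (0, 1]")
        if min(self.sigmas) <= 0:
            raise ValueError("residual sds must be positive")


@dataclass
class PairSpec:
    """Cluster mixture for one neuron pair (x-axis neuron listed first)."""

    neuron_x: str
    neuron_y: str
    clusters: list[ClusterSpec]

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("cluster_specs must not be empty")
        total = sum(c.prob for c in self.clusters)
        if total > 1 + 1e-9:
            raise ValueError("cluster membership probabilities must sum to <= 1")


@dataclass
class AdaptationSpec:
    """Depressive adaptation: saturating-exponential latency drift and count
    depression over early trials, active at high stimulation frequencies.

    About 90% of the drift happens within ``trials_to_saturation`` trials.
    """

    latency_amplitude_ms: float = 0.0
    count_depression: float = 0.0        # fractional drop in spike probability
    trials_to_saturation: int = 20
    frequency_threshold_hz: float = 1.0

    def drift(self, trials: np.ndarray, frequency_hz: float) -> np.ndarray:
        if self.latency_amplitude_ms == 0 or frequency_hz < self.frequency_threshold_hz:
            return np.zeros_like(np.asarray(trials, dtype=float))
        tau = self.trials_to_saturation / math.log(10.0)  # 90% inside saturation window
        return self.latency_amplitude_ms * (1.0 - np.exp(-np.asarray(trials, float) / tau))

    def depression(self, trials: np.ndarray, frequency_hz: float) -> np.ndarray:
        if self.count_depression == 0 or frequency_hz < self.frequency_threshold_hz:
            return np.zeros_like(np.asarray(trials, dtype=float))
        tau = self.trials_to_saturation / math.log(10.0)
        return self.count_depression * (1.0 - np.exp(-np.asarray(trials, float) / tau))


@dataclass
class SyntheticConfig:
    """Full description of one synthetic session."""

    neurons: list[NeuronMeta]
    pairs: list[PairSpec]
    seed: int
    n_trials: int = 200
    frequencies: tuple[float, ...] = (1.0,)
    adaptation: AdaptationSpec = field(default_factory=AdaptationSpec)
    reliability: dict[str, float] = field(default_factory=dict)
    session: str = "synthetic"
    whisker: str = "C2"

    def __post_init__(self) -> None:
        ids = {m.neuron_id for m in self.neurons}
        seen: set[str] = set()
        for p in self.pairs:
            for nid in (p.neuron_x, p.neuron_y):
                if nid not in ids:
                    raise ValueError(f"pair references unknown neuron {nid!r}")
                if nid in seen:
                    raise ValueError(f"neuron {nid!r} appears in more than one pair")
                seen.add(nid)
        for nid, r in self.reliability.items():
            if not 0 < r <= 1:
                raise ValueError(f"reliability for {nid!r} must be in (0, 1]")
        for f in self.frequencies:
            if not 0.05 <= f <= 10.0:
                raise ValueError("frequencies must lie in the 0.066-10 Hz range")

    def meta(self, neuron_id: str) -> NeuronMeta:
        for m in self.neurons:
            if m.neuron_id == neuron_id:
                return m
        raise KeyError(neuron_id)


def _draw_latency(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = 0.0, hi: float = 50.0,
                  max_redraws: int = 10) -> float:
    """One latency, re-drawn up to ``max_redraws`` times to fit [lo, hi)."""
    for _ in range(max_redraws + 1):
        v = rng.normal(mean, sd)
        if lo <= v < hi:
            return v
    return math.nan


def generate_session(config: SyntheticConfig) -> pd.DataFrame:
    """Generate one session of first-spike records.

    Per trial a shared state ``eta ~ N(0,1)`` is drawn once and applied to all
    configured pairs; each pair then draws a cluster membership, latencies
    ``mean + lambda*eta + drift(trial, f) + N(0, sigma)``, and each neuron's
    spike is dropped independently with probability ``1 - reliability``.
    Latencies outside [0, 50) ms are re-drawn up to 10 times, then dropped.
    Deterministic given ``config.seed``.

    Returns a tidy record table (one row per emitted spike).
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    for freq in config.frequencies:
        eta = rng.standard_normal(config.n_trials)
        for pair in config.pairs:
            probs = np.array([c.prob for c in pair.clusters])
            edges = np.cumsum(probs)
            u = rng.random(config.n_trials)
            membership = np.searchsorted(edges, u)  # == len(clusters) -> noise trial
            drift = config.adaptation.drift(np.arange(config.n_trials), freq)
            depress = config.adaptation.depression(np.arange(config.n_trials), freq)
            for t in range(config.n_trials):
                k = membership[t]
                if k >= len(pair.clusters):
                    continue
                spec = pair.clusters[k]
                for i, nid in enumerate((pair.neuron_x, pair.neuron_y)):
                    rel = config.reliability.get(nid, 1.0) * (1.0 - depress[t])
                    if rng.random() >= rel:
                        continue
                    mean = spec.means[i] + spec.loadings[i] * eta[t] + drift[t]
                    v = _draw_latency(rng, mean, spec.sigmas[i])
                    if math.isnan(v):
                        continue
                    m = config.meta(nid)
                    rows.append((config.session, config.whisker, freq, t, nid,
                                 m.layer, m.ei_type, m.column, m.septum, v))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# surrogate control datasets
# ---------------------------------------------------------------------------

def _derangement(n: int, rng: np.random.Generator, max_tries: int = 10_000) -> np.ndarray:
    """Random permutation of range(n) with no fixed point."""
    if n < 2:
        raise ValueError("derangement requires at least 2 elements")
    if n == 2:
        return np.array([1, 0])
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm
    raise RuntimeError("failed to draw a derangement")  # pragma: no cover


def shuffle_pairs(dist: PairDistribution, seed: int | np.random.Generator) -> PairDistribution:
    """Margin-shuffled surrogate: each x latency is re-matched with a
    *different* trial's y latency (a derangement), so both marginal latency
    multisets are preserved exactly while the pairing is destroyed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if dist.n < 2:
        raise ValueError("shuffle surrogate needs at least 2 conjunctive trials")
    perm = _derangement(dist.n, rng)
    pts = np.column_stack([dist.x, dist.y[perm]])
    return dist.replace_points(pts, dist_id=dist.dist_id + ":shuffled")


def gaussian_surrogate(dist: PairDistribution, seed: int | np.random.Generator) -> PairDistribution:
    """Independent bivariate-normal surrogate matching each margin's mean and
    sd; sample count equals the source count, off-diagonal covariance is zero
    by construction.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if dist.n < 2:
        raise ValueError("gaussian surrogate needs at least 2 source points")
    x = rng.normal(dist.x.mean(), dist.x.std(ddof=1), dist.n)
    y = rng.normal(dist.y.mean(), dist.y.std(ddof=1), dist.n)
    return dist.replace_points(np.column_stack([x, y]),
                               dist_id=dist.dist_id + ":gaussian")


def _gaussian_45(rng: np.random.Generator, mean: tuple[float, float],
                 sd: float, rho: float, n: int) -> np.ndarray:
    """Sample a bivariate Gaussian whose PC1 lies at exactly 45 degrees
    (equal axis variances, positive correlation)."""
    cov = np.array([[sd * sd, rho * sd * sd], [rho * sd * sd, sd * sd]])
    return rng.multivariate_normal(np.asarray(mean, float), cov, size=n)


def _cluster_rho(dist: PairDistribution, cluster: ClusterStage2) -> float:
    pts = dist.points[cluster.members]
    r = float(np.corrcoef(pts[:, 0], pts[:, 1])[0, 1])
    return float(np.clip(abs(r), 0.2, 0.95))


def forty_five_control(cluster: ClusterStage2, dist: PairDistribution,
                       seed: int | np.random.Generator) -> PairDistribution:
    """45-degree replacement surrogate.

    All samples within a 6*sigma-bar circle of the cluster mean (sigma-bar =
    mean of the two neurons' cluster sds) are replaced by an equal number of
    samples from a bivariate Gaussian whose first principal component lies at
    exactly 45 degrees.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if cluster.n == 0:
        raise ValueError("empty cluster")
    pts = dist.points
    cpts = pts[cluster.members]
    mean = cpts.mean(axis=0)
    sds = cpts.std(axis=0, ddof=1)
    radius = 6.0 * float(sds.mean())
    inside = np.hypot(pts[:, 0] - mean[0], pts[:, 1] - mean[1]) <= radius
    n_new = int(inside.sum())
    repl = _gaussian_45(rng, tuple(mean), float(sds.mean()),
                        _cluster_rho(dist, cluster), n_new)
    out = np.vstack([pts[~inside], repl])
    return dist.replace_points(out, dist_id=dist.dist_id + ":ctrl45")


def distractor_control(cluster: ClusterStage2, dist: PairDistribution,
                       seed: int | np.random.Generator) -> PairDistribution:
    """Two-cluster distractor surrogate.

    Emits (i) a 45-degree Gaussian at the original cluster mean, with both
    axis sds equal to the mean of the original cluster sds, and (ii) an
    uncorrelated Gaussian with the original sds, offset to the right along a
    15-degree ray: its mean x is the cluster mean x plus 10 sds of the x-axis
    neuron's cluster spike times. Each cloud has the original cluster's size.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cpts = dist.points[cluster.members]
    if len(cpts) == 0:
        raise ValueError("empty cluster")
    mean = cpts.mean(axis=0)
    sds = cpts.std(axis=0, ddof=1)
    if sds[0] <= 0:
        raise ValueError("zero x-variance cluster")
    n = len(cpts)
    first = _gaussian_45(rng, tuple(mean), float(sds.mean()),
                         _cluster_rho(dist, cluster), n)
    dx = 10.0 * sds[0]
    second_mean = (mean[0] + dx, mean[1] + dx * math.tan(math.radians(15.0)))
    second = np.column_stack([
        rng.normal(second_mean[0], sds[0], n),
        rng.normal(second_mean[1], sds[1], n),
    ])
    return dist.replace_points(np.vstack([first, second]),
                               dist_id=dist.dist_id + ":distractor")


# ---------------------------------------------------------------------------
# convenience constructors used throughout tests/examples
# ---------------------------------------------------------------------------

def default_pair_config(seed: int, *, n_trials: int = 200,
                        loadings: tuple[float, float] = (2.0, 1.0),
                        sigmas: tuple[float, float] = (0.5, 0.5),
                        means: tuple[float, float] = (15.0, 22.0),
                        prob: float = 1.0,
                        reliability: float = 1.0,
                        frequency: float = 1.0,
                        adaptation: AdaptationSpec | None = None) -> SyntheticConfig:
    """A single-pair, single-cluster session config with sensible defaults."""
    neurons = [NeuronMeta("n0", "E", "L4"), NeuronMeta("n1", "I", "L5A")]
    pair = PairSpec("n0", "n1", [ClusterSpec(prob, means, loadings, sigmas)])
    return SyntheticConfig(
        neurons=neurons, pairs=[pair], seed=seed, n_trials=n_trials,
        frequencies=(frequency,),
        adaptation=adaptation or AdaptationSpec(),
        reliability={"n0": reliability, "n1": reliability},
    )


def sample_pair_distribution(seed: int, **kwargs) -> PairDistribution:
    """Generate a session from :func:`default_pair_config` and return its
    single pair distribution (conjunctive trials only)."""
    from .pipeline import build_distributions
    cfg = default_pair_config(seed, **kwargs)
    records = generate_session(cfg)
    dists = build_distributions(records)
    if not dists:
        raise RuntimeError("generated session produced no conjunctive trials")
    return dists[0]
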