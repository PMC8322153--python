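"""Core containers shared across the analysis pipeline.

The atomic object of the whole analysis is the :class:`PairDistribution`:
the first-spike latencies of two neurons, collected over the trials of one
stimulus condition on which *both* neurons spiked ("conjunctive" trials).
Everything downstream — cluster extraction, correlation-angle estimation,
adaptation control and the latent-state model — consumes these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EI_TYPES = ("E", "I")
LAYERS = ("L2/3", "L4", "L5A", "L5B/6")

#: analysis window (ms after cortical activation onset)
WINDOW_MS = (0.0, 50.0)

#: offset from stimulus onset to cortical activation onset (ms); applied at
#: load time when input latencies are stimulus-referenced
ONSET_SHIFT_MS = 5.4


@dataclass(frozen=True)
class NeuronMeta:
    """Identity and anatomical metadata of one sorted unit."""

    neuron_id: str
    ei_type: str = "E"
    layer: str = "L4"
    column: str = "C2"
    septum: bool = False

    def __post_init__(self) -> None:
        if self.ei_type not in EI_TYPES:
            raise ValueError(f"ei_type must be one of {EI_TYPES}, got {self.ei_type!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")


@dataclass
class PairDistribution:
    """Conjunctive-trial first-spike pairs of one neuron pair / condition.

    ``x`` holds the latencies of the lower-id neuron (plotted on the x axis),
    ``y`` the other neuron's; ``trials`` are the 0-based trial indices of the
    condition block, strictly increasing.
    """

    dist_id: str
    neuron_x: str
    neuron_y: str
    whisker: str
    frequency_hz: float
    trials: np.ndarray
    x: np.ndarray
    y: np.ndarray
    meta_x: NeuronMeta | None = None
    meta_y: NeuronMeta | None = None

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.trials) == len(self.x) == len(self.y)):
            raise ValueError("trials, x and y must have equal length")
        if len(self.trials) > 1 and np.any(np.diff(self.trials) <= 0):
            raise ValueError("trial indices must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.trials)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of conjunctive first-spike pairs in ms."""
        return np.column_stack([self.x, self.y])

    def replace_points(self, points: np.ndarray, dist_id: str | None = None,
                       trials: np.ndarray | None = None) -> "PairDistribution":
        """Copy of this distribution with new latency pairs (surrogates)."""
        points = np.asarray(points, dtype=float)
        if trials is None:
            trials = (self.trials if len(points) == self.n
                      else np.arange(len(points)))
        return PairDistribution(
            dist_id=dist_id or self.dist_id,
            neuron_x=self.neuron_x, neuron_y=self.neuron_y,
            whisker=self.whisker, frequency_hz=self.frequency_hz,
            trials=np.asarray(trials), x=points[:, 0], y=points[:, 1],
            meta_x=self.meta_x, meta_y=self.meta_y,
        )


@dataclass
class Ellipse:
    """Bounding ellipse: centre, semi-axes and counter-clockwise rotation.

    ``rotation`` is in degrees from the +x axis, normalised to [0, 180).
    A rotation of 0 gives an axis-aligned ("flat") ellipse.
    """

    centre: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        self.rotation = float(self.rotation) % 180.0

    def contains(self, points: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        """Boolean mask of points inside or on the ellipse boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - np.asarray(self.centre)
        phi = np.deg2rad(self.rotation)
        c, s = np.cos(phi), np.sin(phi)
        u = d[:, 0] * c + d[:, 1] * s
        v = -d[:, 0] * s + d[:, 1] * c
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0 + atol

    def boundary(self, n: int = 720) -> np.ndarray:
        """n evenly spaced boundary points (used for the intersection test)."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        phi = np.deg2rad(self.rotation)
        c, s = np.cos(phi), np.sin(phi)
        u, v = a * np.cos(t), b * np.sin(t)
        return np.column_stack([
            self.centre[0] + u * c - v * s,
            self.centre[1] + u * s + v * c,
        ])


@dataclass
class CorrelationResult:
    """Least-squares linear association between two series."""

    r: float
    p: float
    n: int
    slope: float = float("nan")

    @property
    def r2(self) -> float:
        return self.r * self.r


@dataclass
class AngleEstimate:
    """Bootstrap estimate of a point cloud's first-principal-component angle.

    ``theta`` is the angle (degrees in [0, 180)) the PC1 axis makes with +x;
    ``theta45 = min(theta, 90 - theta)`` folds out the arbitrary ordering of
    the two neurons. The CI is the empirical 95% interval over resamples.
    """

    theta: float
    ci_low: float
    ci_high: float
    n_boot: int
    boot_thetas: np.ndarray | None = field(default=None, repr=False)

    @property
    def theta45(self) -> float:
        return min(self.theta, 90.0 - self.theta)


@dataclass
class ClusterStage1:
    """Flat-ellipse (Stage 1) cluster of a pair distribution."""

    members: np.ndarray          # indices into the PairDistribution
    ellipse: Ellipse             # rotation 0
    epsilon: float               # DBSCAN epsilon that produced the seed
    core_members: np.ndarray     # DBSCAN members before 4-sigma expansion

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class ClusterStage2:
    """Bootstrap-refined angled-ellipse (Stage 2) cluster."""

    members: np.ndarray
    ellipse: Ellipse
    epsilon: float
    dist_id: str = ""
    angle: AngleEstimate | None = None

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class ProcessedSeries:
    """A neuron's cluster-trial latency series after adaptation control."""

    neuron_id: str
    trials: np.ndarray
    raw: np.ndarray
    values: np.ndarray
    differenced: bool = False
    rescale: float = 1.0          # 1 or 1/sqrt(2)
    ar_order: int = 0
    ma_order: int = 0

    def __post_init__(self) -> None:
        if self.differenced and len(self.values) != len(self.raw) - 1:
            raise ValueError("differenced series must be one shorter than raw")


@dataclass
class FactorModel:
    """Single-factor model  s_i = lambda_i * eta + sigma_i  of a 2-D cluster.

    ``eta`` is the per-trial shared excitability (state) score; ``sigma_diff``
    is the model-predicted spread of the spike-time difference at fixed state.
    """

    lambda0: float
    lambda1: float
    sigma0: float
    sigma1: float
    eta: np.ndarray
    mean: tuple[float, float] = (0.0, 0.0)

    @property
    def sigma_diff(self) -> float:
        return float(np.hypot(self.sigma0, self.sigma1))


@dataclass
class RDRSummary:
    """Relative-difference spreads under the three coding regimes."""

    rdr1_sigma_diff: float   # sd of s1-s0 over the whole distribution
    rdr2_sigma_diff: float   # sd of s1-s0 within the (detrended) cluster
    rdr3_sigma_diff: float   # state-conditioned spread from the factor model


@dataclass
class StatePrediction:
    """Per-trial latent-state prediction from one cluster's PC1 projection."""

    cluster_id: str
    trials: np.ndarray
    state: np.ndarray
    neuron_ids: tuple[str, str] = ("", "")
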