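"""Stationarity criteria, differencing and automated Box-Jenkins ARIMA
detrending of cluster spike-time series.

Depressive adaptation makes latencies drift over rapidly repeated trials;
a cluster's correlation can only be attributed to non-adaptative shared
excitability once that drift is ruled out or removed. A battery of
criteria decides stationarity; non-stationary single-neuron series are
first-differenced (and divided by sqrt(2) to restore the original scale),
and AR/MA components of automatically selected order remove the
autocorrelation present in, or introduced into, the differenced series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import kpss as sm_kpss, pacf as sm_pacf

from .core import ProcessedSeries
from .geometry import linear_correlation, trial_regressions

log = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def autocorrelation(series: np.ndarray, lag: int = 1) -> tuple[float, float]:
    """Lag-k autocorrelation with the standard large-sample normal
    approximation p-value (the +/- 1.96/sqrt(n) band)."""
    s = np.asarray(series, dtype=float)
    n = len(s)
    if n < lag + 2:
        raise ValueError("series too short")
    d = s - s.mean()
    denom = float((d ** 2).sum())
    if denom == 0:
        raise ValueError("constant series")
    r = float((d[:-lag] * d[lag:]).sum() / denom)
    p = 2.0 * float(stats.norm.sf(abs(r) * np.sqrt(n)))
    return r, p


def kpss_pvalue(series: np.ndarray, regression: str = "c") -> float:
    """KPSS stationarity p-value (level variant by default, automatic lag
    selection). statsmodels interpolates p only inside [0.01, 0.1]; values
    are clipped to that table range."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        _, p, _, _ = sm_kpss(np.asarray(series, float), regression=regression,
                             nlags="auto")
    return float(p)


def bartlett_sphericity(points: np.ndarray) -> tuple[float, float]:
    """Bartlett's test of sphericity (correlation matrix vs identity).

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R|, df = p(p-1)/2.
    """
    pts = np.asarray(points, dtype=float)
    n, k = pts.shape
    corr = np.corrcoef(pts.T)
    det = float(np.linalg.det(corr))
    if det <= 0:
        return float("inf"), 0.0
    chi2 = -(n - 1 - (2 * k + 5) / 6.0) * np.log(det)
    df = k * (k - 1) / 2.0
    return float(chi2), float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# criteria battery
# ---------------------------------------------------------------------------

@dataclass
class StationarityReport:
    """Outcome of the stationarity / factor-analysis criteria battery.

    The stationarity block (c1-c5) decides whether adaptation can be ruled
    out; the factor-analysis gates (c6 Bartlett sphericity, c7 single
    eigenvalue > 1 of the correlation matrix) decide whether a single-factor
    state model is admissible. Raw statistics are kept so either grouping of
    the criteria can be reconstructed.
    """

    mode: str
    c1_correlated: bool
    c2_no_trial_trend: bool
    c3_trial_r2: bool
    c4_kpss: bool
    c5_lag1: bool
    c5_waived: bool
    c6_bartlett: bool
    c7_one_eigenvalue: bool
    r: float
    p_corr: float
    trial_p: tuple[float, float]
    trial_r2: float
    kpss_p: tuple[float, float]
    lag1_p: tuple[float, float]
    bartlett_p: float
    eigenvalues: tuple[float, float]
    reasons: list[str] = field(default_factory=list)

    @property
    def stationary(self) -> bool:
        c5 = self.c5_lag1 or self.c5_waived
        return self.c1_correlated and self.c2_no_trial_trend and self.c3_trial_r2 \
            and self.c4_kpss and c5

    @property
    def criteria_fulfilling(self) -> bool:
        return self.stationary and self.c6_bartlett and self.c7_one_eigenvalue


def evaluate_criteria(points: np.ndarray, trials: np.ndarray,
                      mode: str = "raw",
                      kpss_regression: str = "c") -> StationarityReport:
    """Evaluate the full criteria battery on a cluster's paired series.

    ``mode`` is one of ``raw``, ``differenced``, ``arima``; the lag-1
    autocorrelation requirement (c5) is waived for differenced series but
    not for ARIMA-processed ones. Degenerate (constant) series fail with
    reason codes rather than raising.
    """
    if mode not in ("raw", "differenced", "arima"):
        raise ValueError("mode must be raw, differenced or arima")
    pts = np.asarray(points, dtype=float)
    t = np.asarray(trials, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 cluster trials")
    reasons: list[str] = []
    nan = float("nan")
    degenerate = [np.ptp(pts[:, i]) == 0 for i in range(2)]
    if any(degenerate):
        reasons.append("constant series")
        return StationarityReport(
            mode=mode, c1_correlated=False, c2_no_trial_trend=False,
            c3_trial_r2=False, c4_kpss=False, c5_lag1=False,
            c5_waived=(mode == "differenced"), c6_bartlett=False,
            c7_one_eigenvalue=False, r=nan, p_corr=nan, trial_p=(nan, nan),
            trial_r2=nan, kpss_p=(nan, nan), lag1_p=(nan, nan),
            bartlett_p=nan, eigenvalues=(nan, nan), reasons=reasons)

    corr = linear_correlation(pts)
    c1 = corr.p < 0.005 and corr.r > 0.3
    if not c1:
        reasons.append("not correlated (p<0.005, r>0.3)")

    per_neuron, r2 = trial_regressions(pts, t)
    trial_p = (per_neuron[0].p, per_neuron[1].p)
    c2 = all(p > 0.05 for p in trial_p)
    if not c2:
        reasons.append("trial-index regression significant")
    c3 = r2 < 0.05
    if not c3:
        reasons.append("trial index explains >= 5% of joint variance")

    kp = tuple(kpss_pvalue(pts[:, i], regression=kpss_regression) for i in range(2))
    c4 = all(p > 0.05 for p in kp)
    if not c4:
        reasons.append("KPSS rejects stationarity")

    lp = tuple(autocorrelation(pts[:, i], 1)[1] for i in range(2))
    c5 = all(p > 0.05 for p in lp)
    waived = mode == "differenced"
    if not (c5 or waived):
        reasons.append("lag-1 autocorrelation significant")

    _, bart_p = bartlett_sphericity(pts)
    c6 = bart_p < 0.05   # factor-analysis gate: sphericity must be rejected
    if not c6:
        reasons.append("Bartlett sphericity not rejected")

    rmat = np.corrcoef(pts.T)
    eig = np.sort(np.linalg.eigvalsh(rmat))[::-1]
    c7 = (eig[0] > 1.0) and (eig[1] <= 1.0)   # for 2x2 equivalent to r > 0
    if not c7:
        reasons.append("correlation matrix does not have exactly one eigenvalue > 1")

    return StationarityReport(
        mode=mode, c1_correlated=c1, c2_no_trial_trend=c2, c3_trial_r2=c3,
        c4_kpss=c4, c5_lag1=c5, c5_waived=waived, c6_bartlett=c6,
        c7_one_eigenvalue=c7, r=corr.r, p_corr=corr.p, trial_p=trial_p,
        trial_r2=r2, kpss_p=kp, lag1_p=lp, bartlett_p=bart_p,
        eigenvalues=(float(eig[0]), float(eig[1])), reasons=reasons)


def needs_differencing(series: np.ndarray, trials: np.ndarray,
                       kpss_regression: str = "c") -> bool:
    """Single-neuron differencing trigger: trial regression p <= 0.05, or
    KPSS p <= 0.05, or lag-1 autocorrelation p <= 0.05."""
    s = np.asarray(series, dtype=float)
    t = np.asarray(trials, dtype=float)
    if np.ptp(s) == 0:
        return False
    reg = stats.linregress(t, s)
    if reg.pvalue <= 0.05:
        return True
    if kpss_pvalue(s, regression=kpss_regression) <= 0.05:
        return True
    _, p1 = autocorrelation(s, 1)
    return p1 <= 0.05


# ---------------------------------------------------------------------------
# differencing and ARIMA
# ---------------------------------------------------------------------------

def difference(values: np.ndarray, rescale: bool = True) -> np.ndarray:
    """First differences over consecutive cluster samples, divided by
    sqrt(2) (differencing inflates the sd of an i.i.d. series by about
    sqrt(2), so the rescaled series sits back on the original ms scale)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("series too short to difference")
    d = np.diff(v)
    return d / SQRT2 if rescale else d


def difference_series(series: ProcessedSeries) -> ProcessedSeries:
    """Differenced (and sqrt(2)-rescaled) copy of a raw series."""
    d = difference(series.raw, rescale=True)
    return ProcessedSeries(neuron_id=series.neuron_id, trials=series.trials[1:],
                           raw=series.raw, values=d, differenced=True,
                           rescale=1.0 / SQRT2)


def _lag_pvalues(series: np.ndarray, partial: bool, max_lag: int = 5) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    n = len(s)
    if partial:
        vals = sm_pacf(s, nlags=max_lag, method="ywm")[1:]
    else:
        vals = np.array([autocorrelation(s, k)[0] for k in range(1, max_lag + 1)])
    return 2.0 * stats.norm.sf(np.abs(vals) * np.sqrt(n))


def box_jenkins_orders(series: np.ndarray, max_lag: int = 5) -> tuple[int, int]:
    """Automated Box-Jenkins AR/MA order selection.

    If the lag-1 autocorrelation is negative (r < -0.1) and significant, the
    series is slightly over-differenced: the autocorrelation p-values at
    lags 1-5 are scanned for a sudden cut-off (an increase from below 0.05
    by more than 0.15 from one lag to the next); the last significant lag
    is the MA order. If it is positive (r > 0.1) and significant, the same
    scan on the partial autocorrelations gives the AR order. Otherwise the
    orders are (0, 0).
    """
    s = np.asarray(series, dtype=float)
    if len(s) < 8:
        log.warning("series of length %d too short for order selection", len(s))
        return 0, 0
    if np.ptp(s) == 0:
        return 0, 0
    r1, p1 = autocorrelation(s, 1)
    significant = p1 < 0.05

    def cutoff_order(pvals: np.ndarray) -> int:
        for k in range(len(pvals) - 1):
            if pvals[k] < 0.05 and (pvals[k + 1] - pvals[k]) > 0.15:
                return k + 1
        sig = np.flatnonzero(pvals < 0.05)
        return int(sig[-1] + 1) if len(sig) else 0

    if r1 < -0.1 and significant:
        return 0, cutoff_order(_lag_pvalues(s, partial=False, max_lag=max_lag))
    if r1 > 0.1 and significant:
        return cutoff_order(_lag_pvalues(s, partial=True, max_lag=max_lag)), 0
    return 0, 0


def arima_detrend(values: np.ndarray, orders: tuple[int, int],
                  recenter: float | None = None) -> np.ndarray:
    """Fit an ARMA model of the given (AR, MA) orders to an (unrescaled)
    differenced series and return its residuals on the original ms scale.

    ``recenter`` shifts the residuals back to latency units (the
    pre-differencing series mean); with orders (0, 0) and no recentring the
    series is returned unchanged. A non-convergent fit falls back to orders
    (0, 0) with a warning.
    """
    v = np.asarray(values, dtype=float)
    ar, ma = orders
    if ar == 0 and ma == 0:
        if recenter is None:
            return v.copy()
        return v - v.mean() + recenter
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ARIMA(v, order=(ar, 0, ma), trend="c").fit()
        resid = np.asarray(fit.resid, dtype=float)
        const = float(fit.params[0])
    except Exception as exc:  # non-convergence
        log.warning("ARIMA(%d,0,%d) fit failed (%s); falling back to (0,0)",
                    ar, ma, exc)
        return arima_detrend(v, (0, 0), recenter=recenter)
    base = recenter if recenter is not None else const
    return resid + base


def arima_series(series: ProcessedSeries) -> ProcessedSeries:
    """Box-Jenkins order selection + ARMA detrending of a raw series.

    The series is first differenced (unrescaled), orders are chosen from its
    (partial) autocorrelation structure, the ARMA residuals are recentred by
    the raw-series mean, and the result is aligned with trials[1:].
    """
    d = difference(series.raw, rescale=False)
    ar, ma = box_jenkins_orders(d)
    out = arima_detrend(d, (ar, ma), recenter=float(np.mean(series.raw)))
    return ProcessedSeries(neuron_id=series.neuron_id, trials=series.trials[1:],
                           raw=series.raw, values=out, differenced=True,
                           rescale=1.0, ar_order=ar, ma_order=ma)


# ---------------------------------------------------------------------------
# pair-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class PairProcessing:
    """Adaptation-control outcome for one cluster (or unclustered
    distribution): criteria reports and processed series per mode."""

    raw_report: StationarityReport
    differenced: tuple[ProcessedSeries, ProcessedSeries] | None = None
    differenced_report: StationarityReport | None = None
    arima: tuple[ProcessedSeries, ProcessedSeries] | None = None
    arima_report: StationarityReport | None = None
    differenced_neurons: tuple[bool, bool] = (False, False)

    @property
    def final_mode(self) -> str | None:
        """Mode under which the cluster fulfils all criteria (preference:
        raw stationarity, then ARIMA, then differenced), else None."""
        if self.raw_report.criteria_fulfilling:
            return "raw"
        if self.arima_report is not None and self.arima_report.criteria_fulfilling:
            return "arima"
        if self.differenced_report is not None and self.differenced_report.criteria_fulfilling:
            return "differenced"
        return None


def control_adaptation(points: np.ndarray, trials: np.ndarray,
                       neuron_ids: tuple[str, str] = ("n0", "n1"),
                       kpss_regression: str = "c") -> PairProcessing:
    """Full adaptation-control chain for one cluster's paired series.

    Evaluates the raw criteria; if the cluster is not stationary, each
    neuron whose own series trips a differencing trigger is differenced
    (rescaled by 1/sqrt(2)); when only one neuron is differenced the
    partner's first sample is dropped so a spike time on trial t stays
    matched with the difference between trials t and t-1. The differenced
    and ARIMA-processed variants are then re-evaluated against the criteria.
    """
    pts = np.asarray(points, dtype=float)
    t = np.asarray(trials, dtype=int)
    raw_report = evaluate_criteria(pts, t, mode="raw", kpss_regression=kpss_regression)
    proc = PairProcessing(raw_report=raw_report)
    if raw_report.stationary:
        return proc
    flags = tuple(needs_differencing(pts[:, i], t, kpss_regression) for i in range(2))
    proc.differenced_neurons = flags
    if not any(flags):
        return proc
    if len(pts) < 4:
        return proc

    diff_pair: list[ProcessedSeries] = []
    arima_pair: list[ProcessedSeries] = []
    for i in range(2):
        base = ProcessedSeries(neuron_id=neuron_ids[i], trials=t, raw=pts[:, i],
                               values=pts[:, i])
        if flags[i]:
            diff_pair.append(difference_series(base))
            arima_pair.append(arima_series(base))
        else:
            aligned = ProcessedSeries(neuron_id=neuron_ids[i], trials=t[1:],
                                      raw=pts[:, i], values=pts[1:, i],
                                      differenced=True)
            diff_pair.append(aligned)
            arima_pair.append(aligned)

    diff_pts = np.column_stack([s.values for s in diff_pair])
    arima_pts = np.column_stack([s.values for s in arima_pair])
    proc.differenced = (diff_pair[0], diff_pair[1])
    proc.arima = (arima_pair[0], arima_pair[1])
    if len(diff_pts) >= 10:
        proc.differenced_report = evaluate_criteria(diff_pts, t[1:], mode="differenced",
                                                    kpss_regression=kpss_regression)
        proc.arima_report = evaluate_criteria(arima_pts, t[1:], mode="arima",
                                              kpss_regression=kpss_regression)
    return proc
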