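"""Descriptive characterisations of a session: PSTHs, spiking reliability,
adaptation profiles over trial bins, and trial-series (partial)
autocorrelation diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf

from .core import WINDOW_MS

log = logging.getLogger(__name__)

#: stimulation-frequency group labels used for adaptation pooling: all
#: frequencies <= 0.2 Hz pool into one group, then 1, 2, ..., 10 Hz
FREQUENCY_GROUPS = ("0-0.2",) + tuple(str(k) for k in range(1, 11))


def frequency_group(freq_hz: float) -> str:
    if freq_hz <= 0.2:
        return "0-0.2"
    return str(int(round(freq_hz)))


def psth(records: pd.DataFrame, neuron_ids=None, bin_width_ms: float = 0.5,
         smoothing_sd_ms: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Max-normalised post-stimulus time histogram over the 50 ms window.

    Latencies are binned, smoothed with a Gaussian kernel (sigma in ms), and
    divided by the maximum so the peak is exactly 1. Returns (bin centres,
    normalised histogram).
    """
    df = records if neuron_ids is None else records[records.neuron_id.isin(neuron_ids)]
    if df.empty:
        raise ValueError("empty neuron group")
    lo, hi = WINDOW_MS
    edges = np.arange(lo, hi + bin_width_ms, bin_width_ms)
    counts, _ = np.histogram(df.first_spike_ms.to_numpy(), bins=edges)
    if smoothing_sd_ms > 0:
        smoothed = gaussian_filter1d(counts.astype(float),
                                     smoothing_sd_ms / bin_width_ms)
    else:
        smoothed = counts.astype(float)
    centres = edges[:-1] + bin_width_ms / 2.0
    return centres, smoothed / smoothed.max()


def reliability_histogram(records: pd.DataFrame, n_trials: int | None = None) -> pd.DataFrame:
    """Per (neuron, condition) proportion of trials with at least one spike.

    ``n_trials`` is the trial count per condition block; if omitted it is
    inferred as max(trial) + 1 over the whole record table.
    """
    if records.empty:
        return pd.DataFrame(columns=["neuron_id", "whisker", "frequency_hz", "reliability"])
    total = n_trials if n_trials is not None else int(records.trial.max()) + 1
    grp = (records.groupby(["neuron_id", "whisker", "frequency_hz"])["trial"]
           .nunique().rename("spiking_trials").reset_index())
    grp["reliability"] = grp.spiking_trials / total
    return grp[["neuron_id", "whisker", "frequency_hz", "reliability"]]


@dataclass
class AdaptationProfile:
    """Mean normalised value per 10-trial bin for one frequency group.

    The band half-width is 2 * sd(bin values) / sqrt(bin n), read as a 95%
    confidence interval of the bin mean.
    """

    group: str
    bin_edges: np.ndarray
    means: np.ndarray
    band_halfwidths: np.ndarray
    n_series: int


def adaptation_profile(records: pd.DataFrame, quantity: str = "first_spike",
                       bin_width: int = 10, n_bins: int = 10
                       ) -> dict[str, AdaptationProfile]:
    """Normalised adaptation profiles by stimulation-frequency group.

    For each (neuron, condition) the per-trial quantity (first-spike latency
    or spike count) is z-scored, then pooled within frequency groups and
    10-trial bins. Zero-variance series are excluded with a warning.
    """
    if quantity not in ("first_spike", "count"):
        raise ValueError("quantity must be 'first_spike' or 'count'")
    edges = np.arange(0, bin_width * n_bins + 1, bin_width)
    pooled: dict[str, list[np.ndarray]] = {g: [] for g in FREQUENCY_GROUPS}
    for (nid, wh, freq), df in records.groupby(["neuron_id", "whisker", "frequency_hz"]):
        if quantity == "first_spike":
            series = df.groupby("trial")["first_spike_ms"].min()
            trials = series.index.to_numpy()
            values = series.to_numpy()
        else:
            counts = df.groupby("trial").size()
            n_total = int(records.trial.max()) + 1
            trials = np.arange(n_total)
            values = np.zeros(n_total)
            values[counts.index.to_numpy()] = counts.to_numpy()
        if len(values) < 2 or values.std(ddof=0) == 0:
            log.warning("zero-variance or short series for %s/%s/%s excluded",
                        nid, wh, freq)
            continue
        z = (values - values.mean()) / values.std(ddof=0)
        binned = np.full(n_bins, np.nan)
        which = np.digitize(trials, edges) - 1
        for b in range(n_bins):
            sel = z[which == b]
            if len(sel):
                binned[b] = sel.mean()
        pooled[frequency_group(freq)].append(binned)
    profiles = {}
    for g, rows in pooled.items():
        if not rows:
            continue
        mat = np.vstack(rows)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(mat, axis=0)
            sds = np.nanstd(mat, axis=0, ddof=1)
            counts = np.sum(~np.isnan(mat), axis=0)
        half = 2.0 * sds / np.sqrt(np.maximum(counts, 1))
        profiles[g] = AdaptationProfile(group=g, bin_edges=edges, means=means,
                                        band_halfwidths=half, n_series=len(rows))
    return profiles


def series_acf_pacf(series: np.ndarray, max_lag: int = 20, partial: bool = False
                    ) -> pd.DataFrame:
    """(Partial) autocorrelation of a trial series with large-sample
    normal-approximation p-values (per-lag r * sqrt(n) ~ N(0, 1))."""
    s = np.asarray(series, dtype=float)
    n = len(s)
    if n < max_lag + 2:
        raise ValueError("series shorter than max_lag + 2")
    if partial:
        vals = sm_pacf(s, nlags=max_lag, method="ywm")
    else:
        vals = sm_acf(s, nlags=max_lag, fft=False)
    lags = np.arange(max_lag + 1)
    z = np.abs(vals) * np.sqrt(n)
    p = 2.0 * stats.norm.sf(z)
    p[0] = 0.0
    return pd.DataFrame({"lag": lags, "r": vals, "p": p})
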