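"""Remove a depressive adaptation trend and re-test the correlation angle.

A correlated cluster is given a saturating latency drift (as under rapid
whisker stimulation). The raw series fail the stationarity criteria; both
neurons are first-differenced (rescaled by 1/sqrt(2)) and an
automatically ordered AR/MA model removes the autocorrelation the
differencing introduces. The detrended angle matches the drift-free one.
"""

import numpy as np

import spikepairs as sp
from spikepairs.synthetic import AdaptationSpec

dist = sp.sample_pair_distribution(seed=3, n_trials=120,
                                   loadings=(2.0, 1.0), sigmas=(0.5, 0.5))
adapt = AdaptationSpec(latency_amplitude_ms=3.0, frequency_threshold_hz=0.5)
drifted = dist.points + adapt.drift(dist.trials, 1.0)[:, None]

raw = sp.evaluate_criteria(drifted, dist.trials)
print(f"raw series stationary: {raw.stationary} (reasons: {raw.reasons})")

proc = sp.control_adaptation(drifted, dist.trials)
s0, s1 = proc.arima
print(f"ARIMA orders: neuron 0 (AR {s0.ar_order}, MA {s0.ma_order}), "
      f"neuron 1 (AR {s1.ar_order}, MA {s1.ma_order})")
print(f"ARIMA-processed criteria fulfilled: {proc.arima_report.criteria_fulfilling}")

det = np.column_stack([s0.values, s1.values])
est_det = sp.bootstrap_angle(det, seed=1)
est_base = sp.bootstrap_angle(dist.points, seed=2)
print(f"drift-free theta45 = {est_base.theta45:.1f} deg, "
      f"detrended theta45 = {est_det.theta45:.1f} deg "
      f"(CI ({est_det.ci_low:.1f}, {est_det.ci_high:.1f}))")
# Differencing + low-order MA modelling restores stationarity, and the
# detrended correlation angle agrees with the drift-free counterpart:
# the non-45-degree angle is not an artefact of the trend removal.
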