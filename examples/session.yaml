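# Two-pair synthetic session: each pair's latencies share the per-trial
# state with different gains; block of 200 trials at 1 Hz and 4 Hz with
# mild latency adaptation above 2 Hz.
seed: 7
session: demo
whisker: C2
n_trials: 200
frequencies: [1.0, 4.0]
neurons:
  - {neuron_id: n0, ei_type: E, layer: L4}
  - {neuron_id: n1, ei_type: I, layer: L5A}
  - {neuron_id: n2, ei_type: E, layer: "L5B/6"}
  - {neuron_id: n3, ei_type: E, layer: "L2/3"}
pairs:
  - neuron_x: n0
    neuron_y: n1
    clusters:
      - {prob: 0.9, means: [14.0, 20.0], loadings: [2.0, 1.2], sigmas: [0.5, 0.4]}
  - neuron_x: n2
    neuron_y: n3
    clusters:
      - {prob: 0.9, means: [17.0, 25.0], loadings: [1.6, 1.0], sigmas: [0.4, 0.4]}
adaptation:
  latency_amplitude_ms: 1.5
  count_depression: 0.1
  trials_to_saturation: 20
  frequency_threshold_hz: 2.0
reliability: {n0: 0.9, n1: 0.9, n2: 0.9, n3: 0.9}
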