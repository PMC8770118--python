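bootstrap:
  B: 8192
calibration:
  hille:
    conductivity: 10.5
    length: 3.5
detection:
  k_sigma: 5.0
  min_dwell_ms: 0.5
  threshold_fraction: 0.1
histogram:
  bin_width_nS: 0.25
  smooth_window: 3
  threshold: 0.15
seed: 7
simulate:
  class_weights:
    erratic: 0.165
    multi-level: 0.165
    square-top: 0.335
    step: 0.335
  conductance_sample_n: 2000
  event_stream:
    concentration_nM: 100.0
    duration_s: 30.0
    open_current_pA: 1050.0
    voltage_mV: 100.0
  n_signals: 40
  noise_sd_pA: 5.0
  unit_conductance_nS: 1.1
  voltage_mV: 100.0
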