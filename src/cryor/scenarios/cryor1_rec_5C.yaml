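name: cryor1_rec_5C
kind: recovery
seed: 5
parameters:
  tau_s: 3318.0           # PSS thermal recovery lifetime at 5 C
  a_inf: 0.85
  delta_a: 0.35
  monitor_nm: 554.0
  illumination_s: 100.0
  sample_interval_s: 120.0
  duration_s: 18000.0
  noise_sigma: 0.002
  temperature_C: 5.0
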