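name: cryor1_rec_20C
kind: recovery
seed: 20
parameters:
  tau_s: 942.0            # PSS thermal recovery lifetime at 20 C
  a_inf: 0.85             # dark-state absorbance at the monitoring wavelength (OD)
  delta_a: 0.35           # absorbance depleted by PSS formation (OD)
  monitor_nm: 554.0
  illumination_s: 100.0   # LED-on period preceding the sampled recovery
  sample_interval_s: 120.0
  duration_s: 18000.0     # 5 h
  noise_sigma: 0.002      # OD
  temperature_C: 20.0
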