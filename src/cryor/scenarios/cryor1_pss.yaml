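name: cryor1_pss
kind: pss
seed: 565
parameters:
  ground_bands: [{center_nm: 554.0, sigma_nm: 40.0, amplitude: 1.0}]
  m_bands: [{center_nm: 400.0, sigma_nm: 28.0, amplitude: 0.9}]
  phi_forward: 0.3
  phi_back: 0.75
  k_thermal_per_s: 1.0616e-3      # 1/942 s at 20 C
  extinction_scale: 50000.0       # M^-1 cm^-1 per unit band amplitude
  # LED protocol mirrors the illumination experiments:
  # 565-nm 1.05 mW 100 s to form the PSS, 420-nm 0.19 mW 100 s to quench
  leds:
    green: {center_nm: 565.0, fwhm_nm: 25.0, power_mW: 1.05, beam_area_cm2: 1.0}
    blue: {center_nm: 420.0, fwhm_nm: 25.0, power_mW: 0.19, beam_area_cm2: 1.0}
  step_duration_s: 100.0
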