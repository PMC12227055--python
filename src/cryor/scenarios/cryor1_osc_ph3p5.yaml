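name: cryor1_osc_ph3p5
kind: fsta
seed: 335
parameters:
  pH: 3.5
  excitation_nm: 620.0
  lifetimes_ps: [0.5, 25.0]
  irf_sigma_ps: 0.05
  t0_ps: 0.0
  wavelength_start_nm: 420.0
  wavelength_stop_nm: 740.0
  wavelength_step_nm: 4.0
  # linear 3-ps measurement with decreased step size
  time_linear_start_ps: -0.2
  time_linear_stop_ps: 3.0
  time_linear_step_ps: 0.02
  components:
    - bands:
        - {center_nm: 475.0, sigma_nm: 35.0, amplitude: 7.0}
        - {center_nm: 590.0, sigma_nm: 32.0, amplitude: -5.0}
        - {center_nm: 690.0, sigma_nm: 40.0, amplitude: -3.0}
    - bands:
        - {center_nm: 480.0, sigma_nm: 35.0, amplitude: 5.0}
        - {center_nm: 585.0, sigma_nm: 32.0, amplitude: -4.0}
        - {center_nm: 685.0, sigma_nm: 40.0, amplitude: -2.0}
  # coherent oscillations on the ESA/GSB wings
  oscillations:
    - {wavenumber_cm: 128.0, tau_damp_ps: 0.5, phase_rad: 0.0,
       band_center_nm: 530.0, band_sigma_nm: 25.0, amplitude: 0.8}
    - {wavenumber_cm: 32.0, tau_damp_ps: 1.0, phase_rad: 0.0,
       band_center_nm: 530.0, band_sigma_nm: 25.0, amplitude: 0.5}
  # default residual-analysis band (ESA/GSB wings) and time window
  osc_band_nm: [505.0, 560.0]
  osc_window_ps: [0.15, 1.05]
  noise_sigma: 0.05
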