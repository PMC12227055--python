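name: cryor1_wt_flash_ph8
kind: flash
seed: 8
parameters:
  pH: 8.0
  excitation_nm: 550.0
  states: [K, M]
  lifetimes_s: [2.0e-3, 300.0]      # blue-shifted state decays over minutes
  time_start_s: 1.0e-4
  time_stop_s: 3000.0
  time_points: 90
  wavelength_start_nm: 340.0
  wavelength_stop_nm: 700.0
  wavelength_step_nm: 5.0
  species_spectra:
    K:
      - {center_nm: 615.0, sigma_nm: 30.0, amplitude: 4.0}
      - {center_nm: 550.0, sigma_nm: 35.0, amplitude: -6.0}
    M:
      - {center_nm: 400.0, sigma_nm: 25.0, amplitude: 8.0}
      - {center_nm: 550.0, sigma_nm: 35.0, amplitude: -6.0}
  noise_sigma: 0.05
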