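name: cryor1_flash_ph10p5
kind: flash
seed: 1105
parameters:
  pH: 10.5
  excitation_nm: 540.0
  states: [K, M1, M2]
  lifetimes_s: [1.0e-3, 0.8, 180.0]   # K ms-scale; M1 sub-second; M2 minutes
  time_start_s: 1.0e-5
  time_stop_s: 5000.0
  time_points: 100
  wavelength_start_nm: 340.0
  wavelength_stop_nm: 700.0
  wavelength_step_nm: 5.0
  species_spectra:
    K:
      - {center_nm: 620.0, sigma_nm: 30.0, amplitude: 4.0}
      - {center_nm: 554.0, sigma_nm: 35.0, amplitude: -6.0}
    M1:
      - {center_nm: 402.0, sigma_nm: 25.0, amplitude: 8.0}
      - {center_nm: 554.0, sigma_nm: 35.0, amplitude: -6.0}
    M2:
      - {center_nm: 398.0, sigma_nm: 24.0, amplitude: 8.5}
      - {center_nm: 554.0, sigma_nm: 35.0, amplitude: -6.0}
  noise_sigma: 0.05
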