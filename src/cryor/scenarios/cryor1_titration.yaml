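name: cryor1_titration
kind: titration
seed: 25
parameters:
  pH_start: 2.5
  pH_stop: 11.0
  pH_step: 0.5
  wavelength_start_nm: 250.0
  wavelength_stop_nm: 750.0
  wavelength_step_nm: 2.0
  # ordered acidic -> alkaline species, one visible Gaussian each (OD)
  species:
    - name: red_protonated          # protonated counterion complex
      bands: [{center_nm: 620.0, sigma_nm: 30.0, amplitude: 1.0}]
    - name: blue_deprotonated       # nonprotonated counterion complex
      bands: [{center_nm: 540.0, sigma_nm: 32.0, amplitude: 1.0}]
    - name: rsb_deprotonated        # deprotonated retinal Schiff base
      bands: [{center_nm: 400.0, sigma_nm: 26.0, amplitude: 0.9}]
  pkas: [5.8, 10.3]
  hill: [1.0, 1.0]
  # pH-independent aromatic band used for 280-nm normalization
  reference_band: {center_nm: 280.0, sigma_nm: 18.0, amplitude: 1.5}
  noise_sigma: 0.002
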