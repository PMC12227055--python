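name: cryor1_ephys
kind: ephys
seed: 7
parameters:
  voltages_mV: [-40.0, 0.0, 40.0]
  # ground-state fraction with nonprotonated counterion complex, per voltage
  fraction_nonprot: {"-40.0": 0.3333333333333333, "0.0": 0.6666666666666666, "40.0": 0.8}
  # per-protein unit charges: 500-nm activation positive transient,
  # 620-nm activation negative transient
  unit_charge_pC: {"500": 20.0, "620": -15.0}
  rise_ms: 2.0
  decay_ms: 15.0
  pulse_period_s: 0.25
  n_pulses: 10
  depletion_per_pulse: 0.5
  baseline_pA: -5.0
  pre_pulse_s: 0.1
  sample_rate_hz: 5000.0
  noise_pA: 1.0
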