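# Demo study conditions: 30 healthy volunteers (one session each) and 30 PD
# participants (ON and OFF sessions), 30 s corridor walks at 128 Hz.
# Effect sizes and noise levels are the simulator defaults, written out here
# so the conditions are explicit.
simulate:
  n_hv: 30
  n_pd: 30
  sample_rate: 128.0
  walk_duration_s: 30.0
  step_period_mean_s: 1.1
  step_period_sd_s: 0.02
  severity_range: [10, 70]
  severity_morph_gain: 0.006
  asymmetry_gain: 0.005
  med_effect: 0.25
  noise_sd: 0.3
  amp_jitter_sd: 0.05
  participant_sd: 0.03
  participant_base_sd: 0.12
  updrs_noise_sd: 4.0
  seed: 2026
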