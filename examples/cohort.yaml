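# Minimal cohort configuration: only master_seed is required; every other
# key overrides a default documented in docs/methods.md.
master_seed: 7
n_attrv: 18
n_hc: 21
acquisition:
  snr: 50.0
  noise_model: rician
analysis:
  icc_variant: icc2_1
  rater_flip_rate: 0.2
  csa_one_tailed: true
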