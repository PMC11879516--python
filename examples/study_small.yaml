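# Small end-to-end study configuration: 50 subjects, one ESM week,
# a weak differential-susceptibility regime on paranoia driven by the
# positive-context appraisal.
synth:
  seed: 11
  n_subjects: 50
  n_blocks: 8
  snps_per_block: 8
  block_corr: 0.8
  maf_range: [0.05, 0.5]
  prop_causal: 0.3
  beta_sd: 0.05
  compliance: 0.7268
  target_outcome: paranoia
  context: positive
  true_model: {framework: differential_susceptibility, strength: weak}
  true_params: {b0: 1.3, s0: -0.05, s1: -0.08, c: 5.0, sigma_u: 0.2, sigma_e: 0.35}
n_boot: 80
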