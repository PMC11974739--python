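model:
  n_factors: 8
  n_control: 3
  generator_dim: 40
  encoder_dim: 24
  prep_bins: 25
  weights: {theta: 50.0, alpha: 1.0e-4}
pbt:
  population: 4
  generations: 4
  steps_per_generation: 50
  search:
    theta: [1.0, 1000.0]
    learning_rate: [1.0e-4, 1.0e-2]
  seed: 0
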