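model:
  n_factors: 8
  n_control: 3
  generator_dim: 40
  encoder_dim: 24
  controller_dim: 24
  prep_bins: 25
  weights: {theta: 200.0, alpha: 1.0e-4}
train:
  epochs: 400
  learning_rate: 3.0e-3
  lr_decay: 0.9985
  kl_warmup_epochs: 100
  kl_warmup_epochs_u: 0
  controller_dropout: 0.3
  valid_every: 50
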