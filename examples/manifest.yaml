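# demo manifest: simulate -> train (full + theta=0) -> ablate -> eval
seed: 1
sim:
  n_neurons: 16
  T: 40
  prep_bins: 15
  trials_per_epoch: {BL: 3, AD: 3, WO: 3}
model:
  n_factors: 6
  n_control: 2
  generator_dim: 16
  encoder_dim: 10
  prep_bins: 15
  weights: {theta: 100.0, alpha: 1.0e-4}
train:
  epochs: 40
  kl_warmup_epochs: 10
  valid_every: 10
out_dir: band_demo_run
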