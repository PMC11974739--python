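# band-dynamics

Semi-supervised sequential autoencoder for spiking neural population data.
The model (`band`) infers latent dynamics from binned spike counts — an
initial condition encoding the movement plan from a preparatory window, plus
causally-inferred per-bin control inputs during movement — and jointly trains
a sequence-to-sequence linear behavior decoder so that behaviorally relevant
neural variability is retained even when it barely affects spike
reconstruction. Setting the behavior weight θ to zero recovers the purely
unsupervised variant; ablating the controller after training yields the
autonomous variant.

The package ships with:

- a **synthetic center-out-reach simulator** with full ground truth:
  target-dependent rotational "planned" dynamics, transient 4–5 Hz
  oscillatory corrections in perturbation-epoch trials only, Poisson spike
  emission, and behavior feeding back into the latent state at a
  configurable delay (90 ms by default);
- **metrics**: Poisson likelihood, diagonal-Gaussian KL, bits/spike and
  bits/second against a mean-rate null, pooled ("isotropic") R², explained
  behavior variance, and two PBT objectives;
- **training**: Adam with KL warmup and divergence recovery,
  k-fold cross-validation with exact out-of-fold bookkeeping, and a
  sequential population-based training (PBT) hyperparameter search;
- an **analysis battery**: condition-average baseline, ridge seq2seq
  decoding from factors, a bidirectional RNN decoder ceiling, Gaussian rate
  smoothing, per-trial FFT spectra, shuffle-null oscillatory-neuron
  detection, FFT phase similarity, decoder-weight diagonal lag profiles,
  fixed-lag regression, and full-vs-ablated controller contribution
  decomposition.

Everything runs on numpy: the recurrent networks are built on a small
in-repo reverse-mode autodiff engine (`band.autodiff`, `band.nn`), so there
is no deep-learning framework dependency.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the quantitative acceptance criteria
(metric oracles, exact structural invariants, synthetic supervision-gap /
ablation / lag-recovery experiments, oscillation-detection calibration,
cross-validation bookkeeping, PBT sanity). The recovery experiments train
six small models from scratch and take the bulk of the suite's runtime
(~10 min on one CPU).

## CLI

All commands are thin wrappers over documented library functions.

```bash
band simulate --config sim.yaml --out bundle.h5 --truth truth.npz
band data validate bundle.h5
band data filter --max-speed 1.0 bundle.h5 filtered.h5
band data split --scheme kfold --k 5 --seed 1 bundle.h5
band train --data bundle.h5 --config model.yaml --out ckpt.npz --seed 1
band cv    --data bundle.h5 --config model.yaml --k 5 --out cv.json
band pbt   --data bundle.h5 --config pbt.yaml --out best.npz
band ablate --ckpt ckpt.npz --out autonomous.npz
band infer --ckpt ckpt.npz --data bundle.h5 --out latents.npz
band eval  --ckpt ckpt.npz --data bundle.h5 --metrics bps,bpspike,r2,ev --out metrics.json
band analyze spectrum|oscillatory|lagprofile|fixedlag|contribution \
     --ckpt ckpt.npz --data bundle.h5 --out report.json
band run --manifest manifest.yaml
```

Config files are YAML mirroring the dataclass fields (`SimConfig`,
`ModelConfig` + nested `weights`, `TrainConfig`, `PBTConfig`). A manifest
for `band run` declares `seed`, `sim`, `model`, `train` and `out_dir`, and
executes simulate → train (full and θ=0) → ablate → eval with config hashes
and wall-clock logs written next to `metrics.json`.

## Library sketch

```python
from band import (SimConfig, generate_dataset, ModelConfig, LossWeights,
                  TrainConfig, train_model, ablate_controller,
                  split_trials, SplitSpec, bits_per_spike, r2_isotropic)

dataset, truth = generate_dataset(SimConfig(seed=1))
split = split_trials(dataset, SplitSpec(scheme="holdout", seed=1))
cfg = ModelConfig(n_factors=8, n_control=3, generator_dim=40, encoder_dim=24,
                  weights=LossWeights(theta=200.0, alpha=1e-4))
model, history = train_model(cfg, dataset, split,
                             TrainConfig(epochs=400, kl_warmup_epochs_u=0,
                                         controller_dropout=0.3, seed=1))
autonomous = ablate_controller(model)

out = model.infer(dataset.spikes[split[1]])
print(bits_per_spike(out.rates, dataset.spikes[split[1]]),
      r2_isotropic(dataset.behavior[split[1]], out.behavior_pred))
```

Data is stored as single-file HDF5 bundles (`/spikes`, `/behavior`,
`/condition`, `/epoch` + `bin_width_s`, `prep_bins`, `alignment`, `units`
attributes); an optional NWB reader is available when `pynwb` is installed.
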