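"""Optimization loop, cross-validation orchestration and a sequential PBT.

The trainer minimizes the negative composite objective with Adam, linear KL
warmup and global-norm gradient clipping; it tracks every loss term plus
validation bits/spike and R² per epoch, keeps the best parameters under the
configured validation objective, and aborts to the last good state on
divergence.  PBT is a single-machine, sequential simulation of the
exploit/explore scheme (truncation selection, multiplicative perturbation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .data import SplitSpec, TrialDataset, split_trials
from .metrics import (bits_per_spike, pbt_objective, pbt_objective_nlb,
                      r2_isotropic)
from .model import BandModel, ModelConfig
from .nn import Adam, clip_grad_norm

__all__ = ["TrainConfig", "PBTConfig", "train_model", "cross_validate", "run_pbt"]


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int | None = None       # None = full batch
    learning_rate: float = 3e-3
    lr_decay: float = 1.0               # multiplicative, applied per epoch
    grad_clip: float = 200.0
    kl_warmup_epochs: int = 100
    # separate warmup for the control-input KL; None mirrors kl_warmup_epochs,
    # 0 applies the full penalty from the first step
    kl_warmup_epochs_u: int | None = None
    seed: int = 0
    patience: int | None = None         # epochs without val improvement
    valid_every: int = 25               # epochs between validation evaluations
    input_dropout: float = 0.0
    neuron_dropout: float = 0.0
    # fraction of steps trained with control inputs forced to zero (and no
    # controller gradient), so the autonomous pathway is fit directly and the
    # controller only retains structure it genuinely explains
    controller_dropout: float = 0.0
    keep_best: bool = True

    def __post_init__(self):
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.kl_warmup_epochs > self.epochs:
            raise ValueError("KL warmup must end by the last epoch")
        if self.batch_size is not None and self.batch_size <= 0:
            raise ValueError("batch_size must be positive")


@dataclass
class PBTConfig:
    population: int = 4
    generations: int = 4
    steps_per_generation: int = 50
    exploit_fraction: float = 0.25      # bottom fraction copies top fraction
    perturb_factors: tuple = (0.8, 1.25)
    search: dict = field(default_factory=lambda: {"theta": (1.0, 1000.0),
                                                  "learning_rate": (1e-4, 1e-2)})
    objective: str = "eq_normalized"    # or "eq_nlb"
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name, (lo, hi) in self.search.items():
            if not lo <= hi:
                raise ValueError(f"range for {name!r} is not well-ordered")
        if self.objective not in ("eq_normalized", "eq_nlb"):
            raise ValueError(f"unknown PBT objective {self.objective!r}")


class DivergenceError(RuntimeError):
    pass


def _validation_metrics(model: BandModel, dataset: TrialDataset, idx) -> dict:
    out = model.infer(dataset.spikes[idx])
    bps = bits_per_spike(out.rates, dataset.spikes[idx])
    r2 = r2_isotropic(dataset.behavior[idx], out.behavior_pred)
    from .metrics import poisson_log_likelihood
    L_x = poisson_log_likelihood(out.rates, dataset.spikes[idx]) / len(idx)
    return {"bits_per_spike": bps, "r2": r2, "L_x": L_x}


def _objective_value(metrics: dict, dataset: TrialDataset, kind: str) -> float:
    if kind == "eq_nlb":
        # behavior MSE recoverable from r2 only up to variance scale; use
        # L_x and the pooled MSE directly where available
        return pbt_objective_nlb(metrics["L_x"], metrics.get("mse", 0.0))
    return pbt_objective(metrics["L_x"], dataset.n_neurons, dataset.T, metrics["r2"])


def train_model(model_config: ModelConfig, dataset: TrialDataset, split,
                train_config: TrainConfig, model: BandModel | None = None,
                objective: str = "eq_normalized"):
    """Train a model on the given (train_idx, val_idx) split.

    Returns (model, history).  ``history`` holds per-epoch loss terms and the
    periodic validation metrics; the returned parameters are the history
    argmax of the validation objective (when ``keep_best``).
    """
    train_idx, val_idx = split
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if model is None:
        model = BandModel(model_config, dataset.n_neurons, dataset.T,
                          seed=train_config.seed)
    rng = np.random.default_rng(train_config.seed)
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    spikes = dataset.spikes[train_idx]
    behavior = dataset.behavior[train_idx]

    history = {"epoch": [], "loss": [], "L_x": [], "L_b": [], "KL_g0": [],
               "KL_u": [], "L_L2": [], "val_epoch": [], "val_bits_per_spike": [],
               "val_r2": [], "val_objective": []}
    best = {"objective": -np.inf, "state": None, "epoch": -1}
    # two snapshot generations: when divergence is detected at epoch k, the
    # state saved at the end of epoch k-1 already contains the bad update,
    # so the snapshot from one epoch earlier is restored
    prev_good = last_good = model.state_dict()
    stale = 0

    for epoch in range(train_config.epochs):
        kl_scale = min(1.0, (epoch + 1) / max(train_config.kl_warmup_epochs, 1))
        wu = train_config.kl_warmup_epochs_u
        kl_scale_u = (kl_scale if wu is None
                      else min(1.0, (epoch + 1) / max(wu, 1)))
        if train_config.batch_size is None:
            batches = [np.arange(len(train_idx))]
        else:
            perm = rng.permutation(len(train_idx))
            batches = np.array_split(perm, max(1, len(perm) // train_config.batch_size))
        epoch_loss = 0.0
        diag = {}
        for batch in batches:
            model.zero_grad()
            force_u = (train_config.controller_dropout > 0.0
                       and model.config.n_control > 0
                       and rng.random() < train_config.controller_dropout)
            loss, diag = model.loss_graph(
                spikes[batch], behavior[batch], rng=rng, kl_scale=kl_scale,
                kl_scale_u=kl_scale_u, force_u_zero=force_u,
                input_dropout=train_config.input_dropout,
                neuron_dropout=train_config.neuron_dropout)
            value = loss.item()
            if (not np.isfinite(value) or diag["rate_min"] <= 0.0
                    or not np.isfinite(diag["rate_max"])):
                model.load_state_dict(prev_good)
                history["diverged_at"] = epoch
                return model, history
            loss.backward()
            clip_grad_norm(model.parameters(), train_config.grad_clip)
            opt.step()
            epoch_loss += value * len(batch)
        opt.lr *= train_config.lr_decay
        prev_good, last_good = last_good, model.state_dict()

        history["epoch"].append(epoch)
        history["loss"].append(epoch_loss / len(train_idx))
        for key in ("L_x", "L_b", "KL_g0", "KL_u", "L_L2"):
            history[key].append(diag[key])

        last = epoch == train_config.epochs - 1
        if len(val_idx) and (epoch % train_config.valid_every == 0 or last):
            try:
                vm = _validation_metrics(model, dataset, val_idx)
            except (ValueError, FloatingPointError):
                model.load_state_dict(prev_good)
                history["diverged_at"] = epoch
                return model, history
            obj = _objective_value(vm, dataset, objective)
            history["val_epoch"].append(epoch)
            history["val_bits_per_spike"].append(vm["bits_per_spike"])
            history["val_r2"].append(vm["r2"])
            history["val_objective"].append(obj)
            if obj > best["objective"]:
                best = {"objective": obj, "state": model.state_dict(), "epoch": epoch}
                stale = 0
            else:
                stale += 1
                if train_config.patience is not None and stale > train_config.patience:
                    break

    if train_config.keep_best and best["state"] is not None:
        model.load_state_dict(best["state"])
        history["best_epoch"] = best["epoch"]
    return model, history


def cross_validate(model_config: ModelConfig, dataset: TrialDataset, k: int,
                   train_config: TrainConfig, stratify: bool = True):
    """k-fold CV: each trial is scored exactly once by a model that never saw it.

    Returns a dict with out-of-fold behavior predictions and rates in original
    trial order, pooled metrics, and per-fold metrics.  Per-fold R² is
    computed against the full dataset's per-component grand mean so that the
    pooled value is an exact weighted average of the fold values.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = split_trials(dataset, SplitSpec(scheme="kfold", k=k,
                                            seed=train_config.seed,
                                            stratify=stratify))
    preds = np.full_like(dataset.behavior, np.nan)
    rates = np.zeros(dataset.spikes.shape)
    seen = np.zeros(dataset.n_trials, dtype=int)
    fold_r2, fold_bps = [], []
    grand = dataset.behavior.reshape(-1, dataset.n_behavior).mean(axis=0)

    for train_idx, test_idx in folds:
        model, _ = train_model(model_config, dataset, (train_idx, test_idx),
                               train_config)
        out = model.infer(dataset.spikes[test_idx])
        preds[test_idx] = out.behavior_pred
        rates[test_idx] = out.rates
        seen[test_idx] += 1
        truth = dataset.behavior[test_idx]
        sse = ((truth - out.behavior_pred) ** 2).sum()
        sst = ((truth - grand) ** 2).sum()
        fold_r2.append(1.0 - sse / sst)
        fold_bps.append(bits_per_spike(out.rates, dataset.spikes[test_idx]))

    if not (seen == 1).all():
        raise AssertionError("out-of-fold coverage violated")
    pooled_r2 = r2_isotropic(dataset.behavior, preds)
    return {
        "behavior_pred": preds,
        "rates": rates,
        "pooled_r2": pooled_r2,
        "pooled_bits_per_spike": bits_per_spike(rates, dataset.spikes),
        "fold_r2": np.array(fold_r2),
        "fold_bits_per_spike": np.array(fold_bps),
        "fold_r2_sd": float(np.std(fold_r2)),
    }


# -- population-based training ------------------------------------------------

_PERTURBABLE = {"theta", "alpha"}          # live on model_config.weights
_TRAIN_PARAMS = {"learning_rate", "input_dropout"}


def _get_hyper(model_config: ModelConfig, train_config: TrainConfig, name: str):
    if name in _PERTURBABLE:
        return getattr(model_config.weights, name)
    if name in _TRAIN_PARAMS:
        return getattr(train_config, name)
    raise KeyError(f"unsupported search hyperparameter {name!r}")


def _set_hyper(model_config: ModelConfig, train_config: TrainConfig, name, value):
    if name in _PERTURBABLE:
        setattr(model_config.weights, name, value)
    elif name in _TRAIN_PARAMS:
        setattr(train_config, name, value)
    else:
        raise KeyError(f"unsupported search hyperparameter {name!r}")


def run_pbt(model_config: ModelConfig, dataset: TrialDataset, pbt: PBTConfig,
            train_config: TrainConfig | None = None, split=None):
    """Sequential population-based training.

    Members train for ``steps_per_generation`` epochs per generation; at each
    generation boundary the bottom ``exploit_fraction`` copy parameters and
    hyperparameters from the top performers and perturb the searched
    hyperparameters.  Returns (best model, lineage log).
    """
    rng = np.random.default_rng(pbt.seed)
    if train_config is None:
        train_config = TrainConfig(epochs=pbt.steps_per_generation,
                                   kl_warmup_epochs=1, seed=pbt.seed)
    if split is None:
        split = split_trials(dataset, SplitSpec(scheme="holdout", seed=pbt.seed))
    train_idx, val_idx = split

    members = []
    for i in range(pbt.population):
        mc = copy.deepcopy(model_config)
        tc = replace(train_config, seed=int(rng.integers(2**31)),
                     epochs=pbt.steps_per_generation,
                     kl_warmup_epochs=min(train_config.kl_warmup_epochs,
                                          pbt.steps_per_generation))
        for name, (lo, hi) in pbt.search.items():
            if lo < hi:
                value = float(np.exp(rng.uniform(np.log(max(lo, 1e-12)),
                                                 np.log(max(hi, 1e-12))))) if lo > 0 \
                    else float(rng.uniform(lo, hi))
            else:
                value = lo
            _set_hyper(mc, tc, name, value)
        members.append({"id": i, "model": None, "model_config": mc,
                        "train_config": tc, "objective": -np.inf})

    lineage = []
    n_exploit = max(1, int(np.floor(pbt.exploit_fraction * pbt.population)))
    any_alive = False

    for gen in range(pbt.generations):
        for member in members:
            member["model"], hist = train_model(
                member["model_config"], dataset, (train_idx, val_idx),
                member["train_config"], model=member["model"])
            if "diverged_at" in hist and not hist["val_objective"]:
                member["objective"] = -np.inf
            else:
                vm = _validation_metrics(member["model"], dataset, val_idx)
                member["objective"] = _objective_value(
                    vm, dataset,
                    "eq_nlb" if pbt.objective == "eq_nlb" else "eq_normalized")
                any_alive = True
            lineage.append({"generation": gen, "member": member["id"],
                            "event": "trained",
                            "objective": member["objective"],
                            "hyper": {name: _get_hyper(member["model_config"],
                                                       member["train_config"], name)
                                      for name in pbt.search}})
        if not any_alive:
            raise DivergenceError("all population members diverged")

        if gen == pbt.generations - 1:
            break
        ranked = sorted(members, key=lambda m: m["objective"], reverse=True)
        top, bottom = ranked[:n_exploit], ranked[-n_exploit:]
        for loser in bottom:
            winner = top[int(rng.integers(len(top)))]
            if winner["objective"] <= loser["objective"]:
                continue
            loser["model"] = copy.deepcopy(winner["model"])
            loser["model_config"] = copy.deepcopy(winner["model_config"])
            loser["train_config"] = copy.deepcopy(winner["train_config"])
            perturbed = {}
            for name in pbt.search:
                lo, hi = pbt.search[name]
                value = _get_hyper(loser["model_config"], loser["train_config"], name)
                if lo < hi:
                    value = float(np.clip(
                        value * rng.choice(pbt.perturb_factors), lo, hi))
                    _set_hyper(loser["model_config"], loser["train_config"],
                               name, value)
                perturbed[name] = value
            lineage.append({"generation": gen, "member": loser["id"],
                            "event": "exploit", "copied_from": winner["id"],
                            "hyper": perturbed})

    best = max(members, key=lambda m: m["objective"])
    return best["model"], lineage
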