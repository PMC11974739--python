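"""YAML configuration loading and reproducible experiment manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import yaml

from .data import SplitSpec, save_trial_bundle, split_trials
from .metrics import LossWeights, bits_per_second, bits_per_spike, r2_isotropic
from .model import ModelConfig, ablate_controller, save_checkpoint
from .simulate import SimConfig, generate_dataset
from .training import TrainConfig, train_model

__all__ = [
    "load_yaml_config",
    "sim_config_from_dict",
    "model_config_from_dict",
    "train_config_from_dict",
    "ExperimentManifest",
    "run_experiment",
]


def load_yaml_config(path) -> dict:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return data


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def sim_config_from_dict(data: dict) -> SimConfig:
    return _from_dict(SimConfig, data)


def model_config_from_dict(data: dict) -> ModelConfig:
    data = dict(data)
    if "weights" in data and isinstance(data["weights"], dict):
        data["weights"] = _from_dict(LossWeights, data["weights"])
    return _from_dict(ModelConfig, data)


def train_config_from_dict(data: dict) -> TrainConfig:
    return _from_dict(TrainConfig, data)


def file_fingerprint(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclasses.dataclass
class ExperimentManifest:
    """Declarative simulate -> train -> ablate -> eval experiment."""

    seed: int
    sim: dict
    model: dict
    train: dict
    out_dir: str

    @classmethod
    def from_yaml(cls, path) -> "ExperimentManifest":
        data = load_yaml_config(path)
        if "seed" not in data:
            raise ValueError("manifest requires an explicit seed")
        return cls(seed=int(data["seed"]), sim=data.get("sim", {}),
                   model=data.get("model", {}), train=data.get("train", {}),
                   out_dir=data.get("out_dir", "band_run"))


def run_experiment(manifest: ExperimentManifest) -> dict:
    """Execute a manifest end-to-end; returns the metrics dict.

    Stages: simulate -> train full model -> train θ=0 variant -> ablate ->
    evaluate.  Configuration hashes, data fingerprints and wall-clock times
    are recorded alongside metrics.json in the output directory.
    """
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"seed": manifest.seed, "stages": {}, "config_hashes": {}}
    for name, cfg in (("sim", manifest.sim), ("model", manifest.model),
                      ("train", manifest.train)):
        record["config_hashes"][name] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            record["stages"][name] = {"status": "failed", "error": str(exc)}
            with open(out_dir / "manifest.json", "w") as f:
                json.dump(record, f, indent=2)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        record["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        return result

    sim_cfg = sim_config_from_dict({**manifest.sim, "seed": manifest.seed})
    dataset, _ = stage("simulate", lambda: generate_dataset(sim_cfg))
    bundle = out_dir / "dataset.h5"
    save_trial_bundle(dataset, bundle)
    record["data_fingerprint"] = file_fingerprint(bundle)

    model_cfg = model_config_from_dict(manifest.model)
    train_cfg = train_config_from_dict({**manifest.train, "seed": manifest.seed})
    split = split_trials(dataset, SplitSpec(scheme="holdout", seed=manifest.seed))

    full, hist = stage("train_full", lambda: train_model(model_cfg, dataset, split, train_cfg))
    save_checkpoint(full, out_dir / "full.ckpt", history={"loss": hist["loss"]})

    unsup_cfg = dataclasses.replace(
        model_cfg, weights=dataclasses.replace(model_cfg.weights, theta=0.0))
    unsup, _ = stage("train_unsupervised",
                     lambda: train_model(unsup_cfg, dataset, split, train_cfg))
    save_checkpoint(unsup, out_dir / "unsupervised.ckpt")

    ablated = stage("ablate", lambda: ablate_controller(full))

    def evaluate():
        test_idx = split[1]
        metrics = {}
        for name, model in (("full", full), ("unsupervised", unsup),
                            ("autonomous", ablated)):
            out = model.infer(dataset.spikes[test_idx])
            metrics[name] = {
                "bits_per_spike": bits_per_spike(out.rates, dataset.spikes[test_idx]),
                "bits_per_second": bits_per_second(out.rates, dataset.spikes[test_idx],
                                                   dataset.bin_width),
                "r2": r2_isotropic(dataset.behavior[test_idx], out.behavior_pred),
            }
        return metrics

    metrics = stage("eval", evaluate)
    record["metrics"] = metrics
    with open(out_dir / "metrics.json", "w") as f:
        json.dump(metrics, f, indent=2)
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(record, f, indent=2)
    return metrics
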