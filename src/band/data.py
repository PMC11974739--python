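"""Trial-aligned data containers, on-disk bundles, filtering and splitting.

The universal container is :class:`TrialDataset`: binned spike counts with
paired continuous behavior, per-trial condition (reach target) and epoch
labels.  Bundles are single HDF5 files; an optional NWB reader is provided
when ``pynwb`` is importable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "TrialDataset",
    "SplitSpec",
    "BundleFormatError",
    "save_trial_bundle",
    "load_trial_bundle",
    "load_nwb_bundle",
    "filter_extreme_velocity_trials",
    "split_trials",
]

EPOCHS = ("BL", "AD", "WO")
_EPOCH_CODE = {name: i for i, name in enumerate(EPOCHS)}


class BundleFormatError(ValueError):
    """Raised when an on-disk bundle is missing fields or cannot be parsed."""


@dataclass
class TrialDataset:
    """Binned spikes + behavior with per-trial labels.

    spikes    : (trials, T, N) non-negative integer counts
    behavior  : (trials, T, B) real-valued, ``behavior_units`` (default cm/s)
    bin_width : seconds per bin
    condition : (trials,) integer target label, 1..C
    epoch     : (trials,) strings in {"BL", "AD", "WO"}
    alignment : "go_cue" or "movement_onset"
    prep_bins : bins in the preparatory window (0 < prep_bins < T)
    """

    spikes: np.ndarray
    behavior: np.ndarray
    bin_width: float
    condition: np.ndarray
    epoch: np.ndarray
    alignment: str = "movement_onset"
    prep_bins: int = 25
    behavior_units: str = "cm/s"
    neuron_group: np.ndarray | None = None  # optional per-neuron area label

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        self.behavior = np.asarray(self.behavior, dtype=np.float64)
        self.condition = np.asarray(self.condition, dtype=np.int64)
        self.epoch = np.asarray(self.epoch, dtype="U2")
        self.validate()

    # -- invariants -----------------------------------------------------------

    def validate(self):
        if self.spikes.ndim != 3:
            raise ValueError(f"spikes must be 3-D (trials, T, N); got {self.spikes.shape}")
        if self.behavior.ndim != 3:
            raise ValueError(f"behavior must be 3-D (trials, T, B); got {self.behavior.shape}")
        if np.isnan(self.behavior).any():
            raise ValueError("behavior contains NaN")
        if not np.issubdtype(self.spikes.dtype, np.integer):
            as_int = np.asarray(self.spikes)
            if not np.all(as_int == np.round(as_int)) or np.isnan(as_int).any():
                raise ValueError("spikes must be integral counts")
            self.spikes = as_int.astype(np.int64)
        if (self.spikes < 0).any():
            raise ValueError("spikes must be non-negative")
        if self.spikes.shape[:2] != self.behavior.shape[:2]:
            raise ValueError(
                f"spikes {self.spikes.shape} and behavior {self.behavior.shape} "
                "must share (trials, T)"
            )
        if self.condition.shape != (self.n_trials,):
            raise ValueError("condition must have one label per trial")
        if self.epoch.shape != (self.n_trials,):
            raise ValueError("epoch must have one label per trial")
        bad = set(np.unique(self.epoch)) - set(EPOCHS)
        if bad:
            raise ValueError(f"unknown epoch labels: {sorted(bad)}")
        if self.alignment not in ("go_cue", "movement_onset"):
            raise ValueError(f"unknown alignment: {self.alignment!r}")
        if not (0 < self.prep_bins < self.T):
            raise ValueError(f"prep_bins must be in (0, T={self.T}); got {self.prep_bins}")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")

    # -- convenience ----------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def T(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[2]

    @property
    def n_behavior(self) -> int:
        return self.behavior.shape[2]

    @property
    def move_bins(self) -> int:
        return self.T - self.prep_bins

    def subset(self, indices) -> "TrialDataset":
        indices = np.asarray(indices)
        return replace(
            self,
            spikes=self.spikes[indices],
            behavior=self.behavior[indices],
            condition=self.condition[indices],
            epoch=self.epoch[indices],
        )

    def epoch_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.epoch == name)

    def equals(self, other: "TrialDataset") -> bool:
        return (
            np.array_equal(self.spikes, other.spikes)
            and np.array_equal(self.behavior, other.behavior)
            and np.array_equal(self.condition, other.condition)
            and np.array_equal(self.epoch, other.epoch)
            and self.bin_width == other.bin_width
            and self.prep_bins == other.prep_bins
            and self.alignment == other.alignment
            and self.behavior_units == other.behavior_units
        )


# -- on-disk bundle -----------------------------------------------------------

def save_trial_bundle(dataset: TrialDataset, path) -> str:
    """Write a dataset to a single HDF5 file; round-trips bit-exactly."""
    dataset.validate()
    epoch_codes = np.array([_EPOCH_CODE[e] for e in dataset.epoch], dtype=np.int8)
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=dataset.spikes.astype(np.int32))
        f.create_dataset("behavior", data=dataset.behavior.astype(np.float64))
        f.create_dataset("condition", data=dataset.condition.astype(np.int64))
        ep = f.create_dataset("epoch", data=epoch_codes)
        ep.attrs["legend"] = ",".join(EPOCHS)
        f.attrs["bin_width_s"] = dataset.bin_width
        f.attrs["prep_bins"] = dataset.prep_bins
        f.attrs["alignment"] = dataset.alignment
        f.attrs["units"] = dataset.behavior_units
        if dataset.neuron_group is not None:
            f.create_dataset(
                "neuron_group", data=np.asarray(dataset.neuron_group, dtype="S16")
            )
    return str(path)


def load_trial_bundle(path) -> TrialDataset:
    """Load and validate a bundle written by :func:`save_trial_bundle`."""
    try:
        with h5py.File(path, "r") as f:
            for key in ("spikes", "behavior", "condition", "epoch"):
                if key not in f:
                    raise BundleFormatError(f"bundle missing required array: {key!r}")
            for key in ("bin_width_s", "prep_bins", "alignment", "units"):
                if key not in f.attrs:
                    raise BundleFormatError(f"bundle missing required attribute: {key!r}")
            epoch_codes = f["epoch"][...]
            legend = f["epoch"].attrs.get("legend", ",".join(EPOCHS)).split(",")
            epoch = np.array([legend[c] for c in epoch_codes], dtype="U2")
            group = f["neuron_group"][...].astype("U16") if "neuron_group" in f else None
            return TrialDataset(
                spikes=f["spikes"][...].astype(np.int64),
                behavior=f["behavior"][...],
                bin_width=float(f.attrs["bin_width_s"]),
                condition=f["condition"][...],
                epoch=epoch,
                alignment=str(f.attrs["alignment"]),
                prep_bins=int(f.attrs["prep_bins"]),
                behavior_units=str(f.attrs["units"]),
                neuron_group=group,
            )
    except OSError as exc:  # truncated / non-HDF5 file
        raise BundleFormatError(f"cannot parse bundle {path}: {exc}") from exc


def load_nwb_bundle(path, spikes_series: str, behavior_series: str,
                    **dataset_kwargs) -> TrialDataset:
    """Read binned counts and behavior from named series in an NWB file.

    Requires the optional ``pynwb`` dependency.
    """
    try:
        import pynwb  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "reading NWB files requires the optional dependency 'pynwb'"
        ) from exc
    from pynwb import NWBHDF5IO

    with NWBHDF5IO(str(path), "r") as io:
        nwb = io.read()
        objs = {}
        for name in (spikes_series, behavior_series):
            found = None
            for mod in nwb.processing.values():
                if name in mod.data_interfaces:
                    found = mod.data_interfaces[name]
            if found is None and name in nwb.acquisition:
                found = nwb.acquisition[name]
            if found is None:
                raise BundleFormatError(f"series {name!r} not found in NWB file")
            objs[name] = np.asarray(found.data)
        return TrialDataset(
            spikes=objs[spikes_series], behavior=objs[behavior_series], **dataset_kwargs
        )


# -- trial filtering ----------------------------------------------------------

_SPEED_IN_M_PER_S = {"m/s": 1.0, "cm/s": 0.01, "mm/s": 0.001}


def filter_extreme_velocity_trials(
    dataset: TrialDataset, max_speed: float = 1.0, max_speed_units: str = "m/s"
):
    """Drop trials whose Euclidean speed exceeds ``max_speed`` at any bin.

    Units are reconciled before comparing: the threshold and the dataset's
    behavior units are both converted to m/s.  Returns the kept dataset (order
    preserved) and the excluded trial indices.
    """
    if dataset.behavior_units not in _SPEED_IN_M_PER_S:
        raise ValueError(
            f"cannot interpret behavior units {dataset.behavior_units!r} as a speed"
        )
    if max_speed_units not in _SPEED_IN_M_PER_S:
        raise ValueError(f"unknown speed units {max_speed_units!r}")
    threshold = max_speed * _SPEED_IN_M_PER_S[max_speed_units]
    speed = np.linalg.norm(dataset.behavior, axis=2) * _SPEED_IN_M_PER_S[dataset.behavior_units]
    excluded = np.flatnonzero((speed > threshold).any(axis=1))
    kept = np.setdiff1d(np.arange(dataset.n_trials), excluded)
    return dataset.subset(kept), excluded


# -- splitting ----------------------------------------------------------------

@dataclass
class SplitSpec:
    """Holdout or k-fold split specification; deterministic given ``seed``."""

    scheme: str = "holdout"
    train_fraction: float = 0.8
    k: int = 5
    seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        if self.scheme not in ("holdout", "kfold"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "holdout" and not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")


def _stratifiable(condition: np.ndarray, k: int) -> bool:
    _, counts = np.unique(condition, return_counts=True)
    return bool((counts >= k).all())


def split_trials(dataset: TrialDataset, spec: SplitSpec):
    """Return (train_idx, test_idx) for holdout, or a list of k folds.

    Each fold is a (train_idx, test_idx) pair; test folds are disjoint and
    exhaustive.  Splits are stratified by condition label when every condition
    has at least k (holdout: 2) trials.
    """
    n = dataset.n_trials
    rng = np.random.default_rng(spec.seed)
    if spec.scheme == "holdout":
        n_train = math.ceil(spec.train_fraction * n)
        if n < 2:
            raise ValueError("holdout split needs at least 2 trials")
        if spec.stratify and _stratifiable(dataset.condition, 2):
            train_idx = _stratified_take(dataset.condition, n_train, rng)
        else:
            perm = rng.permutation(n)
            train_idx = np.sort(perm[:n_train])
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        return np.sort(train_idx), test_idx

    if n < spec.k:
        raise ValueError(f"cannot make {spec.k} folds from {n} trials")
    if spec.stratify and _stratifiable(dataset.condition, spec.k):
        assignment = np.empty(n, dtype=np.int64)
        for cond in np.unique(dataset.condition):
            idx = np.flatnonzero(dataset.condition == cond)
            idx = rng.permutation(idx)
            assignment[idx] = np.arange(len(idx)) % spec.k
    else:
        assignment = rng.permutation(np.arange(n) % spec.k)
    folds = []
    for fold in range(spec.k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        folds.append((train_idx, test_idx))
    return folds


def _stratified_take(condition: np.ndarray, n_train: int, rng) -> np.ndarray:
    """Pick n_train indices with per-condition counts by largest remainder."""
    n = len(condition)
    conds, counts = np.unique(condition, return_counts=True)
    exact = counts * (n_train / n)
    base = np.floor(exact).astype(int)
    short = n_train - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    picked = []
    for cond, take in zip(conds, base):
        idx = rng.permutation(np.flatnonzero(condition == cond))
        picked.append(idx[:take])
    return np.sort(np.concatenate(picked))
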