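"""Synthetic center-out-reach generator with full ground truth.

The latent state has a fixed block structure (``n_factors_true >= 6``):

* factors 0-1: "planned" rotation plane.  The initial state sits on a ring at
  the target angle and rotates with period ``rotation_period``; with
  ``rotate_during_prep`` off it is held constant until movement onset.
* factors 2-3: corrective factors.  In adaptation (AD) trials only, a decaying
  sinusoid at ``osc_freq`` with per-trial random phase, onset jitter and
  direction is injected here.  These factors drive behavior directly but have
  exactly zero loading on log-rates: the neural trace of a correction appears
  only through the feedback path below.
* factors 4-5: feedback factors, carrying the full 2-D behavior delayed by
  ``feedback_lag`` and scaled by ``feedback_gain``.  These do load on
  log-rates, so spikes reflect behavior with a positive delay -- the
  ground-truth negative-lag (behavior-leads) relationship used in the lag
  recovery analyses.
* factors 6+: optional extra "nuisance" dimensions with damped noise dynamics
  and neural-only loadings.

Behavior is a linear readout of the planned and corrective blocks; spikes are
Poisson draws from an exponential affine readout of all factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TrialDataset

__all__ = [
    "SimConfig",
    "SyntheticGroundTruth",
    "simulate_latents",
    "emit_spikes",
    "generate_dataset",
    "verify_latent_recursion",
]


@dataclass
class SimConfig:
    n_neurons: int = 30
    n_factors_true: int = 6
    T: int = 55
    prep_bins: int = 25
    bin_width: float = 0.01
    n_targets: int = 8
    # trials per target, per epoch
    trials_per_epoch: dict = field(default_factory=lambda: {"BL": 10, "AD": 10, "WO": 10})
    rotation_period: float = 1.1
    osc_freq: float = 5.0
    osc_onset_jitter: float = 0.08
    osc_amplitude: float = 34.0         # cm/s, peak of the corrective sinusoid
    osc_decay: float = 0.45             # s, exponential decay of the correction
    feedback_lag: float = 0.090
    feedback_gain: float = 0.050
    base_rate: float = 45.0             # Hz
    noise_sd: float = 0.010              # latent state noise per bin
    seed: int = 0
    # readout scales (not spec'd by any reference; exposed for experiments)
    v_scale: float = 7.0                # cm/s, planned velocity magnitude
    # rotate the planned factors during preparation as well (a single linear
    # mode over the whole trial) instead of holding them constant until
    # movement onset; either way the initial state is set by the target
    rotate_during_prep: bool = False
    loading_planned: float = 0.8
    loading_feedback: float = 0.40
    loading_extra: float = 0.15
    rate_spread: float = 0.4            # lognormal sd of per-neuron base rates

    def __post_init__(self):
        if self.n_factors_true < 6:
            raise ValueError("n_factors_true must be >= 6 (2 planned + 2 corrective + 2 feedback)")
        nyquist = 1.0 / (2.0 * self.bin_width)
        if self.osc_freq >= nyquist:
            raise ValueError(f"osc_freq {self.osc_freq} Hz >= Nyquist {nyquist} Hz")
        if self.feedback_lag < 0:
            raise ValueError("feedback_lag must be >= 0")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not (0 < self.prep_bins < self.T):
            raise ValueError("prep_bins must be in (0, T)")

    @property
    def feedback_lag_bins(self) -> int:
        return int(round(self.feedback_lag / self.bin_width))

    @property
    def n_trials(self) -> int:
        return self.n_targets * sum(self.trials_per_epoch.values())


@dataclass
class SyntheticGroundTruth:
    """True latents, inputs and readouts for recovery tests."""

    latents: np.ndarray            # (trials, T, F)
    corrective_input: np.ndarray   # (trials, T, F); zero outside AD transients
    readout_neural: tuple          # (W: F x N, b: N), log-rate in Hz
    readout_behavior: np.ndarray   # F x B
    feedback_lag_bins: int
    feedback_gain: float
    dynamics_prep: np.ndarray      # F x F state matrix during preparation
    dynamics_move: np.ndarray      # F x F state matrix during movement
    feedback_rows: np.ndarray      # factor indices receiving delayed behavior
    condition: np.ndarray
    epoch: np.ndarray
    config: SimConfig
    corrective_log_rate_share: float = np.nan
    corrective_behavior_share: float = np.nan

    def behavior(self, latents: np.ndarray | None = None) -> np.ndarray:
        z = self.latents if latents is None else latents
        return z @ self.readout_behavior

    def log_rates(self, latents: np.ndarray | None = None) -> np.ndarray:
        z = self.latents if latents is None else latents
        W, b = self.readout_neural
        return z @ W + b


def _state_matrices(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    F = config.n_factors_true
    A_prep = np.zeros((F, F))
    A_move = np.zeros((F, F))
    phi = 2.0 * np.pi * config.bin_width / config.rotation_period
    A_move[:2, :2] = [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
    A_prep[:2, :2] = A_move[:2, :2] if config.rotate_during_prep else np.eye(2)
    # corrective (2,3) and feedback (4,5) rows are pure inputs: zero dynamics
    for j in range(6, F):
        A_prep[j, j] = A_move[j, j] = 0.9
    return A_prep, A_move


def _readouts(config: SimConfig, rng: np.random.Generator):
    F, N = config.n_factors_true, config.n_neurons
    Wb = np.zeros((F, 2))
    Wb[:2, :2] = config.v_scale * np.eye(2)   # planned velocity
    Wb[2:4, :2] = np.eye(2)                   # corrective, already in cm/s
    Wn = np.zeros((F, N))
    Wn[:2] = rng.normal(0.0, config.loading_planned, size=(2, N))
    # corrective rows stay exactly zero: corrections are neurally silent
    # except through the lagged feedback factors
    Wn[4:6] = rng.normal(0.0, config.loading_feedback, size=(2, N))
    if F > 6:
        Wn[6:] = rng.normal(0.0, config.loading_extra, size=(F - 6, N))
    bn = np.log(config.base_rate) + rng.normal(0.0, config.rate_spread, size=N)
    return Wn, bn, Wb


def simulate_latents(config: SimConfig) -> SyntheticGroundTruth:
    """Generate ground-truth latents, corrective inputs and readouts."""
    rng = np.random.default_rng([config.seed, 0])
    F, T, prep = config.n_factors_true, config.T, config.prep_bins
    A_prep, A_move = _state_matrices(config)
    Wn, bn, Wb = _readouts(config, rng)
    lag = config.feedback_lag_bins
    dt = config.bin_width

    trials = []
    conditions = []
    epochs = []
    for epoch in ("BL", "AD", "WO"):
        count = config.trials_per_epoch.get(epoch, 0)
        for _ in range(count):
            for target in range(1, config.n_targets + 1):
                trials.append(epoch)
                conditions.append(target)
                epochs.append(epoch)
    n_trials = len(trials)
    condition = np.array(conditions, dtype=np.int64)
    epoch_arr = np.array(epochs, dtype="U2")

    latents = np.zeros((n_trials, T, F))
    corrective = np.zeros((n_trials, T, F))
    behavior = np.zeros((n_trials, T, 2))
    jitter_max = max(int(round(config.osc_onset_jitter / dt)), 0)

    for i in range(n_trials):
        angle = 2.0 * np.pi * (condition[i] - 1) / config.n_targets
        z = np.zeros(F)
        z[:2] = [np.cos(angle), np.sin(angle)]
        z[:2] += rng.normal(0.0, config.noise_sd, size=2)

        # per-trial corrective input (AD epoch only)
        s = np.zeros((T, 2))
        if epoch_arr[i] == "AD" and config.osc_amplitude > 0:
            t0 = prep + rng.integers(0, jitter_max + 1)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            psi = rng.uniform(0.0, 2.0 * np.pi)
            direction = np.array([np.cos(psi), np.sin(psi)])
            tt = np.arange(T)
            rel = (tt - t0) * dt
            env = np.where(tt >= t0, np.exp(-np.maximum(rel, 0.0) / config.osc_decay), 0.0)
            wave = config.osc_amplitude * env * np.sin(2.0 * np.pi * config.osc_freq * rel + phase)
            s = wave[:, None] * direction[None, :]
        corrective[i, :, 2:4] = s

        for t in range(T):
            if t > 0:
                A = A_prep if t <= prep else A_move
                z = A @ z
                noise = rng.normal(0.0, config.noise_sd, size=F)
                noise[4:6] = 0.0  # feedback rows are deterministic inputs
                z = z + noise
            z[2:4] = corrective[i, t, 2:4] + (
                rng.normal(0.0, 0.5 * config.noise_sd, size=2) if config.noise_sd > 0 else 0.0
            )
            if t - lag >= 0 and config.feedback_gain != 0.0:
                z[4:6] = config.feedback_gain * behavior[i, t - lag]
            else:
                z[4:6] = 0.0
            latents[i, t] = z
            behavior[i, t] = z @ Wb

    truth = SyntheticGroundTruth(
        latents=latents,
        corrective_input=corrective,
        readout_neural=(Wn, bn),
        readout_behavior=Wb,
        feedback_lag_bins=lag,
        feedback_gain=config.feedback_gain,
        dynamics_prep=A_prep,
        dynamics_move=A_move,
        feedback_rows=np.array([4, 5]),
        condition=condition,
        epoch=epoch_arr,
        config=config,
    )
    _variance_shares(truth)
    return truth


def _variance_shares(truth: SyntheticGroundTruth):
    """Amplitude bookkeeping: how much the corrective input contributes.

    The corrective input reaches behavior directly (factors 2-3) and reaches
    log-rates only through the delayed feedback factors.  Both shares are
    computed on AD trials and stored on the ground truth.
    """
    cfg = truth.config
    ad = np.flatnonzero(truth.epoch == "AD")
    if len(ad) == 0:
        return
    Wn, _ = truth.readout_neural
    Wb = truth.readout_behavior
    lag = truth.feedback_lag_bins

    corr_behavior = truth.corrective_input[ad] @ Wb        # direct path
    total_behavior = truth.behavior()[ad]
    truth.corrective_behavior_share = float(
        corr_behavior.var() / max(total_behavior.var(), 1e-30)
    )

    # corrective contribution to log-rates: delayed behavior * gain through
    # the feedback rows
    shifted = np.zeros_like(corr_behavior)
    if lag < corr_behavior.shape[1]:
        shifted[:, lag:] = corr_behavior[:, : corr_behavior.shape[1] - lag]
    corr_lograte = (truth.feedback_gain * shifted) @ Wn[truth.feedback_rows]
    total_lograte = truth.log_rates()[ad]
    centered = total_lograte - total_lograte.mean(axis=(0, 1), keepdims=True)
    truth.corrective_log_rate_share = float(
        corr_lograte.var() / max(centered.var(), 1e-30)
    )


def emit_spikes(truth: SyntheticGroundTruth, config: SimConfig) -> TrialDataset:
    """Draw Poisson spike counts from the exponential affine rate readout."""
    rng = np.random.default_rng([config.seed, 1])
    log_rates = truth.log_rates()                      # Hz
    lam = np.exp(log_rates) * config.bin_width         # spikes per bin
    if not np.isfinite(lam).all() or lam.max() > 50.0:
        raise FloatingPointError(
            f"rate overflow: max expected count per bin {lam.max():.3g}"
        )
    spikes = rng.poisson(lam).astype(np.int64)
    return TrialDataset(
        spikes=spikes,
        behavior=truth.behavior(),
        bin_width=config.bin_width,
        condition=truth.condition,
        epoch=truth.epoch,
        alignment="movement_onset",
        prep_bins=config.prep_bins,
        behavior_units="cm/s",
    )


def generate_dataset(config: SimConfig):
    """Simulate latents and emit spikes; returns (TrialDataset, truth)."""
    truth = simulate_latents(config)
    dataset = emit_spikes(truth, config)
    return dataset, truth


def verify_latent_recursion(truth: SyntheticGroundTruth) -> float:
    """Max residual of the latent update rule with inputs accounted for.

    With the corrective input and the delayed-behavior feedback subtracted,
    the remaining state must follow the (noiseless) piecewise-linear
    recursion; returns the maximum absolute residual over all trials/bins.
    Only meaningful for ``noise_sd == 0`` configurations.
    """
    cfg = truth.config
    z = truth.latents
    b = truth.behavior()
    lag = truth.feedback_lag_bins
    worst = 0.0
    for t in range(1, cfg.T):
        A = truth.dynamics_prep if t <= cfg.prep_bins else truth.dynamics_move
        pred = z[:, t - 1] @ A.T
        pred[:, 2:4] = truth.corrective_input[:, t, 2:4]
        if t - lag >= 0 and truth.feedback_gain != 0.0:
            pred[:, 4:6] = truth.feedback_gain * b[:, t - lag]
        else:
            pred[:, 4:6] = 0.0
        worst = max(worst, float(np.abs(z[:, t] - pred).max()))
    return worst
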