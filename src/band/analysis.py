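"""Analysis battery: baselines, spectra, oscillation detection and lag profiles.

Covers the condition-average behavior baseline, ridge seq2seq decoding from
inferred factors, a bidirectional recurrent decoder ceiling, Gaussian rate
smoothing, per-trial FFT spectra, shuffle-null oscillatory-neuron detection,
FFT phase similarity, decoder-weight diagonal lag profiles, fixed-lag
regression and full-vs-ablated controller contribution decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import Ridge

from .autodiff import Tensor, concat, stack
from .data import TrialDataset
from .metrics import bits_per_spike, explained_behavior_variance, r2_isotropic
from .model import BandModel, DecoderWeightMatrix
from .nn import Adam, GRUCell, Linear, Module, clip_grad_norm

__all__ = [
    "SpectrumResult",
    "LagProfile",
    "condition_average_predictor",
    "fit_seq2seq_ridge",
    "BiRNNDecoder",
    "train_birnn_decoder",
    "smooth_rates_gaussian",
    "fft_amplitude_spectrum",
    "detect_oscillatory_neurons",
    "fft_phase_similarity",
    "diagonal_lag_profile",
    "aggregate_lag_profile",
    "fixed_lag_regression",
    "controller_contribution",
]


@dataclass
class SpectrumResult:
    """Per-trial discrete Fourier spectrum (unnormalized forward transform).

    With this normalization, Parseval reads
    ``sum(signal**2) = (|X_0|^2 + 2*sum_mid |X_k|^2 [+ |X_nyq|^2]) / T``.
    """

    frequencies: np.ndarray       # (n_modes,), Hz; index 0 is DC
    coefficients: np.ndarray      # (trials, n_modes, ...) complex
    amplitude: np.ndarray         # |coefficients|
    power: np.ndarray             # amplitude**2
    mean_power: np.ndarray        # (n_modes, ...) trial average

    def mode_nearest(self, freq_hz: float) -> int:
        return int(np.argmin(np.abs(self.frequencies - freq_hz)))


@dataclass
class LagProfile:
    """Value per lag; negative lag = behavior leads the neural factors."""

    lags_s: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.lags_s)
        self.lags_s = np.asarray(self.lags_s)[order]
        self.values = np.asarray(self.values)[order]

    @property
    def peak_lag_s(self) -> float:
        return float(self.lags_s[np.argmax(self.values)])

    @property
    def peak_value(self) -> float:
        return float(np.max(self.values))


# -- baselines ----------------------------------------------------------------

def condition_average_predictor(dataset: TrialDataset, train_idx, test_idx):
    """Predict each test trial by its condition's training-mean time course."""
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    train_conditions = set(dataset.condition[train_idx])
    missing = set(dataset.condition[test_idx]) - train_conditions
    if missing:
        raise ValueError(f"conditions {sorted(missing)} absent from training set")
    means = {
        cond: dataset.behavior[train_idx][dataset.condition[train_idx] == cond].mean(axis=0)
        for cond in train_conditions
    }
    preds = np.stack([means[c] for c in dataset.condition[test_idx]])
    return preds, r2_isotropic(dataset.behavior[test_idx], preds)


def fit_seq2seq_ridge(factors: np.ndarray, behavior: np.ndarray, split,
                      ridge_strengths=(0.01, 0.1, 1.0, 10.0, 100.0),
                      val_fraction: float = 0.2, seed: int = 0):
    """Ridge map from flattened factor sequences to flattened behavior.

    ``split`` is (train_idx, test_idx); the ridge strength is selected on a
    held-out slice of the training trials.  Returns (test predictions,
    fitted Ridge, chosen alpha).
    """
    train_idx = np.asarray(split[0])
    test_idx = np.asarray(split[1])
    n_trials, T, B = behavior.shape
    X = factors.reshape(n_trials, -1)
    Y = behavior.reshape(n_trials, -1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train_idx)
    n_val = max(1, int(round(val_fraction * len(train_idx))))
    val, fit = perm[:n_val], perm[n_val:]
    if np.isscalar(ridge_strengths):
        ridge_strengths = [ridge_strengths]
    best_alpha, best_score = None, -np.inf
    for alpha in ridge_strengths:
        model = Ridge(alpha=alpha).fit(X[fit], Y[fit])
        score = r2_isotropic(Y[val].reshape(-1, T, B),
                             model.predict(X[val]).reshape(-1, T, B))
        if score > best_score:
            best_alpha, best_score = alpha, score
    model = Ridge(alpha=best_alpha).fit(X[train_idx], Y[train_idx])
    preds = model.predict(X[test_idx]).reshape(len(test_idx), T, B)
    return preds, model, best_alpha


class BiRNNDecoder(Module):
    """Bidirectional GRU from binned spikes to per-bin behavior.

    Serves as the non-latent decoding ceiling.  Defaults are placeholders
    chosen here (no authoritative reference values are available); they are
    fully governed by the constructor arguments.
    """

    def __init__(self, n_neurons: int, behavior_dims: int, hidden: int = 64,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fwd = GRUCell(n_neurons, hidden, rng)
        self.bwd = GRUCell(n_neurons, hidden, rng)
        self.head = Linear(2 * hidden, behavior_dims, rng)
        self.hidden = hidden

    def forward(self, spikes: np.ndarray) -> Tensor:
        batch, T, _ = spikes.shape
        steps = [Tensor(np.asarray(spikes[:, t], dtype=np.float64)) for t in range(T)]
        hf = Tensor(np.zeros((batch, self.hidden)))
        hb = Tensor(np.zeros((batch, self.hidden)))
        fwd_states, bwd_states = [], []
        for x in steps:
            hf = self.fwd(x, hf)
            fwd_states.append(hf)
        for x in reversed(steps):
            hb = self.bwd(x, hb)
            bwd_states.append(hb)
        bwd_states.reverse()
        outs = [self.head(concat([f, b], axis=1)) for f, b in zip(fwd_states, bwd_states)]
        return stack(outs, axis=1)

    def predict(self, spikes: np.ndarray) -> np.ndarray:
        return self.forward(spikes).data


def train_birnn_decoder(dataset: TrialDataset, split, hidden: int = 64,
                        epochs: int = 150, learning_rate: float = 3e-3,
                        grad_clip: float = 50.0, seed: int = 0):
    """Fit the biRNN decoder by MSE; returns (decoder, test preds, test R²)."""
    train_idx, test_idx = np.asarray(split[0]), np.asarray(split[1])
    dec = BiRNNDecoder(dataset.n_neurons, dataset.n_behavior, hidden=hidden, seed=seed)
    opt = Adam(dec.parameters(), lr=learning_rate)
    target = Tensor(dataset.behavior[train_idx])
    spikes = dataset.spikes[train_idx]
    for _ in range(epochs):
        dec.zero_grad()
        loss = ((dec.forward(spikes) - target) ** 2).mean()
        if not np.isfinite(loss.item()):
            raise FloatingPointError("biRNN training diverged")
        loss.backward()
        clip_grad_norm(dec.parameters(), grad_clip)
        opt.step()
    preds = dec.predict(dataset.spikes[test_idx])
    return dec, preds, r2_isotropic(dataset.behavior[test_idx], preds)


# -- spectra ------------------------------------------------------------------

def smooth_rates_gaussian(spikes: np.ndarray, sigma_s: float = 0.030,
                          bin_width: float = 0.01) -> np.ndarray:
    """Per-neuron, per-trial Gaussian smoothing of counts (reflect edges).

    The kernel is normalized, so the output stays in counts/bin and total
    counts are conserved for interior-supported input.
    """
    if sigma_s <= 0:
        raise ValueError("sigma must be positive")
    if sigma_s < bin_width / 2:
        import warnings
        warnings.warn("smoothing sigma below half a bin has little effect")
    return gaussian_filter1d(np.asarray(spikes, dtype=np.float64),
                             sigma=sigma_s / bin_width, axis=1, mode="reflect")


def fft_amplitude_spectrum(signal: np.ndarray, bin_width: float) -> SpectrumResult:
    """Per-trial DFT along the time axis (axis 1) of a (trials, T, ...) array."""
    signal = np.asarray(signal, dtype=np.float64)
    if np.isnan(signal).any():
        raise ValueError("signal contains NaN")
    T = signal.shape[1]
    coeffs = np.fft.rfft(signal, axis=1)
    freqs = np.fft.rfftfreq(T, bin_width)
    amp = np.abs(coeffs)
    power = amp**2
    return SpectrumResult(frequencies=freqs, coefficients=coeffs, amplitude=amp,
                          power=power, mean_power=power.mean(axis=0))


def detect_oscillatory_neurons(dataset: TrialDataset, band_hz=(4.0, 5.0),
                               n_shuffle: int = 500, threshold_sd: float = 4.0,
                               sigma_s: float = 0.030, seed: int = 0,
                               min_trials: int = 5):
    """Flag neurons with perturbation-induced oscillations in the given band.

    For each neuron and each band mode: the trial-mean power of the smoothed
    rate must exceed the shuffle-null mean + ``threshold_sd``·SD in adaptation
    trials while staying within the null band in baseline trials.  The null
    shuffles each trial's counts across time independently, re-smooths and
    re-FFTs.  Returns (flags, per-neuron diagnostics).
    """
    ad = dataset.epoch_indices("AD")
    bl = dataset.epoch_indices("BL")
    if len(ad) < min_trials or len(bl) < min_trials:
        raise ValueError(
            f"need at least {min_trials} trials per epoch; got AD={len(ad)}, BL={len(bl)}"
        )
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(dataset.T, dataset.bin_width)
    modes = sorted({int(np.argmin(np.abs(freqs - f))) for f in band_hz})

    def band_power(counts):  # counts: (..., trials, T) -> (..., n_modes)
        sm = gaussian_filter1d(counts.astype(np.float64),
                               sigma=sigma_s / dataset.bin_width,
                               axis=-1, mode="reflect")
        p = np.abs(np.fft.rfft(sm, axis=-1)) ** 2
        return p[..., modes].mean(axis=-2)  # trial-mean power per mode

    flags = np.zeros(dataset.n_neurons, dtype=bool)
    diagnostics = []
    for n in range(dataset.n_neurons):
        stats = {}
        for name, idx in (("AD", ad), ("BL", bl)):
            counts = dataset.spikes[idx, :, n]                  # (trials, T)
            observed = band_power(counts)
            tiled = np.broadcast_to(counts, (n_shuffle,) + counts.shape)
            shuffled = rng.permuted(tiled, axis=-1)
            null = band_power(shuffled)                         # (n_shuffle, n_modes)
            stats[name] = (observed, null.mean(axis=0), null.std(axis=0))
        induced = False
        for m in range(len(modes)):
            obs_ad, mu_ad, sd_ad = (s[m] for s in stats["AD"])
            obs_bl, mu_bl, sd_bl = (s[m] for s in stats["BL"])
            if obs_ad > mu_ad + threshold_sd * sd_ad and \
               obs_bl <= mu_bl + threshold_sd * sd_bl:
                induced = True
        flags[n] = induced
        diagnostics.append({
            "modes": modes,
            "AD_power": stats["AD"][0], "AD_null_mean": stats["AD"][1],
            "AD_null_sd": stats["AD"][2],
            "BL_power": stats["BL"][0], "BL_null_mean": stats["BL"][1],
            "BL_null_sd": stats["BL"][2],
        })
    return flags, diagnostics


def fft_phase_similarity(true_behavior: np.ndarray, pred_behavior: np.ndarray,
                         bin_width: float, per_trial: bool = False) -> dict:
    """Cosine similarity between Fourier coefficients of true and predicted
    behavior, per frequency mode.

    Default pooling treats each trial/component coefficient as an (Re, Im)
    pair and computes one amplitude-weighted cosine per mode; with
    ``per_trial`` the unweighted mean of per-trial phase cosines is returned.
    Modes with zero amplitude in the truth are reported as NaN.
    """
    if true_behavior.shape != pred_behavior.shape:
        raise ValueError("true and predicted behavior must have equal shapes")
    ct = np.fft.rfft(true_behavior, axis=1)
    cp = np.fft.rfft(pred_behavior, axis=1)
    freqs = np.fft.rfftfreq(true_behavior.shape[1], bin_width)
    n_modes = ct.shape[1]
    sims = np.full(n_modes, np.nan)
    for m in range(n_modes):
        a = ct[:, m].ravel()
        b = cp[:, m].ravel()
        na = np.linalg.norm(a)
        nb = np.linalg.norm(b)
        if na == 0:
            continue
        if per_trial:
            ok = (np.abs(a) > 0) & (np.abs(b) > 0)
            if not ok.any():
                continue
            sims[m] = float(np.mean(np.cos(np.angle(a[ok]) - np.angle(b[ok]))))
        elif nb > 0:
            sims[m] = float(np.real(np.vdot(a, b)) / (na * nb))
    return {"frequencies": freqs, "similarity": sims}


# -- lag analyses -------------------------------------------------------------

def diagonal_lag_profile(W: DecoderWeightMatrix, factor: int, behavior_dim: int,
                         movement_window: tuple, bin_width: float) -> LagProfile:
    """Sum the decoder weights along fixed factor-to-behavior time offsets.

    The window (start, stop) restricts both time axes to the movement phase.
    Lag = behavior time - factor time; converted to seconds.  Negative lag
    means behavior leads the neural factors.
    """
    start, stop = movement_window
    if not (0 <= start < stop <= W.T):
        raise ValueError(f"invalid movement window {movement_window} for T={W.T}")
    block = W.block(factor, behavior_dim)[start:stop, start:stop]
    M = block.shape[0]
    lags = np.arange(-(M - 1), M)
    values = np.array([np.trace(block, offset=int(l)) for l in lags])
    return LagProfile(lags_s=lags * bin_width, values=values)


def aggregate_lag_profile(W: DecoderWeightMatrix, movement_window: tuple,
                          bin_width: float) -> LagProfile:
    """Sum |diagonal profile| over all factor/behavior pairs.

    The factor basis of a trained model is arbitrary up to sign and rotation,
    so signed sums across pairs can cancel; aggregating absolute per-pair
    diagonal sums preserves lag structure.
    """
    total = None
    for f in range(W.n_factors):
        for b in range(W.behavior_dims):
            prof = diagonal_lag_profile(W, f, b, movement_window, bin_width)
            total = np.abs(prof.values) if total is None else total + np.abs(prof.values)
    return LagProfile(lags_s=prof.lags_s, values=total)


def fixed_lag_regression(latents: np.ndarray, behavior: np.ndarray, split,
                         bin_width: float, max_lag_s: float = 0.150,
                         movement_window: tuple | None = None,
                         ridge_alpha: float = 1.0) -> LagProfile:
    """Ridge regressions from the per-bin latent state to lagged behavior.

    For each lag in [-max_lag, +max_lag] (negative = behavior earlier than
    the latent state), fits on training trials and reports out-of-sample
    pooled R² on test trials.  ``movement_window`` restricts the latent time
    points used (defaults to all bins).
    """
    train_idx, test_idx = np.asarray(split[0]), np.asarray(split[1])
    T = latents.shape[1]
    start, stop = movement_window if movement_window is not None else (0, T)
    max_lag = int(round(max_lag_s / bin_width))
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.full(len(lags), np.nan)
    for i, lag in enumerate(lags):
        ts = [t for t in range(start, stop) if 0 <= t + lag < T]
        if not ts:
            raise ValueError(f"lag {lag} bins exhausts the trial length")
        X_tr = np.concatenate([latents[train_idx, t] for t in ts])
        Y_tr = np.concatenate([behavior[train_idx, t + lag] for t in ts])
        X_te = np.concatenate([latents[test_idx, t] for t in ts])
        Y_te = np.concatenate([behavior[test_idx, t + lag] for t in ts])
        model = Ridge(alpha=ridge_alpha).fit(X_tr, Y_tr)
        values[i] = r2_isotropic(Y_te, model.predict(X_te))
    return LagProfile(lags_s=lags * bin_width, values=values)


# -- controller contribution --------------------------------------------------

def controller_contribution(full_model: BandModel, ablated_model: BandModel,
                            dataset: TrialDataset) -> dict:
    """Per-trial, per-epoch and per-bin differences between full and ablated
    models: Δbits/spike (neural) and Δexplained behavior variance.
    """
    if ablated_model.config is not full_model.config and \
            ablated_model.config != full_model.config:
        raise ValueError("ablated model must derive from the full model")
    if not ablated_model.ablated:
        raise ValueError("second argument must be an ablated model")
    out_full = full_model.infer(dataset.spikes)
    out_ab = ablated_model.infer(dataset.spikes)

    n = dataset.n_trials
    d_bits = np.zeros(n)
    d_ev = np.zeros(n)
    for i in range(n):
        sp = dataset.spikes[i:i + 1]
        if sp.sum() > 0:
            d_bits[i] = (bits_per_spike(out_full.rates[i:i + 1], sp)
                         - bits_per_spike(out_ab.rates[i:i + 1], sp))
        d_ev[i] = (explained_behavior_variance(dataset.behavior[i:i + 1],
                                               out_full.behavior_pred[i:i + 1])
                   - explained_behavior_variance(dataset.behavior[i:i + 1],
                                                 out_ab.behavior_pred[i:i + 1]))

    per_epoch = {}
    for name in ("BL", "AD", "WO"):
        idx = dataset.epoch_indices(name)
        if len(idx) == 0:
            continue
        per_epoch[name] = {
            "d_bits_per_spike": float(d_bits[idx].mean()),
            "d_explained_variance": float(d_ev[idx].mean()),
        }

    # per-bin decomposition: Poisson ΔLL and behavior Δsquared-error per bin
    ll_full = (dataset.spikes * np.log(out_full.rates) - out_full.rates)
    ll_ab = (dataset.spikes * np.log(out_ab.rates) - out_ab.rates)
    per_bin_neural = (ll_full - ll_ab).sum(axis=2).mean(axis=0)
    se_full = ((dataset.behavior - out_full.behavior_pred) ** 2).sum(axis=2)
    se_ab = ((dataset.behavior - out_ab.behavior_pred) ** 2).sum(axis=2)
    per_bin_behavior = (se_ab - se_full).mean(axis=0)

    return {
        "per_trial_d_bits_per_spike": d_bits,
        "per_trial_d_explained_variance": d_ev,
        "per_epoch": per_epoch,
        "per_bin_d_loglik": per_bin_neural,
        "per_bin_d_behavior_se": per_bin_behavior,
        "total_d_bits_per_spike": float(
            bits_per_spike(out_full.rates, dataset.spikes)
            - bits_per_spike(out_ab.rates, dataset.spikes)),
        "total_d_explained_variance": float(
            explained_behavior_variance(dataset.behavior, out_full.behavior_pred)
            - explained_behavior_variance(dataset.behavior, out_ab.behavior_pred)),
    }
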