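"""Loss terms and evaluation metrics.

Includes the Poisson log-likelihood, diagonal-Gaussian KL, the composite
semi-supervised loss breakdown, bits/spike and bits/second against a
mean-rate null model, pooled ("isotropic") R², explained behavior variance,
and the two population-based-training objectives.

Likelihoods are in nats internally; only the bits metrics convert to base 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "poisson_log_likelihood",
    "kl_gaussian",
    "band_loss",
    "bits_per_spike",
    "bits_per_second",
    "r2_isotropic",
    "r2_per_component",
    "explained_behavior_variance",
    "pbt_objective",
    "pbt_objective_nlb",
    "select_heldout_neurons",
]

LN2 = np.log(2.0)


@dataclass
class LossWeights:
    """Weights of the composite objective; KL weights default to 1 (fixed)."""

    theta: float = 0.0       # behavior supervision weight
    alpha: float = 0.0       # L2 penalty weight on recurrent weights
    beta_kl_g0: float = 1.0
    beta_kl_u: float = 1.0

    def __post_init__(self):
        for name in ("theta", "alpha", "beta_kl_g0", "beta_kl_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LossBreakdown:
    """Additive terms of the training objective (a maximized quantity)."""

    L_x: float      # Poisson log-likelihood (nats)
    L_b: float      # negative behavior MSE
    L_L2: float     # squared-norm penalty on recurrent weights
    KL_g0: float
    KL_u: float
    weights: LossWeights

    @property
    def total(self) -> float:
        w = self.weights
        return (
            self.L_x
            + w.theta * self.L_b
            - w.alpha * self.L_L2
            - w.beta_kl_g0 * self.KL_g0
            - w.beta_kl_u * self.KL_u
        )


def poisson_log_likelihood(rates: np.ndarray, spikes: np.ndarray,
                           per_trial: bool = False):
    """Sum over all entries of ``y*ln(lam) - lam - ln(y!)``.

    ``rates`` are expected counts per bin (same shape as ``spikes``).  Returns
    the total in nats, and additionally a per-trial vector (summing over the
    trailing axes) when ``per_trial`` is true.
    """
    rates = np.asarray(rates, dtype=np.float64)
    spikes = np.asarray(spikes)
    if rates.shape != spikes.shape:
        raise ValueError(f"shape mismatch: rates {rates.shape} vs spikes {spikes.shape}")
    if (spikes < 0).any() or not np.all(spikes == np.round(spikes)):
        raise ValueError("spikes must be non-negative integers")
    if (rates <= 0).any():
        raise ValueError("rates must be strictly positive")
    ll = spikes * np.log(rates) - rates - gammaln(spikes + 1.0)
    total = float(ll.sum())
    if per_trial:
        axes = tuple(range(1, ll.ndim))
        return total, ll.sum(axis=axes)
    return total


def kl_gaussian(mean_q, sd_q, mean_p=0.0, sd_p=1.0) -> float:
    """Closed-form KL(q || p) for diagonal Gaussians, summed over all entries."""
    mean_q = np.asarray(mean_q, dtype=np.float64)
    sd_q = np.asarray(sd_q, dtype=np.float64)
    mean_p = np.broadcast_to(np.asarray(mean_p, dtype=np.float64), mean_q.shape)
    sd_p = np.broadcast_to(np.asarray(sd_p, dtype=np.float64), sd_q.shape)
    if (sd_q <= 0).any() or (sd_p <= 0).any():
        raise ValueError("standard deviations must be positive")
    term = (
        np.log(sd_p / sd_q)
        + (sd_q**2 + (mean_q - mean_p) ** 2) / (2.0 * sd_p**2)
        - 0.5
    )
    return float(term.sum())


def band_loss(trajectory, spikes, behavior, weights: LossWeights,
              l2_norm: float = 0.0) -> LossBreakdown:
    """Assemble the composite loss from an inferred trajectory.

    ``trajectory`` must expose ``rates``, ``behavior_pred``, ``g0_mean``,
    ``g0_sd``, ``u_mean``, ``u_sd`` (see :class:`band.model.LatentTrajectory`).
    L_x is summed over bins/neurons and averaged over trials; the MSE averages
    over trials, bins and components.
    """
    n_trials = spikes.shape[0]
    L_x = poisson_log_likelihood(trajectory.rates, spikes) / n_trials
    L_b = -float(np.mean((behavior - trajectory.behavior_pred) ** 2))
    KL_g0 = kl_gaussian(trajectory.g0_mean, trajectory.g0_sd) / n_trials
    if trajectory.u_mean is not None and trajectory.u_mean.size:
        KL_u = kl_gaussian(trajectory.u_mean, trajectory.u_sd) / n_trials
    else:
        KL_u = 0.0
    return LossBreakdown(L_x=L_x, L_b=L_b, L_L2=l2_norm, KL_g0=KL_g0,
                         KL_u=KL_u, weights=weights)


# -- bits metrics -------------------------------------------------------------

def _delta_ll_vs_null(rates, spikes):
    rates = np.asarray(rates, dtype=np.float64)
    spikes = np.asarray(spikes)
    if (rates <= 0).any():
        raise ValueError("rates must be strictly positive")
    # null model: each neuron's mean count per bin over the evaluated set
    axes = tuple(range(spikes.ndim - 1))
    null = spikes.mean(axis=axes, keepdims=True).astype(np.float64)
    null = np.maximum(null, 1e-10)
    ll_model = spikes * np.log(rates) - rates
    ll_null = spikes * np.log(null) - null
    return float((ll_model - ll_null).sum())


def bits_per_spike(rates, spikes) -> float:
    """Log-likelihood improvement over the mean-rate null, per spike, base 2."""
    n_sp = int(np.sum(spikes))
    if n_sp == 0:
        raise ValueError("no spikes in the evaluation set")
    return _delta_ll_vs_null(rates, spikes) / (LN2 * n_sp)


def bits_per_second(rates, spikes, bin_width: float) -> float:
    """bits/spike scaled by spikes per second of evaluated data."""
    spikes = np.asarray(spikes)
    total_seconds = spikes.size / spikes.shape[-1] * bin_width
    return _delta_ll_vs_null(rates, spikes) / (LN2 * total_seconds)


def bits_metric_as_printed(rates, spikes) -> float:
    """Debug variant with the base-2 log outside the sum.

    One printed form of the metric reads ``(1/n_sp) * log2(sum ΔL)``; it is
    undefined when the summed improvement is non-positive, in which case NaN
    is returned.  The established definition is :func:`bits_per_spike`.
    """
    n_sp = int(np.sum(spikes))
    delta = _delta_ll_vs_null(rates, spikes)
    if delta <= 0:
        return float("nan")
    return float(np.log2(delta) / n_sp)


# -- behavior metrics ---------------------------------------------------------

def _pooled_sums(true, pred):
    true = np.asarray(true, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if true.shape != pred.shape:
        raise ValueError(f"shape mismatch: {true.shape} vs {pred.shape}")
    flat_t = true.reshape(-1, true.shape[-1])
    flat_p = pred.reshape(-1, pred.shape[-1])
    grand = flat_t.mean(axis=0, keepdims=True)   # per-component grand mean
    sse = ((flat_t - flat_p) ** 2).sum()
    sst = ((flat_t - grand) ** 2).sum()
    return sse, sst, flat_t.size


def r2_isotropic(true, pred) -> float:
    """1 - SSE/SST pooled over trials, bins and behavior components."""
    sse, sst, _ = _pooled_sums(true, pred)
    if sst == 0:
        raise ValueError("behavior has zero variance")
    return 1.0 - sse / sst


def r2_per_component(true, pred) -> float:
    """Average of per-component R² (the common library convention)."""
    true = np.asarray(true, dtype=np.float64).reshape(-1, np.shape(true)[-1])
    pred = np.asarray(pred, dtype=np.float64).reshape(-1, np.shape(pred)[-1])
    vals = []
    for j in range(true.shape[1]):
        sst = ((true[:, j] - true[:, j].mean()) ** 2).sum()
        if sst == 0:
            raise ValueError(f"behavior component {j} has zero variance")
        vals.append(1.0 - ((true[:, j] - pred[:, j]) ** 2).sum() / sst)
    return float(np.mean(vals))


def explained_behavior_variance(true, pred) -> float:
    """Total variance minus mean squared error, in behavior units squared."""
    sse, sst, n = _pooled_sums(true, pred)
    return (sst - sse) / n


# -- PBT objectives -----------------------------------------------------------

def pbt_objective(L_x: float, n_neurons: int, n_bins: int, r2: float) -> float:
    """Normalized likelihood minus behavior deficit; maximize."""
    if n_neurons <= 0 or n_bins <= 0:
        raise ValueError("N and T must be positive")
    return L_x / (n_neurons * n_bins) - (1.0 - r2)


def pbt_objective_nlb(L_x: float, mse: float, theta: float = 1e-4) -> float:
    """Likelihood with a small fixed-weight behavior MSE penalty; maximize."""
    return L_x - theta * mse


# -- co-smoothing support -----------------------------------------------------

def select_heldout_neurons(n_neurons: int, fraction: float, seed: int) -> np.ndarray:
    """Seeded choice of held-out neuron indices for co-smoothing evaluation."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    k = max(1, int(round(fraction * n_neurons)))
    return np.sort(rng.choice(n_neurons, size=k, replace=False))
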