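"""Sequential autoencoder with behavior alignment.

Architecture (all recurrent cells are GRUs):

* an initial-condition encoder: bidirectional GRU restricted *by interface* to
  the first ``prep_bins`` bins of spiking, producing a Gaussian posterior over
  the generator's initial state ``g0``;
* a causal controller encoder: a strictly forward-in-time GRU over movement
  bins (optionally also fed the previous factor state), producing a per-bin
  Gaussian posterior over control inputs ``u``;
* a generator GRU unrolled for all bins (zero input during preparation),
  whose state is read out linearly into factors; rates are the exponential of
  an affine readout of factors (spikes/bin);
* a behavior decoder: a single affine map from the flattened factor sequence
  to the flattened behavior sequence (or a per-bin linear map).

Setting the behavior weight θ=0 recovers the unsupervised variant; ablating
the controller forces ``u`` to the prior mean (zero), leaving autonomous
dynamics driven by ``g0`` alone.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat, stack
from .metrics import LossWeights
from .nn import GRUCell, Linear, Module

__all__ = [
    "ModelConfig",
    "LatentTrajectory",
    "DecoderWeightMatrix",
    "BandModel",
    "ablate_controller",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


@dataclass
class ModelConfig:
    n_factors: int = 8
    n_control: int = 4
    generator_dim: int = 200
    encoder_dim: int = 64
    controller_dim: int | None = None     # defaults to encoder_dim
    prep_bins: int = 25
    causal_controller: bool = True
    controller_sees_factors: bool = True
    # movement bins of delay between spikes and the controller input; 0 gives
    # the controller same-bin access (causal; no future bins), >=1 makes
    # inference strictly one-step-ahead so control inputs cannot absorb the
    # current bin's Poisson noise
    controller_input_delay: int = 0
    behavior_dims: int = 2
    behavior_decoder: str = "seq2seq_linear"   # or "per_step_linear"
    behavior_loss_movement_only: bool = False
    u_prior: str = "iid"                       # or "ar1"
    u_prior_ar1_rho: float = 0.95
    # initial update-gate bias of the generator GRU; positive values start
    # the generator in a state-retaining regime, stabilizing the learning of
    # autonomous dynamics over long trials
    generator_update_bias: float = 0.0
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.n_control < 0:
            raise ValueError("n_control must be >= 0")
        if self.controller_input_delay < 0:
            raise ValueError("controller_input_delay must be >= 0")
        if self.behavior_decoder not in ("seq2seq_linear", "per_step_linear"):
            raise ValueError(f"unknown behavior_decoder {self.behavior_decoder!r}")
        if self.u_prior not in ("iid", "ar1"):
            raise ValueError(f"unknown u_prior {self.u_prior!r}")
        if not self.causal_controller:
            raise ValueError(
                "only the causal controller is implemented; the non-causal "
                "variant is intentionally unsupported"
            )
        if isinstance(self.weights, dict):
            self.weights = LossWeights(**self.weights)

    @property
    def ctrl_dim(self) -> int:
        return self.controller_dim if self.controller_dim is not None else self.encoder_dim


@dataclass
class LatentTrajectory:
    """Inferred posterior statistics and generated quantities for a batch."""

    g0_mean: np.ndarray        # (trials, generator_dim)
    g0_sd: np.ndarray
    u_mean: np.ndarray | None  # (trials, T - prep_bins, n_control); None if no controller
    u_sd: np.ndarray | None
    factors: np.ndarray        # (trials, T, n_factors)
    rates: np.ndarray          # (trials, T, N), spikes/bin, strictly positive
    behavior_pred: np.ndarray  # (trials, T, B)

    def __post_init__(self):
        if (self.rates <= 0).any():
            raise ValueError("rates must be strictly positive")


@dataclass
class DecoderWeightMatrix:
    """The (T·factors) x (T·behavior) affine map of the seq2seq decoder.

    Flattened-factor index order is (time, factor); flattened-behavior index
    order is (time, component), matching ``factors.reshape(trials, T*F)``.
    """

    weights: np.ndarray   # (T * n_factors, T * behavior_dims)
    bias: np.ndarray      # (T * behavior_dims,)
    T: int
    n_factors: int
    behavior_dims: int

    def block(self, factor: int, behavior_dim: int) -> np.ndarray:
        """T x T view: rows = factor time, columns = behavior time."""
        w = self.weights.reshape(self.T, self.n_factors, self.T, self.behavior_dims)
        return w[:, factor, :, behavior_dim]

    def apply(self, factors: np.ndarray) -> np.ndarray:
        flat = factors.reshape(factors.shape[0], self.T * self.n_factors)
        out = flat @ self.weights + self.bias
        return out.reshape(factors.shape[0], self.T, self.behavior_dims)


class _Forward:
    """Graph-side forward results (Tensors), used to assemble training losses."""

    __slots__ = ("g0_mean", "g0_logvar", "u_mean", "u_logvar", "factors",
                 "log_rates", "rates", "behavior_pred")


class BandModel(Module):
    def __init__(self, config: ModelConfig, n_neurons: int, T: int, seed: int = 0):
        if config.prep_bins >= T:
            raise ValueError(f"prep_bins {config.prep_bins} must be < T {T}")
        if config.n_control > 0 and T - config.prep_bins <= 0:
            raise ValueError("controller requested but there are no movement bins")
        self.config = config
        self.n_neurons = n_neurons
        self.T = T
        self.ablated = False
        rng = np.random.default_rng(seed)
        cfg = config
        enc, gen = cfg.encoder_dim, cfg.generator_dim

        self.ic_fwd = GRUCell(n_neurons, enc, rng)
        self.ic_bwd = GRUCell(n_neurons, enc, rng)
        self.ic_readout = Linear(2 * enc, 2 * gen, rng)
        if cfg.n_control > 0:
            con_in = n_neurons + (cfg.n_factors if cfg.controller_sees_factors else 0)
            self.con_cell = GRUCell(con_in, cfg.ctrl_dim, rng)
            self.con_readout = Linear(cfg.ctrl_dim, 2 * cfg.n_control, rng)
        self.gen_cell = GRUCell(cfg.n_control, gen, rng,
                                update_bias=cfg.generator_update_bias)
        self.fac_readout = Linear(gen, cfg.n_factors, rng, bias=False)
        self.rate_readout = Linear(cfg.n_factors, n_neurons, rng, scale=0.1)
        if cfg.behavior_decoder == "seq2seq_linear":
            self.decoder = Linear(T * cfg.n_factors, T * cfg.behavior_dims, rng, scale=0.0)
        else:
            self.decoder = Linear(cfg.n_factors, cfg.behavior_dims, rng, scale=0.0)

    # -- forward pass ---------------------------------------------------------

    def forward(self, spikes: np.ndarray, sample: bool = False,
                rng: np.random.Generator | None = None,
                force_u_zero: bool = False,
                heldout_neurons: np.ndarray | None = None,
                heldout_rescale: bool = False,
                input_dropout: float = 0.0,
                neuron_dropout: float = 0.0) -> _Forward:
        """Build the full computation graph for a batch of trials.

        ``spikes``: (trials, T, N).  In eval mode (``sample=False``) posterior
        means are used and the pass is deterministic.  ``heldout_neurons``
        masks the named neurons from both encoders (co-smoothing); rates are
        still produced for all neurons.
        """
        cfg = self.config
        if spikes.ndim != 3 or spikes.shape[1] != self.T or spikes.shape[2] != self.n_neurons:
            raise ValueError(
                f"expected spikes (trials, {self.T}, {self.n_neurons}); got {spikes.shape}"
            )
        if sample and rng is None:
            raise ValueError("sampling requires an rng")
        enc_input = np.asarray(spikes, dtype=np.float64)
        if heldout_neurons is not None:
            enc_input = enc_input.copy()
            if heldout_rescale:
                # mirror inverted neuron dropout so that masked evaluation
                # stays in the input distribution seen during training
                frac = len(np.atleast_1d(heldout_neurons)) / self.n_neurons
                enc_input /= (1.0 - frac)
            enc_input[:, :, heldout_neurons] = 0.0
        if neuron_dropout > 0.0:
            # whole neurons silenced per trial, constant over time
            # (co-smoothing-style masking, inverted scaling on the rest)
            keep = (rng.random((enc_input.shape[0], 1, enc_input.shape[2]))
                    >= neuron_dropout)
            enc_input = enc_input * keep / (1.0 - neuron_dropout)
        if input_dropout > 0.0:
            keep = (rng.random(enc_input.shape) >= input_dropout)
            enc_input = enc_input * keep / (1.0 - input_dropout)

        batch = enc_input.shape[0]
        prep = cfg.prep_bins
        force_zero = force_u_zero or self.ablated
        out = _Forward()

        # initial-condition encoder: interface limited to the first prep bins
        prep_flat = Tensor(enc_input[:, :prep].reshape(batch * prep, -1))
        gates_f = self.ic_fwd.input_gates(prep_flat).reshape(
            batch, prep, 3 * cfg.encoder_dim)
        gates_b = self.ic_bwd.input_gates(prep_flat).reshape(
            batch, prep, 3 * cfg.encoder_dim)
        hf = Tensor(np.zeros((batch, cfg.encoder_dim)))
        hb = Tensor(np.zeros((batch, cfg.encoder_dim)))
        for t in range(prep):
            hf = self.ic_fwd.step_pre(gates_f[:, t], hf)
        for t in reversed(range(prep)):
            hb = self.ic_bwd.step_pre(gates_b[:, t], hb)
        ic = self.ic_readout(concat([hf, hb], axis=1))
        g0_mean = ic[:, : cfg.generator_dim]
        g0_logvar = ic[:, cfg.generator_dim:]
        out.g0_mean, out.g0_logvar = g0_mean, g0_logvar
        if sample:
            eps = Tensor(rng.standard_normal((batch, cfg.generator_dim)))
            g0 = g0_mean + (g0_logvar * 0.5).exp() * eps
        else:
            g0 = g0_mean

        h = g0.tanh()
        use_controller = cfg.n_control > 0
        if use_controller:
            c = Tensor(np.zeros((batch, cfg.ctrl_dim)))
            n_move = self.T - prep
            move_flat = Tensor(enc_input[:, prep:].reshape(batch * n_move, -1))
            spike_gates = (move_flat @ self.con_cell.Wx[: self.n_neurons]
                           + self.con_cell.b).reshape(batch, n_move,
                                                      3 * cfg.ctrl_dim)
            factor_gate_w = (self.con_cell.Wx[self.n_neurons:]
                             if cfg.controller_sees_factors else None)
        zero_u = Tensor(np.zeros((batch, cfg.n_control)))

        factors, log_rates, u_means, u_logvars = [], [], [], []
        f_prev = None
        for t in range(self.T):
            if t < prep or not use_controller:
                u_t = zero_u
            else:
                j = t - prep - cfg.controller_input_delay
                if j >= 0:
                    xg = spike_gates[:, j]
                else:  # zero spike input during the delay warmup
                    xg = Tensor(np.zeros((batch, 3 * cfg.ctrl_dim))) + self.con_cell.b
                if cfg.controller_sees_factors:
                    xg = xg + f_prev @ factor_gate_w
                c = self.con_cell.step_pre(xg, c)
                u_stats = self.con_readout(c)
                u_mean = u_stats[:, : cfg.n_control]
                u_logvar = u_stats[:, cfg.n_control:]
                u_means.append(u_mean)
                u_logvars.append(u_logvar)
                if force_zero:
                    u_t = zero_u
                elif sample:
                    eps = Tensor(rng.standard_normal((batch, cfg.n_control)))
                    u_t = u_mean + (u_logvar * 0.5).exp() * eps
                else:
                    u_t = u_mean
            h = self.gen_cell(u_t, h)
            f_t = self.fac_readout(h)
            factors.append(f_t)
            log_rates.append(self.rate_readout(f_t))
            f_prev = f_t

        out.factors = stack(factors, axis=1)                 # (batch, T, F)
        out.log_rates = stack(log_rates, axis=1)
        out.rates = out.log_rates.exp()
        out.u_mean = stack(u_means, axis=1) if u_means else None
        out.u_logvar = stack(u_logvars, axis=1) if u_logvars else None
        out.behavior_pred = self._decode(out.factors, batch)
        return out

    def _decode(self, factors: Tensor, batch: int) -> Tensor:
        cfg = self.config
        if cfg.behavior_decoder == "seq2seq_linear":
            flat = factors.reshape(batch, self.T * cfg.n_factors)
            return self.decoder(flat).reshape(batch, self.T, cfg.behavior_dims)
        flat = factors.reshape(batch * self.T, cfg.n_factors)
        return self.decoder(flat).reshape(batch, self.T, cfg.behavior_dims)

    # -- public numpy-side API ------------------------------------------------

    def infer(self, spikes: np.ndarray, n_posterior_samples: int = 0,
              seed: int = 0) -> LatentTrajectory:
        """Eval-mode inference; optionally average rates over posterior samples."""
        fwd = self.forward(spikes, sample=False)
        rates = fwd.rates.data
        if n_posterior_samples > 0:
            rng = np.random.default_rng(seed)
            acc = np.zeros_like(rates)
            for _ in range(n_posterior_samples):
                acc += self.forward(spikes, sample=True, rng=rng).rates.data
            rates = acc / n_posterior_samples
        u_mean = fwd.u_mean.data if fwd.u_mean is not None else None
        u_sd = np.exp(0.5 * fwd.u_logvar.data) if fwd.u_logvar is not None else None
        return LatentTrajectory(
            g0_mean=fwd.g0_mean.data,
            g0_sd=np.exp(0.5 * fwd.g0_logvar.data),
            u_mean=u_mean,
            u_sd=u_sd,
            factors=fwd.factors.data,
            rates=rates,
            behavior_pred=fwd.behavior_pred.data,
        )

    def encode_initial_condition(self, spikes_prep: np.ndarray):
        """Gaussian posterior over g0 from the preparatory window only."""
        cfg = self.config
        if spikes_prep.ndim != 3 or spikes_prep.shape[1] != cfg.prep_bins:
            raise ValueError(
                f"expected (trials, prep_bins={cfg.prep_bins}, N); got {spikes_prep.shape}"
            )
        batch = spikes_prep.shape[0]
        steps = [Tensor(np.asarray(spikes_prep[:, t], dtype=np.float64))
                 for t in range(cfg.prep_bins)]
        hf = Tensor(np.zeros((batch, cfg.encoder_dim)))
        hb = Tensor(np.zeros((batch, cfg.encoder_dim)))
        for x in steps:
            hf = self.ic_fwd(x, hf)
        for x in reversed(steps):
            hb = self.ic_bwd(x, hb)
        ic = self.ic_readout(concat([hf, hb], axis=1)).data
        return ic[:, : cfg.generator_dim], np.exp(0.5 * ic[:, cfg.generator_dim:])

    def encode_controller(self, spikes_move: np.ndarray,
                          factors_prev: np.ndarray | None = None):
        """Per-bin Gaussian posterior over u from movement-phase spikes.

        Strictly causal: the posterior at movement bin t depends only on
        movement bins <= t.  When the controller is wired to see factors and
        no ``factors_prev`` is given, zeros are substituted.
        """
        cfg = self.config
        if cfg.n_control == 0:
            return (np.zeros((spikes_move.shape[0], spikes_move.shape[1], 0)),) * 2
        Tm = spikes_move.shape[1]
        if Tm == 0:
            raise ValueError("controller requested but zero movement bins provided")
        batch = spikes_move.shape[0]
        c = Tensor(np.zeros((batch, cfg.ctrl_dim)))
        means, sds = [], []
        for t in range(Tm):
            j = t - cfg.controller_input_delay
            x = Tensor(np.asarray(spikes_move[:, j], dtype=np.float64) if j >= 0
                       else np.zeros((batch, self.n_neurons)))
            if cfg.controller_sees_factors:
                f = (np.zeros((batch, cfg.n_factors)) if factors_prev is None
                     else factors_prev[:, t])
                x = concat([x, Tensor(f)], axis=1)
            c = self.con_cell(x, c)
            stats = self.con_readout(c).data
            means.append(stats[:, : cfg.n_control])
            sds.append(np.exp(0.5 * stats[:, cfg.n_control:]))
        return np.stack(means, axis=1), np.stack(sds, axis=1)

    def decode_behavior_seq2seq(self, factors: np.ndarray):
        """Apply the trained seq2seq map; returns (behavior_pred, weight matrix)."""
        cfg = self.config
        if cfg.behavior_decoder != "seq2seq_linear":
            raise ValueError("model was configured with a per-step decoder")
        if factors.shape[1] != self.T:
            raise ValueError(
                f"the seq2seq map is specific to T={self.T}; got T={factors.shape[1]}"
            )
        wm = self.decoder_weight_matrix()
        return wm.apply(np.asarray(factors, dtype=np.float64)), wm

    def decoder_weight_matrix(self) -> DecoderWeightMatrix:
        cfg = self.config
        if cfg.behavior_decoder != "seq2seq_linear":
            raise ValueError("weight matrix is only defined for the seq2seq decoder")
        return DecoderWeightMatrix(
            weights=self.decoder.W.data.copy(),
            bias=self.decoder.b.data.copy(),
            T=self.T,
            n_factors=cfg.n_factors,
            behavior_dims=cfg.behavior_dims,
        )

    # -- training-side loss graph --------------------------------------------

    def loss_graph(self, spikes: np.ndarray, behavior: np.ndarray,
                   rng: np.random.Generator | None = None, sample: bool = True,
                   kl_scale: float = 1.0, kl_scale_u: float | None = None,
                   input_dropout: float = 0.0, neuron_dropout: float = 0.0,
                   force_u_zero: bool = False):
        """Return (negative-loss Tensor to minimize, diagnostics dict).

        Mirrors the additive objective: Poisson log-likelihood + θ·(-MSE)
        - α·L2 - β·KLs, all averaged per trial; the trainer minimizes the
        negation.  The Poisson term omits the ln(y!) constant (no gradient).
        """
        cfg = self.config
        w = cfg.weights
        batch = spikes.shape[0]
        fwd = self.forward(spikes, sample=sample, rng=rng,
                           force_u_zero=force_u_zero,
                           input_dropout=input_dropout,
                           neuron_dropout=neuron_dropout)

        target = Tensor(np.asarray(spikes, dtype=np.float64))
        L_x = ((target * fwd.log_rates).sum() - fwd.rates.sum()) * (1.0 / batch)

        kl_g0 = _kl_std_normal(fwd.g0_mean, fwd.g0_logvar) * (1.0 / batch)
        if force_u_zero:
            # autonomous-pathway training step: no controller gradient at all
            kl_u = Tensor(0.0)
        elif fwd.u_mean is not None:
            if cfg.u_prior == "iid":
                kl_u = _kl_std_normal(fwd.u_mean, fwd.u_logvar) * (1.0 / batch)
            else:
                kl_u = _kl_ar1(fwd.u_mean, fwd.u_logvar, cfg.u_prior_ar1_rho) * (1.0 / batch)
        else:
            kl_u = Tensor(0.0)

        l2 = (self.gen_cell.Wh ** 2).sum()
        if cfg.n_control > 0:
            l2 = l2 + (self.con_cell.Wh ** 2).sum()

        if kl_scale_u is None:
            kl_scale_u = kl_scale
        loss = (-L_x + kl_scale * w.beta_kl_g0 * kl_g0
                + kl_scale_u * w.beta_kl_u * kl_u + w.alpha * l2)
        mse_value = float(np.mean((behavior - fwd.behavior_pred.data) ** 2))
        if w.theta != 0.0:
            target_b = Tensor(np.asarray(behavior, dtype=np.float64))
            err = fwd.behavior_pred - target_b
            if cfg.behavior_loss_movement_only:
                err = err[:, cfg.prep_bins:, :]
            loss = loss + w.theta * (err ** 2).mean()

        diag = {
            "rate_min": float(fwd.rates.data.min()),
            "rate_max": float(fwd.rates.data.max()),
            "L_x": L_x.item(),
            "L_b": -mse_value,
            "KL_g0": kl_g0.item(),
            "KL_u": kl_u.item(),
            "L_L2": l2.item(),
        }
        return loss, diag


def _kl_std_normal(mean: Tensor, logvar: Tensor) -> Tensor:
    return 0.5 * (logvar.exp() + mean**2 - 1.0 - logvar).sum()


def _kl_ar1(mean: Tensor, logvar: Tensor, rho: float) -> Tensor:
    """KL(q || AR(1) prior) for a per-bin diagonal Gaussian posterior.

    Prior: u_1 ~ N(0,1); u_t | u_{t-1} ~ N(rho*u_{t-1}, 1 - rho^2).
    """
    var = logvar.exp()
    m0, v0, lv0 = mean[:, 0], var[:, 0], logvar[:, 0]
    kl = 0.5 * (v0 + m0**2 - 1.0 - lv0).sum()
    s2 = 1.0 - rho**2
    m_t, m_p = mean[:, 1:], mean[:, :-1]
    v_t, v_p = var[:, 1:], var[:, :-1]
    e_sq = v_t + m_t**2 - 2.0 * rho * m_t * m_p + rho**2 * (v_p + m_p**2)
    kl = kl + (0.5 * (np.log(s2) - logvar[:, 1:]) + e_sq * (0.5 / s2) - 0.5).sum()
    return kl


def ablate_controller(model: BandModel) -> BandModel:
    """Return a view of the model with control inputs forced to zero.

    Parameters are shared with the original (no copy drift); the original is
    unmodified.  Idempotent on already-ablated models; raises for models that
    never had a controller.
    """
    if model.config.n_control == 0:
        raise ValueError("model is already autonomous (n_control=0)")
    if model.ablated:
        return model
    ablated = copy.copy(model)
    ablated.ablated = True
    return ablated


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(model: BandModel, path, history: dict | None = None) -> str:
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "n_neurons": model.n_neurons,
        "T": model.T,
        "ablated": model.ablated,
        "history": history or {},
    }
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return str(path)


def load_checkpoint(path) -> tuple[BandModel, dict]:
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        state = {k[len("param:"):]: f[k] for k in f.files if k.startswith("param:")}
    cfg_dict = meta["config"]
    cfg_dict["weights"] = LossWeights(**cfg_dict["weights"])
    config = ModelConfig(**cfg_dict)
    model = BandModel(config, meta["n_neurons"], meta["T"], seed=0)
    model.load_state_dict(state)
    model.ablated = bool(meta["ablated"])
    return model, meta.get("history", {})
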