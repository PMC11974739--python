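"""Neural-network building blocks on top of the autodiff engine.

Provides a tiny Module system, Linear and GRUCell layers, and an Adam
optimizer with global-norm gradient clipping.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Module", "Linear", "GRUCell", "Adam", "clip_grad_norm"]


class Module:
    """Base class: collects parameters from attributes, lists and submodules."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data[...] = state[name]


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float | None = None):
        if scale is None:
            scale = 1.0 / np.sqrt(max(n_in, 1))
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class GRUCell(Module):
    """Gated recurrent unit; gate order along the weight columns is (r, z, n).

    ``update_bias`` initializes the update-gate bias; positive values bias the
    cell toward retaining its state (useful for generators that must hold a
    plan over many steps).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 update_bias: float = 0.0):
        self.n_in = n_in
        self.n_hidden = n_hidden
        sx = 1.0 / np.sqrt(max(n_in, 1))
        sh = 1.0 / np.sqrt(n_hidden)
        self.Wx = Tensor(rng.normal(0.0, sx, size=(n_in, 3 * n_hidden)), requires_grad=True)
        self.Wh = Tensor(rng.normal(0.0, sh, size=(n_hidden, 3 * n_hidden)), requires_grad=True)
        b = np.zeros(3 * n_hidden)
        b[n_hidden:2 * n_hidden] = update_bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        return self.step_pre(x @ self.Wx + self.b, h)

    def step_pre(self, xg: Tensor, h: Tensor) -> Tensor:
        """Step from precomputed input gates (see :meth:`input_gates`)."""
        H = self.n_hidden
        hg = h @ self.Wh
        r = (xg[:, :H] + hg[:, :H]).sigmoid()
        z = (xg[:, H:2 * H] + hg[:, H:2 * H]).sigmoid()
        n = (xg[:, 2 * H:] + r * hg[:, 2 * H:]).tanh()
        return (1.0 - z) * n + z * h

    def input_gates(self, x_flat: Tensor) -> Tensor:
        """Batch the input-to-gate product over all timesteps at once.

        ``x_flat``: (batch*T, n_in); returns (batch*T, 3*hidden).
        """
        return x_flat @ self.Wx + self.b

    @property
    def recurrent_weight(self) -> Tensor:
        return self.Wh


def clip_grad_norm(params, max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
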