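"""Shared neural-network plumbing: parameter initialisation, the Adam
optimizer, an LSTM cell, and early stopping.

Parameters live in flat ``{name: Tensor}`` dictionaries; checkpointing is a
deep copy of the underlying arrays, so restoring a checkpoint is bit-exact.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, sigmoid, tanh

__all__ = ["glorot", "Adam", "LSTMLayer", "EarlyStopper", "clone_params", "set_params"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def clone_params(params: dict) -> dict:
    return {k: np.array(v.data, copy=True) for k, v in params.items()}


def set_params(params: dict, snapshot: dict) -> None:
    for k, v in params.items():
        v.data = np.array(snapshot[k], copy=True)


class Adam:
    """Adam optimizer over a ``{name: Tensor}`` parameter dictionary."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.95,
                 beta2: float = 0.95, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LSTMLayer:
    """A single forward LSTM layer (batch-major, one step at a time)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, prefix: str):
        self.in_dim = in_dim
        self.hidden = hidden
        self.prefix = prefix
        self.params: dict[str, Tensor] = {}
        for gate in ("i", "f", "g", "o"):
            self.params[f"{prefix}_Wx_{gate}"] = Tensor(
                glorot(rng, in_dim, hidden), requires_grad=True)
            self.params[f"{prefix}_Wh_{gate}"] = Tensor(
                glorot(rng, hidden, hidden), requires_grad=True)
            # forget-gate bias at 1.0 is the standard stabilisation
            bias = np.ones(hidden) if gate == "f" else np.zeros(hidden)
            self.params[f"{prefix}_b_{gate}"] = Tensor(bias, requires_grad=True)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        p = self.params
        pre = self.prefix
        i = sigmoid(x @ p[f"{pre}_Wx_i"] + h @ p[f"{pre}_Wh_i"] + p[f"{pre}_b_i"])
        f = sigmoid(x @ p[f"{pre}_Wx_f"] + h @ p[f"{pre}_Wh_f"] + p[f"{pre}_b_f"])
        g = tanh(x @ p[f"{pre}_Wx_g"] + h @ p[f"{pre}_Wh_g"] + p[f"{pre}_b_g"])
        o = sigmoid(x @ p[f"{pre}_Wx_o"] + h @ p[f"{pre}_Wh_o"] + p[f"{pre}_b_o"])
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        return h_new, c_new


class EarlyStopper:
    """Stop when the validation loss fails to improve for `patience` epochs.

    ``update`` returns True when training should stop; ``best_epoch`` is the
    1-based epoch of the best validation loss seen (its checkpoint is the one
    to restore).
    """

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.bad = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        self.epoch += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epoch
            self.bad = 0
        else:
            self.bad += 1
        return self.bad >= self.patience
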