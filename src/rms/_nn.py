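"""Small neural-network layer library on top of :mod:`rms._autodiff`.

Layers own named :func:`Parameter` tensors; a model collects them into a flat
``{name: Tensor}`` mapping for the optimizer and for checkpointing.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor

__all__ = ["Conv3", "Linear", "LSTMCell", "Adam"]


class Conv3:
    """3x3 same-padding convolution with He-initialised weights."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((cout, cin, 3, 3))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * 9)), size=(cout, cin, 3, 3))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3x3(x, self.w, self.b)

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.w": self.w, f"{prefix}.b": self.b}


class Linear:
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(din)
        self.w = Parameter(rng.uniform(-bound, bound, size=(din, dout)))
        self.b = Parameter(np.zeros(dout))

    def __call__(self, x: Tensor) -> Tensor:
        return (x @ self.w) + self.b

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.w": self.w, f"{prefix}.b": self.b}


class LSTMCell:
    """Single LSTM layer; gate order (input, forget, cell, output).

    Forget-gate bias initialised to 1, the standard trick that keeps early
    rollout steps close to a pass-through.
    """

    def __init__(self, din: int, dhid: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(dhid)
        self.w_ih = Parameter(rng.uniform(-bound, bound, size=(din, 4 * dhid)))
        self.w_hh = Parameter(rng.uniform(-bound, bound, size=(dhid, 4 * dhid)))
        b = np.zeros(4 * dhid)
        b[dhid:2 * dhid] = 1.0
        self.b = Parameter(b)
        self.dhid = dhid

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = (x @ self.w_ih) + (h @ self.w_hh) + self.b
        d = self.dhid
        i = ad.sigmoid(ad.narrow(z, 1, 0, d))
        f = ad.sigmoid(ad.narrow(z, 1, d, d))
        g = ad.tanh(ad.narrow(z, 1, 2 * d, d))
        o = ad.sigmoid(ad.narrow(z, 1, 3 * d, d))
        c_new = f * c + i * g
        h_new = o * ad.tanh(c_new)
        return h_new, c_new

    def params(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.w_ih": self.w_ih, f"{prefix}.w_hh": self.w_hh, f"{prefix}.b": self.b}


class Adam:
    """Adam optimizer over a named parameter dict; state is checkpointable."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def state_dict(self) -> dict:
        out = {"t": self.t, "lr": self.lr}
        for k in self.params:
            out[f"m::{k}"] = self.m[k]
            out[f"v::{k}"] = self.v[k]
        return out

    def load_state_dict(self, state: dict):
        self.t = int(state["t"])
        for k in self.params:
            self.m[k] = np.asarray(state[f"m::{k}"], dtype=np.float32)
            self.v[k] = np.asarray(state[f"v::{k}"], dtype=np.float32)
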