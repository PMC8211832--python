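"""Network building blocks: linear layers, Mish MLPs and an LSTM cell."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: recursive parameter collection and dtype casting."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            params.extend(_collect(v))
        return params

    def astype(self, dtype) -> "Module":
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


def _collect(obj) -> list[Tensor]:
    if isinstance(obj, Tensor) and obj.requires_grad:
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out = []
        for item in obj:
            out.extend(_collect(item))
        return out
    if isinstance(obj, dict):
        out = []
        for item in obj.values():
            out.extend(_collect(item))
        return out
    return []


class Linear(Module):
    """Affine map on the last axis, Kaiming-uniform initialized."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        bound = float(np.sqrt(1.0 / d_in))
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(d_in, d_out)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias


class MLP(Module):
    """Multi-layer perceptron with Mish on hidden layers, linear output.

    `dims` lists every layer width including input and output, e.g.
    [32, 32, 16, 1].
    """

    def __init__(self, dims, rng: np.random.Generator, dtype=np.float64,
                 final_activation=None):
        self.layers = [
            Linear(a, b, rng, dtype=dtype) for a, b in zip(dims[:-1], dims[1:])
        ]
        self.final_activation = final_activation
        self.dims = list(dims)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for layer in self.layers[:-1]:
            h = ad.mish(layer(h))
        h = self.layers[-1](h)
        if self.final_activation is not None:
            h = self.final_activation(h)
        return h


class LSTMCell(Module):
    """Standard LSTM cell; gate order (input, forget, cell, output)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.d_hidden = d_hidden
        bound = float(np.sqrt(1.0 / d_hidden))
        self.w_ih = Tensor(
            rng.uniform(-bound, bound, size=(d_in, 4 * d_hidden)).astype(dtype),
            requires_grad=True,
        )
        self.w_hh = Tensor(
            rng.uniform(-bound, bound, size=(d_hidden, 4 * d_hidden)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(4 * d_hidden, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        gates = ad.matmul(x, self.w_ih) + ad.matmul(h, self.w_hh) + self.bias
        H = self.d_hidden
        i = ad.sigmoid(gates[..., 0:H])
        f = ad.sigmoid(gates[..., H:2 * H])
        g = ad.tanh(gates[..., 2 * H:3 * H])
        o = ad.sigmoid(gates[..., 3 * H:4 * H])
        c_new = f * c + i * g
        h_new = o * ad.tanh(c_new)
        return h_new, c_new
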