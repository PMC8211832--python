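"""Adam optimizer and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class ReduceLROnPlateau:
    """Multiply lr by `factor` when the monitored loss stops improving.

    "Stops improving" means: no improvement greater than `threshold` over the
    best value for `patience` consecutive epochs.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.7, patience: int = 30,
                 threshold: float = 1e-4):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must lie in (0, 1)")
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.best = np.inf
        self.stale = 0

    def step(self, loss: float) -> bool:
        """Register an epoch loss; returns True if the lr was decayed."""
        if loss < self.best - self.threshold:
            self.best = loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.optimizer.lr *= self.factor
            self.stale = 0
            return True
        return False
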