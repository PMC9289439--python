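"""Optimizers: Adam and SGD with momentum and stepwise learning-rate decay."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adaptive-moment optimizer (bias-corrected first/second moments)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.value -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(
                p.value.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    """SGD with optional momentum; ``lr`` is mutable for step schedules."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if self.momentum:
                v *= self.momentum
                v += p.grad
                update = v
            else:
                update = p.grad
            p.value -= (self.lr * update).astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
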