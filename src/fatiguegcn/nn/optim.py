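"""First-order optimizers: Adam and Adamax (infinity-norm Adam variant).

``weight_decay`` is classic L2 regularization added to the gradient before
the moment updates.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .layers import Parameter

__all__ = ["Optimizer", "Adam", "Adamax"]


class Optimizer:
    def __init__(self, params: Sequence[Parameter], lr: float, weight_decay: float = 0.0) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError

    def _grad(self, p: Parameter) -> np.ndarray:
        g = p.grad
        if self.weight_decay:
            g = g + self.weight_decay * p.value
        return g


class Adam(Optimizer):
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        super().__init__(params, lr, weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = self._grad(p)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class Adamax(Optimizer):
    """Adam with the second moment replaced by an exponentially weighted infinity norm."""

    def __init__(self, params: Sequence[Parameter], lr: float = 2e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        super().__init__(params, lr, weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.u = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        for p, m, u in zip(self.params, self.m, self.u):
            g = self._grad(p)
            m *= self.b1
            m += (1 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p.value -= self.lr * (m / bc1) / (u + self.eps)
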