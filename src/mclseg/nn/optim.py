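"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["SGD"]


class SGD:
    """v <- momentum * v + grad;  p <- p - lr * v."""

    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {lr}")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
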