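"""Optimizers and learning-rate schedule for the slide-level models.

SGD with momentum/weight decay and RMSprop match the conventions of the
mainstream deep-learning frameworks (decoupled velocity buffer; RMSprop with
a running mean of squared gradients). Cosine annealing decays the learning
rate from its initial value to ``eta_min`` over a fixed horizon.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["SGD", "RMSprop", "CosineAnnealingLR"]


class _Optimizer:
    def __init__(self, params, lr: float):
        self.params: list[Tensor] = list(params)
        if not self.params:
            raise ValueError("optimizer received no parameters")
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD(_Optimizer):
    def __init__(self, params, lr: float = 1e-3, momentum: float = 0.9,
                 weight_decay: float = 5e-4):
        super().__init__(params, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v


class RMSprop(_Optimizer):
    def __init__(self, params, lr: float = 1e-5, alpha: float = 0.99,
                 eps: float = 1e-8):
        super().__init__(params, lr)
        self.alpha = alpha
        self.eps = eps
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self._sq):
            if p.grad is None:
                continue
            s *= self.alpha
            s += (1.0 - self.alpha) * p.grad**2
            p.data = p.data - self.lr * p.grad / (np.sqrt(s) + self.eps)


class CosineAnnealingLR:
    """Cosine decay of an optimizer's lr over `t_max` steps (epochs)."""

    def __init__(self, optimizer: _Optimizer, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.t_max = int(t_max)
        self.eta_min = eta_min
        self.base_lr = optimizer.lr
        self.t = 0

    def step(self):
        self.t = min(self.t + 1, self.t_max)
        self.optimizer.lr = self.eta_min + 0.5 * (self.base_lr - self.eta_min) * (
            1.0 + math.cos(math.pi * self.t / self.t_max))

    @property
    def current_lr(self) -> float:
        return self.optimizer.lr
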