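"""Adam optimisation, one-cycle learning-rate scheduling, and weight EMA."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "OneCycleLR", "EMA"]


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = dict(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m = self._m[k]
            v = self._v[k]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class OneCycleLR:
    """Cosine one-cycle schedule: warm up to max_lr, then anneal down.

    Mirrors the common default shape (30% of steps rising from
    max_lr / div_factor, the remainder falling to max_lr / final_div).
    """

    def __init__(self, optimizer: Adam, max_lr: float, total_steps: int,
                 pct_start: float = 0.3, div_factor: float = 25.0,
                 final_div: float = 1e4):
        if total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        self.opt = optimizer
        self.max_lr = max_lr
        self.total_steps = total_steps
        self.pct_start = pct_start
        self.initial_lr = max_lr / div_factor
        self.final_lr = max_lr / final_div
        self._step = 0
        self.opt.lr = self.initial_lr

    @staticmethod
    def _cos(lo: float, hi: float, pct: float) -> float:
        return hi + (lo - hi) * (1.0 + math.cos(math.pi * pct)) / 2.0

    def step(self) -> float:
        self._step += 1
        pct = min(self._step / self.total_steps, 1.0)
        up = max(self.pct_start, 1e-12)
        if pct <= self.pct_start:
            lr = self._cos(self.initial_lr, self.max_lr, pct / up)
        else:
            lr = self._cos(self.max_lr, self.final_lr,
                           (pct - up) / max(1.0 - up, 1e-12))
        self.opt.lr = lr
        return lr


class EMA:
    """Exponential moving average of parameter values.

    shadow <- decay * shadow + (1 - decay) * live. decay = 0 keeps the
    shadow identical to the live weights.
    """

    def __init__(self, params: dict[str, Tensor], decay: float = 0.999):
        if not 0.0 <= decay < 1.0:
            raise ValueError("decay must be in [0, 1)")
        self.decay = decay
        self._live = dict(params)
        self.shadow = {k: p.data.copy() for k, p in params.items()}

    def update(self) -> None:
        d = self.decay
        for k, p in self._live.items():
            self.shadow[k] *= d
            self.shadow[k] += (1.0 - d) * p.data

    def copy_to(self, params: dict[str, Tensor]) -> None:
        for k, p in params.items():
            if k in self.shadow:
                p.data = self.shadow[k].copy()

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.shadow.items()}
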