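"""Optimisers and learning-rate schedules.

``Adam`` applies weight decay as an L2 penalty added to the gradient
(classic coupled decay); ``AdamW`` decouples the decay from the adaptive
step. ``cosine_warmup`` is a linear-warmup / cosine-annealing schedule.
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam", "AdamW", "cosine_warmup"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    decoupled = False

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decoupled and getattr(p, "decay", True):
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay and self.decoupled and getattr(p, "decay", True):
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    decoupled = True


def cosine_warmup(step: int, total_steps: int, base_lr: float,
                  warmup_steps: int = 0) -> float:
    """Learning rate at ``step``: linear warm-up then cosine annealing to 0."""
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    frac = (step - warmup_steps) / max(1, total_steps - warmup_steps)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))
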