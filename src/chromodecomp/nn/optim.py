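"""Adam with l2 weight decay, and the cosine-annealing schedule."""

from __future__ import annotations

import math

import numpy as np


class Adam:
    """Adam; l2 weight decay is added to the gradient (classic coupled form)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k].astype(p.dtype)
            if self.weight_decay and not k.endswith("_b"):
                g = g + self.weight_decay * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)


def cosine_annealing_lr(base_lr: float, epoch: int, period: int, lr_min: float = 0.0) -> float:
    """lr(t) = lr_min + (base - lr_min)(1 + cos(pi t / T)) / 2."""
    if period <= 0:
        return base_lr
    return lr_min + 0.5 * (base_lr - lr_min) * (1.0 + math.cos(math.pi * min(epoch, period) / period))
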