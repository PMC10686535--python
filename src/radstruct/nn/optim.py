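"""Optimization: SGD with momentum, gradient clipping, plateau LR decay."""

from __future__ import annotations

import numpy as np


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    total = 0.0
    for g in grads.values():
        total += float((g.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads.values():
            g *= scale
    return norm


class SGDMomentum:
    """Minibatch SGD with classical momentum: v <- mu v - lr g; p <- p + v."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            v = self.velocity[k]
            v *= self.momentum
            v -= self.lr * grads[k]
            p += v


class PlateauScheduler:
    """Halve (by ``factor``) the LR when the monitored score stops improving.

    ``patience`` epochs without improvement trigger one decay; the LR
    never drops below ``floor``.
    """

    def __init__(
        self,
        optimizer: SGDMomentum,
        factor: float = 0.5,
        patience: int = 3,
        floor: float = 1e-4,
        min_delta: float = 1e-6,
    ):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.floor = floor
        self.min_delta = min_delta
        self.best = -np.inf
        self.stale = 0

    def update(self, score: float) -> bool:
        """Report an epoch score; returns True if the LR was decayed."""
        if score > self.best + self.min_delta:
            self.best = score
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.stale = 0
            new_lr = max(self.optimizer.lr * self.factor, self.floor)
            changed = new_lr < self.optimizer.lr
            self.optimizer.lr = new_lr
            return changed
        return False
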