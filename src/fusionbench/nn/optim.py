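"""Adam optimizer and one-cycle learning-rate schedule for the numpy nets."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Adam", "one_cycle_lr"]


class Adam:
    """Adam with bias correction, operating on a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 warmup_frac: float = 0.3, div_factor: float = 25.0,
                 final_div_factor: float = 1e4) -> float:
    """One-cycle schedule: linear warm-up to ``max_lr`` over ``warmup_frac``
    of the horizon, then cosine anneal down to ``max_lr / final_div_factor``.

    ``step`` is 0-based; the horizon is ``total_steps``.
    """
    if total_steps <= 1:
        return max_lr
    warm = max(1, int(round(warmup_frac * total_steps)))
    lo = max_lr / div_factor
    if step < warm:
        return lo + (max_lr - lo) * step / warm
    end = max_lr / final_div_factor
    frac = (step - warm) / max(1, total_steps - warm)
    frac = min(1.0, frac)
    return end + (max_lr - end) * 0.5 * (1 + math.cos(math.pi * frac))
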