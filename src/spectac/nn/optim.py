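"""Adam optimizer."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE
from .layers import Parameter


class Adam:
    """Adam with optional global gradient-norm clipping (guards the
    occasional adversarial-gradient blow-up on small batches)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(
                float((p.grad**2).sum()) for p in self.params if p.grad is not None
            ))
            if total > self.clip_norm:
                scale = DTYPE(self.clip_norm / total)
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
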