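"""Adam optimizer for the numpy layer stack."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .layers import Param

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected first and second moment estimates.

    Defaults follow the convention of adversarial image-translation training:
    learning rate 2e-4 with moment decays (0.5, 0.999).
    """

    def __init__(self, params: Sequence[Param], lr: float = 2e-4,
                 betas: tuple = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
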