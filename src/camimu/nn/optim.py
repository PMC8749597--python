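"""Nadam — Adam with Nesterov momentum (Dozat 2016, simplified schedule).

The update applies the Nesterov look-ahead to the bias-corrected first
moment:

    m ← β₁ m + (1−β₁) g          v ← β₂ v + (1−β₂) g²
    step = lr · (β₁·m̂ + (1−β₁)·g/(1−β₁ᵗ)) / (√v̂ + ε)

with m̂, v̂ the usual bias-corrected moments.  A global gradient-norm clip
guards the recurrent layers against rare exploding-gradient steps.
"""

from __future__ import annotations

import numpy as np


class Nadam:
    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        clipnorm: float | None = 5.0,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clipnorm = clipnorm
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        self.t += 1
        if self.clipnorm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in self.grads))
            if total > self.clipnorm:
                scale = self.clipnorm / (total + 1e-12)
                for g in self.grads:
                    g *= scale
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            m_hat = m / b1t
            v_hat = v / b2t
            update = (self.beta1 * m_hat + (1.0 - self.beta1) * g / b1t) / (
                np.sqrt(v_hat) + self.eps
            )
            p -= (self.lr * update).astype(p.dtype)
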