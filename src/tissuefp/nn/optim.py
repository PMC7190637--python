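"""Adam optimizer over the (name, param, grad) triples exposed by layers."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.entries = list(params)  # [(name, param, grad)]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for _, p, _ in self.entries]
        self.v = [np.zeros_like(p) for _, p, _ in self.entries]
        self.t = 0

    def zero_grad(self) -> None:
        for _, _, g in self.entries:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (name, p, g), m, v in zip(self.entries, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
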