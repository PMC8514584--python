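"""Adam optimiser for the layer library."""

from __future__ import annotations

import numpy as np

from .layers import Param

F32 = np.float32


class Adam:
    def __init__(self, params: list[Param], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self) -> None:
        """Apply one update from the accumulated gradients, then zero them."""
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.g
            v *= self.b2
            v += (1.0 - self.b2) * (p.g * p.g)
            p.v -= F32(self.lr) * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.g[...] = 0.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0
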