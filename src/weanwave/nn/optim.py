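"""AdamW with decoupled weight decay."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["AdamW"]


class AdamW:
    """Adam update plus decoupled weight decay (`p -= lr * wd * p`).

    Defaults mirror the training recipe used throughout the package:
    lr 1e-4, weight decay 5e-2.  The first/second-moment state is kept in
    float32 — standard optimizer practice that halves the state's memory
    traffic without affecting parameter precision.
    """

    def __init__(self, params, lr=1e-4, weight_decay=5e-2,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros(p.data.shape, dtype=np.float32) for p in self.params]
        self._v = [np.zeros(p.data.shape, dtype=np.float32) for p in self.params]

    def step(self):
        self.t += 1
        bias1 = 1.0 - self.b1 ** self.t
        bias2 = 1.0 - self.b2 ** self.t
        step_size = self.lr / bias1
        inv_sqrt_bias2 = 1.0 / math.sqrt(bias2)
        decay = 1.0 - self.lr * self.weight_decay
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad.astype(np.float32, copy=False)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            denom = np.sqrt(v)
            denom *= inv_sqrt_bias2
            denom += self.eps
            p.data *= decay
            p.data -= step_size * (m / denom)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
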