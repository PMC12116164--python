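"""Optimisers for the numpy network."""

from __future__ import annotations

import numpy as np


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr=0.01, momentum=0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            buf *= self.momentum
            buf += p.grad
            p.data -= (self.lr * buf).astype(p.data.dtype, copy=False)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= update.astype(p.data.dtype, copy=False)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
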