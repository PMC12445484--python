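"""Optimizers.  SGD with Nesterov-free momentum and decoupled weight decay
is all the micro-scale training loop needs."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD"]


class SGD:
    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
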