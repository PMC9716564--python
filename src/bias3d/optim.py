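"""Adam optimizer with L2 weight decay and global-norm gradient clipping."""

from __future__ import annotations

import numpy as np


def clip_global_norm(params, max_norm):
    """Scale all gradients in-place so their global L2 norm is <= max_norm."""
    total = 0.0
    for t in params.values():
        if t.grad is not None:
            total += float((t.grad * t.grad).sum())
    norm = np.sqrt(total)
    if max_norm and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for t in params.values():
            if t.grad is not None:
                t.grad *= scale
    return norm


class Adam:
    """Standard Adam; `weight_decay` adds the L2 penalty gradient wd * w."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
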