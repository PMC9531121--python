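"""Adam optimizer (the paper-profile training algorithm)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam"]


class Adam:
    """Adam with optional coupled L2 weight decay (PyTorch ``Adam`` semantics:
    the decay term is added to the gradient before the moment updates).

    Parameters flagged ``requires_grad=False`` are skipped entirely, which is
    how encoder freezing interacts with the optimizer: moment state for frozen
    parameters is neither read nor advanced.
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 no_decay: set | None = None):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.no_decay = no_decay if no_decay is not None else set()
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = [0] * len(self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and id(p) not in self.no_decay:
                g = g + self.weight_decay * p.data
            self._t[i] += 1
            t = self._t[i]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            m_hat = self._m[i] / (1 - self.b1 ** t)
            v_hat = self._v[i] / (1 - self.b2 ** t)
            p.data -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(np.float32)
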