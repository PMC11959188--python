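"""Adam optimizer and the multi-step learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "lr_at_epoch"]


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def lr_at_epoch(epoch: int, base_lr: float, factor: float, milestones: list[int]) -> float:
    """Learning rate in force during 1-based `epoch`: decayed once per passed milestone."""
    n = sum(1 for m in milestones if epoch > m)
    return base_lr * factor ** n
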