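"""Optimisers and learning-rate schedules.

``lars_step`` is exposed as a pure function (array in, array out) so the
layer-wise trust ratio can be verified against its closed form independently
of the stateful optimiser that wraps it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lars_trust_ratio", "lars_step", "SGD", "LARS", "warmup_cosine_lr"]


def lars_trust_ratio(param: np.ndarray, grad: np.ndarray,
                     trust_coefficient: float, weight_decay: float,
                     eps: float = 1e-9) -> float:
    """Layer-wise local learning rate: tc * ||p|| / (||g|| + wd*||p|| + eps).

    A zero-norm parameter block falls back to a pass-through ratio of 1.
    """
    p_norm = float(np.linalg.norm(param))
    if p_norm == 0.0:
        return 1.0
    g_norm = float(np.linalg.norm(grad))
    return trust_coefficient * p_norm / (g_norm + weight_decay * p_norm + eps)


def lars_step(param: np.ndarray, grad: np.ndarray, global_lr: float,
              trust_coefficient: float = 0.001, weight_decay: float = 0.0,
              momentum: float = 0.9, velocity: np.ndarray | None = None,
              eps: float = 1e-9):
    """One LARS update on a single parameter block.

    Returns ``(new_param, new_velocity)``.
    """
    local_lr = lars_trust_ratio(param, grad, trust_coefficient, weight_decay, eps)
    update = grad + weight_decay * param
    if velocity is None:
        velocity = np.zeros_like(param)
    velocity = momentum * velocity + global_lr * local_lr * update
    return param - velocity, velocity


def warmup_cosine_lr(epoch: int, total_epochs: int, warmup_epochs: int,
                     base_lr: float, peak_lr: float) -> float:
    """Linear warm-up from ``base_lr`` to ``peak_lr``, then cosine decay to 0."""
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return base_lr + (peak_lr - base_lr) * (epoch + 1) / warmup_epochs
    if total_epochs <= warmup_epochs:
        return peak_lr
    t = (epoch - warmup_epochs) / max(1, total_epochs - warmup_epochs)
    return peak_lr * 0.5 * (1.0 + np.cos(np.pi * min(t, 1.0)))


class _Optimizer:
    def __init__(self, params):
        self.params = [p for p in params if p.requires_grad]

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD(_Optimizer):
    """Stochastic gradient descent with momentum and optional clipping.

    ``max_grad_norm`` rescales the global gradient norm before the update,
    guarding against momentum-amplified runaway on small batches.
    """

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0,
                 max_grad_norm=None):
        super().__init__(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.max_grad_norm = max_grad_norm
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        scale = 1.0
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad ** 2))
                                for p in self.params if p.grad is not None))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / (total + 1e-12)
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype) * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v


class LARS(_Optimizer):
    """Layer-wise adaptive rate scaling with momentum.

    The global learning rate is set per step/epoch through ``lr`` (driven by a
    warm-up schedule); each parameter block additionally receives a local rate
    proportional to its norm ratio.
    """

    def __init__(self, params, lr=0.0, trust_coefficient=0.001,
                 momentum=0.9, weight_decay=1e-4, eps=1e-9):
        super().__init__(params)
        self.lr = lr
        self.trust_coefficient = trust_coefficient
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.eps = eps
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            new_p, new_v = lars_step(p.data, g, self.lr, self.trust_coefficient,
                                     self.weight_decay, self.momentum,
                                     self.velocity[i], self.eps)
            p.data = new_p
            self.velocity[i] = new_v
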