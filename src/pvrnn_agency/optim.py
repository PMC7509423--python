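"""Adam optimizer over :class:`~pvrnn_agency.autodiff.Tensor` parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the standard bias correction.

    Defaults follow the training settings used throughout this package
    (alpha=0.001, beta1=0.9, beta2=0.999); error regression re-uses the
    class with a larger step size.
    """

    def __init__(self, params, alpha=0.001, beta1=0.9, beta2=0.999,
                 eps=1e-8, clip_norm=None):
        self.params = list(params)
        self.alpha = alpha
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.alpha * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
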