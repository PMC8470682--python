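"""Adaptive-moment (Adam) optimiser over a Sequential's parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(
        self,
        model,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, layer, pname in self.model.named_params():
            g = layer.grads.get(pname)
            if g is None:
                continue
            g = g.astype(np.float32)
            m = self._m.setdefault(name, np.zeros_like(g))
            v = self._v.setdefault(name, np.zeros_like(g))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            layer.params[pname] = layer.params[pname] - update.astype(np.float32)
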