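"""AdamW with decoupled weight decay over named parameter dicts."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Decoupled-weight-decay Adam over a flat ``{name: array}`` store.

    Only names in ``trainable`` are updated; the rest keep their values and
    optimizer state untouched, which makes per-stage freezing bit-exact.
    """

    def __init__(self, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t: dict[str, int] = {}

    def step(self, params: dict, grads: dict, trainable=None) -> None:
        names = params.keys() if trainable is None else trainable
        for name in names:
            g = grads.get(name)
            if g is None:
                continue
            p = params[name]
            if name not in self._m:
                self._m[name] = np.zeros_like(p)
                self._v[name] = np.zeros_like(p)
                self._t[name] = 0
            self._t[name] += 1
            t = self._t[name]
            m = self._m[name] = self.beta1 * self._m[name] + (1 - self.beta1) * g
            v = self._v[name] = self.beta2 * self._v[name] + (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**t)
            v_hat = v / (1 - self.beta2**t)
            p -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                            + self.weight_decay * p)
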