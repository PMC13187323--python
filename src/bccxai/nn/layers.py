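"""Layers with explicit forward caches and hand-written backward passes.

Data layout is NHWC.  Each layer stores its parameters in ``params`` and
accumulates gradients in ``grads`` (same keys) during ``backward``; an
optimizer consumes both dicts.  Convolution uses im2col built on
``sliding_window_view`` and a precomputed scatter index for the backward
col2im, which keeps everything in vectorized numpy.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base: parameter-free layers just implement forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-style strided convolution with 'same'-ish zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * c_in
        # He weights.  Biases are set so each channel's response to a flat
        # patch of intensity u bends (ReLU kink) at u ~ Uniform(0, 1):
        # b = -(sum of weights) * u.  Zero biases would make the rectified
        # stack positively homogeneous in intensity — no channel could be
        # selective for an interior intensity band.
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel, kernel, c_in, c_out))
        self.params = {
            "W": W,
            "b": -W.sum(axis=(0, 1, 2)) * rng.uniform(0.0, 1.0, size=c_out),
        }
        self._idx_cache = {}

    def _indices(self, h_out, w_out):
        key = (h_out, w_out)
        if key not in self._idx_cache:
            oh = np.arange(h_out) * self.stride
            ow = np.arange(w_out) * self.stride
            ki = np.arange(self.k)
            # padded-input coordinates per (out_y, out_x, ky, kx)
            idx_h = oh[:, None, None, None] + ki[None, None, :, None]
            idx_w = ow[None, :, None, None] + ki[None, None, None, :]
            self._idx_cache[key] = (
                np.broadcast_to(idx_h, (h_out, w_out, self.k, self.k)),
                np.broadcast_to(idx_w, (h_out, w_out, self.k, self.k)),
            )
        return self._idx_cache[key]

    def forward(self, x, training: bool = False):
        n, h, w, _ = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]                      # (N, Ho, Wo, C, k, k)
        h_out, w_out = win.shape[1], win.shape[2]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(
            n * h_out * w_out, k * k * self.c_in
        )
        w_mat = self.params["W"].reshape(k * k * self.c_in, self.c_out)
        out = cols @ w_mat + self.params["b"]
        self._cache = (cols, x.shape, (h_out, w_out))
        return out.reshape(n, h_out, w_out, self.c_out)

    def backward(self, dout):
        cols, x_shape, (h_out, w_out) = self._cache
        n, h, w, c = x_shape
        p, k, s = self.pad, self.k, self.stride
        dmat = dout.reshape(n * h_out * w_out, self.c_out)
        self.grads["W"] = (cols.T @ dmat).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        w_mat = self.params["W"].reshape(k * k * c, self.c_out)
        dcols = (dmat @ w_mat.T).reshape(n, h_out, w_out, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        idx_h, idx_w = self._indices(h_out, w_out)
        np.add.at(
            dxp,
            (np.arange(n)[:, None, None, None, None], idx_h[None], idx_w[None]),
            dcols,
        )
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def forward(self, x, training: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)),
            "b": rng.uniform(-0.1, 0.1, size=d_out),
        }

    def forward(self, x, training: bool = False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference.  Needs an rng per forward."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def forward(self, x, training: bool = False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / (h * w)


class Flatten(Layer):
    """(N, H, W, C) -> (N, H*W*C); keeps coarse spatial detail for the trunk."""

    def forward(self, x, training: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class FeatureNorm(Layer):
    """Per-feature standardization with externally supplied statistics.

    The counterpart of inference-mode batch normalization for the pooled
    feature vector: statistics are frozen snapshots (refreshed between
    training stages), so the transform is deterministic and the backward
    pass treats them as constants.
    """

    def __init__(self, dim: int):
        super().__init__()
        self.mean = np.zeros(dim)
        self.std = np.ones(dim)

    def set_stats(self, feats: np.ndarray, floor: float = 1e-3) -> None:
        self.mean[...] = feats.mean(axis=0)
        self.std[...] = np.maximum(feats.std(axis=0), floor)

    def forward(self, x, training: bool = False):
        return (x - self.mean) / self.std

    def backward(self, dout):
        return dout / self.std


class GlobalAvgMaxPool(Layer):
    """(N, H, W, C) -> (N, 2C): concatenated spatial mean and maximum.

    The mean channel carries area-weighted evidence; the max channel carries
    translation-invariant *presence* evidence, which matters when a texture
    occupies a small fraction of the image.
    """

    def forward(self, x, training: bool = False):
        self._shape = x.shape
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        self._argmax = flat.argmax(axis=1)        # (N, C)
        return np.concatenate([flat.mean(axis=1), flat.max(axis=1)], axis=1)

    def backward(self, dout):
        n, h, w, c = self._shape
        d_avg, d_max = dout[:, :c], dout[:, c:]
        dx = np.broadcast_to(d_avg[:, None, None, :], self._shape) / (h * w)
        dflat = np.zeros((n, h * w, c))
        np.put_along_axis(dflat, self._argmax[:, None, :], d_max[:, None, :],
                          axis=1)
        return dx + dflat.reshape(self._shape)
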