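"""Desk-scale multi-task convolutional classifier for dermoscopic patterns.

A small strided-convolution backbone (three blocks, global average pooling
by default, with avg+max and flatten variants) feeds a normalized pooled
feature vector into a three-layer classifier: a shared dense trunk with
dropout and two parallel output layers — one 1-logit binary diagnosis head
and one 7-logit multilabel pattern head.  The design mirrors, at toy
scale, lightweight mobile architectures used for dermoscopic triage; it
trains on one CPU.

Parameters live in a flat ``{name: array}`` store with names prefixed by
component (``block1.conv.W``, ``trunk.W``, ``binary_head.b``, ...), which
makes per-stage freezing (by prefix) and checkpointing straightforward.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .layers import (Conv2d, Dense, Dropout, FeatureNorm, Flatten,
                     GlobalAvgMaxPool, GlobalAvgPool, ReLU)
from .losses import sigmoid


class MultiTaskPatternCNN(BaseEstimator):
    """Shared-backbone classifier with binary and 7-flag pattern heads.

    Parameters
    ----------
    channels : tuple of int
        Output channels of the three stride-2 convolution blocks.
    hidden : int
        Width of the shared classifier trunk.
    dropout : float
        Trunk dropout rate (training mode only).
    random_state : int
        Seed for weight initialization and dropout.
    config : TrainConfig, optional
        Training schedule used by :meth:`fit`; defaults to the package's
        three-stage schedule.

    Attributes
    ----------
    params_ : dict
        Flat parameter store (views into the layers' arrays).
    history_ : dict
        Per-stage training history after :meth:`fit`.
    """

    N_BLOCKS = 3

    def __init__(self, channels=(16, 32, 96), hidden: int = 96,
                 dropout: float = 0.0, pool: str = "avg",
                 image_size: int = 64, random_state: int = 0, config=None):
        self.channels = channels
        self.hidden = hidden
        self.dropout = dropout
        self.pool = pool
        self.image_size = image_size
        self.random_state = random_state
        self.config = config

    # ------------------------------------------------------------------ build
    def build(self, in_channels: int = 1):
        """Initialize layers and the flat parameter store (idempotent)."""
        if hasattr(self, "params_"):
            return self
        rng = np.random.default_rng(
            np.random.SeedSequence(self.random_state, spawn_key=(100,))
        )
        chans = (in_channels, *self.channels)
        self._blocks = []
        for i in range(self.N_BLOCKS):
            conv = Conv2d(chans[i], chans[i + 1], kernel=3, stride=2, pad=1,
                          rng=rng)
            self._blocks.append((conv, ReLU()))
        if self.pool == "avg":
            self._gap = GlobalAvgPool()
            trunk_in = self.channels[-1]
        elif self.pool == "avgmax":
            self._gap = GlobalAvgMaxPool()
            trunk_in = 2 * self.channels[-1]
        elif self.pool == "flatten":
            self._gap = Flatten()
            side = self.image_size
            for _ in range(self.N_BLOCKS):
                side = (side + 1) // 2        # stride-2, pad-1, kernel-3
            trunk_in = side * side * self.channels[-1]
        else:
            raise ValueError("pool must be 'avg', 'avgmax' or 'flatten'")
        self._fnorm = FeatureNorm(trunk_in)
        self._trunk = Dense(trunk_in, self.hidden, rng=rng)
        self._trunk_relu = ReLU()
        self._dropout = Dropout(self.dropout)
        self._binary_head = Dense(self.hidden, 1, rng=rng)
        self._pattern_head = Dense(self.hidden, 7, rng=rng)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(self.random_state, spawn_key=(101,))
        )
        self.params_ = {"fnorm.mean": self._fnorm.mean,
                        "fnorm.std": self._fnorm.std}
        for i, (conv, _) in enumerate(self._blocks, start=1):
            for k, v in conv.params.items():
                self.params_[f"block{i}.conv.{k}"] = v
        for prefix, layer in (("trunk", self._trunk),
                              ("binary_head", self._binary_head),
                              ("pattern_head", self._pattern_head)):
            for k, v in layer.params.items():
                self.params_[f"{prefix}.{k}"] = v
        return self

    def _named_layers(self):
        out = []
        for i, (conv, _) in enumerate(self._blocks, start=1):
            out.append((f"block{i}.conv", conv))
        out += [("trunk", self._trunk), ("binary_head", self._binary_head),
                ("pattern_head", self._pattern_head)]
        return out

    def collect_grads(self) -> dict:
        """Flat gradient dict matching ``params_`` keys (after backward)."""
        grads = {}
        for prefix, layer in self._named_layers():
            for k, v in layer.grads.items():
                grads[f"{prefix}.{k}"] = v
        return grads

    # ---------------------------------------------------------------- forward
    @staticmethod
    def _as_nhwc(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4:
            raise ValueError("X must have shape (n, h, w) or (n, h, w, c)")
        return X

    def forward(self, X, training: bool = False):
        """Full forward pass; returns ``(binary_logits, pattern_logits)``.

        Layer caches are left in place for a subsequent ``backward``.
        """
        x = self._as_nhwc(X)
        for conv, relu in self._blocks:
            x = relu.forward(conv.forward(x, training), training)
        self._features = x                       # post-ReLU feature maps
        g = self._fnorm.forward(self._gap.forward(x, training))
        h = self._trunk_relu.forward(self._trunk.forward(g, training), training)
        h = self._dropout.forward(h, training,
                                  rng=self._dropout_rng if training else None)
        logit_b = self._binary_head.forward(h, training)[:, 0]
        logits_p = self._pattern_head.forward(h, training)
        return logit_b, logits_p

    def backward(self, d_binary=None, d_pattern=None,
                 through_backbone: bool = True):
        """Backpropagate head gradients; returns d(features) or d(input).

        ``d_binary`` has shape (n,), ``d_pattern`` (n, 7); either may be
        None.  With ``through_backbone=False`` the pass stops at the global
        pooling and returns the gradient w.r.t. the backbone feature maps.
        """
        n = None
        dh = 0.0
        if d_binary is not None:
            n = d_binary.shape[0]
            dh = dh + self._binary_head.backward(
                np.asarray(d_binary, dtype=float)[:, None]
            )
        if d_pattern is not None:
            n = np.asarray(d_pattern).shape[0]
            dh = dh + self._pattern_head.backward(
                np.asarray(d_pattern, dtype=float)
            )
        if n is None:
            raise ValueError("at least one head gradient is required")
        dh = self._dropout.backward(dh)
        dg = self._trunk.backward(self._trunk_relu.backward(dh))
        dfeat = self._gap.backward(self._fnorm.backward(dg))
        if not through_backbone:
            return dfeat
        dx = dfeat
        for conv, relu in reversed(self._blocks):
            dx = conv.backward(relu.backward(dx))
        return dx

    # -------------------------------------------------------------- inference
    def predict_proba(self, X) -> dict:
        """Probabilities: ``{"binary": (n,), "patterns": (n, 7)}``."""
        logit_b, logits_p = self.forward(X, training=False)
        return {"binary": sigmoid(logit_b), "patterns": sigmoid(logits_p)}

    def predict(self, X) -> np.ndarray:
        """Binary BCC / non-BCC diagnosis from the binary head (>= 0.5)."""
        return (self.predict_proba(X)["binary"] >= 0.5).astype(int)

    def predict_patterns(self, X, threshold: float = 0.5) -> np.ndarray:
        """Hard 7-flag pattern predictions (probability >= threshold)."""
        return (self.predict_proba(X)["patterns"] >= threshold).astype(int)

    def backbone_features(self, X) -> np.ndarray:
        """Pooled/flattened backbone features in inference mode."""
        x = self._as_nhwc(X)
        for conv, relu in self._blocks:
            x = relu.forward(conv.forward(x, False), False)
        if self.pool == "avg":
            return x.mean(axis=(1, 2))
        if self.pool == "avgmax":
            return np.concatenate(
                [x.mean(axis=(1, 2)), x.max(axis=(1, 2))], axis=1
            )
        return x.reshape(x.shape[0], -1)

    def update_feature_norm(self, X) -> None:
        """Refresh the pooled-feature normalization statistics from data."""
        self._fnorm.set_stats(self.backbone_features(X))

    def trunk_forward_from_features(self, g, training: bool = False):
        """Classifier pass from raw pooled features (backbone frozen)."""
        g = self._fnorm.forward(g)
        h = self._trunk_relu.forward(self._trunk.forward(g, training), training)
        h = self._dropout.forward(h, training,
                                  rng=self._dropout_rng if training else None)
        return (self._binary_head.forward(h, training)[:, 0],
                self._pattern_head.forward(h, training))

    def feature_activations_and_gradients(self, X, head: str = "binary",
                                          class_index: int = 0):
        """Feature maps of the last conv block and d(score)/d(features).

        The score is the selected head logit; the gradient is computed by
        the model's own backward pass in inference mode (no dropout).
        """
        if head not in ("binary", "pattern"):
            raise ValueError("head must be 'binary' or 'pattern'")
        logit_b, logits_p = self.forward(X, training=False)
        n = self._features.shape[0]
        if head == "binary":
            dA = self.backward(d_binary=np.ones(n), through_backbone=False)
        else:
            if not 0 <= class_index < logits_p.shape[1]:
                raise ValueError("class_index out of range for pattern head")
            seed = np.zeros_like(logits_p)
            seed[:, class_index] = 1.0
            dA = self.backward(d_pattern=seed, through_backbone=False)
        return self._features, dA

    # ------------------------------------------------------------- fit / io
    def fit(self, X, y):
        """Three-stage training on images ``X`` and 7-flag SR labels ``y``.

        The binary diagnosis target is derived from the pattern labels by
        the clinical decision rule.  See ``bccxai.training`` for the stage
        schedule.
        """
        from ..training import TrainConfig, three_stage_train

        config = self.config if self.config is not None else TrainConfig()
        self.build(in_channels=self._as_nhwc(X).shape[-1])
        self.history_ = three_stage_train(self, X, y, config)
        return self

    def save_weights(self, path) -> None:
        np.savez(path, **self.params_)

    def load_weights(self, path, in_channels: int = 1):
        self.build(in_channels=in_channels)
        with np.load(path) as data:
            for name in self.params_:
                self.params_[name][...] = data[name]
        return self
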