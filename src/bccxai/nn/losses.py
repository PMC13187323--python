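"""Focal loss for imbalanced multilabel targets, with analytic gradients.

The focal loss down-weights easy examples:  L = -w (1 - p_t)^gamma log p_t
with p_t the probability the model assigns to the true flag.  gamma = 0 and
unit weights recover plain binary cross-entropy exactly.  Probabilities are
clamped to [1e-7, 1 - 1e-7] before the logarithm.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                    np.exp(x) / (1.0 + np.exp(x)))


def focal_loss(probs, targets, gamma: float = 2.0, class_weights=None) -> float:
    """Mean focal loss over all (sample, class) entries.

    Parameters
    ----------
    probs : array-like
        Predicted probabilities in (0, 1) (clamped at 1e-7 internally).
    targets : array-like
        Binary flags, same shape.
    gamma : float >= 0
        Focusing exponent; 0 recovers binary cross-entropy.
    class_weights : array-like, optional
        Per-class weight broadcast over the last axis.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(np.asarray(probs, dtype=float), _EPS, 1 - _EPS)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError("probs and targets must have the same shape")
    w = 1.0 if class_weights is None else np.asarray(class_weights, dtype=float)
    p_t = t * p + (1 - t) * (1 - p)
    loss = -w * (1 - p_t) ** gamma * np.log(p_t)
    return float(np.mean(loss))


def binary_cross_entropy(probs, targets) -> float:
    """Mean binary cross-entropy (the gamma = 0 focal limit)."""
    return focal_loss(probs, targets, gamma=0.0)


def focal_loss_and_grad(logits, targets, gamma: float = 2.0, class_weights=None):
    """Focal loss on sigmoid(logits) and its gradient w.r.t. the logits.

    Returns ``(loss, dlogits)`` with the gradient of the *mean* loss, for
    direct use in backpropagation.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    s = np.asarray(logits, dtype=float)
    t = np.asarray(targets, dtype=float)
    w = 1.0 if class_weights is None else np.asarray(class_weights, dtype=float)
    p = sigmoid(s)
    pc = np.clip(p, _EPS, 1 - _EPS)
    p_t = t * pc + (1 - t) * (1 - pc)
    one_m = 1 - p_t
    loss = float(np.mean(-w * one_m**gamma * np.log(p_t)))
    # dL/dp_t, with the gamma = 0 branch free of the 0^(-1) singularity
    if gamma == 0:
        dl_dpt = -w / p_t
    else:
        dl_dpt = w * (gamma * one_m ** (gamma - 1) * np.log(p_t)
                      - one_m**gamma / p_t)
    sign = 2 * t - 1                      # dp_t/dp
    dlogits = dl_dpt * sign * p * (1 - p) / s.size
    return loss, dlogits
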