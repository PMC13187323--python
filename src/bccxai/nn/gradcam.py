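"""Gradient-weighted class activation mapping for the multi-task model.

The localization map of a target score (a head logit) is built from the
gradients of that score flowing into the last convolutional feature layer:
channel weights are the spatially averaged gradients, the map is the
rectified weighted sum of the feature maps, bilinearly upsampled to image
size and min-max normalized to [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.transform import resize


def gradcam(model, image, head: str = "binary", class_index: int = 0) -> np.ndarray:
    """Class activation map of one image, in [0, 1] at image resolution.

    Parameters
    ----------
    model : object
        Must expose ``feature_activations_and_gradients(X, head,
        class_index)`` returning the designated conv layer's activations
        and the target-score gradients, both shaped (1, h, w, c).
    image : array-like
        Single image, shape (h, w) or (h, w, c).
    head, class_index :
        Target output: the binary-diagnosis logit or one pattern logit.

    Notes
    -----
    A map that is constant before normalization (e.g. all activations
    rectified away) is returned as all-zeros with a warning.
    """
    img = np.asarray(image, dtype=float)
    spatial = img.shape[:2]
    X = img[None]
    A, dA = model.feature_activations_and_gradients(X, head=head,
                                                    class_index=class_index)
    weights = dA.mean(axis=(1, 2))                 # (1, c) pooled gradients
    cam = np.maximum((A * weights[:, None, None, :]).sum(axis=-1), 0.0)[0]
    cam = resize(cam, spatial, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    lo, hi = float(cam.min()), float(cam.max())
    if hi - lo == 0:
        warnings.warn("constant class activation map: returning all-zeros")
        return np.zeros(spatial)
    return (cam - lo) / (hi - lo)
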