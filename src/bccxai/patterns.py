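"""Dermoscopic pattern label codification and the pattern-to-diagnosis rule.

Seven dermoscopic patterns are tracked per lesion, in a fixed order:

======  =========================  ====================
flag    pattern                    diagnostic role
======  =========================  ====================
PN      pigment network            negative criterion
U       ulceration                 BCC-positive
ON      ovoid nests                BCC-positive
MG      multiglobules              BCC-positive
ML      maple-leaf-like            BCC-positive
SW      spoke wheel                BCC-positive
AT      arborizing telangiectasia  BCC-positive
======  =========================  ====================

A lesion label is a binary 7-vector in this order.  The clinical decision
rule mirrors how dermatologists read these patterns: a lesion showing at
least one of the six BCC-positive patterns is called BCC; a lesion showing
no pattern, or only the pigment network, is called non-BCC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical pattern order used by every module and every CSV column layout.
PATTERN_NAMES: tuple[str, ...] = ("PN", "U", "ON", "MG", "ML", "SW", "AT")

#: Number of tracked dermoscopic patterns.
N_PATTERNS: int = len(PATTERN_NAMES)

#: Index of the pigment-network flag (the negative criterion).
PN_INDEX: int = 0

#: Indices of the six BCC-positive patterns.
BCC_PATTERN_INDICES: tuple[int, ...] = tuple(range(1, N_PATTERNS))


def validate_pattern_vector(patterns) -> np.ndarray:
    """Validate and coerce a single 7-flag pattern vector.

    Parameters
    ----------
    patterns : array-like
        Sequence of 7 values, each 0 or 1.

    Returns
    -------
    numpy.ndarray
        Integer array of shape ``(7,)``.

    Raises
    ------
    ValueError
        If the vector is not length 7 or contains non-binary entries.
    """
    arr = np.asarray(patterns)
    if arr.shape != (N_PATTERNS,):
        raise ValueError(
            f"pattern vector must have shape ({N_PATTERNS},), got {arr.shape}"
        )
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("pattern vector entries must be 0 or 1")
    return arr.astype(int)


def validate_pattern_matrix(patterns) -> np.ndarray:
    """Validate an ``(n_images, 7)`` stack of pattern vectors."""
    arr = np.asarray(patterns)
    if arr.ndim != 2 or arr.shape[1] != N_PATTERNS:
        raise ValueError(
            f"pattern matrix must have shape (n, {N_PATTERNS}), got {arr.shape}"
        )
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("pattern matrix entries must be 0 or 1")
    return arr.astype(int)


def encode_diagnosis(patterns, pn_veto: bool = False) -> int:
    """Map a 7-flag pattern vector to the binary BCC / non-BCC diagnosis.

    Returns 1 (BCC) iff at least one of the six BCC-positive patterns
    (U, ON, MG, ML, SW, AT) is present.  The all-zero vector and a
    pigment-network-only vector both map to 0 (non-BCC).

    Parameters
    ----------
    patterns : array-like
        Binary 7-vector in :data:`PATTERN_NAMES` order.
    pn_veto : bool, default False
        If True, a present pigment network vetoes the diagnosis even when a
        BCC-positive pattern co-occurs.  The default follows the clinical
        sufficiency rule (one BCC pattern suffices); the veto variant is
        provided because PN + BCC-pattern co-occurrence is never shown in
        the canonical worked examples.

    Returns
    -------
    int
        1 for BCC, 0 for non-BCC.
    """
    arr = validate_pattern_vector(patterns)
    has_bcc_pattern = bool(arr[list(BCC_PATTERN_INDICES)].any())
    if pn_veto and arr[PN_INDEX] == 1:
        return 0
    return int(has_bcc_pattern)


def encode_diagnoses(patterns, pn_veto: bool = False) -> np.ndarray:
    """Vectorized :func:`encode_diagnosis` over an ``(n, 7)`` matrix."""
    arr = validate_pattern_matrix(patterns)
    diag = arr[:, list(BCC_PATTERN_INDICES)].any(axis=1).astype(int)
    if pn_veto:
        diag[arr[:, PN_INDEX] == 1] = 0
    return diag


def labels_to_frame(labels, image_ids=None) -> pd.DataFrame:
    """Build the canonical label table (``image_id`` + one column per flag)."""
    arr = validate_pattern_matrix(labels)
    if image_ids is None:
        image_ids = [f"img_{i:05d}" for i in range(arr.shape[0])]
    if len(image_ids) != arr.shape[0]:
        raise ValueError("image_ids length does not match labels")
    frame = pd.DataFrame(arr, columns=list(PATTERN_NAMES))
    frame.insert(0, "image_id", list(image_ids))
    return frame


def frame_to_labels(frame: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Inverse of :func:`labels_to_frame`; returns (image_ids, labels)."""
    missing = [c for c in ("image_id", *PATTERN_NAMES) if c not in frame.columns]
    if missing:
        raise ValueError(f"label table missing columns: {missing}")
    labels = validate_pattern_matrix(frame[list(PATTERN_NAMES)].to_numpy())
    return frame["image_id"].astype(str).tolist(), labels
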