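"""Clinically-inspired evaluation of predicted pattern vectors.

Beyond standard per-pattern confusion metrics, these evaluations capture the
clinical sufficiency logic of BCC diagnosis: a dermatologist needs only one
correctly detected BCC pattern in a BCC lesion, the pigment network acts as
a negative criterion in non-BCC lesions, and a pattern-free lesion should be
predicted pattern-free.  Empty subgroups yield *undefined* rates (NaN) with
a zero count — never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import (
    BCC_PATTERN_INDICES,
    PATTERN_NAMES,
    PN_INDEX,
    validate_pattern_matrix,
)


def _confusion_rates(pred: np.ndarray, ref: np.ndarray) -> dict:
    """recall / specificity / precision / accuracy from two binary vectors.

    Undefined rates (empty denominator) are NaN.
    """
    tp = int(((pred == 1) & (ref == 1)).sum())
    tn = int(((pred == 0) & (ref == 0)).sum())
    fp = int(((pred == 1) & (ref == 0)).sum())
    fn = int(((pred == 0) & (ref == 1)).sum())

    def rate(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "recall": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "precision": rate(tp, tp + fp),
        "accuracy": rate(tp + tn, tp + tn + fp + fn),
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


@dataclass
class ClinicalXAIMetrics:
    """Rates of the clinical sufficiency logic, with subgroup sizes.

    ``NaN`` marks a rate whose subgroup is empty (undefined, not zero).
    """

    no_pattern_accuracy: float
    n_no_pattern: int
    pn_metrics: dict
    n_pn_reference: int
    bcc_pattern_hit_rate: float
    bcc_metrics: dict
    n_bcc_pattern_reference: int
    binary_metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "no_pattern_accuracy": self.no_pattern_accuracy,
            "n_no_pattern": self.n_no_pattern,
            "pn_metrics": self.pn_metrics,
            "n_pn_reference": self.n_pn_reference,
            "bcc_pattern_hit_rate": self.bcc_pattern_hit_rate,
            "bcc_metrics": self.bcc_metrics,
            "n_bcc_pattern_reference": self.n_bcc_pattern_reference,
            "binary_metrics": self.binary_metrics,
        }


def clinical_xai_metrics(predicted, reference) -> ClinicalXAIMetrics:
    """Compute the clinically-inspired rates from aligned pattern vectors.

    Parameters
    ----------
    predicted, reference : array-like of shape (n_images, 7)
        Binary pattern vectors, aligned by position.

    Notes
    -----
    * ``no_pattern_accuracy`` — among images whose reference is all-zero,
      the fraction predicted all-zero.
    * ``pn_metrics`` — confusion metrics of the pigment-network column.
    * ``bcc_pattern_hit_rate`` — among images whose reference carries at
      least one BCC-positive pattern, the fraction whose predicted
      BCC-positive set intersects the reference set (one shared pattern
      suffices for the clinical rationale).
    """
    pred = validate_pattern_matrix(predicted)
    ref = validate_pattern_matrix(reference)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference must be aligned")

    bcc_ix = list(BCC_PATTERN_INDICES)

    no_pattern = ref.sum(axis=1) == 0
    n_np = int(no_pattern.sum())
    np_acc = (
        float((pred[no_pattern].sum(axis=1) == 0).mean()) if n_np else float("nan")
    )

    pn = _confusion_rates(pred[:, PN_INDEX], ref[:, PN_INDEX])

    has_bcc = ref[:, bcc_ix].any(axis=1)
    n_bcc = int(has_bcc.sum())
    if n_bcc:
        hits = (pred[has_bcc][:, bcc_ix] & ref[has_bcc][:, bcc_ix]).any(axis=1)
        hit_rate = float(hits.mean())
    else:
        hit_rate = float("nan")

    # image-level "any BCC pattern present" as a binary signal
    bcc_any = _confusion_rates(
        pred[:, bcc_ix].any(axis=1).astype(int), has_bcc.astype(int)
    )

    from .patterns import encode_diagnoses

    binary = _confusion_rates(encode_diagnoses(pred), encode_diagnoses(ref))

    return ClinicalXAIMetrics(
        no_pattern_accuracy=np_acc,
        n_no_pattern=n_np,
        pn_metrics=pn,
        n_pn_reference=int(ref[:, PN_INDEX].sum()),
        bcc_pattern_hit_rate=hit_rate,
        bcc_metrics=bcc_any,
        n_bcc_pattern_reference=n_bcc,
        binary_metrics=binary,
    )


def per_pattern_metrics(predicted, reference, fold_ids=None) -> pd.DataFrame:
    """Standard confusion metrics per pattern, optionally fold-averaged.

    Without folds, one row per pattern with recall / specificity /
    precision / accuracy plus raw counts.  With ``fold_ids`` (an array
    assigning each image to a fold), metrics are computed per fold then
    averaged with unweighted fold means; across-fold variances are added
    as ``<metric>_var`` and folds where a metric is undefined are excluded
    from its average (their number reported in ``<metric>_n_undefined``).
    """
    pred = validate_pattern_matrix(predicted)
    ref = validate_pattern_matrix(reference)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference must be aligned")

    metric_names = ("recall", "specificity", "precision", "accuracy")
    rows = []
    if fold_ids is None:
        for j, name in enumerate(PATTERN_NAMES):
            rows.append({"pattern": name,
                         **_confusion_rates(pred[:, j], ref[:, j])})
        return pd.DataFrame(rows).set_index("pattern")

    fold_ids = np.asarray(fold_ids)
    if fold_ids.shape[0] != pred.shape[0]:
        raise ValueError("fold_ids must assign every image to a fold")
    folds = np.unique(fold_ids)
    for j, name in enumerate(PATTERN_NAMES):
        per_fold = {m: [] for m in metric_names}
        for f in folds:
            sel = fold_ids == f
            rates = _confusion_rates(pred[sel, j], ref[sel, j])
            for m in metric_names:
                per_fold[m].append(rates[m])
        row = {"pattern": name}
        for m in metric_names:
            vals = np.asarray(per_fold[m], dtype=float)
            defined = vals[~np.isnan(vals)]
            row[m] = float(defined.mean()) if defined.size else float("nan")
            row[f"{m}_var"] = (
                float(defined.var(ddof=0)) if defined.size else float("nan")
            )
            row[f"{m}_n_undefined"] = int(np.isnan(vals).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("pattern")
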