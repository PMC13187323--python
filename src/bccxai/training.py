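"""Three-stage multi-task training, multilabel stratified folds, augmentation.

The training strategy mirrors a transfer-learning protocol at desk scale:

* stage 1 — train the classifier only (backbone frozen) on the binary
  BCC / non-BCC task;
* stage 2 — unfreeze the deeper backbone blocks and fine-tune, still on
  the binary task, at a lower learning rate;
* stage 3 — with the backbone frozen again, retrain the classifier's
  pattern head (the 7-flag output), at a rate no higher than stage 2's.

Learning rates are non-increasing across stages.  Because the toy backbone
starts from random weights rather than large-scale pretraining, the
absolute schedule (rates, epoch counts) was chosen by pilot runs on the
synthetic generator and is documented in the package's methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage.filters import gaussian
from skimage.transform import ProjectiveTransform, rotate, warp

from .metrics import _confusion_rates, clinical_xai_metrics, per_pattern_metrics
from .patterns import N_PATTERNS, encode_diagnoses, validate_pattern_matrix
from .synthetic import component_rng
from .nn.losses import focal_loss_and_grad
from .nn.optim import AdamW

_BLOCK_PREFIXES = ("block1", "block2", "block3")


@dataclass
class StageConfig:
    """One training stage: schedule, trainable scope and task."""

    name: str
    epochs: int
    lr: float
    scope: tuple[str, ...]     # parameter-name prefixes that may update
    task: str                  # "binary" or "pattern"
    augment: bool = True
    weight_decay: float = 0.0


@dataclass
class TrainConfig:
    """Full three-stage schedule plus shared optimization settings.

    Defaults were fixed by pilot runs on the synthetic generator: stage 1
    fits the classifier on frozen random backbone features, stage 2
    fine-tunes the deeper backbone blocks at a lower rate (the earliest
    block keeps its intensity-band-selective initialization, playing the
    role the preserved early stack plays in full-scale transfer learning),
    stage 3 trains the pattern head on the frozen backbone and trunk.
    Stage learning rates must be non-increasing.  Geometric augmentation is
    off by default because interpolation smears the generator's disjoint
    intensity bands; it can be enabled per stage for other data.
    """

    stages: tuple[StageConfig, ...] = (
        StageConfig("classifier", epochs=40, lr=2e-3,
                    scope=("trunk", "binary_head"), task="binary",
                    augment=False),
        StageConfig("finetune", epochs=150, lr=5e-4,
                    scope=("block2", "block3", "trunk", "binary_head"),
                    task="binary", augment=False),
        StageConfig("pattern", epochs=2000, lr=3e-4,
                    scope=("pattern_head",), task="pattern",
                    augment=False, weight_decay=1e-3),
    )
    batch_size: int = 32
    gamma: float = 2.0
    class_weighting: str = "inverse_prevalence"   # or "none"
    k_folds: int = 5
    seed: int = 0
    rotation: bool = True
    perspective: bool = True
    blur: bool = True
    n_cached_augments: int = 4   # extra augmented copies in frozen-backbone stages

    def validate(self) -> None:
        if len(self.stages) != 3:
            raise ValueError("the training strategy has exactly three stages")
        lrs = [s.lr for s in self.stages]
        if not all(a >= b for a, b in zip(lrs, lrs[1:])):
            raise ValueError("stage learning rates must be non-increasing")
        for s in self.stages:
            if s.task not in ("binary", "pattern"):
                raise ValueError(f"unknown task {s.task!r}")
            if s.epochs < 1:
                raise ValueError("every stage needs >= 1 epoch")


# ---------------------------------------------------------------- k-fold
def stratified_kfold_split(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Iterative multilabel stratification into k disjoint folds.

    Greedy label-by-rarity assignment: repeatedly take the label with the
    fewest unassigned positives and deal its examples to the fold with the
    greatest remaining demand for that label (ties: most remaining
    capacity, then seeded random).  Label-free examples are dealt by
    capacity.  Folds partition all indices; per-fold label proportions
    track the global proportions.

    Parameters
    ----------
    labels : array of shape (n, m)
        Binary label matrix (any m >= 1; pass the 7 pattern flags plus the
        derived binary diagnosis for the canonical use).
    k : int
        Number of folds, 2 <= k <= n.
    """
    y = np.asarray(labels)
    if y.ndim != 2 or not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be a binary (n, m) matrix")
    n, m = y.shape
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))

    counts = y.sum(axis=0)
    scarce = counts[counts > 0]
    if (scarce < k).any():
        warnings.warn(
            "some label columns have fewer positives than folds; "
            "best-effort placement"
        )
    desired = np.tile(counts / k, (k, 1)).astype(float)   # (k, m)
    capacity = np.full(k, n / k)
    assignment = np.full(n, -1)

    remaining = np.ones(n, dtype=bool)
    while True:
        pos_left = (y[remaining] == 1).sum(axis=0)
        if not (pos_left > 0).any():
            break
        j = np.argmin(np.where(pos_left > 0, pos_left, np.inf))
        idx = np.flatnonzero(remaining & (y[:, j] == 1))
        rng.shuffle(idx)
        for i in idx:
            best = np.flatnonzero(desired[:, j] == desired[:, j].max())
            if best.size > 1:
                caps = capacity[best]
                best = best[caps == caps.max()]
            f = int(rng.choice(best))
            assignment[i] = f
            desired[f] -= y[i]
            capacity[f] -= 1
            remaining[i] = False
    for i in np.flatnonzero(remaining):
        best = np.flatnonzero(capacity == capacity.max())
        f = int(rng.choice(best))
        assignment[i] = f
        capacity[f] -= 1

    return [np.flatnonzero(assignment == f) for f in range(k)]


# ---------------------------------------------------------------- augment
def augment(image, seed: int | None = None, rng=None, rotation: bool = True,
            perspective: bool = True, blur: bool = True) -> np.ndarray:
    """Seeded random rotation, perspective warp and Gaussian blur.

    Emulates acquisition variability: lesion orientation, camera angle and
    slight defocus.  Output has the input's shape, clipped to [0, 1].
    With every toggle off this is the identity.
    """
    img = np.asarray(image, dtype=float)
    if rng is None:
        rng = component_rng(0 if seed is None else seed, "augment")
    out = img
    if rotation:
        out = rotate(out, angle=float(rng.uniform(-30, 30)), mode="edge",
                     order=1)
    if perspective:
        h, w = out.shape[:2]
        src = np.array([[0, 0], [0, h - 1], [w - 1, h - 1], [w - 1, 0]],
                       dtype=float)
        dst = src + rng.uniform(-0.06, 0.06, size=src.shape) * min(h, w)
        tform = ProjectiveTransform()
        tform.estimate(dst, src)
        out = warp(out, tform, mode="edge", order=1)
    if blur:
        out = gaussian(out, sigma=float(rng.uniform(0.2, 1.0)),
                       preserve_range=True)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------- training
def _scope_params(model, prefixes) -> set[str]:
    return {name for name in model.params_
            if any(name.startswith(p + ".") for p in prefixes)}


def _pattern_class_weights(labels, mode: str):
    """Alpha-balanced per-class weights: ``(w_positive, w_negative)``.

    Each class's positive and negative terms are reweighted inversely to
    their frequency, so rare patterns are not drowned by their negatives.
    Returns None when weighting is disabled.
    """
    if mode == "none":
        return None
    prev = np.clip(labels.mean(axis=0), 0.05, 0.95)
    return 0.5 / prev, 0.5 / (1.0 - prev)


def _classifier_backward(model, d_binary=None, d_pattern=None):
    """Backward through the classifier only (cached-feature fast path)."""
    dh = 0.0
    if d_binary is not None:
        dh = dh + model._binary_head.backward(d_binary[:, None])
    if d_pattern is not None:
        dh = dh + model._pattern_head.backward(d_pattern)
    dh = model._dropout.backward(dh)
    model._trunk.backward(model._trunk_relu.backward(dh))


def three_stage_train(model, images, sr_labels, config: TrainConfig) -> dict:
    """Run the three-stage schedule; returns the per-stage history.

    ``images`` is (n, h, w[, c]) in [0, 1]; ``sr_labels`` the (n, 7) SR
    pattern flags.  The binary target is derived by the clinical decision
    rule.  Each stage gets a fresh AdamW state restricted to its scope, so
    frozen parameters are bit-identical before and after the stage.
    """
    config.validate()
    X = np.asarray(images, dtype=float)
    Y = validate_pattern_matrix(sr_labels)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("images and labels must be aligned")
    y_bin = encode_diagnoses(Y).astype(float)
    model.build(in_channels=1 if X.ndim == 3 else X.shape[-1])

    rng = component_rng(config.seed, "training")
    w_pattern = _pattern_class_weights(Y, config.class_weighting)
    w_binary = _pattern_class_weights(y_bin[:, None], config.class_weighting)
    history = {"stages": [], "config": asdict(config)}

    for stage in config.stages:
        model.update_feature_norm(X)   # refresh pooled-feature statistics
        scope = _scope_params(model, stage.scope)
        opt = AdamW(lr=stage.lr, weight_decay=stage.weight_decay)
        touches_backbone = any(p in _BLOCK_PREFIXES for p in stage.scope)
        use_cache = not touches_backbone
        feats, y_b_st, Y_st = None, None, None
        if use_cache:
            # Backbone frozen: augmentation happens once, up front, and only
            # the cached pooled features circulate through the epochs.
            feats = model.backbone_features(X)
            y_b_st, Y_st = y_bin, Y
            if stage.augment and config.n_cached_augments > 0:
                extra = []
                for _ in range(config.n_cached_augments):
                    Xa = np.stack([
                        augment(im, rng=rng, rotation=config.rotation,
                                perspective=config.perspective,
                                blur=config.blur)
                        for im in X
                    ])
                    extra.append(model.backbone_features(Xa))
                feats = np.concatenate([feats, *extra])
                reps = config.n_cached_augments + 1
                y_b_st = np.tile(y_bin, reps)
                Y_st = np.tile(Y, (reps, 1))

        losses = []
        n = feats.shape[0] if use_cache else X.shape[0]
        for _ in range(stage.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                if use_cache:
                    logit_b, logits_p = model.trunk_forward_from_features(
                        feats[idx], training=True
                    )
                else:
                    xb = X[idx]
                    if stage.augment:
                        xb = np.stack([
                            augment(im, rng=rng, rotation=config.rotation,
                                    perspective=config.perspective,
                                    blur=config.blur)
                            for im in xb
                        ])
                    logit_b, logits_p = model.forward(xb, training=True)
                yb = y_b_st if use_cache else y_bin
                yp = Y_st if use_cache else Y
                if stage.task == "binary":
                    t = yb[idx]
                    w_el = None
                    if w_binary is not None:
                        w_el = t * w_binary[0][0] + (1 - t) * w_binary[1][0]
                    loss, dlog = focal_loss_and_grad(
                        logit_b, t, gamma=config.gamma, class_weights=w_el,
                    )
                    d_b, d_p = dlog, None
                else:
                    t = yp[idx]
                    w_el = None
                    if w_pattern is not None:
                        w_pos, w_neg = w_pattern
                        w_el = t * w_pos + (1 - t) * w_neg
                    loss, dlog = focal_loss_and_grad(
                        logits_p, t, gamma=config.gamma, class_weights=w_el,
                    )
                    d_b, d_p = None, dlog
                if use_cache:
                    _classifier_backward(model, d_binary=d_b, d_pattern=d_p)
                else:
                    model.backward(d_binary=d_b, d_pattern=d_p,
                                   through_backbone=touches_backbone)
                opt.step(model.params_, model.collect_grads(), trainable=scope)
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / n_batches)
        history["stages"].append({
            "name": stage.name,
            "epochs": stage.epochs,
            "lr": stage.lr,
            "task": stage.task,
            "scope": list(stage.scope),
            "trainable_params": sorted(scope),
            "losses": losses,
        })
    return history


def evaluate_model(model, images, reference_labels, fold_ids=None,
                   threshold: float = 0.5) -> dict:
    """Evaluate a trained multi-task model against reference pattern labels.

    Reports per-pattern confusion metrics (fold-averaged with variance when
    ``fold_ids`` is given), the clinically-inspired rates, and binary
    diagnosis metrics by both routes: the decision rule applied to the
    predicted pattern flags, and the binary head itself.  The two routes
    may disagree; both are always reported.
    """
    ref = validate_pattern_matrix(reference_labels)
    if not hasattr(model, "history_"):
        warnings.warn("model has no training history; evaluating as-is")
    pred_patterns = model.predict_patterns(images, threshold=threshold)
    diag_rule = encode_diagnoses(pred_patterns)
    diag_head = model.predict(images)
    diag_ref = encode_diagnoses(ref)

    report = {
        "per_pattern": per_pattern_metrics(pred_patterns, ref,
                                           fold_ids=fold_ids)
        .reset_index().to_dict(orient="records"),
        "clinical_xai": clinical_xai_metrics(pred_patterns, ref).to_dict(),
        "binary_from_patterns": _confusion_rates(diag_rule, diag_ref),
        "binary_from_head": _confusion_rates(diag_head, diag_ref),
        "n_images": int(ref.shape[0]),
    }
    return report
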