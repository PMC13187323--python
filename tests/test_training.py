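"""Stratified folds, augmentation, three-stage training and evaluation."""

import numpy as np
import pytest

from bccxai.nn.model import MultiTaskPatternCNN
from bccxai.patterns import encode_diagnoses
from bccxai.training import (
    StageConfig,
    TrainConfig,
    augment,
    evaluate_model,
    stratified_kfold_split,
    three_stage_train,
)


def _tiny_config(seed=0, ep=(2, 2, 4)):
    stages = (
        StageConfig("classifier", epochs=ep[0], lr=1e-3,
                    scope=("trunk", "binary_head"), task="binary",
                    augment=False),
        StageConfig("finetune", epochs=ep[1], lr=5e-4,
                    scope=("block2", "block3", "trunk", "binary_head"),
                    task="binary", augment=False),
        StageConfig("pattern", epochs=ep[2], lr=3e-4,
                    scope=("pattern_head",), task="pattern", augment=False),
    )
    return TrainConfig(stages=stages, seed=seed)


class TestStratifiedKFold:
    @pytest.mark.parametrize("n,k", [(23, 3), (100, 5), (57, 4)])
    def test_partition_property(self, n, k, rng):
        labels = rng.integers(0, 2, (n, 8))
        folds = stratified_kfold_split(labels, k, seed=1)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == n
        assert len(np.unique(all_idx)) == n

    def test_balanced_binary_label_splits_exactly(self):
        labels = np.zeros((100, 1), dtype=int)
        labels[:50, 0] = 1
        folds = stratified_kfold_split(labels, 5, seed=0)
        for f in folds:
            assert len(f) == 20
            assert labels[f].sum() == 10

    def test_multilabel_prevalence_within_tolerance(self, rng):
        prev = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.15, 0.25])
        labels = (rng.random((700, 7)) < prev).astype(int)
        folds = stratified_kfold_split(labels, 5, seed=2)
        global_prev = labels.mean(axis=0)
        for f in folds:
            assert np.abs(labels[f].mean(axis=0) - global_prev).max() < 0.05

    def test_scarce_label_warns(self):
        labels = np.zeros((20, 2), dtype=int)
        labels[0, 1] = 1
        labels[:10, 0] = 1
        with pytest.warns(UserWarning):
            folds = stratified_kfold_split(labels, 5, seed=0)
        assert sum(len(f) for f in folds) == 20

    def test_bad_k_rejected(self, rng):
        labels = rng.integers(0, 2, (10, 2))
        with pytest.raises(ValueError):
            stratified_kfold_split(labels, 1, seed=0)
        with pytest.raises(ValueError):
            stratified_kfold_split(labels, 11, seed=0)


class TestAugment:
    def test_identity_when_disabled(self, rng):
        img = rng.random((32, 32))
        out = augment(img, seed=0, rotation=False, perspective=False,
                      blur=False)
        np.testing.assert_array_equal(out, img)

    def test_seed_determinism(self, rng):
        img = rng.random((32, 32))
        np.testing.assert_array_equal(augment(img, seed=5), augment(img, seed=5))

    def test_output_contract(self, rng):
        img = rng.random((32, 32))
        out = augment(img, seed=1)
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 1

    def test_blur_lowers_an_impulse(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        out = augment(img, seed=2, rotation=False, perspective=False,
                      blur=True)
        assert out.max() < 1.0


class TestThreeStageTrain:
    @pytest.fixture(scope="class")
    def trained(self, small_dataset):
        X = np.stack(small_dataset.images)
        model = MultiTaskPatternCNN(channels=(4, 6, 8), hidden=12,
                                    random_state=0, config=_tiny_config())
        before = {}
        model.build()
        before = {k: v.copy() for k, v in model.params_.items()}
        model.fit(X, small_dataset.true_labels)
        return model, before, X, small_dataset.true_labels

    def test_freeze_contracts_bit_exact(self, trained):
        model, before, _, _ = trained
        hist = model.history_["stages"]
        # stage 1 and 3 never touch the backbone; stage 2 spares block1
        assert not any(p.startswith("block")
                       for p in hist[0]["trainable_params"])
        assert not any(p.startswith("block1")
                       for p in hist[1]["trainable_params"])
        np.testing.assert_array_equal(model.params_["block1.conv.W"],
                                      before["block1.conv.W"])

    def test_pattern_stage_leaves_binary_head_untouched(self, trained):
        model, _, _, _ = trained
        assert model.history_["stages"][2]["trainable_params"] == [
            "pattern_head.W", "pattern_head.b"
        ]

    def test_history_bookkeeping(self, trained):
        model, _, _, _ = trained
        for stage, ep in zip(model.history_["stages"], (2, 2, 4)):
            assert len(stage["losses"]) == ep

    def test_training_reduces_loss(self, small_dataset):
        X = np.stack(small_dataset.images)
        cfg = _tiny_config(ep=(15, 2, 2))
        model = MultiTaskPatternCNN(channels=(4, 6, 8), hidden=12,
                                    random_state=0, config=cfg)
        model.fit(X, small_dataset.true_labels)
        losses = model.history_["stages"][0]["losses"]
        assert losses[-1] < losses[0]

    def test_stage_validation(self):
        cfg = _tiny_config()
        bad = TrainConfig(stages=cfg.stages[:2], seed=0)
        with pytest.raises(ValueError):
            bad.validate()
        increasing = TrainConfig(stages=(
            StageConfig("a", 1, 1e-4, ("trunk",), "binary"),
            StageConfig("b", 1, 1e-3, ("trunk",), "binary"),
            StageConfig("c", 1, 1e-3, ("trunk",), "pattern"),
        ))
        with pytest.raises(ValueError):
            increasing.validate()


class TestEvaluateModel:
    class _Oracle:
        """Stub model that answers with a fixed label matrix."""

        def __init__(self, labels):
            self.labels = np.asarray(labels)
            self.history_ = {}

        def predict_patterns(self, X, threshold=0.5):
            return self.labels

        def predict(self, X):
            return encode_diagnoses(self.labels)

    def test_oracle_model_scores_ones(self, rng):
        ref = rng.integers(0, 2, (30, 7))
        report = evaluate_model(self._Oracle(ref), np.zeros((30, 8, 8)), ref)
        assert report["binary_from_patterns"]["accuracy"] == 1.0
        assert report["binary_from_head"]["accuracy"] == 1.0
        assert all(row["recall"] in (1.0,) or np.isnan(row["recall"])
                   for row in report["per_pattern"])

    def test_constant_negative_model(self, rng):
        ref = rng.integers(0, 2, (30, 7))
        ref[0] = 1   # ensure positives exist
        report = evaluate_model(self._Oracle(np.zeros_like(ref)),
                                np.zeros((30, 8, 8)), ref)
        for row in report["per_pattern"]:
            assert row["recall"] == 0.0
            assert row["specificity"] == 1.0

    def test_untrained_model_warns(self, rng):
        model = MultiTaskPatternCNN(channels=(4, 6, 8), hidden=12,
                                    random_state=0).build()
        model.update_feature_norm(np.zeros((2, 32, 32)))
        ref = rng.integers(0, 2, (4, 7))
        with pytest.warns(UserWarning):
            evaluate_model(model, np.zeros((4, 32, 32)), ref)
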