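"""Focal loss, backward passes, optimizer freezing, class activation maps."""

import numpy as np
import pytest

from bccxai.nn import AdamW, MultiTaskPatternCNN, focal_loss, gradcam, sigmoid
from bccxai.nn.losses import binary_cross_entropy, focal_loss_and_grad


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy(self, rng):
        p = rng.uniform(0.01, 0.99, size=(16, 7))
        t = rng.integers(0, 2, size=(16, 7))
        assert focal_loss(p, t, gamma=0.0) == pytest.approx(
            binary_cross_entropy(p, t), abs=1e-9
        )

    def test_chance_probability_gives_ln2(self):
        assert focal_loss([0.5], [1], gamma=0.0) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_formula_evaluation(self):
        # p = 0.9, target 1, gamma 2 -> (0.1)^2 * (-ln 0.9)
        assert focal_loss([0.9], [1], gamma=2.0) == pytest.approx(
            0.01 * -np.log(0.9), abs=1e-12
        )

    def test_perfect_prediction_vanishes(self):
        assert focal_loss([1 - 1e-9], [1], gamma=2.0) < 1e-6

    def test_focal_never_exceeds_cross_entropy(self, rng):
        p = rng.uniform(0.01, 0.99, size=50)
        t = rng.integers(0, 2, size=50)
        for pi, ti in zip(p, t):
            assert focal_loss([pi], [ti], gamma=2.0) <= focal_loss(
                [pi], [ti], gamma=0.0
            ) + 1e-12

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss([0.5], [1], gamma=-1.0)

    @pytest.mark.parametrize("gamma", [0.0, 1.0, 2.0])
    def test_gradient_matches_finite_differences(self, gamma, rng):
        logits = rng.normal(size=12)
        targets = rng.integers(0, 2, size=12).astype(float)
        _, grad = focal_loss_and_grad(logits, targets, gamma=gamma)
        eps = 1e-6
        for i in range(12):
            bumped = logits.copy()
            bumped[i] += eps
            up, _ = focal_loss_and_grad(bumped, targets, gamma=gamma)
            bumped[i] -= 2 * eps
            dn, _ = focal_loss_and_grad(bumped, targets, gamma=gamma)
            assert grad[i] == pytest.approx((up - dn) / (2 * eps), abs=1e-6)


class TestModel:
    @pytest.fixture()
    def model(self):
        return MultiTaskPatternCNN(channels=(4, 6, 8), hidden=10,
                                   random_state=0).build()

    def test_head_shapes(self, model, rng):
        X = rng.random((3, 32, 32))
        lb, lp = model.forward(X)
        assert lb.shape == (3,) and lp.shape == (3, 7)
        assert model.predict(X).shape == (3,)
        assert model.predict_patterns(X).shape == (3, 7)

    def test_backward_matches_finite_differences(self, model, rng):
        model.update_feature_norm(rng.random((6, 32, 32)))
        X = rng.random((2, 32, 32))
        y = np.array([1.0, 0.0])

        def loss():
            lb, _ = model.forward(X)
            return focal_loss_and_grad(lb, y, gamma=2.0)[0]

        lb, _ = model.forward(X)
        _, d = focal_loss_and_grad(lb, y, gamma=2.0)
        model.backward(d_binary=d, through_backbone=True)
        grads = model.collect_grads()
        eps = 1e-6
        for name in ("block1.conv.W", "block2.conv.b", "trunk.W",
                     "binary_head.b"):
            flat = model.params_[name].ravel()
            for t in range(0, flat.size, max(1, flat.size // 4)):
                orig = flat[t]
                flat[t] = orig + eps
                up = loss()
                flat[t] = orig - eps
                dn = loss()
                flat[t] = orig
                assert grads[name].ravel()[t] == pytest.approx(
                    (up - dn) / (2 * eps), abs=1e-6
                )

    def test_weight_roundtrip(self, model, tmp_path, rng):
        X = rng.random((2, 32, 32))
        before = model.predict_proba(X)
        model.save_weights(tmp_path / "w.npz")
        other = MultiTaskPatternCNN(channels=(4, 6, 8), hidden=10,
                                    random_state=99)
        other.load_weights(tmp_path / "w.npz")
        after = other.predict_proba(X)
        np.testing.assert_array_equal(before["patterns"], after["patterns"])


class TestAdamW:
    def test_only_trainable_names_update(self, rng):
        params = {"a": rng.normal(size=3), "b": rng.normal(size=3)}
        frozen = params["b"].copy()
        grads = {"a": np.ones(3), "b": np.ones(3)}
        opt = AdamW(lr=0.1)
        for _ in range(5):
            opt.step(params, grads, trainable={"a"})
        np.testing.assert_array_equal(params["b"], frozen)
        assert not np.allclose(params["a"], 0)

    def test_decoupled_weight_decay_shrinks_parameters(self):
        params = {"a": np.full(2, 10.0)}
        opt = AdamW(lr=0.1, weight_decay=0.5)
        opt.step(params, {"a": np.zeros(2)})
        assert (params["a"] < 10.0).all()


class TestGradCAM:
    class _OneChannelModel:
        """Target score = spatial mean of feature channel 0."""

        def __init__(self, features):
            self.features = features

        def feature_activations_and_gradients(self, X, head, class_index):
            A = self.features[None]
            dA = np.zeros_like(A)
            dA[..., 0] = 1.0 / (A.shape[1] * A.shape[2])
            return A, dA

    def test_analytic_single_channel_oracle(self, rng):
        feats = rng.normal(size=(8, 8, 3))
        model = self._OneChannelModel(feats)
        cam = gradcam(model, np.zeros((8, 8)), head="binary")
        expected = np.maximum(feats[..., 0], 0) / (8 * 8)
        expected = (expected - expected.min()) / np.ptp(expected)
        np.testing.assert_allclose(cam, expected, atol=1e-9)

    def test_contract_shape_and_range(self, rng):
        model = MultiTaskPatternCNN(channels=(4, 6, 8), hidden=10,
                                    random_state=1).build()
        img = rng.random((64, 64))
        cam = gradcam(model, img, head="pattern", class_index=3)
        assert cam.shape == (64, 64)
        assert cam.min() >= 0 and cam.max() <= 1

    def test_determinism_on_duplicated_image(self, rng):
        model = MultiTaskPatternCNN(channels=(4, 6, 8), hidden=10,
                                    random_state=1).build()
        img = rng.random((32, 32))
        np.testing.assert_array_equal(gradcam(model, img), gradcam(model, img))

    def test_constant_map_warns_and_zeros(self):
        class Dead:
            def feature_activations_and_gradients(self, X, head, class_index):
                A = np.zeros((1, 4, 4, 2))
                return A, np.ones_like(A)

        with pytest.warns(UserWarning):
            cam = gradcam(Dead(), np.zeros((16, 16)))
        assert (cam == 0).all()

    def test_invalid_head_rejected(self, rng):
        model = MultiTaskPatternCNN(channels=(4, 6, 8), hidden=10,
                                    random_state=1).build()
        with pytest.raises(ValueError):
            model.feature_activations_and_gradients(
                rng.random((1, 32, 32)), head="nonsense"
            )


def test_sigmoid_is_stable_at_extremes():
    assert sigmoid(np.array([-1000.0]))[0] == 0.0
    assert sigmoid(np.array([1000.0]))[0] == 1.0
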