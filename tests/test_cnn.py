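"""CNN engine: layer-by-layer oracles, loss closed forms, training behavior."""

import dataclasses

import numpy as np
import pytest

from vesselseg.cnn import (
    ConvLayer,
    FCLayer,
    FlattenLayer,
    LayerError,
    PoolLayer,
    CNNModel,
    TrainConfig,
    build_default_cnn,
    load_checkpoint,
    sample_patches,
    save_checkpoint,
    segment_cnn,
    softmax_loss,
    softmax_probabilities,
    train_cnn,
)


def conv_oracle(x, W, b):
    """Independent triple-loop valid cross-correlation, one sample."""
    C, H, Wd = x.shape
    O, _, k, _ = W.shape
    out = np.zeros((O, H - k + 1, Wd - k + 1))
    for o in range(O):
        for i in range(out.shape[1]):
            for j in range(out.shape[2]):
                acc = b[o]
                for c in range(C):
                    for u in range(k):
                        for v in range(k):
                            acc += x[c, i + u, j + v] * W[o, c, u, v]
                out[o, i, j] = acc
    return out


class TestConvLayer:
    def test_identity_kernel_passthrough(self):
        layer = ConvLayer(1, 1, 1, activation="identity")
        layer.W[:] = 1.0
        layer.b[:] = 0.0
        x = np.random.default_rng(0).random((2, 1, 5, 5))
        assert np.allclose(layer.forward(x), x)

    def test_unit_sum_kernel_on_constant(self):
        layer = ConvLayer(1, 1, 3, activation="identity")
        layer.W[:] = 1.0 / 9.0
        layer.b[:] = 0.0
        out = layer.forward(np.full((1, 1, 6, 6), 0.7))
        assert np.allclose(out, 0.7)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            layer = ConvLayer(2, 3, 3, activation="identity", rng=rng)
            x = rng.normal(size=(1, 2, 6, 7))
            expected = conv_oracle(x[0], layer.W, layer.b)
            assert np.allclose(layer.forward(x)[0], expected, atol=1e-10)

    def test_receptive_set_restricts_input_maps(self, rng):
        receptive = np.array([[True, False], [False, True]])
        layer = ConvLayer(2, 2, 3, activation="identity", receptive=receptive, rng=rng)
        x = rng.normal(size=(1, 2, 5, 5))
        out = layer.forward(x)
        # output map 0 must ignore input map 1 entirely
        x2 = x.copy()
        x2[:, 1] += 10.0
        assert np.allclose(layer.forward(x2)[:, 0], out[:, 0])

    def test_shape_validation(self):
        layer = ConvLayer(1, 1, 3)
        with pytest.raises(LayerError):
            layer.forward(np.zeros((1, 2, 5, 5)))
        with pytest.raises(LayerError, match="odd"):
            ConvLayer(1, 1, 4)


class TestPoolLayer:
    def test_mean_pool_constant_preserved(self):
        layer = PoolLayer(1, 2, down="mean")
        out = layer.forward(np.full((1, 1, 4, 4), 3.3))
        assert out.shape == (1, 1, 2, 2)
        assert np.allclose(out, 3.3)

    def test_mean_pool_with_deviations_direct_substitution(self):
        layer = PoolLayer(1, 2, down="mean")
        layer.u[:] = 2.0
        layer.c[:] = 1.0
        block = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        assert np.allclose(layer.forward(block), 2 * 2.5 + 1)

    def test_max_pool(self):
        layer = PoolLayer(1, 2, down="max")
        block = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        assert layer.forward(block)[0, 0, 0, 0] == 4.0

    def test_odd_size_pad_to_fit(self):
        layer = PoolLayer(1, 2, down="mean")
        out = layer.forward(np.ones((1, 1, 5, 5)))
        assert out.shape == (1, 1, 3, 3)

    def test_rejects_empty_and_bad_window(self):
        with pytest.raises(LayerError):
            PoolLayer(1, 1)
        with pytest.raises(LayerError):
            PoolLayer(1, 2).forward(np.zeros((1, 1, 0, 4)))


class TestFCLayer:
    def test_identity_weights(self):
        layer = FCLayer(3, 3, activation="identity")
        layer.W[:] = np.eye(3)
        layer.b[:] = 0.0
        x = np.array([[1.0, -2.0, 3.0]])
        assert np.allclose(layer.forward(x), x)

    def test_zero_weights_yield_bias(self):
        layer = FCLayer(4, 2, activation="identity")
        layer.W[:] = 0.0
        layer.b[:] = [5.0, -1.0]
        assert np.allclose(layer.forward(np.ones((3, 4))), [5.0, -1.0])

    def test_matches_dot_product_oracle(self, rng):
        layer = FCLayer(3, 3, activation="identity", rng=rng)
        x = rng.normal(size=(2, 3))
        expected = np.array([[sum(layer.W[o, i] * xv[i] for i in range(3)) + layer.b[o] for o in range(3)] for xv in x])
        assert np.allclose(layer.forward(x), expected, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(LayerError):
            FCLayer(3, 2).forward(np.zeros((1, 4)))


class TestSoftmax:
    def test_symmetry_and_normalization(self):
        assert np.allclose(softmax_probabilities([0.0, 0.0]), [0.5, 0.5])
        p = softmax_probabilities(np.random.default_rng(1).normal(size=(5, 4)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=(3, 4))
        assert np.allclose(softmax_probabilities(logits), softmax_probabilities(logits + 17.3))

    def test_closed_form_ln2(self):
        assert np.allclose(softmax_probabilities([np.log(2), 0.0]), [2 / 3, 1 / 3])

    def test_rejects_non_finite(self):
        with pytest.raises(LayerError):
            softmax_probabilities([np.inf, 0.0])

    def test_loss_perfect_prediction_is_zero(self):
        assert softmax_loss(np.array([[1.0, 0.0]]), [1]) == pytest.approx(0.0)

    def test_loss_uniform_prediction_is_log_p(self):
        for P in (2, 3, 5):
            probs = np.full((1, P), 1.0 / P)
            assert softmax_loss(probs, [1]) == pytest.approx(np.log(P))

    def test_loss_direct_substitution(self):
        probs = np.array([[0.8, 0.2], [0.4, 0.6]])
        expected = -(np.log(0.8) + np.log(0.6)) / 2
        assert softmax_loss(probs, [1, 2]) == pytest.approx(expected)

    def test_loss_rejects_out_of_range_labels(self):
        with pytest.raises(LayerError, match="labels"):
            softmax_loss(np.array([[0.5, 0.5]]), [3])
        with pytest.raises(LayerError, match="labels"):
            softmax_loss(np.array([[0.5, 0.5]]), [0])

    def test_loss_nonnegative_on_random_inputs(self, rng):
        for _ in range(50):
            probs = softmax_probabilities(rng.normal(size=(4, 3)))
            labels = rng.integers(1, 4, size=4)
            assert softmax_loss(probs, labels) >= 0.0


def numeric_gradient(f, param, eps=1e-6):
    g = np.zeros_like(param)
    it = np.nditer(param, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = param[idx]
        param[idx] = orig + eps
        hi = f()
        param[idx] = orig - eps
        lo = f()
        param[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g


class TestGradients:
    def test_analytic_gradients_match_central_differences(self, rng):
        """Softmax loss gradient through a 1-conv micro-model, all parameters."""
        conv = ConvLayer(1, 2, 3, activation="relu", rng=rng)
        fc = FCLayer(2 * 2 * 2, 2, activation="identity", rng=rng)
        model = CNNModel([conv, FlattenLayer(), fc], n_classes=2, patch_size=4)
        x = rng.normal(size=(3, 1, 4, 4))
        labels = np.array([0, 1, 0])

        def loss_fn():
            return softmax_loss(softmax_probabilities(model.forward_logits(x)), labels + 1)

        probs = model.forward(x)
        onehot = np.eye(2)[labels]
        model.backward_from_logits((probs - onehot) / len(labels))
        for name, p, g in model.parameters():
            gn = numeric_gradient(loss_fn, p)
            denom = max(np.abs(gn).max(), 1e-8)
            assert np.abs(g - gn).max() / denom < 1e-4, name


class TestTraining:
    @staticmethod
    def toy_patches(rng, n=40):
        bright = np.full((n // 2, 1, 5, 5), 0.9) + rng.normal(0, 0.02, (n // 2, 1, 5, 5))
        dark = np.full((n // 2, 1, 5, 5), 0.1) + rng.normal(0, 0.02, (n // 2, 1, 5, 5))
        X = np.concatenate([dark, bright])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    @staticmethod
    def micro_model(rng):
        conv = ConvLayer(1, 2, 3, activation="relu", rng=rng)
        fc = FCLayer(2 * 3 * 3, 2, activation="identity", rng=rng)
        return CNNModel([conv, FlattenLayer(), fc], n_classes=2, patch_size=5)

    def test_zero_learning_rate_leaves_parameters_unchanged(self, rng):
        X, y = self.toy_patches(rng)
        model = self.micro_model(rng)
        before = [p.copy() for _, p, _ in model.parameters()]
        train_cnn(X, y, model, TrainConfig(learning_rate=0.0, epochs=2, seed=0))
        after = [p for _, p, _ in model.parameters()]
        assert all(np.array_equal(b, a) for b, a in zip(before, after))

    def test_separable_problem_loss_decreases_and_fits(self, rng):
        X, y = self.toy_patches(rng)
        model = self.micro_model(rng)
        model, history = train_cnn(X, y, model, TrainConfig(learning_rate=0.1, epochs=8, seed=0))
        assert all(b <= a + 1e-12 for a, b in zip(history[:4], history[1:5]))
        preds = model.forward(X).argmax(axis=1)
        assert (preds == y).mean() == 1.0

    def test_training_is_reproducible(self, rng):
        X, y = self.toy_patches(rng)
        cfg = TrainConfig(learning_rate=0.05, epochs=3, seed=11)
        m1, h1 = train_cnn(X, y, self.micro_model(np.random.default_rng(5)), cfg)
        m2, h2 = train_cnn(X, y, self.micro_model(np.random.default_rng(5)), cfg)
        assert h1 == h2
        for (_, p1, _), (_, p2, _) in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1, p2)


class TestSegmentCNN:
    def test_all_background_head(self, easy_phantom):
        model = build_default_cnn(patch_size=17, seed=0)
        fc = model.layers[-1]
        fc.W[:] = 0.0
        fc.b[:] = [30.0, -30.0]  # logits force class 0
        prob = segment_cnn(easy_phantom.image, model, stride=4, assembly_window=5)
        assert prob[1].max() < 1e-10

    def test_probabilities_sum_to_one(self, easy_phantom):
        model = build_default_cnn(patch_size=17, seed=0)
        prob = segment_cnn(easy_phantom.image, model, stride=4, assembly_window=5)
        assert prob.shape == (2,) + easy_phantom.image.shape
        assert np.allclose(prob.sum(axis=0), 1.0, atol=1e-9)

    def test_rejects_small_image(self):
        model = build_default_cnn(patch_size=17, seed=0)
        with pytest.raises(LayerError, match="smaller"):
            segment_cnn(np.zeros((10, 10)), model)


class TestSamplingAndCheckpoint:
    def test_patch_labels_match_mask_centers(self, easy_phantom, rng):
        X, y = sample_patches(
            [easy_phantom.image], [easy_phantom.mask], 9, 40, 1.0, rng
        )
        assert X.shape == (40, 1, 9, 9)
        assert set(np.unique(y)) <= {0, 1}
        assert 0.4 <= y.mean() <= 0.6  # 1:1 balance

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_default_cnn(patch_size=9, seed=3)
        for _, p, _ in model.parameters():
            p += rng.normal(0, 0.1, p.shape)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        for (_, p1, _), (_, p2, _) in zip(model.parameters(), loaded.parameters()):
            assert np.array_equal(p1, p2)
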