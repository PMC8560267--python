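"""FCN (any-size, crop, multi-loss, gradients) and CRF (energy, ICM) checks."""

import itertools

import numpy as np
import pytest

from vesselseg.cnn import TrainConfig
from vesselseg.crf import CRFError, CRFModel, crf_energy, crf_refine, icm
from vesselseg.fcn import (
    FCNModel,
    LayerError,
    UpsampleLayer,
    build_default_fcn,
    crop_align,
    fcn_forward,
    fcn_multi_loss,
    majority_downsample,
    softmax_map,
    train_fcn,
)


class TestUpsample:
    def test_doubles_shape_and_interpolates(self):
        x = np.arange(4.0).reshape(1, 1, 2, 2)
        y = UpsampleLayer().forward(x)
        assert y.shape == (1, 1, 4, 4)
        assert np.allclose(y[0, 0, ::2, ::2], x[0, 0])  # exact at even sites
        assert y[0, 0, 0, 1] == pytest.approx((x[0, 0, 0, 0] + x[0, 0, 0, 1]) / 2)

    def test_backward_is_exact_adjoint(self, rng):
        up = UpsampleLayer()
        x = rng.normal(size=(1, 2, 3, 4))
        gy = rng.normal(size=(1, 2, 6, 8))
        # <Ax, gy> == <x, A^T gy> for an exact adjoint
        lhs = (up.forward(x) * gy).sum()
        rhs = (x * up.backward(gy)).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestCropAlign:
    def test_equal_shapes_identity(self, rng):
        x = rng.normal(size=(1, 1, 8, 8))
        assert np.array_equal(crop_align(x, (8, 8)), x)

    def test_centered_crop_drops_border(self):
        x = np.arange(100.0).reshape(1, 1, 10, 10)
        out = crop_align(x, (8, 8))
        assert np.array_equal(out, x[:, :, 1:9, 1:9])

    def test_explicit_offsets(self):
        x = np.arange(36.0).reshape(6, 6)
        out = crop_align(x, (3, 3), crop_spec=(2, 1))
        assert np.array_equal(out, x[2:5, 1:4])

    def test_reference_larger_than_feature_rejected(self):
        with pytest.raises(LayerError):
            crop_align(np.zeros((4, 4)), (6, 6))
        with pytest.raises(LayerError):
            crop_align(np.zeros((6, 6)), (4, 4), crop_spec=(4, 0))


class TestFCNForward:
    def test_any_size_contract(self):
        model = build_default_fcn(seed=0)
        for size in ((16, 16), (23, 31)):
            prob = fcn_forward(np.random.default_rng(0).random(size), model)
            assert prob.shape == (2,) + size

    def test_probabilities_sum_to_one(self, easy_phantom):
        prob = fcn_forward(easy_phantom.image, build_default_fcn(seed=1))
        assert np.allclose(prob.sum(axis=0), 1.0, atol=1e-12)

    def test_below_minimum_size_rejected(self):
        with pytest.raises(LayerError, match="minimum"):
            fcn_forward(np.zeros((4, 4)), build_default_fcn())

    def test_micro_model_hand_oracle(self):
        """Head with fixed weights reduces the FCN to a checkable map."""
        model = build_default_fcn(seed=0)
        x = np.random.default_rng(3).random((8, 8))
        logits, aux = model.forward_logits(x[None, None])
        # aux head operates at half resolution
        assert aux.shape == (1, 2, 4, 4)
        # per-pixel softmax of the full-res logits matches manual computation
        manual = np.exp(logits[0]) / np.exp(logits[0]).sum(axis=0, keepdims=True)
        assert np.allclose(softmax_map(logits)[0], manual, atol=1e-12)


class TestMultiLoss:
    def test_single_head_weight_one_equals_pixel_softmax_loss(self):
        rng = np.random.default_rng(0)
        probs = softmax_map(rng.normal(size=(2, 4, 4)))
        labels = rng.integers(0, 2, (4, 4))
        expected = -np.mean(
            [np.log(probs[labels[i, j], i, j]) for i in range(4) for j in range(4)]
        )
        assert fcn_multi_loss([probs], labels) == pytest.approx(expected)

    def test_zero_weights_select_single_head(self):
        rng = np.random.default_rng(1)
        p_full = softmax_map(rng.normal(size=(2, 4, 4)))
        p_half = softmax_map(rng.normal(size=(2, 2, 2)))
        labels = rng.integers(0, 2, (4, 4))
        only_half = fcn_multi_loss([p_full, p_half], labels, weights=[0.0, 1.0])
        assert only_half == pytest.approx(fcn_multi_loss([p_half], labels))

    def test_two_heads_weighted_sum_matches_manual(self):
        rng = np.random.default_rng(2)
        p_full = softmax_map(rng.normal(size=(2, 4, 4)))
        p_half = softmax_map(rng.normal(size=(2, 2, 2)))
        labels = rng.integers(0, 2, (4, 4))
        combo = fcn_multi_loss([p_full, p_half], labels, weights=[0.7, 0.3])
        manual = 0.7 * fcn_multi_loss([p_full], labels) + 0.3 * fcn_multi_loss([p_half], labels)
        assert combo == pytest.approx(manual)

    def test_majority_downsample_votes_and_ties(self):
        labels = np.array([[1, 1, 0, 0], [1, 0, 0, 0], [0, 1, 1, 0], [1, 1, 1, 1]])
        down = majority_downsample(labels, 2)
        assert down[0, 0] == 1  # 3 of 4 vote foreground
        assert down[0, 1] == 0  # unanimous background
        assert down[1, 0] == 1  # 3 of 4
        # 2-2 tie resolves to the smaller label
        tie = majority_downsample(np.array([[0, 1], [1, 0]]), 2)
        assert tie[0, 0] == 0


class TestFCNGradients:
    def test_full_model_gradient_check(self, rng):
        from vesselseg.fcn import _pixel_softmax_loss_grad, majority_downsample

        model = FCNModel(seed=0)
        x = rng.random((1, 1, 8, 8))
        labels = rng.integers(0, 2, (8, 8))

        def loss_fn():
            logits, aux = model.forward_logits(x)
            lf, _ = _pixel_softmax_loss_grad(logits, labels, 1.0)
            la, _ = _pixel_softmax_loss_grad(aux, majority_downsample(labels, 2), 1.0)
            return 0.7 * lf + 0.3 * la

        logits, aux = model.forward_logits(x)
        _, gf = _pixel_softmax_loss_grad(logits, labels, 1.0)
        _, ga = _pixel_softmax_loss_grad(aux, majority_downsample(labels, 2), 1.0)
        model.backward(0.7 * gf, 0.3 * ga)

        eps = 1e-6
        for name, p, g in model.parameters():
            flat = p.ravel()
            idx = np.random.default_rng(1).choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                hi = loss_fn()
                flat[i] = orig - eps
                lo = loss_fn()
                flat[i] = orig
                gn = (hi - lo) / (2 * eps)
                assert abs(g.ravel()[i] - gn) < 1e-4 * max(abs(gn), 1e-3), name


class TestFCNTraining:
    def test_loss_decreases_on_phantoms(self, easy_phantom):
        import dataclasses as dc

        from vesselseg.phantom import PRESETS, generate_dataset

        phantoms, _ = generate_dataset(dc.replace(PRESETS["easy"], image_size=32), 4, seed=3, val_fraction=0.0)
        cfg = TrainConfig(learning_rate=0.2, epochs=6, batch_size=1, seed=0)
        _, history = train_fcn([p.image for p in phantoms], [p.mask for p in phantoms], cfg)
        assert history[-1] < history[0]


# ---------------------------------------------------------------------------
# CRF
# ---------------------------------------------------------------------------

def crf_energy_oracle(lab, unary, w):
    """Exhaustive double-loop Potts energy."""
    H, W = lab.shape
    e = sum(unary[lab[i, j], i, j] for i in range(H) for j in range(W))
    for i in range(H):
        for j in range(W):
            if i + 1 < H and lab[i, j] != lab[i + 1, j]:
                e += w
            if j + 1 < W and lab[i, j] != lab[i, j + 1]:
                e += w
    return e


class TestCRFEnergy:
    def test_zero_pairwise_weight_is_unary_sum(self, rng):
        unary = rng.random((2, 3, 3))
        lab = rng.integers(0, 2, (3, 3))
        crf = CRFModel(unary=unary, pairwise_weight=0.0)
        expected = sum(unary[lab[i, j], i, j] for i in range(3) for j in range(3))
        assert crf_energy(lab, crf) == pytest.approx(expected)

    def test_uniform_labeling_has_zero_pairwise_contribution(self, rng):
        unary = rng.random((2, 4, 4))
        e0 = crf_energy(np.zeros((4, 4), int), CRFModel(unary=unary, pairwise_weight=0.0))
        e1 = crf_energy(np.zeros((4, 4), int), CRFModel(unary=unary, pairwise_weight=5.0))
        assert e0 == pytest.approx(e1)

    def test_matches_exhaustive_oracle_on_3x3(self, rng):
        for _ in range(20):
            unary = rng.random((2, 3, 3))
            lab = rng.integers(0, 2, (3, 3))
            w = float(rng.random())
            crf = CRFModel(unary=unary, pairwise_weight=w)
            assert crf_energy(lab, crf) == pytest.approx(crf_energy_oracle(lab, unary, w))

    def test_pairwise_matrix_must_be_symmetric(self):
        with pytest.raises(CRFError, match="symmetric"):
            CRFModel(unary=np.zeros((2, 2, 2)), pairwise_matrix=np.array([[0, 1], [0.5, 0]]))

    def test_shape_mismatch_rejected(self):
        crf = CRFModel(unary=np.zeros((2, 3, 3)))
        with pytest.raises(CRFError):
            crf_energy(np.zeros((4, 4), int), crf)


class TestICM:
    def test_weight_zero_refinement_is_argmax_bitwise(self, rng):
        prob = rng.random((2, 6, 6))
        prob /= prob.sum(axis=0, keepdims=True)
        assert np.array_equal(crf_refine(prob, pairwise_weight=0.0), prob.argmax(axis=0).astype(np.uint8))

    def test_large_weight_conforms_isolated_pixel(self):
        prob = np.full((2, 5, 5), 0.0)
        prob[0] = 0.9
        prob[1] = 0.1
        prob[:, 2, 2] = [0.2, 0.8]  # one flipped pixel in a background sea
        mask = crf_refine(prob, pairwise_weight=10.0)
        assert mask[2, 2] == 0

    def test_energy_non_increasing_every_sweep(self, rng):
        prob = rng.random((2, 8, 8))
        prob /= prob.sum(axis=0, keepdims=True)
        crf = CRFModel.from_probabilities(prob, pairwise_weight=0.7)
        _, energies = icm(crf, prob.argmax(axis=0))
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_best_restart_reaches_enumerated_minimum_or_documented_local_min(self, rng):
        """All 2^12 labelings of 3x4 instances vs best-of-three-restarts ICM."""
        shapes = (3, 4)
        for trial in range(5):
            prob = rng.random((2,) + shapes)
            prob /= prob.sum(axis=0, keepdims=True)
            w = 0.5
            crf = CRFModel.from_probabilities(prob, pairwise_weight=w)
            best_enum = np.inf
            for bits in itertools.product((0, 1), repeat=12):
                lab = np.array(bits).reshape(shapes)
                best_enum = min(best_enum, crf_energy(lab, crf))
            refined = crf_refine(prob, pairwise_weight=w, restarts=("argmax", "background", "foreground"))
            e_icm = crf_energy(refined, crf)
            e_argmax = crf_energy(prob.argmax(axis=0), crf)
            assert e_icm <= e_argmax + 1e-9
            # reach the enumerated optimum, or stop in a labeling no
            # single-pixel flip can improve (a true ICM fixed point)
            if e_icm > best_enum + 1e-9:
                for i in range(shapes[0]):
                    for j in range(shapes[1]):
                        flipped = refined.copy()
                        flipped[i, j] = 1 - flipped[i, j]
                        assert crf_energy(flipped, crf) >= e_icm - 1e-9
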