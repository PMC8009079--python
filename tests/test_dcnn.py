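"""Forward-pass reference ops, shape algebra, backprop, and training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harimages.dcnn import (
    ConvLayerSpec,
    DCNN,
    ModelConfig,
    TrainingConfig,
    _conv_forward,
    _pool_forward,
    build_model,
    conv2d_multichannel,
    conv_output_shape,
    dense_forward,
    flatten_concat,
    maxpool,
    predict,
    same_padding,
    softmax,
    sparse_categorical_cross_entropy,
    train,
)


class TestConvOutputShape:
    def test_same_padding_preserves_size_at_stride_1(self):
        before, after = same_padding(2)
        assert (40 - 2 + before + after) // 1 + 1 == 40

    @pytest.mark.parametrize(
        "size, filt, pad, stride, expected",
        [(5, 2, 0, 1, 4), (4, 2, 0, 2, 2), (40, 2, 0, 1, 39)],
    )
    def test_arithmetic(self, size, filt, pad, stride, expected):
        assert conv_output_shape(size, filt, pad, stride) == expected

    def test_oversized_filter_rejected(self):
        with pytest.raises(ValueError):
            conv_output_shape(3, 5, 0, 1)


class TestConv2dMultichannel:
    def test_identity_kernel(self, rng):
        X = rng.normal(size=(4, 4, 1))
        out = conv2d_multichannel(X, np.ones((1, 1, 1)))
        np.testing.assert_allclose(out, X[..., 0])

    def test_hand_sum_all_ones(self):
        X = np.ones((2, 2, 1))
        out = conv2d_multichannel(X, np.ones((2, 2, 1)))
        assert out.shape == (1, 1)
        assert out[0, 0] == 4.0

    def test_channel_summation(self):
        X = np.ones((3, 3, 2))
        out = conv2d_multichannel(X, np.ones((1, 1, 2)))
        np.testing.assert_allclose(out, 2.0)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            conv2d_multichannel(rng.normal(size=(3, 3, 2)), np.ones((2, 2, 3)))

    def test_fast_batched_path_matches_reference(self, rng):
        """Dual route: the training-path convolution vs the naive transcription."""
        for _ in range(20):
            X = rng.normal(size=(6, 6, 3))
            K = rng.normal(size=(2, 2, 3, 4))
            ref = conv2d_multichannel(X, K)
            fast, _ = _conv_forward(
                X[None].astype(np.float64), K, np.zeros(4), (0, 0, 0, 0), (1, 1)
            )
            np.testing.assert_allclose(fast[0], ref, atol=1e-6)


class TestMaxPool:
    def test_two_by_two(self):
        np.testing.assert_array_equal(maxpool(np.array([[1.0, 2.0], [3.0, 4.0]]), 2), [[4.0]])

    def test_constant_input_reduced_size(self):
        out = maxpool(np.full((4, 4), 7.0), 2)
        assert out.shape == (2, 2)
        assert (out == 7.0).all()

    def test_trailing_remainder_dropped(self):
        assert maxpool(np.zeros((5, 5)), 2).shape == (2, 2)

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            maxpool(np.zeros((4, 4)), 0)

    def test_fast_batched_pool_matches_reference(self, rng):
        X = rng.normal(size=(3, 6, 6, 2))
        Y, _ = _pool_forward(X, 2)
        for n in range(3):
            for c in range(2):
                np.testing.assert_allclose(Y[n, :, :, c], maxpool(X[n, :, :, c], 2))


class TestFlattenDense:
    def test_flatten_lengths(self):
        assert len(flatten_concat([np.zeros((2, 2))])) == 4
        assert len(flatten_concat([np.zeros((2, 2)), np.zeros((3, 1))])) == 7
        assert len(flatten_concat([])) == 0

    def test_dense_identity_and_bias(self):
        h = np.array([1.0, 2.0])
        np.testing.assert_allclose(dense_forward(h, np.eye(2), np.zeros(2)), h)
        np.testing.assert_allclose(
            dense_forward(h, np.zeros((2, 2)), np.array([5.0, -1.0])), [5.0, -1.0]
        )

    def test_dense_hand_computed_relu(self):
        out = dense_forward(
            np.array([1.0, 2.0]), np.array([[1.0, 1.0], [0.0, 1.0]]), np.zeros(2), "relu"
        )
        np.testing.assert_allclose(out, [3.0, 2.0])

    def test_dense_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dense_forward(np.zeros(3), np.zeros((2, 2)), np.zeros(2))


class TestSoftmax:
    def test_equal_logits_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(6)), np.full(6, 1 / 6))

    def test_closed_form(self):
        np.testing.assert_allclose(softmax(np.array([0.0, np.log(2)])), [1 / 3, 2 / 3])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=10), st.floats(-100, 100))
    def test_normalization_and_shift_invariance(self, logits, shift):
        x = np.array(logits)
        p = softmax(x)
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(softmax(x + shift), p, atol=1e-9)


TINY = ModelConfig(
    input_shape=(8, 8, 2),
    conv_layers=(ConvLayerSpec(n_filters=2),),
    pool_sizes=(2,),
    dense_sizes=(6,),
    dropout_rate=0.0,
    n_classes=3,
)


class TestBuildModel:
    def test_default_shape_algebra(self):
        model = build_model(ModelConfig())
        shapes = dict(model.layer_shapes)
        assert shapes["conv0"] == (40, 40, 2)
        assert shapes["pool0"] == (20, 20, 2)
        assert shapes["conv1"] == (20, 20, 4)
        assert shapes["pool1"] == (10, 10, 4)
        assert shapes["flatten"] == (400,)
        assert shapes["output"] == (6,)

    def test_forward_on_zero_image_is_probability_vector(self):
        model = build_model(ModelConfig())
        model.initialize(seed=0)
        probs = softmax(model.forward(np.zeros((1, 40, 40, 3), dtype=np.float32)))
        assert probs.shape == (1, 6)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            ModelConfig(pool_sizes=(2,))
        with pytest.raises(ValueError, match="collapses"):
            build_model(
                ModelConfig(
                    input_shape=(4, 4, 3),
                    conv_layers=(ConvLayerSpec(2), ConvLayerSpec(4)),
                    pool_sizes=(4, 4),
                )
            )

    def test_input_shape_mismatch_rejected(self):
        model = build_model(TINY)
        model.initialize(seed=0)
        with pytest.raises(ValueError, match="input"):
            model.forward(np.zeros((1, 5, 5, 2), dtype=np.float32))


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        """Analytic backprop vs central finite differences on a tiny net."""
        model = build_model(TINY)
        model.initialize(seed=1)
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        X = rng.normal(size=(4, 8, 8, 2))  # float64 so the check is not dtype-limited
        y = np.array([0, 1, 2, 1])

        def loss() -> float:
            return sparse_categorical_cross_entropy(model.forward(X), y)

        logits, cache = model.forward(X, training=True, return_cache=True)
        grads = model._backward(softmax(logits), y, cache)
        eps = 1e-5
        for name in ("K0", "bc0", "W0", "bd0", "Wout", "bout"):
            flat = model.params[name].ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


def _quadrant_images(n_per_class, rng):
    """Two trivially separable classes: bright top-left vs bottom-right quadrant."""
    images, labels = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            img = np.zeros((8, 8, 2), dtype=np.float32)
            sl = np.s_[:4, :4] if cls == 0 else np.s_[4:, 4:]
            img[sl] = rng.uniform(0.5, 1.0, size=(4, 4, 2))
            images.append(img)
            labels.append(cls)
    return np.stack(images), np.array(labels)


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        X, y = _quadrant_images(20, rng)
        model = build_model(ModelConfig(**{**TINY.__dict__, "n_classes": 2}))
        train(model, X, y, TrainingConfig(epochs=10, batch_size=8, seed=0))
        assert model.history.loss[-1] < model.history.loss[0]

    def test_training_is_deterministic_in_seed(self, rng):
        X, y = _quadrant_images(10, rng)
        cfg = ModelConfig(**{**TINY.__dict__, "n_classes": 2})
        tc = TrainingConfig(epochs=3, batch_size=8, seed=5)
        m1 = train(build_model(cfg), X, y, tc)
        m2 = train(build_model(cfg), X, y, tc)
        assert m1.history.loss == m2.history.loss
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_reaches_perfect_training_accuracy_on_separable_toys(self, rng):
        X, y = _quadrant_images(20, rng)
        model = build_model(ModelConfig(**{**TINY.__dict__, "n_classes": 2}))
        train(model, X, y, TrainingConfig(epochs=30, batch_size=8, seed=0))
        pred, _ = predict(model, X)
        assert (pred == y).mean() == 1.0

    def test_invalid_training_inputs_rejected(self, rng):
        model = build_model(TINY)
        X, y = _quadrant_images(4, rng)
        with pytest.raises(ValueError, match="empty"):
            train(model, X[:0], y[:0], TrainingConfig(epochs=1))
        with pytest.raises(ValueError, match=r"\[0, 3\)"):
            train(model, X, y + 5, TrainingConfig(epochs=1))
        with pytest.raises(ValueError, match="integer"):
            train(model, X, y.astype(float), TrainingConfig(epochs=1))


class TestPredict:
    def test_batch_size_preserved_and_probs_normalized(self, rng):
        model = build_model(TINY)
        model.initialize(seed=0)
        X = rng.normal(size=(7, 8, 8, 2)).astype(np.float32)
        labels, probs = predict(model, X)
        assert labels.shape == (7,) and probs.shape == (7, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_exact_tie_resolves_to_lowest_class_index(self):
        model = build_model(TINY)
        model.initialize(seed=0)
        # zero weights => identical logits => full tie across classes
        model.params = {k: np.zeros_like(v) for k, v in model.params.items()}
        labels, probs = predict(model, np.ones((2, 8, 8, 2), dtype=np.float32))
        np.testing.assert_allclose(probs, 1 / 3)
        assert (labels == 0).all()
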