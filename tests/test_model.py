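"""CNNDF architecture, numerics and training contracts."""

import numpy as np
import pytest

from cvmstage import nn
from cvmstage.filters import build_bank
from cvmstage.model import (CNNDF, ModelConfig, TrainConfig, build_cnndf,
                            count_parameters, load_model, predict, save_model,
                            train_cnndf)

# spatial ladder and channel widths of the default architecture
EXPECTED_SHAPES = {
    "Input": (77, 35, 1),
    "Directional": (77, 35, 8),
    "Match": (77, 35, 8),
    "Dir_Leaky_Relu": (77, 35, 8),
    "Conv_0": (77, 35, 8),
    "Batch_0": (77, 35, 8),
    "ADD_1": (77, 35, 8),
    "Max_1": (39, 18, 8),
    "Skip_Con_1": (39, 18, 32),
    "Max_2": (20, 9, 32),
    "Skip_Con_2": (20, 9, 64),
    "Max_3": (10, 5, 64),
    "Skip_Con_3": (10, 5, 128),
    "Max_4": (5, 3, 128),
    "Skip_Con_4": (5, 3, 256),
    "Flatten": (3840,),
    "Dense_1": (64,),
    "Batch_11": (64,),
    "Relu_11": (64,),
    "Output_Dense": (5,),
}


@pytest.fixture(scope="module")
def default_model():
    return build_cnndf(ModelConfig(seed=0))


class TestArchitecture:
    def test_every_layer_output_shape(self, default_model):
        _, spec = default_model
        for name, shape in EXPECTED_SHAPES.items():
            assert spec.shape_of(name) == shape, name

    def test_flattened_feature_length(self, default_model):
        _, spec = default_model
        assert spec.shape_of("Flatten") == (3840,)

    def test_parameter_budget(self, default_model):
        model, spec = default_model
        counts = count_parameters(model)
        assert counts["total"] <= 715_000
        assert counts["total"] == spec.total_params
        assert counts["trainable"] + counts["non_trainable"] == counts["total"]

    def test_dense_layer_parameter_arithmetic(self, default_model):
        model, spec = default_model
        dense1 = next(l for l in spec.layers if l.name == "Dense_1")
        assert dense1.params == 3840 * 64 + 64      # 245 824 weights + 64 biases

    def test_pointwise_conv_parameter_arithmetic(self, default_model):
        model, _ = default_model
        conv_skip1 = model.blocks[0].conv_skip      # 1x1, 8 -> 32
        assert sum(p.size for p in conv_skip1.params()) == 8 * 32 + 32

    def test_six_class_head(self):
        model, spec = build_cnndf(ModelConfig(num_classes=6, seed=0))
        assert spec.shape_of("Output_Dense") == (6,)

    def test_bank_must_have_eight_kernels(self):
        partial = build_bank(angles=(0.0, 45.0, 90.0, -45.0, 26.56, -26.56,
                                     63.43, -63.43))
        bad = build_bank()
        object.__setattr__(bad, "kernels", bad.kernels[:5])
        object.__setattr__(bad, "angles_deg", bad.angles_deg[:5])
        with pytest.raises(ValueError):
            CNNDF(ModelConfig(), bad)
        CNNDF(ModelConfig(), partial)   # any ordering of 8 kernels is fine

    def test_initial_directional_layer_is_zero_dc(self, default_model):
        model, _ = default_model
        const = np.full((2, 77, 35, 1), 0.37, dtype=np.float32)
        out = model.directional.forward(const)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_directional_init_equals_bank_convolution(self, default_model):
        # every bank kernel is point-symmetric, so the correlation the layer
        # computes coincides with true convolution by the bank
        from cvmstage.filters import apply_bank, build_bank
        model, _ = default_model
        bank = build_bank()
        stack = bank.as_stack()
        np.testing.assert_allclose(stack, stack[:, ::-1, ::-1], atol=0)
        rng = np.random.default_rng(3)
        img = rng.random((77, 35))
        expected = apply_bank(img, bank)
        got = model.directional.forward(
            img[None, :, :, None].astype(np.float32))[0]
        np.testing.assert_allclose(got.transpose(2, 0, 1), expected,
                                   atol=1e-4)

    def test_random_init_ablation_differs(self):
        tuned = CNNDF(ModelConfig(seed=0))
        ablated = CNNDF(ModelConfig(seed=0, random_init=True))
        assert not np.allclose(tuned.directional.W.val, ablated.directional.W.val)
        # everything downstream is identical
        np.testing.assert_array_equal(tuned.dense1.W.val, ablated.dense1.W.val)


class TestPredict:
    def test_probabilities_sum_to_one(self, default_model):
        model, _ = default_model
        rng = np.random.default_rng(0)
        probs = model.predict_proba(rng.random((4, 77, 35)))
        assert probs.shape == (4, 5)
        assert probs.min() >= 0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_for_fixed_seed(self):
        x = np.random.default_rng(1).random((3, 77, 35))
        p1 = CNNDF(ModelConfig(seed=5)).predict_proba(x)
        p2 = CNNDF(ModelConfig(seed=5)).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_single_image_convenience(self, default_model):
        model, _ = default_model
        out = predict(model, np.random.default_rng(0).random((77, 35)))
        assert out.shape == (5,)

    def test_wrong_input_shape_rejected(self, default_model):
        model, _ = default_model
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((2, 40, 40)))


class TestGradients:
    """Central-difference checks of every layer's backward pass."""

    def _check(self, layer, x, rtol=2e-2, training=True):
        rng = np.random.default_rng(0)
        y = layer.forward(x, training=training)
        r = rng.standard_normal(y.shape).astype(np.float32)
        dx = layer.backward(r)

        def loss(xv):
            return float((layer.forward(xv, training=training) * r).sum())

        eps = 1e-2
        idx = [tuple(rng.integers(0, s) for s in x.shape) for _ in range(6)]
        for ix in idx:
            xp, xm = x.copy(), x.copy()
            xp[ix] += eps
            xm[ix] -= eps
            num = (loss(xp) - loss(xm)) / (2 * eps)
            assert num == pytest.approx(float(dx[ix]), rel=rtol, abs=2e-2)

    def test_conv2d_zero_padding(self):
        rng = np.random.default_rng(2)
        layer = nn.Conv2D(3, 4, 3, rng)
        self._check(layer, rng.random((2, 8, 7, 3), dtype=np.float32))

    def test_conv2d_symmetric_padding(self):
        rng = np.random.default_rng(3)
        layer = nn.Conv2D(2, 3, 5, rng, pad_mode="symmetric")
        self._check(layer, rng.random((2, 9, 8, 2), dtype=np.float32))

    def test_depthwise_conv(self):
        rng = np.random.default_rng(4)
        layer = nn.DepthwiseConv2D(3, 3, rng, pad_mode="symmetric")
        self._check(layer, rng.random((2, 7, 6, 3), dtype=np.float32))

    def test_batchnorm_training_mode(self):
        rng = np.random.default_rng(5)
        layer = nn.BatchNorm(3, ndim=4)
        self._check(layer, rng.random((4, 5, 4, 3), dtype=np.float32))

    def test_dense(self):
        rng = np.random.default_rng(6)
        layer = nn.Dense(7, 4, rng)
        self._check(layer, rng.random((5, 7), dtype=np.float32))

    def test_maxpool_ceil(self):
        rng = np.random.default_rng(7)
        layer = nn.MaxPool2x2Ceil()
        # distinct values so the argmax is stable under the probe
        x = rng.permutation(2 * 7 * 5 * 3).reshape(2, 7, 5, 3).astype(np.float32)
        self._check(layer, x)

    def test_maxpool_ceil_shapes(self):
        x = np.zeros((1, 77, 35, 8), dtype=np.float32)
        y = nn.MaxPool2x2Ceil().forward(x)
        assert y.shape == (1, 39, 18, 8)

    def test_conv_weight_gradient(self):
        rng = np.random.default_rng(8)
        layer = nn.Conv2D(2, 2, 3, rng)
        x = rng.random((2, 6, 5, 2), dtype=np.float32)
        r = rng.standard_normal((2, 6, 5, 2)).astype(np.float32)
        layer.forward(x)
        layer.backward(r)
        eps = 1e-2
        for ix in [(0, 0, 0, 0), (1, 2, 1, 1), (2, 2, 0, 1)]:
            w0 = layer.W.val[ix]
            layer.W.val[ix] = w0 + eps
            lp = float((layer.forward(x) * r).sum())
            layer.W.val[ix] = w0 - eps
            lm = float((layer.forward(x) * r).sum())
            layer.W.val[ix] = w0
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(layer.W.grad[ix]), rel=2e-2,
                                        abs=2e-2)


class TestTraining:
    def test_one_step_updates_directional_weights(self, small_crops):
        x, y6 = small_crops
        model = CNNDF(ModelConfig(num_classes=6, seed=1))
        before = model.directional.W.val.copy()
        train_cnndf(model, x, y6, TrainConfig(epochs=1, batch_size=16, seed=1))
        after = model.directional.W.val
        assert np.abs(after - before).max() > 0
        assert np.isfinite(after).all()

    def test_same_seed_training_is_bit_identical(self, small_crops):
        x, y6 = small_crops
        outs = []
        for _ in range(2):
            model = CNNDF(ModelConfig(num_classes=6, seed=2))
            train_cnndf(model, x, y6, TrainConfig(epochs=2, batch_size=16,
                                                  seed=2))
            outs.append([p.val.copy() for p in model.params()])
        for a, b in zip(*outs):
            np.testing.assert_array_equal(a, b)

    def test_history_records_losses_and_accuracies(self, small_crops):
        x, y6 = small_crops
        model = CNNDF(ModelConfig(num_classes=6, seed=3))
        hist = train_cnndf(model, x, y6,
                           TrainConfig(epochs=2, batch_size=16, seed=3),
                           val_images=x[:8], val_labels=y6[:8])
        assert hist["epoch"] == [1, 2]
        assert len(hist["train_loss"]) == 2
        assert np.isfinite(hist["val_acc"]).all()

    def test_empty_training_set_rejected(self):
        model = CNNDF(ModelConfig(seed=0))
        with pytest.raises(ValueError):
            train_cnndf(model, np.zeros((0, 77, 35)), np.zeros(0, dtype=int))

    def test_out_of_range_label_rejected(self, small_crops):
        x, _ = small_crops
        model = CNNDF(ModelConfig(num_classes=5, seed=0))
        with pytest.raises(ValueError):
            train_cnndf(model, x[:4], np.array([1, 2, 3, 6]),
                        TrainConfig(epochs=1))

    def test_checkpoint_round_trip(self, small_crops, tmp_path):
        x, y6 = small_crops
        model = CNNDF(ModelConfig(num_classes=6, seed=4))
        train_cnndf(model, x[:16], y6[:16], TrainConfig(epochs=1, seed=4))
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict_proba(x[:4]),
                                      model.predict_proba(x[:4]))
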