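"""CNN-TCN classifier: gradients, causality, parameter efficiency, shapes."""

import numpy as np
import pytest

from eyewrite import CnnTcnNet, ModelConfig, count_parameters
from eyewrite.nn import (Conv1d, DepthwiseSeparableCausalConv, SEBlock)
from eyewrite.nn.model import TCNBranchConfig
from eyewrite.training import cross_entropy, softmax


def _no_dropout_cfg(**kw):
    kw.setdefault("tcn", TCNBranchConfig(dropout=0.0))
    kw.setdefault("head_dropout", 0.0)
    return ModelConfig(**kw)


class TestDepthwiseSeparableConv:
    def test_parameter_count_formula(self):
        # C_in*k + C_in*C_out = 32*3 + 32*32 = 1120, against 3072 for the
        # standard convolution it replaces
        layer = DepthwiseSeparableCausalConv(32, 32, kernel=3)
        assert sum(p.size for p in layer.parameters()) == 1120
        standard = Conv1d(32, 32, kernel=3, padding="causal", bias=False)
        assert sum(p.size for p in standard.parameters()) == 3072

    def test_causality_of_layer(self, rng):
        layer = DepthwiseSeparableCausalConv(4, 8, kernel=3, dilation=2,
                                             rng=rng)
        x = rng.normal(size=(2, 4, 40))
        y0 = layer.forward(x)
        for t in (5, 17, 33):
            xp = x.copy()
            xp[:, :, t] += 10.0
            yp = layer.forward(xp)
            np.testing.assert_array_equal(y0[:, :, :t], yp[:, :, :t])
            assert not np.allclose(y0[:, :, t], yp[:, :, t])

    def test_identity_configuration(self):
        layer = DepthwiseSeparableCausalConv(3, 3, kernel=1)
        layer.depthwise.W.data[:] = 1.0
        layer.pointwise.W.data[:, :, 0] = np.eye(3)
        x = np.random.default_rng(0).normal(size=(2, 3, 10))
        np.testing.assert_allclose(layer.forward(x), x, atol=1e-12)


class TestSEBlock:
    def test_gating_is_channelwise_constant(self, rng):
        se = SEBlock(8, reduction=4, rng=rng)
        x = rng.normal(size=(3, 8, 20)) + 5.0  # keep x away from 0
        y = se.forward(x)
        ratio = y / x
        assert np.ptp(ratio, axis=2).max() < 1e-10
        assert np.all(ratio > 0) and np.all(ratio < 1)

    def test_zero_input_zero_output(self):
        se = SEBlock(8, reduction=4)
        np.testing.assert_array_equal(se.forward(np.zeros((2, 8, 5))),
                                      np.zeros((2, 8, 5)))

    def test_saturated_gate_approaches_identity(self, rng):
        se = SEBlock(4, reduction=2, rng=rng)
        se.fc2.W.data[:] = 0.0
        se.fc2.b.data[:] = 50.0  # sigmoid(50) ~ 1
        x = rng.normal(size=(2, 4, 6))
        np.testing.assert_allclose(se.forward(x), x, rtol=1e-10)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SEBlock(6, reduction=4)


class TestModelForward:
    def test_logit_shape_and_finiteness(self, rng):
        net = CnnTcnNet(ModelConfig(input_length=64, n_classes=10))
        logits = net.forward(rng.normal(size=(4, 64, 2)))
        assert logits.shape == (4, 10)
        assert np.all(np.isfinite(logits))

    def test_eval_mode_deterministic(self, rng):
        net = CnnTcnNet(ModelConfig(input_length=64, n_classes=10))
        x = rng.normal(size=(3, 64, 2))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    @pytest.mark.parametrize("fusion", ["parallel", "serial", "cnn_only",
                                        "tcn_only"])
    def test_all_fusion_variants_produce_logits(self, fusion, rng):
        net = CnnTcnNet(ModelConfig(input_length=64, n_classes=7,
                                    fusion=fusion))
        assert net.forward(rng.normal(size=(2, 64, 2))).shape == (2, 7)

    def test_wrong_length_named_in_error(self, rng):
        net = CnnTcnNet(ModelConfig(input_length=64, n_classes=10))
        with pytest.raises(ValueError, match="64"):
            net.forward(rng.normal(size=(2, 60, 2)))

    def test_large_magnitude_inputs_stay_finite(self, rng):
        net = CnnTcnNet(ModelConfig(input_length=64, n_classes=10))
        logits = net.forward(rng.normal(size=(2, 64, 2)) * 1e3)
        assert np.all(np.isfinite(logits))

    def test_float32_cast_matches_float64(self, rng):
        x = rng.normal(size=(2, 64, 2))
        a = CnnTcnNet(ModelConfig(n_classes=10, seed=3)).forward(x)
        b = CnnTcnNet(ModelConfig(n_classes=10, seed=3)).astype(
            np.float32).forward(x)
        np.testing.assert_allclose(a, b, atol=1e-3)


class TestCheckpointing:
    def test_save_load_round_trip(self, tmp_path, rng):
        cfg = ModelConfig(input_length=64, n_classes=10, seed=4)
        net = CnnTcnNet(cfg)
        x = rng.normal(size=(2, 64, 2))
        before = net.forward(x)
        path = tmp_path / "model.npz"
        net.save(path)
        other = CnnTcnNet(ModelConfig(input_length=64, n_classes=10,
                                      seed=99)).load(path)
        np.testing.assert_allclose(other.forward(x), before, atol=1e-12)

    def test_mismatched_architecture_rejected(self, tmp_path):
        net = CnnTcnNet(ModelConfig(input_length=64, n_classes=10))
        path = tmp_path / "model.npz"
        net.save(path)
        other = CnnTcnNet(ModelConfig(input_length=64, n_classes=12))
        with pytest.raises(ValueError, match="hash"):
            other.load(path)


class TestCausality:
    def test_prepool_activations_causal(self, rng):
        # output before the first pooling must not react to future inputs
        net = CnnTcnNet(_no_dropout_cfg(input_length=64, n_classes=10))
        x = rng.normal(size=(2, 64, 2))
        base = net.tcn_prepool_activations(x)
        positions = rng.choice(np.arange(1, 64), size=20, replace=False)
        for t in positions:
            xp = x.copy()
            xp[:, t, :] += 5.0
            pert = net.tcn_prepool_activations(xp)
            np.testing.assert_array_equal(base[:, :, :t], pert[:, :, :t])


class TestParameterCounts:
    def test_monotone_in_input_length(self):
        small = count_parameters(ModelConfig(input_length=64, n_classes=10))
        large = count_parameters(ModelConfig(input_length=128, n_classes=10))
        assert small < large

    def test_cnn_only_is_branch_plus_head(self):
        full = count_parameters(ModelConfig(n_classes=10))
        cnn = count_parameters(ModelConfig(n_classes=10, fusion="cnn_only"))
        tcn = count_parameters(ModelConfig(n_classes=10, fusion="tcn_only"))
        assert cnn < full and tcn < full

    def test_not_divisible_by_four_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_length=62, n_classes=10)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        cfg = _no_dropout_cfg(input_length=16, n_classes=3, seed=3)
        net = CnnTcnNet(cfg)
        x = rng.normal(size=(4, 16, 2))
        y = rng.integers(0, 3, size=4)
        eye = np.eye(3)

        def loss():
            return cross_entropy(softmax(net.forward(x, training=True)),
                                 eye[y])

        probs = softmax(net.forward(x, training=True))
        net.zero_grad()
        net.backward((probs - eye[y]) / 4)

        for p in net.parameters():
            flat, gflat = p.data.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size),
                                replace=False):
                h, old = 1e-6, flat[i]
                flat[i] = old + h
                lp = loss()
                flat[i] = old - h
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * h)
                assert abs(num - gflat[i]) <= 1e-5 * max(1.0, abs(num)), \
                    f"{p.name}[{i}]: numeric {num} vs analytic {gflat[i]}"

    @pytest.mark.parametrize("fusion", ["serial", "cnn_only", "tcn_only"])
    def test_gradients_flow_in_every_variant(self, fusion, rng):
        net = CnnTcnNet(_no_dropout_cfg(input_length=16, n_classes=3,
                                        fusion=fusion, seed=1))
        x = rng.normal(size=(3, 16, 2))
        probs = softmax(net.forward(x, training=True))
        net.zero_grad()
        net.backward((probs - np.eye(3)[[0, 1, 2]]) / 3)
        grads = [np.abs(p.grad).max() for p in net.parameters()]
        assert all(np.isfinite(g) for g in grads)
        assert sum(g > 0 for g in grads) >= len(grads) - 2
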