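"""Architecture contracts of the attention encoder--decoder generator."""

import time

import numpy as np
import pytest

from phasepaint import nn
from phasepaint.errors import ConfigurationError, DimensionError
from phasepaint.nn import Tensor
from phasepaint.segnet import (
    NetworkConfig,
    SCSEGate,
    SEGate,
    SegNet,
    load_checkpoint,
    save_checkpoint,
)

TINY = NetworkConfig(n_stages=2, base_channels=8, cardinality=2, se_reduction=2)


class TestSEGate:
    def test_zero_weights_halve_the_input(self):
        gate = SEGate(4, 2)
        for p in gate.parameters():
            p.data[:] = 0
        x = np.random.default_rng(0).standard_normal((2, 4, 3, 3))
        out = gate(Tensor(x))
        np.testing.assert_allclose(out.data, x / 2, rtol=1e-6)

    def test_shape_preserved(self):
        gate = SEGate(8, 4, rng=np.random.default_rng(1))
        x = np.random.default_rng(2).standard_normal((3, 8, 5, 7))
        assert gate(Tensor(x)).shape == x.shape

    def test_matches_hand_rolled_pool_matmul_oracle(self):
        rng = np.random.default_rng(3)
        gate = SEGate(2, 1, rng=rng)
        w1, b1 = gate.fc1.weight.data, gate.fc1.bias.data
        w2, b2 = gate.fc2.weight.data, gate.fc2.bias.data
        x = rng.standard_normal((1, 2, 2, 2))
        # independent oracle: explicit pooling, matmuls, sigmoid, rescale
        s = x.mean(axis=(2, 3))
        h = np.maximum(s @ w1 + b1, 0)
        g = 1 / (1 + np.exp(-(h @ w2 + b2)))
        expected = x * g[:, :, None, None]
        np.testing.assert_allclose(gate(Tensor(x)).data, expected, atol=1e-6)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            SEGate(6, 4)


class TestSCSEGate:
    def test_shape_preserved(self):
        gate = SCSEGate(8, 4, rng=np.random.default_rng(4))
        x = np.random.default_rng(5).standard_normal((2, 8, 6, 6))
        assert gate(Tensor(x)).shape == x.shape

    def test_zero_weights_halve_the_input_under_max(self):
        gate = SCSEGate(4, 2, combine="max")
        for p in gate.parameters():
            p.data[:] = 0
        x = np.random.default_rng(6).standard_normal((2, 4, 3, 3))
        np.testing.assert_allclose(gate(Tensor(x)).data, x / 2, rtol=1e-6)

    def test_matches_hand_computed_single_channel_example(self):
        gate = SCSEGate(1, 1, combine="max", rng=np.random.default_rng(7))
        x = np.array([[[[1.0, -2.0], [0.5, 3.0]]]])
        # channel branch oracle
        w1, b1 = gate.channel_gate.fc1.weight.data, gate.channel_gate.fc1.bias.data
        w2, b2 = gate.channel_gate.fc2.weight.data, gate.channel_gate.fc2.bias.data
        s = x.mean(axis=(2, 3))
        gch = 1 / (1 + np.exp(-(np.maximum(s @ w1 + b1, 0) @ w2 + b2)))
        cse = x * gch[:, :, None, None]
        # spatial branch oracle (1x1 convs on the channel-pooled map)
        sw1 = gate.sp1.weight.data[:, 0, 0, 0]
        sb1 = gate.sp1.bias.data
        sw2 = gate.sp2.weight.data[0, :, 0, 0]
        sb2 = gate.sp2.bias.data[0]
        pooled = x.mean(axis=1)
        hidden = np.maximum(pooled[:, None] * sw1[None, :, None, None] + sb1[None, :, None, None], 0)
        gsp = 1 / (1 + np.exp(-((hidden * sw2[None, :, None, None]).sum(axis=1) + sb2)))
        sse = x * gsp[:, None]
        np.testing.assert_allclose(
            gate(Tensor(x)).data, np.maximum(cse, sse), atol=1e-6
        )

    def test_add_combination(self):
        gate = SCSEGate(4, 2, combine="add")
        for p in gate.parameters():
            p.data[:] = 0
        x = np.ones((1, 4, 2, 2))
        np.testing.assert_allclose(gate(Tensor(x)).data, x, rtol=1e-6)


class TestEncoderDecoder:
    def test_pyramid_spatial_halving_to_8x8_at_5_stages(self):
        cfg = NetworkConfig(n_stages=5, base_channels=8, cardinality=2, se_reduction=2)
        net = SegNet(cfg)
        feats = net.encode(np.zeros((1, 1, 256, 256), np.float32))
        sizes = [f.shape[2] for f in feats]
        assert sizes == [128, 64, 32, 16, 8]

    def test_doubling_base_channels_doubles_stage_widths(self):
        a = NetworkConfig(base_channels=8, cardinality=2, se_reduction=2)
        b = NetworkConfig(base_channels=16, cardinality=2, se_reduction=2)
        assert [2 * c for c in a.stage_channels()] == b.stage_channels()
        fa = SegNet(a).encode(np.zeros((1, 1, 64, 64), np.float32))
        fb = SegNet(b).encode(np.zeros((1, 1, 64, 64), np.float32))
        assert all(2 * x.shape[1] == y.shape[1] for x, y in zip(fa, fb))

    def test_output_shape_matches_input_and_probability_range(self):
        net = SegNet(TINY).eval()
        x = np.random.default_rng(8).random((2, 1, 64, 64)).astype(np.float32)
        out = net(Tensor(x))
        assert out.shape == (2, 1, 64, 64)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_indivisible_input_dims_rejected(self):
        with pytest.raises(DimensionError):
            SegNet(TINY).encode(np.zeros((1, 1, 62, 62), np.float32))

    def test_gradient_reaches_every_encoder_stage(self):
        net = SegNet(TINY)
        x = np.random.default_rng(9).random((1, 1, 32, 32)).astype(np.float32)
        out = net(Tensor(x))
        out.sum().backward()
        for stage in net.stages:
            g = stage.conv1.weight.grad
            assert g is not None and np.abs(g).max() > 0

    def test_eval_mode_is_repeatable_train_mode_is_stochastic(self):
        net = SegNet(NetworkConfig(n_stages=2, base_channels=8, cardinality=2,
                                   se_reduction=2, dropout_p=0.5, norm="group"))
        x = np.random.default_rng(10).random((1, 1, 32, 32)).astype(np.float32)
        net.eval()
        with nn.no_grad():
            a, b = net(Tensor(x)).data, net(Tensor(x)).data
        np.testing.assert_array_equal(a, b)
        net.train()
        with nn.no_grad():
            c, d = net(Tensor(x)).data, net(Tensor(x)).data
        assert not np.array_equal(c, d)

    def test_tiny_config_forward_is_fast(self):
        net = SegNet(TINY).eval()
        x = np.zeros((1, 1, 64, 64), np.float32)
        net.predict(x)  # warm-up
        t0 = time.perf_counter()
        net.predict(x)
        assert time.perf_counter() - t0 < 1.0


class TestCheckpoint:
    def test_round_trip_reproduces_eval_outputs_exactly(self, tmp_path):
        net = SegNet(TINY).eval()
        x = np.random.default_rng(11).random((1, 1, 64, 64)).astype(np.float32)
        ref = net.predict(x)
        path = tmp_path / "model.npz"
        save_checkpoint(path, net, extra={"note": "test"})
        back, extra = load_checkpoint(path)
        assert extra == {"note": "test"}
        assert back.config == TINY
        np.testing.assert_array_equal(back.predict(x), ref)
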