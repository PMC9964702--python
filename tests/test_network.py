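"""Architecture blocks: shape contracts, attention-gate semantics, heads."""

import numpy as np
import pytest

import sdsseg.autograd as ag
from sdsseg.layers import Conv
from sdsseg.network import (AttentionGate, AuxiliaryHead, BridgeBlock,
                            ConvBlock2d, DeConvBlock, NetworkConfig,
                            ResBlock3d, SegmentationNet)


def rng():
    return np.random.default_rng(0)


class TestResBlock:
    def test_downsampling_halves_plane_and_expands_channels(self):
        blk = ResBlock3d(rng(), cin=8, bottleneck=4, downsample=True)
        x = ag.Tensor(np.random.rand(2, 8, 5, 32, 32).astype(np.float32))
        y = blk(x)
        assert y.shape == (2, 16, 5, 16, 16)

    def test_same_resolution_block_keeps_extents(self):
        blk = ResBlock3d(rng(), cin=16, bottleneck=4, downsample=False)
        y = blk(ag.Tensor(np.random.rand(1, 16, 3, 8, 8).astype(np.float32)))
        assert y.shape == (1, 16, 3, 8, 8)
        assert blk.identity_shortcut

    def test_zero_convolutions_give_zero_output(self):
        blk = ResBlock3d(rng(), cin=4, bottleneck=2, downsample=True)
        for p in blk.parameters():
            p.data = np.zeros_like(p.data)
        y = blk(ag.Tensor(np.zeros((1, 4, 3, 8, 8), dtype=np.float32)))
        assert np.all(y.data == 0)

    def test_identity_path_recovers_input(self):
        # identity shortcut + zeroed Path A => output = relu(x) = x for x >= 0
        blk = ResBlock3d(rng(), cin=8, bottleneck=2, downsample=False)
        for p in [blk.conv3.w, blk.conv3.b]:
            p.data = np.zeros_like(p.data)
        x = np.random.rand(1, 8, 3, 6, 6).astype(np.float32)
        np.testing.assert_allclose(blk(ag.Tensor(x)).data, x, atol=1e-6)

    def test_odd_extent_downsampling_raises(self):
        blk = ResBlock3d(rng(), cin=4, bottleneck=2, downsample=True)
        with pytest.raises(ValueError, match="odd"):
            blk(ag.Tensor(np.zeros((1, 4, 3, 7, 7), dtype=np.float32)))


class TestConvBlock:
    def test_halves_extents(self):
        blk = ConvBlock2d(rng(), 4, 16)
        y = blk(ag.Tensor(np.random.rand(2, 4, 64, 64).astype(np.float32)))
        assert y.shape == (2, 16, 32, 32)

    def test_odd_extent_raises(self):
        blk = ConvBlock2d(rng(), 4, 8)
        with pytest.raises(ValueError, match="even"):
            blk(ag.Tensor(np.zeros((1, 4, 9, 9), dtype=np.float32)))

    def test_translation_consistency_of_stride_arithmetic(self):
        """Shifting the input by 2 pixels shifts the pooled output by 1."""
        blk = ConvBlock2d(rng(), 1, 4)
        blk.eval()
        base = np.zeros((1, 1, 32, 32), dtype=np.float32)
        base[0, 0, 10:14, 10:14] = 1.0
        shifted = np.roll(base, 2, axis=3)
        y0 = blk(ag.Tensor(base)).data
        y1 = blk(ag.Tensor(shifted)).data
        np.testing.assert_allclose(y1[..., 6:10], np.roll(y0, 1, axis=3)[..., 6:10],
                                   atol=1e-5)


class TestBridge:
    def test_folds_slice_axis_and_keeps_plane(self):
        blk = BridgeBlock(rng(), cin=8, cout=12)
        y = blk(ag.Tensor(np.random.rand(2, 8, 5, 40, 40).astype(np.float32)))
        assert y.shape == (2, 12, 40, 40)

    def test_zero_input_gives_zero_prenorm_output(self):
        blk = BridgeBlock(rng(), cin=4, cout=4)
        blk.conv.b.data[:] = 0
        pre = blk.conv(ag.Tensor(np.zeros((1, 4, 3, 8, 8), dtype=np.float32)))
        assert np.all(pre.data == 0)


class TestAttentionGate:
    def test_zero_psi_gives_half_gain(self):
        gate = AttentionGate(rng(), ch_x=6, ch_g=6)
        gate.psi.w.data[:] = 0
        gate.psi.b.data[:] = 0
        x = np.random.rand(2, 6, 8, 8).astype(np.float32)
        g = np.random.rand(2, 6, 8, 8).astype(np.float32)
        y = gate(ag.Tensor(x), ag.Tensor(g))
        np.testing.assert_allclose(y.data, 0.5 * x, atol=1e-6)

    def test_alpha_strictly_inside_unit_interval(self):
        gate = AttentionGate(rng(), ch_x=4, ch_g=8)
        for i in range(20):
            r = np.random.default_rng(i)
            x = ag.Tensor(r.standard_normal((1, 4, 8, 8)).astype(np.float32))
            g = ag.Tensor(r.standard_normal((1, 8, 4, 4)).astype(np.float32))
            gate(x, g)
            assert np.all(gate.last_alpha > 0) and np.all(gate.last_alpha < 1)

    def test_scalar_hand_case(self):
        """W_x = W_g = psi = 1, biases 0, x = 2, g = 3 -> alpha = sigmoid(5)."""
        gate = AttentionGate(rng(), ch_x=1, ch_g=1, f_int=1)
        gate.wx.w.data[:] = 1
        gate.wg.w.data[:] = 1
        gate.wg.b.data[:] = 0
        gate.psi.w.data[:] = 1
        gate.psi.b.data[:] = 0
        x = ag.Tensor(np.full((1, 1, 1, 1), 2.0, dtype=np.float32))
        g = ag.Tensor(np.full((1, 1, 1, 1), 3.0, dtype=np.float32))
        y = gate(x, g)
        alpha = 1.0 / (1.0 + np.exp(-5.0))
        np.testing.assert_allclose(gate.last_alpha.item(), alpha, atol=1e-6)
        np.testing.assert_allclose(y.data.item(), 2.0 * alpha, atol=1e-6)

    def test_strongly_negative_gating_suppresses_attention(self):
        # with positive gating weights the gate direction is well defined:
        # a strongly negative gating signal must lower the mean alpha
        gate = AttentionGate(rng(), ch_x=4, ch_g=4)
        gate.wg.w.data = np.abs(gate.wg.w.data)
        gate.psi.w.data = np.abs(gate.psi.w.data)
        r = np.random.default_rng(3)
        x = ag.Tensor(r.standard_normal((1, 4, 8, 8)).astype(np.float32))
        g_pos = ag.Tensor(np.full((1, 4, 8, 8), 3.0, dtype=np.float32))
        g_neg = ag.Tensor(np.full((1, 4, 8, 8), -50.0, dtype=np.float32))
        gate(x, g_pos)
        mean_pos = gate.last_alpha.mean()
        gate(x, g_neg)
        mean_neg = gate.last_alpha.mean()
        assert mean_neg < mean_pos


class TestDecoderBlocks:
    def test_deconv_doubles_and_concatenates(self):
        blk = DeConvBlock(rng(), cin_up=16, cin_skip=8, cout=12)
        x = ag.Tensor(np.random.rand(1, 16, 14, 14).astype(np.float32))
        skip = ag.Tensor(np.random.rand(1, 8, 28, 28).astype(np.float32))
        assert blk(x, skip).shape == (1, 12, 28, 28)

    def test_deconv_mismatched_skip_raises(self):
        blk = DeConvBlock(rng(), cin_up=4, cin_skip=4, cout=4)
        x = ag.Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))
        skip = ag.Tensor(np.zeros((1, 4, 15, 15), dtype=np.float32))
        with pytest.raises(ValueError, match="match"):
            blk(x, skip)

    def test_auxiliary_head_reaches_full_size_and_normalizes(self):
        head = AuxiliaryHead(rng(), cin=16, n_up=3, classes=3)
        y = head(ag.Tensor(np.random.rand(2, 16, 8, 8).astype(np.float32)))
        assert y.shape == (2, 3, 64, 64)
        np.testing.assert_allclose(y.data.sum(axis=1), 1.0, atol=1e-5)


class TestFullNetwork:
    def test_four_full_size_heads_with_configured_classes(self, tiny_netcfg):
        net = SegmentationNet(tiny_netcfg)
        img = np.random.rand(2, 1, 16, 16).astype(np.float32)
        patch = np.random.rand(2, 1, 3, 16, 16).astype(np.float32)
        heads = net(img, patch)
        assert [h.shape for h in heads] == [(2, c, 16, 16) for c in (2, 3, 4, 4)]
        for h in heads:
            np.testing.assert_allclose(h.data.sum(axis=1), 1.0, atol=1e-5)

    def test_inference_is_deterministic(self, tiny_netcfg):
        net = SegmentationNet(tiny_netcfg)
        net.eval()
        img = np.random.rand(1, 1, 16, 16).astype(np.float32)
        patch = np.random.rand(1, 1, 3, 16, 16).astype(np.float32)
        a = net(img, patch)
        b = net(img, patch)
        for ha, hb in zip(a, b):
            assert np.array_equal(ha.data, hb.data)

    def test_same_seed_same_weights_different_seed_differs(self, tiny_netcfg):
        import dataclasses

        n1 = SegmentationNet(tiny_netcfg)
        n2 = SegmentationNet(tiny_netcfg)
        n3 = SegmentationNet(dataclasses.replace(tiny_netcfg, seed=1))
        for p1, p2 in zip(n1.parameters(), n2.parameters()):
            assert np.array_equal(p1.data, p2.data)
        assert any(not np.array_equal(p1.data, p3.data)
                   for p1, p3 in zip(n1.parameters(), n3.parameters()))

    def test_mainstream_init_is_independent_of_head_classes(self, tiny_netcfg):
        import dataclasses

        n1 = SegmentationNet(tiny_netcfg)  # heads (2, 3, 4, 4)
        n2 = SegmentationNet(dataclasses.replace(tiny_netcfg,
                                                 head_classes=(4, 4, 4, 4)))
        np.testing.assert_array_equal(n1.conv_blocks[0].conv1.w.data,
                                      n2.conv_blocks[0].conv1.w.data)
        np.testing.assert_array_equal(n1.final_proj.w.data, n2.final_proj.w.data)
        np.testing.assert_array_equal(n1.deconvs[2].conv2.w.data,
                                      n2.deconvs[2].conv2.w.data)

    def test_parameter_count_matches_layerwise_sum(self, tiny_netcfg):
        net = SegmentationNet(tiny_netcfg)
        expected = 0
        for m in net.modules():
            for attr in ("w", "b", "gamma", "beta"):
                p = getattr(m, attr, None)
                if p is not None and getattr(p, "requires_grad", False):
                    expected += p.data.size
        assert net.n_parameters() == expected
        # and the count is reproducible for a fixed configuration
        assert net.n_parameters() == SegmentationNet(tiny_netcfg).n_parameters()

    def test_wrong_input_size_raises(self, tiny_netcfg):
        net = SegmentationNet(tiny_netcfg)
        with pytest.raises(ValueError, match="in-plane"):
            net(np.zeros((1, 1, 32, 32), dtype=np.float32),
                np.zeros((1, 1, 3, 32, 32), dtype=np.float32))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(in_plane=(50, 50)).validate()
        with pytest.raises(ValueError):
            NetworkConfig(context_slices=4).validate()
        with pytest.raises(ValueError):
            NetworkConfig(base_channels=1).validate()
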