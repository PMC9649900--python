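"""Convolution arithmetic, block contracts, recurrence, forward pass."""

import numpy as np
import pytest

from scintiseg.network import (ConvSpec, DilatedResidualBlock, InceptionBlock,
                               ModelConfig, RecurrentSegmenter,
                               conv_output_size, recurrent_step)
from scintiseg.nn import Tensor
from scintiseg.nn.autodiff import conv2d


class TestConvOutputSize:
    def test_paper_consistent_zero_padding_case(self):
        # i=10, k=3, d=2: effective kernel n = 3 + 2*1 = 5, o = 10 - 5 + 1 = 6
        spec = ConvSpec(kernel=3, dilation=2, padding=0, stride=1)
        assert spec.effective_kernel == 5
        assert conv_output_size(10, spec) == 6

    def test_same_convolution(self):
        assert conv_output_size(256, ConvSpec(kernel=3, padding=1)) == 256

    def test_agrees_with_executed_layers_on_grid(self, rng):
        checked = 0
        for i in (7, 10, 16, 21, 32):
            for k in (1, 3, 5):
                for d in (1, 2, 3):
                    for p in (0, 1, 2):
                        for s in (1, 2):
                            spec = ConvSpec(kernel=k, dilation=d, padding=p,
                                            stride=s)
                            n = spec.effective_kernel
                            if i + 2 * p < n:
                                continue
                            x = Tensor(rng.standard_normal((1, 1, i, i)))
                            w = Tensor(rng.standard_normal((1, 1, k, k)))
                            out = conv2d(x, w, stride=s, dilation=d, padding=p)
                            o = conv_output_size(i, spec)
                            assert out.shape[-1] == o and out.shape[-2] == o
                            checked += 1
        assert checked >= 100

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError):
            conv_output_size(4, ConvSpec(kernel=3, dilation=3, padding=0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ConvSpec(kernel=0)


class TestDilatedResidualBlock:
    def test_identity_configuration(self, rng):
        blk = DilatedResidualBlock(2, 2, dilation=2,
                                   rng=np.random.default_rng(0))
        # zero the residual path, make the 1x1 skip the identity
        blk.conv2.weight.data[:] = 0
        blk.bn2.beta.data[:] = 0
        blk.bn2.gamma.data[:] = 1
        blk.skip.weight.data[:] = np.eye(2).reshape(2, 2, 1, 1)
        blk.skip.bias.data[:] = 0
        blk.eval()
        x = Tensor(rng.standard_normal((1, 2, 8, 8)))
        out = blk(x)
        np.testing.assert_allclose(out.data, x.data, atol=1e-5)

    @pytest.mark.parametrize("size", [32, 64, 128])
    def test_spatial_size_preserved(self, rng, size):
        blk = DilatedResidualBlock(1, 4, dilation=2,
                                   rng=np.random.default_rng(0))
        out = blk(Tensor(rng.standard_normal((1, 1, size, size))))
        assert out.shape == (1, 4, size, size)

    def test_gradient_flows_through_skip_path(self, rng):
        blk = DilatedResidualBlock(1, 3, rng=np.random.default_rng(0))
        blk.conv1.weight.data[:] = 0  # silence the residual path
        x = Tensor(rng.standard_normal((1, 1, 8, 8)), requires_grad=True)
        (blk(x).sum()).backward()
        assert np.abs(x.grad).max() > 0

    def test_channel_mismatch_raises(self, rng):
        blk = DilatedResidualBlock(2, 4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="channel"):
            blk(Tensor(rng.standard_normal((1, 3, 8, 8))))


class TestInceptionBlock:
    def test_halves_resolution(self, rng):
        blk = InceptionBlock(4, 10, rng=np.random.default_rng(0))
        out = blk(Tensor(rng.standard_normal((2, 4, 64, 64))))
        assert out.shape == (2, 10, 32, 32)

    def test_output_channels_sum_of_branches(self, rng):
        for out_ch in (5, 8, 12, 16):
            blk = InceptionBlock(3, out_ch, rng=np.random.default_rng(0))
            out = blk(Tensor(rng.standard_normal((1, 3, 16, 16))))
            assert out.shape[1] == out_ch

    def test_branch_shapes_match_conv_arithmetic(self, rng):
        blk = InceptionBlock(4, 10, rng=np.random.default_rng(0))
        x = Tensor(rng.standard_normal((1, 4, 32, 32)))
        # 5x5 stride-2 branch: o = floor((32 + 4 - 5)/2) + 1 = 16
        spec = ConvSpec(kernel=5, stride=2, padding=2)
        assert blk.b55(x).shape[-1] == conv_output_size(32, spec)

    def test_odd_spatial_size_rejected(self, rng):
        blk = InceptionBlock(2, 5, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="even"):
            blk(Tensor(rng.standard_normal((1, 2, 15, 15))))


class TestRecurrentStep:
    def test_hand_arithmetic_1x1(self):
        # scalars: u=2, x_prev=3, W_F=0.5, W_R=0.25, b=1 -> z = 1+0.75+1 = 2.75
        u = Tensor(np.full((1, 1, 1, 1), 2.0))
        x_prev = Tensor(np.full((1, 1, 1, 1), 3.0))
        w_f = Tensor(np.full((1, 1, 1, 1), 0.5))
        w_r = Tensor(np.full((1, 1, 1, 1), 0.25))
        b = Tensor(np.array([1.0]))
        z = recurrent_step(u, x_prev, w_f, w_r, b)
        assert z.data.item() == pytest.approx(2.75)

    def test_zero_recurrent_weights_degenerate(self, rng):
        u = Tensor(rng.standard_normal((1, 2, 6, 6)))
        x_prev = Tensor(rng.standard_normal((1, 2, 6, 6)))
        w_f = Tensor(rng.standard_normal((2, 2, 3, 3)))
        w_r = Tensor(np.zeros((2, 2, 3, 3)))
        b = Tensor(np.zeros(2))
        z = recurrent_step(u, x_prev, w_f, w_r, b, padding=1)
        ff = conv2d(u, w_f, b, padding=1)
        np.testing.assert_allclose(z.data, ff.data, atol=1e-6)

    def test_zero_initial_state_is_feedforward_plus_bias(self, rng):
        u = Tensor(rng.standard_normal((1, 2, 6, 6)))
        w_f = Tensor(rng.standard_normal((2, 2, 3, 3)))
        w_r = Tensor(rng.standard_normal((2, 2, 3, 3)))
        b = Tensor(rng.standard_normal(2))
        z = recurrent_step(u, Tensor(np.zeros((1, 2, 6, 6))), w_f, w_r, b,
                           padding=1)
        ff = conv2d(u, w_f, b, padding=1)
        np.testing.assert_allclose(z.data, ff.data, atol=1e-6)


def small_config(**kw):
    defaults = dict(stage_channels=[3, 6, 12], input_size=32, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestForward:
    def test_membership_shape_and_range(self, rng):
        model = RecurrentSegmenter(small_config())
        seg = model.segment(rng.random((32, 32)))
        assert seg.membership.shape == (32, 32)
        assert (seg.membership >= 0).all() and (seg.membership <= 1).all()
        assert set(np.unique(seg.mask.mask)) <= {0, 1}

    def test_t1_equals_single_feedforward_pass(self, rng):
        model = RecurrentSegmenter(small_config()).eval()
        x = Tensor(rng.random((1, 1, 32, 32)))
        out_t1 = model(x, t=1)
        # manual single pass with zero state
        from scintiseg.nn import concat
        features = model.decoder(model.bottleneck(model.encoder(x)))
        u = concat([features, x], axis=1)
        cell = model.cells[0]
        zero = Tensor(np.zeros((1, features.shape[1], 32, 32)))
        state = model.state_act(cell(u, zero))
        manual = model.head(state)
        np.testing.assert_allclose(out_t1.data, manual.data, atol=1e-6)

    def test_parameter_count_invariant_under_unrolling(self, rng):
        model = RecurrentSegmenter(small_config())
        n = model.n_parameters()
        x = Tensor(rng.random((1, 1, 32, 32)))
        for t in (1, 2, 3):
            model(x, t=t)
        assert model.n_parameters() == n

    def test_unshared_weights_add_parameters(self):
        shared = RecurrentSegmenter(small_config(share_recurrent_weights=True,
                                                 recurrence_t=3))
        unshared = RecurrentSegmenter(small_config(
            share_recurrent_weights=False, recurrence_t=3))
        assert unshared.n_parameters() > shared.n_parameters()

    def test_recurrence_changes_output(self, rng):
        model = RecurrentSegmenter(small_config()).eval()
        x = Tensor(rng.random((1, 1, 32, 32)))
        out1, out3 = model(x, t=1), model(x, t=3)
        assert not np.allclose(out1.data, out3.data)

    def test_deterministic_for_fixed_seed(self, rng):
        img = rng.random((32, 32))
        a = RecurrentSegmenter(small_config(seed=5)).segment(img)
        b = RecurrentSegmenter(small_config(seed=5)).segment(img)
        np.testing.assert_array_equal(a.logits, b.logits)

    def test_invalid_inputs(self, rng):
        model = RecurrentSegmenter(small_config())
        with pytest.raises(ValueError, match="t must be >= 1|recurrence"):
            model(Tensor(rng.random((1, 1, 32, 32))), t=0)
        with pytest.raises(ValueError, match="NCHW"):
            model(Tensor(rng.random((32, 32))))

    def test_ablation_flags_change_architecture(self):
        full = RecurrentSegmenter(small_config())
        plain = RecurrentSegmenter(small_config(
            use_dilated=False, use_inception=False, use_residual=False))
        assert plain.n_parameters() != full.n_parameters()
        assert plain.encoder.layers[0].skip is None
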