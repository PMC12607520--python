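"""Unit tests for the neural building blocks: shape contracts, closed-form
special cases (zero weights, constant inputs) and equivalence with the
straight-line oracle re-implementations."""

import numpy as np
import pytest

import oracles
from endomoe.autograd import Tensor
from endomoe.blocks import (
    BlockConfig,
    ChannelGate,
    ExpertBlock,
    ExpertConvStack,
    SpatialChannelAttention,
    SqueezeExcite,
    Stem,
    Transition,
)
from endomoe.nn import ConfigurationError


def _zero_params(module):
    for p in module.parameters():
        p.data[:] = 0.0
    for m in module.modules():
        for name, buf in getattr(m, "_buffers", {}).items():
            buf[:] = 1.0 if "var" in name else 0.0


CFG16 = BlockConfig(in_channels=16, bottleneck_channels=8, conv_groups=4,
                    se_reduction=8, attn_reduction=8)


class TestStem:
    def test_output_shape_224(self, rng):
        stem = Stem(rng, 3, 64)
        out = stem(Tensor(rng.normal(size=(1, 3, 224, 224))))
        assert out.shape == (1, 64, 56, 56)

    def test_zero_input_zero_weights_gives_zero(self, rng):
        stem = Stem(rng, 3, 8)
        _zero_params(stem)
        stem.eval()
        out = stem(Tensor(np.zeros((2, 3, 16, 16))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_outputs_nonnegative(self, rng):
        stem = Stem(rng, 3, 8)
        out = stem(Tensor(rng.normal(size=(2, 3, 32, 32))))
        assert (out.data >= 0).all()

    def test_impulse_response_equals_pooled_kernel(self, rng):
        """A unit impulse convolved with a known 7x7 kernel, then max-pooled,
        equals the max of the kernel over each pooling window."""
        stem = Stem(rng, 3, 1)
        stem.eval()  # BN is identity (unit/zero running stats)
        stem.bn.eps = 0.0
        kernel = rng.normal(size=(1, 3, 7, 7))
        stem.conv.weight.data = kernel
        x = np.zeros((1, 3, 16, 16))
        x[0, 0, 8, 8] = 1.0  # impulse in channel 0
        out = stem(Tensor(x)).data
        expected = oracles.max_pool_ref(
            oracles.relu_ref(oracles.conv2d_ref(x, kernel, stride=2)), 3, 2
        )
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_channel_mismatch_error(self, rng):
        stem = Stem(rng, 3, 8)
        with pytest.raises(ConfigurationError, match="3"):
            stem(Tensor(np.zeros((1, 4, 16, 16))))


class TestAttention:
    def test_zero_weights_give_half_gates_and_quarter_output(self, rng):
        attn = SpatialChannelAttention(CFG16, rng)
        _zero_params(attn)
        attn.eval()
        z = Tensor(rng.normal(size=(2, 16, 6, 6)))
        maps, zf = attn(z)
        np.testing.assert_allclose(maps.spatial_gate, 0.5)
        np.testing.assert_allclose(maps.channel_gate, 0.5)
        np.testing.assert_allclose(zf.data, 0.25 * z.data, rtol=1e-12)

    def test_gates_in_unit_interval_and_attenuation(self, rng):
        attn = SpatialChannelAttention(CFG16, rng)
        z = Tensor(rng.normal(size=(2, 16, 6, 6)))
        maps, zf = attn(z)
        for g in (maps.spatial_gate, maps.channel_gate):
            assert (g > 0).all() and (g < 1).all()
        assert (np.abs(zf.data) <= np.abs(z.data)).all()
        assert (np.sign(zf.data) == np.sign(z.data)).all()

    def test_constant_channel_pools_to_constant(self, rng):
        z = np.zeros((1, 16, 5, 5))
        z[0, 3] = 2.5
        pooled = Tensor(z).data.mean(axis=(2, 3))
        assert pooled[0, 3] == pytest.approx(2.5)

    def test_two_channel_gate_matches_hand_formula(self, rng):
        """1x1x2 input with hand-set 2->1->2 bottleneck weights."""
        gate = ChannelGate(2, 2, rng)
        gate.squeeze.weight.data[:] = np.array([0.5, -1.0]).reshape(1, 2, 1, 1)
        gate.excite.weight.data[:] = np.array([2.0, -0.5]).reshape(2, 1, 1, 1)
        z = Tensor(np.array([1.0, -2.0]).reshape(1, 2, 1, 1))
        out = gate(z).data.reshape(2)
        hidden = max(0.5 * 1.0 + (-1.0) * (-2.0), 0.0)  # ReLU(2.5) = 2.5
        expected = 1 / (1 + np.exp(-np.array([2.0 * hidden, -0.5 * hidden])))
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_reduction_divisibility_enforced(self, rng):
        with pytest.raises(ConfigurationError):
            SpatialChannelAttention(
                BlockConfig(in_channels=10, attn_reduction=16), rng
            )


class TestConvStack:
    def test_shape_restored(self, rng):
        stack = ExpertConvStack(CFG16, rng)
        out = stack(Tensor(rng.normal(size=(2, 16, 5, 7))))
        assert out.shape == (2, 16, 5, 7)

    def test_zero_weights_zero_output(self, rng):
        stack = ExpertConvStack(CFG16, rng)
        _zero_params(stack)
        stack.eval()
        out = stack(Tensor(rng.normal(size=(1, 16, 4, 4))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_grouped_conv_respects_groups(self, rng):
        """With 2 groups, output channels of group 0 must not depend on the
        inputs of group 1 (zeroing group-1 inputs leaves them unchanged)."""
        from endomoe.nn import Conv2d

        conv = Conv2d(4, 4, 3, rng, groups=2, bias=False)
        x = rng.normal(size=(1, 4, 5, 5))
        x_zeroed = x.copy()
        x_zeroed[:, 2:] = 0.0
        full = conv(Tensor(x)).data
        part = conv(Tensor(x_zeroed)).data
        np.testing.assert_allclose(full[:, :2], part[:, :2], rtol=1e-12)
        assert not np.allclose(full[:, 2:], part[:, 2:])

    def test_bottleneck_group_divisibility(self, rng):
        with pytest.raises(ConfigurationError):
            ExpertConvStack(
                BlockConfig(in_channels=16, bottleneck_channels=6, conv_groups=4,
                            se_reduction=8, attn_reduction=8), rng
            )


class TestSqueezeExcite:
    def test_zero_weights_give_half_gates(self, rng):
        se = SqueezeExcite(CFG16, rng)
        _zero_params(se)
        gate = se(Tensor(rng.normal(size=(2, 16, 4, 4))))
        np.testing.assert_allclose(gate.data, 0.5)

    def test_gate_range(self, rng):
        se = SqueezeExcite(CFG16, rng)
        g = se(Tensor(rng.normal(size=(3, 16, 4, 4)))).data
        assert (g > 0).all() and (g < 1).all()

    def test_constant_map_pools_to_constants(self, rng):
        se = SqueezeExcite(CFG16, rng)
        consts = rng.normal(size=16)
        x = np.broadcast_to(consts[None, :, None, None], (1, 16, 6, 6)).copy()
        expected = oracles.channel_gate_ref(se, x)
        np.testing.assert_allclose(se(Tensor(x)).data, expected, rtol=1e-12)


class TestExpertBlock:
    def test_preserves_shape(self, rng):
        block = ExpertBlock(CFG16, rng)
        out = block(Tensor(rng.normal(size=(2, 16, 8, 8))))
        assert out.shape == (2, 16, 8, 8)

    def test_zero_main_path_reduces_to_relu_of_input(self, rng):
        block = ExpertBlock(CFG16, rng)
        _zero_params(block)
        block.eval()
        z = rng.normal(size=(2, 16, 4, 4))
        out = block(Tensor(z))
        # gates are 0.5 everywhere but X3 is 0, so the residual dominates
        np.testing.assert_allclose(out.data, np.maximum(z, 0.0), rtol=1e-12)

    def test_ablation_flags_change_structure(self, rng):
        full = ExpertBlock(CFG16, rng)
        no_se = ExpertBlock(
            BlockConfig(in_channels=16, bottleneck_channels=8, conv_groups=4,
                        se_reduction=8, attn_reduction=8, use_se=False), rng
        )
        se_params = sum(p.data.size for p in full.se.parameters())
        assert full.count_parameters() - no_se.count_parameters() == se_params

    def test_channel_mismatch_raises(self, rng):
        block = ExpertBlock(CFG16, rng)
        with pytest.raises(ConfigurationError):
            block(Tensor(np.zeros((1, 8, 4, 4))))


class TestTransition:
    def test_halves_spatial_and_sets_channels(self, rng):
        tr = Transition(48, 32, rng)
        out = tr(Tensor(rng.normal(size=(2, 48, 14, 14))))
        assert out.shape == (2, 32, 7, 7)
        assert (out.data >= 0).all()

    def test_constant_input_identity_conv_preserves_constant(self, rng):
        tr = Transition(4, 4, rng)
        tr.conv.weight.data = np.eye(4).reshape(4, 4, 1, 1)
        tr.eval()
        tr.bn.eps = 0.0
        x = np.full((1, 4, 4, 4), 3.0)
        out = tr(Tensor(x))
        np.testing.assert_allclose(out.data, 3.0, rtol=1e-6)

    def test_pooling_means_on_known_grid(self, rng):
        tr = Transition(1, 1, rng)
        tr.conv.weight.data[:] = 1.0
        tr.eval()
        tr.bn.eps = 0.0
        x = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        out = tr(Tensor(x)).data
        expected = oracles.avg_pool_ref(x, 2)
        np.testing.assert_allclose(out, expected, rtol=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_block_oracle_equivalence(seed):
    """Every block agrees with an independent straight-line re-evaluation of
    its defining equations on random <=8x8x16 inputs (train-mode BN)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(2, 16, 8, 8))

    attn = SpatialChannelAttention(CFG16, rng)
    sg, cg, zf = oracles.attention_ref(attn, x)
    maps, out = attn(Tensor(x))
    np.testing.assert_allclose(out.data, zf, rtol=1e-5, atol=1e-12)
    np.testing.assert_allclose(maps.spatial_gate, sg[:, 0], rtol=1e-5)

    stack = ExpertConvStack(CFG16, rng)
    np.testing.assert_allclose(
        stack(Tensor(x)).data, oracles.conv_stack_ref(stack, x),
        rtol=1e-5, atol=1e-10,
    )

    se = SqueezeExcite(CFG16, rng)
    np.testing.assert_allclose(
        se(Tensor(x)).data, oracles.channel_gate_ref(se, x), rtol=1e-5
    )

    block = ExpertBlock(CFG16, rng)
    np.testing.assert_allclose(
        block(Tensor(x)).data, oracles.expert_block_ref(block, x),
        rtol=1e-5, atol=1e-10,
    )

    tr = Transition(16, 8, rng)
    np.testing.assert_allclose(
        tr(Tensor(x)).data, oracles.transition_ref(tr, x), rtol=1e-5, atol=1e-10
    )

    from endomoe.blocks import GlobalContext

    gc = GlobalContext(16, 8, rng)
    np.testing.assert_allclose(
        gc(Tensor(x)).data, oracles.channel_gate_ref(gc, x), rtol=1e-5
    )
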