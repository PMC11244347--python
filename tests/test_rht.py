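"""Residual hybrid transformer blocks: window plumbing, attention oracles,
residual identities and composition."""

import numpy as np
import pytest

from medfuse.autodiff import Tensor
from medfuse.nn import LayerNorm
from medfuse.rht import (RHTA, RHTB, ChannelAttentionModule, OverlappingAttention,
                         RHTConfig, RHTStack, WindowAttention, window_partition,
                         window_reverse)


def share_weights(wmsa: WindowAttention, oam: OverlappingAttention):
    C = wmsa.dim
    oam.q.weight.data = wmsa.qkv.weight.data[:, :C].copy()
    oam.q.bias.data = wmsa.qkv.bias.data[:C].copy()
    oam.kv.weight.data = wmsa.qkv.weight.data[:, C:].copy()
    oam.kv.bias.data = wmsa.qkv.bias.data[C:].copy()
    oam.proj.weight.data = wmsa.proj.weight.data.copy()
    oam.proj.bias.data = wmsa.proj.bias.data.copy()
    oam.rel_bias_table.data = wmsa.rel_bias_table.data.copy()


class TestWindowPartition:
    def test_64x64_with_window8_gives_64_windows_of_64_tokens(self, rng):
        x = Tensor(rng.normal(size=(1, 64, 64, 3)))
        wins = window_partition(x, 8)
        assert wins.shape == (64, 64, 3)

    def test_reverse_of_partition_is_bit_exact_identity(self, rng):
        x = rng.normal(size=(2, 16, 24, 3))
        wins = window_partition(Tensor(x), 8)
        back = window_reverse(wins, 8, 2, 16, 24)
        np.testing.assert_array_equal(back.data, x)

    def test_non_divisible_dims_raise(self, rng):
        with pytest.raises(ValueError):
            window_partition(Tensor(rng.normal(size=(1, 60, 64, 3))), 8)


class TestWindowAttention:
    def test_matches_bruteforce_on_2x2_token_windows(self, rng):
        wm = WindowAttention(3, 2, 1, np.random.default_rng(5))
        wm.proj.weight.data = np.eye(3)  # expose raw attention output
        wins = rng.normal(size=(3, 4, 3))
        out = wm.attend(Tensor(wins)).data
        qkvw, qkvb = wm.qkv.weight.data, wm.qkv.bias.data
        bias_tab = wm.rel_bias_table.data[wm.rel_index][:, :, 0]
        for n in range(wins.shape[0]):
            qkv = wins[n] @ qkvw + qkvb
            q, k, v = qkv[:, :3], qkv[:, 3:6], qkv[:, 6:]
            a = q @ k.T / np.sqrt(3) + bias_tab
            a = np.exp(a - a.max(axis=1, keepdims=True))
            a /= a.sum(axis=1, keepdims=True)
            np.testing.assert_allclose(out[n], a @ v, atol=1e-6)

    def test_identical_value_rows_reproduce_that_value(self, rng):
        # attention rows are convex weights: if every token in a window is
        # identical, q/k/v rows repeat and the output token equals v
        wm = WindowAttention(3, 2, 1, np.random.default_rng(5))
        wm.proj.weight.data = np.eye(3)
        wm.rel_bias_table.data = rng.normal(size=wm.rel_bias_table.shape)
        tok = np.tile(rng.normal(size=(1, 1, 3)), (2, 4, 1))
        out = wm.attend(Tensor(tok)).data
        v = tok[0, 0] @ wm.qkv.weight.data[:, 6:] + wm.qkv.bias.data[6:]
        np.testing.assert_allclose(out[0], np.tile(v, (4, 1)), atol=1e-10)

    def test_output_in_convex_hull_of_values(self, rng):
        wm = WindowAttention(3, 4, 1, np.random.default_rng(6))
        wm.proj.weight.data = np.eye(3)
        # make the value projection the identity so values == input tokens
        wm.qkv.weight.data[:, 6:] = np.eye(3)
        wm.qkv.bias.data[6:] = 0.0
        wins = rng.normal(size=(2, 16, 3))
        out = wm.attend(Tensor(wins)).data
        assert (out <= wins.max(axis=1, keepdims=True) + 1e-10).all()
        assert (out >= wins.min(axis=1, keepdims=True) - 1e-10).all()

    def test_padding_path_preserves_arbitrary_shape(self, rng):
        wm = WindowAttention(3, 8, 1, np.random.default_rng(7))
        x = Tensor(rng.normal(size=(1, 60, 61, 3)))
        assert wm(x).shape == (1, 60, 61, 3)


class TestOverlappingAttention:
    def test_gamma_zero_reduces_to_wmsa(self, rng):
        r = np.random.default_rng(8)
        wm = WindowAttention(3, 4, 1, np.random.default_rng(9))
        wm.proj.weight.data = r.normal(size=(3, 3))
        wm.rel_bias_table.data = r.normal(size=wm.rel_bias_table.shape)
        oam = OverlappingAttention(3, 4, 0.0, 1, np.random.default_rng(10))
        share_weights(wm, oam)
        x = Tensor(rng.normal(size=(2, 10, 9, 3)))  # exercises padding too
        np.testing.assert_allclose(oam(x).data, wm(x).data, atol=1e-10)

    def test_overlap_window_size_rounding(self):
        oam = OverlappingAttention(3, 4, 0.5, 1, np.random.default_rng(0))
        assert oam.overlap_win == 6
        assert oam.rel_index.shape == (16, 36)

    def test_identical_tokens_everywhere_give_constant_output(self, rng):
        oam = OverlappingAttention(3, 4, 0.5, 1, np.random.default_rng(1))
        oam.proj.weight.data = np.eye(3)
        token = rng.normal(size=3)
        x = Tensor(np.tile(token, (1, 16, 16, 1)))
        out = oam(x).data
        v = token @ oam.kv.weight.data[:, 3:] + oam.kv.bias.data[3:]
        # interior windows see only copies of the token; border windows mix
        # in zero padding, so check the interior
        np.testing.assert_allclose(out[0, 4:12, 4:12], np.tile(v, (8, 8, 1)), atol=1e-10)


class TestChannelAttention:
    def test_gate_values_in_unit_interval(self, rng):
        cam = ChannelAttentionModule(3, np.random.default_rng(2))
        cam.conv2.weight.data = rng.normal(size=cam.conv2.weight.shape)
        gate = cam.channel_gate(Tensor(rng.normal(size=(2, 3, 8, 8)))).data
        assert (gate > 0).all() and (gate < 1).all()

    def test_gate_bypass_equals_scaled_conv_path(self, rng):
        cam = ChannelAttentionModule(3, np.random.default_rng(2), scale=0.01)
        cam.conv2.weight.data = rng.normal(size=cam.conv2.weight.shape)
        x = Tensor(rng.normal(size=(1, 3, 8, 8)))
        forced = cam(x, gate_override=Tensor(np.ones((1, 3)))).data
        from medfuse.nn import gelu

        path = cam.conv2(gelu(cam.conv1(x))).data
        np.testing.assert_allclose(forced, path * 0.01, atol=1e-12)

    def test_zero_input_zero_biases_give_zero_output(self):
        cam = ChannelAttentionModule(3, np.random.default_rng(2))
        out = cam(Tensor(np.zeros((1, 3, 8, 8)))).data
        np.testing.assert_array_equal(out, 0.0)


class TestResidualBlocks:
    @pytest.mark.parametrize("cls", [RHTA, RHTB])
    def test_zero_init_block_is_exact_identity(self, rng, cls):
        blk = cls(RHTConfig(), np.random.default_rng(3))
        x = rng.normal(size=(2, 3, 16, 16))
        np.testing.assert_array_equal(blk(Tensor(x)).data, x)

    def test_zero_init_stack_is_exact_identity_with_padding(self, rng):
        stack = RHTStack(RHTConfig(), np.random.default_rng(4))
        x = rng.normal(size=(1, 3, 21, 13))  # not multiples of the window
        np.testing.assert_array_equal(stack(Tensor(x)).data, x)

    def test_rhta_matches_term_by_term_composition(self, rng):
        blk = RHTA(RHTConfig(), np.random.default_rng(5))
        # make the residual sub-paths non-trivial
        r = np.random.default_rng(6)
        blk.wmsa.proj.weight.data = r.normal(scale=0.1, size=(3, 3))
        blk.cam.conv2.weight.data = r.normal(scale=0.1, size=blk.cam.conv2.weight.shape)
        blk.mlp.fc2.weight.data = r.normal(scale=0.1, size=blk.mlp.fc2.weight.shape)
        x = Tensor(rng.normal(size=(1, 3, 16, 16)))
        tok = x.transpose(0, 2, 3, 1)
        n1 = blk.ln1(tok)
        r1 = blk.cam(n1.transpose(0, 3, 1, 2)).transpose(0, 2, 3, 1) + blk.wmsa(n1) + tok
        expect = (blk.mlp(blk.ln2(r1)) + r1).transpose(0, 3, 1, 2).data
        np.testing.assert_allclose(blk(x).data, expect, atol=1e-12)

    def test_rhtb_matches_term_by_term_composition(self, rng):
        blk = RHTB(RHTConfig(), np.random.default_rng(7))
        r = np.random.default_rng(8)
        blk.oam.proj.weight.data = r.normal(scale=0.1, size=(3, 3))
        blk.mlp.fc2.weight.data = r.normal(scale=0.1, size=blk.mlp.fc2.weight.shape)
        x = Tensor(rng.normal(size=(1, 3, 16, 16)))
        tok = x.transpose(0, 2, 3, 1)
        r1 = blk.oam(blk.ln1(tok)) + tok
        expect = (blk.mlp(blk.ln2(r1)) + r1).transpose(0, 3, 1, 2).data
        np.testing.assert_allclose(blk(x).data, expect, atol=1e-12)

    def test_stack_equals_explicit_block_composition(self, rng):
        stack = RHTStack(RHTConfig(), np.random.default_rng(9))
        r = np.random.default_rng(10)
        for blk in [*stack.blocks_a, stack.block_b]:
            blk.mlp.fc2.weight.data = r.normal(scale=0.1, size=blk.mlp.fc2.weight.shape)
        x = Tensor(rng.normal(size=(1, 3, 16, 16)))
        y = x
        for blk in stack.blocks_a:
            y = blk(y)
        y = stack.block_b(y)
        np.testing.assert_array_equal(stack(x).data, y.data)

    def test_stack_parameter_count_bookkeeping(self):
        stack = RHTStack(RHTConfig(), np.random.default_rng(11))
        per_a = stack.blocks_a[0].num_parameters()
        per_b = stack.block_b.num_parameters()
        assert stack.num_parameters() == 3 * per_a + per_b


def test_layernorm_is_invariant_to_constant_channel_shift(rng):
    ln = LayerNorm(3)
    x = Tensor(rng.normal(size=(2, 4, 4, 3)))
    shifted = Tensor(x.data + 7.5)
    np.testing.assert_allclose(ln(x).data, ln(shifted).data, atol=1e-9)


def test_config_validation():
    with pytest.raises(ValueError):
        RHTConfig(embed_dim=3, num_heads=2)
    with pytest.raises(ValueError):
        RHTConfig(overlap_ratio=1.5)
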