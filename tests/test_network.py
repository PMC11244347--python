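"""Three-branch fusion network: construction, layer conformance, forward
contract, ablations and checkpointing."""

import numpy as np
import pytest

from medfuse.autodiff import Tensor
from medfuse.colorspace import ImagePair
from medfuse.dynamic_conv import DCB, VanillaConvBlock
from medfuse.network import (FusionNetwork, FusionNetworkConfig, build_network,
                             from_network_range, fuse_pair, load_checkpoint,
                             save_checkpoint, to_network_range)


@pytest.fixture(scope="module")
def default_net():
    return build_network(FusionNetworkConfig(seed=0))


class TestConstruction:
    def test_layer_table_conformance(self, default_net):
        # stem: k3, 2→3; in-branch: k3, 3→3; head: k1, 3→1
        stem_w = default_net.stem.conv.kernels.data
        assert stem_w.shape[1:] == (3, 2, 3, 3)
        for branch in default_net.branches:
            for dcb in branch.dcbs:
                assert dcb.conv.kernels.data.shape[1:] == (3, 3, 3, 3)
        assert default_net.head.kernels.data.shape[1:] == (1, 3, 1, 1)

    def test_branch_depths_are_one_two_three(self, default_net):
        assert [len(b.dcbs) for b in default_net.branches] == [1, 2, 3]
        assert all(b.rht is not None for b in default_net.branches)

    def test_same_seed_gives_bit_identical_parameters(self):
        a = build_network(FusionNetworkConfig(seed=11)).state_dict()
        b = build_network(FusionNetworkConfig(seed=11)).state_dict()
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_single_scale_builds_one_branch_with_fewer_parameters(self):
        multi = build_network(FusionNetworkConfig(seed=0))
        single = build_network(FusionNetworkConfig(seed=0, multi_scale=False))
        assert len(single.branches) == 1
        assert single.num_parameters() < multi.num_parameters()

    def test_invalid_widths_raise(self):
        with pytest.raises(ValueError):
            FusionNetworkConfig(mid_channels=0)
        with pytest.raises(ValueError):
            FusionNetworkConfig(mid_channels=3, num_heads=2)

    def test_parameter_manifest_totals(self, default_net):
        m = default_net.parameter_manifest()
        assert m["total"] == m["stem"] + m["branch0"] + m["branch1"] + m["branch2"] + m["head"]


class TestForward:
    def test_output_shape_and_tanh_range(self, default_net, rng):
        y = Tensor(rng.uniform(-1, 1, (2, 1, 64, 64)))
        s = Tensor(rng.uniform(-1, 1, (2, 1, 64, 64)))
        out = default_net(y, s).data
        assert out.shape == (2, 1, 64, 64)
        assert (out >= -1.0).all() and (out <= 1.0).all()

    def test_forward_is_deterministic(self, default_net, rng):
        y = Tensor(rng.uniform(-1, 1, (1, 1, 32, 32)))
        s = Tensor(rng.uniform(-1, 1, (1, 1, 32, 32)))
        default_net.eval()
        np.testing.assert_array_equal(default_net(y, s).data, default_net(y, s).data)

    def test_shape_mismatch_raises(self, default_net, rng):
        with pytest.raises(ValueError):
            default_net(Tensor(rng.normal(size=(1, 1, 32, 32))),
                        Tensor(rng.normal(size=(1, 1, 32, 16))))

    def test_branch_sum_masking_oracle(self, rng):
        # zeroing two branches' outputs reproduces the head applied to the
        # remaining branch alone
        net = build_network(FusionNetworkConfig(seed=3))
        y = Tensor(rng.uniform(-1, 1, (1, 1, 32, 32)))
        s = Tensor(rng.uniform(-1, 1, (1, 1, 32, 32)))
        keep = net.branches[1]
        zero = lambda x: x * 0.0
        originals = [b.forward for b in net.branches]
        try:
            for i, b in enumerate(net.branches):
                if b is not keep:
                    b.forward = (lambda f: lambda x: zero(f(x)))(b.forward)
            masked = net(y, s).data
        finally:
            for b, f in zip(net.branches, originals):
                b.forward = f
        import medfuse.autodiff as ad

        x = net.stem(ad.concat([y, s], axis=1))
        expect = net.head(keep(x)).tanh().data
        np.testing.assert_allclose(masked, expect, atol=1e-10)


class TestAblations:
    def test_vanilla_conv_swap(self, rng):
        net = build_network(FusionNetworkConfig(seed=0, use_mdc=False))
        assert isinstance(net.stem, VanillaConvBlock)
        out = net(Tensor(rng.uniform(-1, 1, (1, 1, 32, 32))),
                  Tensor(rng.uniform(-1, 1, (1, 1, 32, 32)))).data
        assert out.shape == (1, 1, 32, 32) and np.isfinite(out).all()

    def test_rht_removal(self, rng):
        net = build_network(FusionNetworkConfig(seed=0, use_rht=False))
        assert all(b.rht is None for b in net.branches)
        out = net(Tensor(rng.uniform(-1, 1, (1, 1, 32, 32))),
                  Tensor(rng.uniform(-1, 1, (1, 1, 32, 32)))).data
        assert out.shape == (1, 1, 32, 32) and np.isfinite(out).all()


class TestFusePair:
    def test_neutral_chroma_gives_grayscale_output(self, default_net, rng):
        pair = ImagePair(structural=rng.uniform(0, 1, (40, 40)),
                         functional=rng.uniform(0, 1, (40, 40)))
        fused = fuse_pair(pair, default_net)
        np.testing.assert_allclose(fused[..., 0], fused[..., 1], atol=1e-9)
        np.testing.assert_allclose(fused[..., 1], fused[..., 2], atol=1e-9)

    def test_identity_network_stub_recovers_functional_image(self, rng):
        class IdentityStub(FusionNetwork):
            def forward(self, y_func, structural):
                return y_func

        net = IdentityStub(FusionNetworkConfig(seed=0))
        func = rng.uniform(0, 1, (32, 32, 3))
        pair = ImagePair(structural=rng.uniform(0, 1, (32, 32)), functional=func)
        fused = fuse_pair(pair, net)
        assert np.abs(fused - func).max() < 1.0 / 255.0

    def test_untrained_network_yields_valid_image(self, default_net):
        from medfuse.synthetic import generate_pair

        fused = fuse_pair(generate_pair(48, 48, seed=5), default_net)
        assert fused.shape == (48, 48, 3)
        assert np.isfinite(fused).all()
        assert fused.min() >= 0.0 and fused.max() <= 1.0


def test_range_mapping_roundtrip(rng):
    x = rng.uniform(0, 1, (8, 8))
    np.testing.assert_allclose(from_network_range(to_network_range(x)), x, atol=1e-12)


def test_checkpoint_roundtrip(tmp_path, default_net, rng):
    path = tmp_path / "net.npz"
    save_checkpoint(path, default_net, extra={"note": "test"})
    net2, extra = load_checkpoint(path)
    assert extra == {"note": "test"}
    y = Tensor(rng.uniform(-1, 1, (1, 1, 32, 32)))
    s = Tensor(rng.uniform(-1, 1, (1, 1, 32, 32)))
    np.testing.assert_array_equal(default_net(y, s).data, net2(y, s).data)
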