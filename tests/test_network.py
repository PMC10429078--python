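"""Architecture contracts: shapes, parameter counts, variant plumbing,
attention-gating identities, checkpoint round-trips."""

import numpy as np
import pytest

from fegnet.autograd import Tensor
from fegnet.labels import DensityMap, KernelSpec, PointSet, generate_density
from fegnet.network import (BACKBONE_PLAN, FEGNet, NetworkSpec, build_backbone,
                            build_fem, build_regression_head,
                            count_from_density)

TINY = dict(width_multiplier=0.0625, seed=0)


def brute_force_vgg_prefix_params() -> int:
    """Sum k^2*c_in*c_out + c_out over the ten-conv plan, independently."""
    total, c_in = 0, 3
    for c_out in [64, 64, 128, 128, 256, 256, 256, 512, 512, 512]:
        total += 9 * c_in * c_out + c_out
        c_in = c_out
    return total


class TestBackbone:
    def test_full_width_output_is_eighth_resolution_512_channels(self):
        backbone = build_backbone(NetworkSpec(width_multiplier=1.0, seed=0))
        out = backbone(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
        assert out.data.shape == (1, 512, 8, 8)

    def test_parameter_count_matches_brute_force(self):
        backbone = build_backbone(NetworkSpec(width_multiplier=1.0, seed=0))
        assert sum(p.data.size for p in backbone.parameters()) \
            == brute_force_vgg_prefix_params() == 7_635_264

    def test_scaled_width_channels(self):
        backbone = build_backbone(NetworkSpec(width_multiplier=0.125, seed=0))
        out = backbone(Tensor(np.zeros((1, 3, 128, 128), dtype=np.float32)))
        assert out.data.shape == (1, 64, 16, 16)

    def test_plan_matches_vgg_prefix(self):
        convs = [c for c in BACKBONE_PLAN if c != "M"]
        pools = [c for c in BACKBONE_PLAN if c == "M"]
        assert convs == [64, 64, 128, 128, 256, 256, 256, 512, 512, 512]
        assert len(pools) == 3

    def test_pretrained_with_scaled_width_rejected(self):
        with pytest.raises(ValueError, match="width_multiplier"):
            NetworkSpec(width_multiplier=0.5, pretrained_backbone="weights.npz")

    def test_pretrained_roundtrip_from_npz(self, tmp_path):
        spec = NetworkSpec(width_multiplier=1.0, seed=1)
        src = build_backbone(spec)
        import fegnet.nn as nn

        convs = [l for l in src.layers if isinstance(l, nn.Conv2d)]
        arrays = {}
        for i, conv in enumerate(convs):
            arrays[f"w{i}"] = conv.weight.data
            arrays[f"b{i}"] = conv.bias.data
        np.savez(tmp_path / "vgg.npz", **arrays)
        dst = build_backbone(NetworkSpec(width_multiplier=1.0, seed=99,
                                         pretrained_backbone=str(tmp_path / "vgg.npz")))
        for a, b in zip(src.parameters(), dst.parameters()):
            np.testing.assert_array_equal(a.data, b.data)


class TestHeadAndFEM:
    def test_head_produces_single_channel_at_eighth_scale(self):
        spec = NetworkSpec(**TINY)
        head = build_regression_head(spec)
        feats = Tensor(np.random.default_rng(0)
                       .standard_normal((1, spec.scale(512), 4, 4)).astype(np.float32))
        out = head(feats)
        assert out.data.shape == (1, 1, 4, 4)

    def test_zero_features_give_zero_raw_density(self):
        spec = NetworkSpec(**TINY)
        head = build_regression_head(spec)
        out = head(Tensor(np.zeros((1, spec.scale(512), 4, 4), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_fem_paths_by_variant(self):
        feats = np.random.default_rng(1).standard_normal((1, 32, 4, 4)).astype(np.float32)
        for variant, has_att, has_sup in [("full", True, True),
                                          ("baseline2", True, False),
                                          ("baseline3", False, True)]:
            fem = build_fem(NetworkSpec(variant=variant, **TINY))
            att, prob = fem(Tensor(feats))
            assert (att is not None) == has_att
            assert (prob is not None) == has_sup
            for t in (att, prob):
                if t is not None:
                    assert t.data.shape == (1, 1, 4, 4)
                    assert 0 < t.data.min() <= t.data.max() < 1

    def test_fem_rejected_for_baseline1(self):
        with pytest.raises(ValueError):
            build_fem(NetworkSpec(variant="baseline1", **TINY))


class TestForward:
    @staticmethod
    def _random_image(side=32, seed=0):
        return np.random.default_rng(seed).random((side, side, 3)).astype(np.float32)

    def test_full_variant_output_contract(self):
        net = FEGNet(NetworkSpec(variant="full", **TINY))
        batch, _ = FEGNet.prepare(self._random_image())
        out = net.forward(batch)
        assert out.density.data.shape == (1, 1, 32, 32)
        assert out.raw_density.data.shape == (1, 1, 4, 4)
        assert 0 < out.attention.data.min() <= out.attention.data.max() < 1
        assert 0 < out.probability.data.min() <= out.probability.data.max() < 1
        assert np.isfinite(out.density.data).all()

    @pytest.mark.parametrize("variant,att,prob", [
        ("baseline1", False, False),
        ("baseline2", True, False),
        ("baseline3", False, True),
        ("full", True, True),
    ])
    def test_variant_outputs(self, variant, att, prob):
        net = FEGNet(NetworkSpec(variant=variant, **TINY))
        out = net.forward(FEGNet.prepare(self._random_image())[0])
        assert (out.attention is not None) == att
        assert (out.probability is not None) == prob

    def test_forward_deterministic(self):
        net = FEGNet(NetworkSpec(variant="full", **TINY))
        batch, _ = FEGNet.prepare(self._random_image(seed=3))
        a = net.forward(batch).density.data
        b = net.forward(batch).density.data
        np.testing.assert_array_equal(a, b)

    def test_indivisible_input_rejected_but_predict_pads(self):
        net = FEGNet(NetworkSpec(variant="baseline1", **TINY))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 3, 30, 30), dtype=np.float32))
        dm = net.predict_density(self._random_image(side=30))
        assert dm.values.shape == (30, 30)

    def _saturated_attention_net(self, bias: float):
        """Full net whose attention path's final bias is driven to ±bias."""
        net = FEGNet(NetworkSpec(variant="full", width_multiplier=0.0625, seed=4))
        # make the head non-trivial (final layer is zero-initialized by design)
        rng = np.random.default_rng(5)
        last = net.head.layers[-1]
        last.weight.data = rng.standard_normal(last.weight.data.shape).astype(np.float32) * 0.1
        net.fem.attention_path.proj.weight.data[:] = 0.0
        net.fem.attention_path.proj.bias.data[:] = bias
        return net

    def test_saturated_attention_equals_ungated_head(self):
        """f -> 1 reduces the gated density to the baseline1 output."""
        net = self._saturated_attention_net(bias=50.0)
        base = FEGNet(NetworkSpec(variant="baseline1", width_multiplier=0.0625, seed=4))
        for p_src, p_dst in zip(net.backbone.parameters(), base.backbone.parameters()):
            p_dst.data = p_src.data.copy()
        for p_src, p_dst in zip(net.head.parameters(), base.head.parameters()):
            p_dst.data = p_src.data.copy()
        img = self._random_image(seed=6)
        batch, _ = FEGNet.prepare(img)
        batch = FEGNet.normalize(batch)
        gated = net.forward(batch).density.data
        ungated = base.forward(batch).density.data
        np.testing.assert_allclose(gated, ungated, atol=1e-3)

    def test_zero_attention_annihilates_density(self):
        net = self._saturated_attention_net(bias=-50.0)
        batch, _ = FEGNet.prepare(self._random_image(seed=7))
        out = net.forward(FEGNet.normalize(batch))
        np.testing.assert_allclose(out.density.data, 0.0, atol=1e-6)


class TestCountAndCheckpoint:
    def test_count_is_map_sum(self):
        assert count_from_density(DensityMap(np.zeros((8, 8)))) == 0.0
        ps = PointSet("a", 64, 64, [(float(x), float(x)) for x in range(5, 61, 8)])
        d = generate_density(ps, KernelSpec(window_side=5))
        assert count_from_density(d) == pytest.approx(ps.count, abs=1e-5)
        doubled = DensityMap(d.values * 2)
        assert count_from_density(doubled) == pytest.approx(2 * ps.count, abs=1e-5)

    def test_checkpoint_roundtrip(self, tmp_path):
        net = FEGNet(NetworkSpec(variant="full", **TINY))
        rng = np.random.default_rng(8)
        for p in net.parameters():
            p.data = rng.standard_normal(p.data.shape).astype(np.float32) * 0.05
        path = tmp_path / "ckpt.npz"
        net.save(path)
        loaded = FEGNet.load(path)
        img = np.random.default_rng(9).random((32, 32, 3)).astype(np.float32)
        np.testing.assert_array_equal(net.predict_density(img).values,
                                      loaded.predict_density(img).values)
        assert loaded.spec.variant == "full"

    def test_summary_mentions_all_parts(self):
        text = FEGNet(NetworkSpec(variant="full", **TINY)).summary()
        for token in ("backbone", "head", "fem", "parameters"):
            assert token in text
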