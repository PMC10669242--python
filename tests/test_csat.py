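"""Tests for the CSAT backbone: blocks, attention module, assembly, accounting."""

import numpy as np
import pytest

from rckd.csat import (CSATConfig, CSAT, SATModule, SATBlock, TransformerBlock,
                       Stem, build_csat, count_parameters, count_macs, format_gmac)
from rckd.nn import Tensor, Sequential, Conv2d
from rckd.nn.autograd import no_grad


class TestConfig:
    def test_defaults_reproduce_the_printed_stage_table(self):
        cfg = CSATConfig()
        assert cfg.stage_depths == [2, 2, 6, 4]
        assert cfg.stage_transformers == [0, 0, 2, 2]
        assert cfg.stage_channels == [32, 48, 96, 176]
        assert cfg.pooled_size == 7
        assert cfg.num_classes == 1000

    @pytest.mark.parametrize("bad", [
        dict(stage_depths=[2, 2, 6]),
        dict(stage_channels=[32, 48, 96, 0]),
        dict(pooled_size=0),
        dict(stem_variant="huge"),
    ])
    def test_invalid_configs_are_rejected(self, bad):
        with pytest.raises(ValueError):
            CSATConfig(**bad)

    def test_yaml_round_trip_and_unknown_key_error(self, tmp_path, tiny_config):
        path = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(path)
        loaded = CSATConfig.from_yaml(path)
        assert loaded == tiny_config
        path.write_text("stem_channels: 8\nwindow_size: 7\n")
        with pytest.raises(ValueError, match="window_size"):
            CSATConfig.from_yaml(path)


class TestStem:
    @pytest.mark.parametrize("size,out", [(384, 96), (4, 1), (224, 56)])
    def test_output_is_quarter_resolution(self, size, out):
        stem = Stem(CSATConfig())
        stem.init_parameters(np.random.default_rng(0))
        with no_grad():
            y = stem(Tensor(np.zeros((1, 3, size, size))))
        assert y.shape == (1, 32, out, out)

    def test_patchify_variant_matches_contract(self):
        stem = Stem(CSATConfig(stem_variant="patchify"))
        with no_grad():
            y = stem(Tensor(np.zeros((1, 3, 64, 64))))
        assert y.shape == (1, 32, 16, 16)

    def test_indivisible_size_names_the_axis(self):
        stem = Stem(CSATConfig())
        with pytest.raises(ValueError, match="height"):
            stem(Tensor(np.zeros((1, 3, 30, 32))))
        with pytest.raises(ValueError, match="width"):
            stem(Tensor(np.zeros((1, 3, 32, 30))))


class TestSATModule:
    def test_constant_input_gives_constant_attention_and_scaled_output(self, rng):
        sat = SATModule(pooled_size=7, qk_dim=5)
        sat.init_parameters(np.random.default_rng(3))
        x = Tensor(np.full((2, 8, 20, 20), 1.7))
        with no_grad():
            amap = sat.attention(x)
            out = sat(x)
        assert float(amap.data.max() - amap.data.min()) == 0.0
        scale = float(amap.data.flat[0])
        assert np.allclose(out.data, scale * x.data)

    def test_output_shape_equals_input_shape(self, rng):
        sat = SATModule()
        sat.init_parameters(rng)
        for shape in [(2, 32, 56, 56), (1, 4, 1, 1), (1, 3, 5, 13)]:
            with no_grad():
                assert sat(Tensor(rng.normal(size=shape))).shape == shape

    def test_descriptor_is_always_pooled_size_square(self, rng):
        sat = SATModule(pooled_size=7)
        sat.init_parameters(rng)
        for hw in [(7, 7), (56, 56), (3, 11), (224, 160)]:
            with no_grad():
                d = sat.descriptor(Tensor(rng.normal(size=(1, 6) + hw)))
            assert d.shape == (1, 1, 7, 7)

    def test_single_token_grid_attention_equals_its_value(self, rng):
        # softmax over one token is 1, so the map is V everywhere
        sat = SATModule(pooled_size=1, qk_dim=5)
        sat.init_parameters(np.random.default_rng(6))
        x = Tensor(rng.normal(size=(1, 4, 9, 9)))
        with no_grad():
            ms = sat.descriptor(x)
            tokens = ms + sat.peg(ms)
            qkv = sat.qkv(tokens.reshape(1, 1, 1).transpose(0, 2, 1))
            v = qkv.data[0, 0, -1]
            amap = sat.attention(x)
        assert np.allclose(amap.data, v)

    def test_parameter_budget_is_129_per_module(self):
        assert count_parameters(SATModule(pooled_size=7, qk_dim=5)) == 129


class TestSATBlock:
    def test_residual_shape_preservation(self, rng, tiny_config):
        blk = SATBlock(8, tiny_config)
        blk.init_parameters(rng)
        x = Tensor(rng.normal(size=(1, 8, 14, 14)))
        with no_grad():
            assert blk(x).shape == x.shape

    def test_zero_convolutions_reduce_to_identity(self, rng, tiny_config):
        blk = SATBlock(8, tiny_config)
        blk.init_parameters(rng)
        for name, p in blk.named_parameters():
            if "sat." not in name:
                p.data = np.zeros_like(p.data)
        x = Tensor(rng.normal(size=(2, 8, 10, 10)))
        with no_grad():
            assert np.allclose(blk(x).data, x.data)

    def test_closed_form_parameter_count(self, tiny_config):
        # depthwise 7x7 (no bias) + norm + expand 1x1 + GRN + project 1x1 + SAT
        D, e = 8, tiny_config.conv_expansion
        expected = D * 49 + 2 * D + (D * e * D + e * D) + 2 * e * D + (e * D * D + D) + 129
        assert count_parameters(SATBlock(D, tiny_config)) == expected


class TestTransformerBlock:
    def test_token_round_trip_shape(self, rng):
        tb = TransformerBlock(16, heads=4, mlp_hidden=64)
        tb.init_parameters(rng)
        x = Tensor(rng.normal(size=(1, 16, 12, 12)))
        with no_grad():
            assert tb(x).shape == (1, 16, 12, 12)

    def test_zero_projections_give_identity(self, rng):
        tb = TransformerBlock(16, heads=4, mlp_hidden=64)
        tb.init_parameters(rng)
        tb.proj.weight.data = np.zeros_like(tb.proj.weight.data)
        tb.fc2.weight.data = np.zeros_like(tb.fc2.weight.data)
        tb.fc2.bias.data = np.zeros_like(tb.fc2.bias.data)
        x = Tensor(rng.normal(size=(2, 16, 5, 5)))
        with no_grad():
            assert np.allclose(tb(x).data, x.data)

    def test_batch_equivariance(self, rng):
        tb = TransformerBlock(8, heads=2, mlp_hidden=16)
        tb.init_parameters(rng)
        x = rng.normal(size=(4, 8, 6, 6))
        perm = np.array([2, 0, 3, 1])
        with no_grad():
            out = tb(Tensor(x)).data
            out_perm = tb(Tensor(x[perm])).data
        assert np.allclose(out[perm], out_perm, atol=1e-10)


class TestAssembly:
    def test_classification_head_gives_probability_vector(self, tiny_config):
        model = build_csat(tiny_config, head="classification", seed=0)
        with no_grad():
            out = model(Tensor(np.random.default_rng(0).normal(size=(2, 3, 64, 64))))
        assert out.shape == (2, 3)
        assert np.allclose(out.data.sum(axis=1), 1.0)

    def test_one_weight_set_runs_at_multiple_resolutions(self, tiny_config):
        model = build_csat(tiny_config, head="classification", seed=0)
        rng = np.random.default_rng(1)
        with no_grad():
            for r in (32, 64, 96):
                assert model(Tensor(rng.normal(size=(1, 3, r, r)))).shape == (1, 3)

    def test_stage_resolutions_follow_the_table(self, tiny_config):
        model = build_csat(tiny_config, seed=0)
        with no_grad():
            feats = model.forward_features(Tensor(np.zeros((1, 3, 128, 128))))
        sizes = {k: v.shape[-1] for k, v in feats.items()}
        assert sizes == {"stem": 32, "stage1": 32, "stage2": 16,
                         "stage3": 8, "stage4": 4}

    def test_invalid_head_name_raises(self, tiny_config):
        with pytest.raises(ValueError, match="head"):
            CSAT(tiny_config, head="detection")


class TestAccounting:
    def test_single_conv_mac_formula(self):
        model = Sequential(Conv2d(3, 16, 3, stride=1, padding=1))
        assert count_macs(model, (3, 32, 32)) == 9 * 3 * 16 * 32 * 32  # 442,368

    def test_symbolic_parameter_oracle_matches_framework_count(self, tiny_config):
        """Independent closed-form sum over layers vs the reported count."""
        c = tiny_config
        ch, e = c.stage_channels, c.conv_expansion

        def conv_p(i, o, k, bias=True):
            return i * o * k * k + (o if bias else 0)

        total = conv_p(3, c.stem_hidden, 3) + 2 * c.stem_hidden \
            + conv_p(c.stem_hidden, ch[0], 3) + 2 * ch[0]
        for cin, cout in zip(ch[:-1], ch[1:]):
            total += conv_p(cin, cout, 3) + 2 * cout
        for D, n_sat, n_tr, r in zip(ch, c.stage_depths, c.stage_transformers,
                                     c.transformer_mlp_ratio):
            blk = D * 49 + 2 * D + conv_p(D, e * D, 1) + 2 * e * D + conv_p(e * D, D, 1) + 129
            total += n_sat * blk
            h = int(r * D)
            tr = 2 * D + 3 * D * D + D * D + 2 * D + D * h + h + h * D + D
            total += n_tr * tr
        total += ch[3] * c.num_classes + c.num_classes
        model = build_csat(tiny_config, head="classification")
        assert count_parameters(model) == total

    def test_mac_count_scales_quadratically_with_resolution(self, tiny_config):
        model = build_csat(tiny_config, head="classification")
        m64 = count_macs(model, (3, 64, 64))
        m128 = count_macs(model, (3, 128, 128))
        # fully convolutional portion scales exactly x4; fixed-size SAT token
        # and head terms perturb the ratio only marginally
        assert m128 / m64 == pytest.approx(4.0, rel=0.02)

    def test_gmac_formatting(self):
        assert format_gmac(1_083_017_140) == "1.08"
        assert format_gmac(5_330_161_664) == "5.33"
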