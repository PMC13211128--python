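import numpy as np
import pytest

from mfsleepnet import nn
from mfsleepnet.model import (
    Backbone,
    BasicBlock,
    Bottleneck,
    ForwardResult,
    FusionModule,
    GatedTemporalChannelAttention,
    MFSleepNet,
    ModelConfig,
    Stem,
    concat_baseline_forward,
    eca_kernel_size,
    temporal_length,
)
from mfsleepnet.profiles import get_profile


def brute_force_temporal_length(L):
    """Independent composition of the conv/pool output-length formulas."""
    for k, s, p in ((7, 2, 3), (3, 2, 1), (3, 2, 1), (3, 2, 1), (3, 2, 1)):
        L = (L + 2 * p - k) // s + 1
    return L


class TestTemporalLength:
    @pytest.mark.parametrize("L,expected", [(3200, 100), (3000, 94), (3750, 118)])
    def test_known_values(self, L, expected):
        assert temporal_length(L) == expected
        assert brute_force_temporal_length(L) == expected

    def test_exact_32x_when_divisible(self):
        for L in (32, 320, 960, 3200, 6400):
            assert temporal_length(L) == L // 32

    def test_matches_oracle_on_range(self):
        for L in range(32, 400):
            assert temporal_length(L) == brute_force_temporal_length(L)

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            temporal_length(31)


class TestEcaKernel:
    def test_default_width_gives_7(self):
        assert eca_kernel_size(2048) == 7

    def test_always_odd(self):
        for c in (8, 16, 64, 128, 512, 1024, 2048, 4096):
            assert eca_kernel_size(c) % 2 == 1

    def test_config_validator_reproduces_rule(self):
        cfg = ModelConfig().validate()
        assert cfg.fused_dim == 2048
        assert cfg.eca_kernel_effective() == 7


class TestStem:
    def test_lengths(self):
        stem = Stem(2, 64, np.random.default_rng(0))
        for L, expect in ((3000, 750), (3200, 800)):
            out = stem(nn.Tensor(np.random.default_rng(1).normal(size=(1, 2, L))))
            assert out.data.shape == (1, 64, expect)

    def test_zero_input_zero_output(self):
        stem = Stem(1, 8, np.random.default_rng(2))
        stem.conv.bias.data[:] = 0.0
        out = stem(nn.Tensor(np.zeros((1, 1, 64))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_too_short_rejected(self):
        stem = Stem(1, 8, np.random.default_rng(3))
        with pytest.raises(ValueError, match="too short"):
            stem(nn.Tensor(np.zeros((1, 1, 4))))


class TestBackbones:
    def test_default_eeg_output_shape(self):
        # full-width EEG path on a short input: (B, 2048, T(L))
        bb = Backbone(2, 64, (256, 512, 1024, 2048), (3, 4, 6, 3),
                      Bottleneck, np.random.default_rng(0))
        out = bb(nn.Tensor(np.random.default_rng(1).normal(size=(1, 2, 320))))
        assert out.data.shape == (1, 2048, temporal_length(320))

    def test_default_eog_output_shape(self):
        bb = Backbone(1, 64, (64, 128, 256, 512), (2, 2, 2, 2),
                      BasicBlock, np.random.default_rng(0))
        out = bb(nn.Tensor(np.random.default_rng(1).normal(size=(1, 1, 320))))
        assert out.data.shape == (1, 512, temporal_length(320))

    def test_both_branches_share_temporal_schedule(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0)
        x = np.random.default_rng(2).normal(size=(1, 1, 960))
        f_eeg = model.eeg_backbone(nn.Tensor(x))
        f_eog = model.eog_backbone(nn.Tensor(x))
        assert f_eeg.data.shape[-1] == f_eog.data.shape[-1] == 30

    def test_channel_mismatch_rejected(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0)
        with pytest.raises(ValueError, match="channels"):
            model.eeg_backbone(nn.Tensor(np.zeros((1, 5, 960))))


class TestProjection:
    def test_embedding_widths(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0)
        E = tiny_config.embed_dim_s
        x = np.random.default_rng(3).normal(size=(2, 1, 960))
        assert model.embed_eeg(x).data.shape == (2, E, 30)
        assert model.embed_eog(x).data.shape == (2, E, 30)

    def test_1x1_conv_is_per_timestep_linear_map(self):
        conv = nn.Conv1d(3, 4, 1, rng=np.random.default_rng(4))
        W = np.random.default_rng(5).normal(size=(4, 3))
        conv.weight.data = W[:, :, None]
        conv.bias.data[:] = 0.0
        x = np.random.default_rng(6).normal(size=(2, 3, 7))
        out = conv(nn.Tensor(x)).data
        np.testing.assert_allclose(out, np.einsum("oc,bct->bot", W, x),
                                   atol=1e-12)


class TestFusion:
    def make(self, E=8):
        return FusionModule(E, 1, np.random.default_rng(0))

    def test_zero_logits_give_half_weights(self):
        fus = self.make()
        for conv in (fus.eog_to_eeg_1, fus.eog_to_eeg_2,
                     fus.eeg_to_eog_1, fus.eeg_to_eog_2):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        rng = np.random.default_rng(1)
        f_eeg = nn.Tensor(rng.normal(size=(2, 8, 5)))
        f_eog = nn.Tensor(rng.normal(size=(2, 8, 5)))
        fused, w = fus(f_eeg, f_eog)
        np.testing.assert_array_equal(w["w_eog_to_eeg"].data, 0.5)
        expected = 0.5 * np.concatenate([f_eeg.data, f_eog.data], axis=1)
        np.testing.assert_array_equal(fused.data, expected)

    def test_weights_strictly_in_unit_interval(self):
        fus = self.make()
        rng = np.random.default_rng(2)
        _, w = fus(nn.Tensor(rng.normal(size=(3, 8, 4))),
                   nn.Tensor(rng.normal(size=(3, 8, 4))))
        for v in w.values():
            assert ((v.data > 0) & (v.data < 1)).all()

    def test_zero_eog_gives_constant_per_channel_scaling(self):
        fus = self.make()
        rng = np.random.default_rng(3)
        f_eeg = nn.Tensor(rng.normal(size=(1, 8, 6)))
        f_eog = nn.Tensor(np.zeros((1, 8, 6)))
        fused, w = fus(f_eeg, f_eog)
        # weight depends only on the zero descriptor: constant over time
        scale = w["w_eog_to_eeg"].data[0, :, 0]
        np.testing.assert_allclose(fused.data[0, :8], f_eeg.data[0] * scale[:, None])

    def test_concat_order_eeg_first(self):
        fus = self.make()
        f_eeg = nn.Tensor(np.full((1, 8, 3), 5.0))
        f_eog = nn.Tensor(np.full((1, 8, 3), -5.0))
        fused, _ = fus(f_eeg, f_eog, bypass=True)
        assert (fused.data[0, :8] == 5.0).all()
        assert (fused.data[0, 8:] == -5.0).all()

    def test_fused_width_is_double(self):
        fus = FusionModule(1024, 1, np.random.default_rng(4))
        rng = np.random.default_rng(5)
        fused, _ = fus(nn.Tensor(rng.normal(size=(1, 1024, 4))),
                       nn.Tensor(rng.normal(size=(1, 1024, 4))))
        assert fused.data.shape[1] == 2048

    def test_time_mismatch_rejected(self):
        fus = self.make()
        with pytest.raises(ValueError, match="time"):
            fus(nn.Tensor(np.zeros((1, 8, 4))), nn.Tensor(np.zeros((1, 8, 5))))


class TestGTCA:
    def make(self, C=16):
        return GatedTemporalChannelAttention(C, 8, 3, np.random.default_rng(0))

    def test_gate_saturated_high_returns_input(self):
        block = self.make()
        block.gate_conv.weight.data[:] = 0.0
        block.gate_conv.bias.data[:] = 1e3  # g -> 1
        x = nn.Tensor(np.random.default_rng(1).normal(size=(2, 16, 5)))
        out, w = block(x)
        # f_gate == f_fused; only the ECA rescaling remains
        np.testing.assert_array_equal(w["g"].data, 1.0)
        np.testing.assert_array_equal(out.data, x.data * w["eca_w"].data)

    def test_gate_saturated_low_returns_temporal_path(self):
        block = self.make()
        block.gate_conv.weight.data[:] = 0.0
        block.gate_conv.bias.data[:] = -1e3  # g -> 0
        x = nn.Tensor(np.random.default_rng(2).normal(size=(2, 16, 5)))
        out, w = block(x)
        z = nn.mean_time(x)
        a = nn.sigmoid(block.ta_conv2(nn.relu(block.ta_conv1(z))))
        f_temp = block.bn(x * a + x)
        np.testing.assert_allclose(out.data, f_temp.data * w["eca_w"].data,
                                   atol=1e-12)

    def test_constant_descriptor_gives_equal_eca_weights(self):
        block = self.make()
        block.gate_conv.bias.data[:] = 1e3  # keep f_gate == input
        block.gate_conv.weight.data[:] = 0.0
        x = nn.Tensor(np.ones((1, 16, 5)) * 2.5)
        _, w = block(x)
        eca = w["eca_w"].data[0, :, 0]
        # interior channels see identical neighborhoods (edge padding differs)
        assert np.ptp(eca[1:-1]) < 1e-12

    def test_bottleneck_width(self):
        block = GatedTemporalChannelAttention(2048, 8, 7, np.random.default_rng(3))
        z = nn.mean_time(nn.Tensor(np.random.default_rng(4).normal(size=(1, 2048, 4))))
        mid = block.ta_conv1(z)
        assert mid.data.shape == (1, 256, 1)

    def test_preserves_shape(self):
        block = self.make()
        x = nn.Tensor(np.random.default_rng(5).normal(size=(3, 16, 9)))
        out, _ = block(x)
        assert out.data.shape == x.data.shape

    def test_residual_add_variant(self):
        block = GatedTemporalChannelAttention(
            16, 8, 3, np.random.default_rng(6), eca_residual_add=True)
        block.gate_conv.weight.data[:] = 0.0
        block.gate_conv.bias.data[:] = 1e3
        x = nn.Tensor(np.random.default_rng(7).normal(size=(1, 16, 4)))
        out, w = block(x)
        np.testing.assert_allclose(out.data,
                                   x.data * w["eca_w"].data + x.data, atol=1e-12)


class TestClassify:
    def test_rows_sum_to_one(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0)
        rng = np.random.default_rng(8)
        res = model.forward(rng.normal(size=(4, 1, 960)),
                            rng.normal(size=(4, 1, 960)))
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-6)
        assert res.probabilities.shape == (4, 5)

    def test_zero_head_gives_uniform(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0)
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        rng = np.random.default_rng(9)
        res = model.forward(rng.normal(size=(2, 1, 960)),
                            rng.normal(size=(2, 1, 960)))
        np.testing.assert_allclose(res.probabilities, 0.2, atol=1e-12)


class TestForward:
    def test_smoke_and_taps(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0)
        rng = np.random.default_rng(10)
        res = model.forward(rng.normal(size=(4, 1, 960)),
                            rng.normal(size=(4, 1, 960)))
        assert isinstance(res, ForwardResult)
        assert np.isfinite(res.probabilities).all()
        for tap in ("eeg_branch", "eog_branch", "gated_output"):
            assert tap in res.intermediates

    def test_eval_determinism(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0).eval()
        rng = np.random.default_rng(11)
        eeg = rng.normal(size=(2, 1, 960))
        eog = rng.normal(size=(2, 1, 960))
        a = model.forward(eeg, eog).probabilities
        b = model.forward(eeg, eog).probabilities
        np.testing.assert_array_equal(a, b)

    def test_bypass_equals_concat_baseline_bit_exact(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0).eval()
        rng = np.random.default_rng(12)
        eeg = rng.normal(size=(2, 1, 960))
        eog = rng.normal(size=(2, 1, 960))
        bypassed = model.forward(eeg, eog, fusion_bypass=True, gtca_bypass=True)
        baseline = concat_baseline_forward(model, eeg, eog)
        np.testing.assert_array_equal(bypassed.logits.data, baseline.logits.data)
        np.testing.assert_array_equal(bypassed.probabilities,
                                      baseline.probabilities)

    def test_all_parameters_receive_gradients(self, fast_profile):
        cfg = ModelConfig.from_profile(fast_profile, width_multiplier=1 / 32)
        model = MFSleepNet(cfg, seed=1)
        rng = np.random.default_rng(13)
        res = model.forward(rng.normal(size=(8, 1, 960)),
                            rng.normal(size=(8, 1, 960)))
        loss = nn.cross_entropy(res.logits, rng.integers(0, 5, 8))
        model.zero_grad()
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, f"{name} got no gradient"
            assert np.abs(p.grad).max() > 0, f"{name} gradient all zero"

    def test_attention_weights_in_unit_interval(self, tiny_config):
        model = MFSleepNet(tiny_config, seed=0)
        rng = np.random.default_rng(14)
        res = model.forward(rng.normal(size=(2, 1, 960)),
                            rng.normal(size=(2, 1, 960)))
        for key in ("w_eog_to_eeg", "w_eeg_to_eog", "a", "g", "eca_w"):
            v = res.weights[key].data
            assert ((v > 0) & (v < 1)).all(), key


class TestConfig:
    def test_yaml_round_trip(self, tiny_config):
        text = tiny_config.to_yaml()
        back = ModelConfig.from_yaml(text)
        assert back == tiny_config

    def test_default_table_shapes(self):
        cfg = ModelConfig().validate()
        assert cfg.eeg_widths_s == (256, 512, 1024, 2048)
        assert cfg.eog_widths_s == (64, 128, 256, 512)
        assert cfg.embed_dim_s == 1024
        assert cfg.fused_dim == 2048
        assert cfg.ta_bottleneck == 256

    def test_width_multiplier_scales_jointly(self):
        cfg = ModelConfig(width_multiplier=1 / 16)
        assert cfg.stem_width_s == 4
        assert cfg.eeg_widths_s == (16, 32, 64, 128)
        assert cfg.embed_dim_s == 64
        assert cfg.fused_dim == 128

    def test_invalid_modality(self):
        with pytest.raises(ValueError):
            ModelConfig(modality="emg").validate()

    def test_from_profile_channels(self):
        cfg = ModelConfig.from_profile(get_profile("shhs"))
        assert cfg.eeg_in_channels == 2
        assert cfg.eog_in_channels == 2
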