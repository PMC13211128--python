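"""The multimodal sleep-staging network.

Two modality-specific 1-D residual backbones (bottleneck blocks for EEG,
basic blocks for EOG) downsample 30-s epochs by a factor of 32, project
both branches into a shared embedding width, exchange information through
bidirectional channel-wise gating, refine the concatenated representation
with a gated temporal-channel attention block, and classify with global
average pooling plus a linear head.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import nn
from .nn import Tensor
from .profiles import DatasetProfile

__all__ = [
    "ModelConfig",
    "MFSleepNet",
    "ForwardResult",
    "temporal_length",
    "eca_kernel_size",
    "concat_baseline_forward",
]


def _conv_out(L, k, s, p):
    return (L + 2 * p - k) // s + 1


#: (kernel, stride, padding) of every temporal-length-changing layer:
#: stem conv, stem max-pool, then the stride-2 conv of stages 2-4.
_STRIDE_SCHEDULE = ((7, 2, 3), (3, 2, 1), (3, 2, 1), (3, 2, 1), (3, 2, 1))


def temporal_length(L: int) -> int:
    """Output temporal length of either backbone; equals L/32 when 32 | L."""
    if L < 32:
        raise ValueError(f"input length {L} is below the minimum of 32 samples")
    for k, s, p in _STRIDE_SCHEDULE:
        L = _conv_out(L, k, s, p)
    return L


def eca_kernel_size(channels: int) -> int:
    """Adaptive cross-channel kernel: odd integer near (log2(C) + 1) / 2."""
    t = int((math.log2(channels) + 1) / 2)
    k = t if t % 2 == 1 else t + 1
    return max(k, 3)


def _scaled(width, m):
    return max(int(round(width * m)), 1)


@dataclass
class ModelConfig:
    eeg_in_channels: int = 2
    eog_in_channels: int = 1
    stem_width: int = 64
    eeg_stage_widths: tuple = (256, 512, 1024, 2048)
    eeg_block_counts: tuple = (3, 4, 6, 3)
    bottleneck_expansion: int = 4
    eog_stage_widths: tuple = (64, 128, 256, 512)
    eog_block_counts: tuple = (2, 2, 2, 2)
    embed_dim: int = 1024
    ta_reduction: int = 8
    fusion_reduction: int = 1
    eca_kernel: int | None = None  # None -> adaptive rule
    eca_residual_add: bool = False
    n_classes: int = 5
    width_multiplier: float = 1.0
    modality: str = "both"  # both | eeg | eog
    use_fusion: bool = True
    use_gtca: bool = True

    # -- derived widths (all scale jointly under width_multiplier) ---------

    @property
    def stem_width_s(self):
        return _scaled(self.stem_width, self.width_multiplier)

    @property
    def eeg_widths_s(self):
        return tuple(_scaled(w, self.width_multiplier) for w in self.eeg_stage_widths)

    @property
    def eog_widths_s(self):
        return tuple(_scaled(w, self.width_multiplier) for w in self.eog_stage_widths)

    @property
    def embed_dim_s(self):
        return _scaled(self.embed_dim, self.width_multiplier)

    @property
    def fused_dim(self):
        return 2 * self.embed_dim_s if self.modality == "both" else self.embed_dim_s

    @property
    def ta_bottleneck(self):
        return max(self.fused_dim // self.ta_reduction, 1)

    def eca_kernel_effective(self):
        return self.eca_kernel if self.eca_kernel is not None else eca_kernel_size(self.fused_dim)

    def validate(self):
        if self.modality not in ("both", "eeg", "eog"):
            raise ValueError("modality must be both/eeg/eog")
        k = self.eca_kernel_effective()
        if k % 2 == 0:
            raise ValueError("ECA kernel must be odd")
        if self.modality == "both" and self.fused_dim != 2 * self.embed_dim_s:
            raise ValueError("fused width must be twice the embedding width")
        return self

    @classmethod
    def from_profile(cls, profile: DatasetProfile, **kwargs) -> "ModelConfig":
        return cls(eeg_in_channels=profile.eeg_channels,
                   eog_in_channels=profile.eog_channels, **kwargs).validate()

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)

    def to_yaml(self) -> str:
        d = asdict(self)
        for key in ("eeg_stage_widths", "eeg_block_counts", "eog_stage_widths",
                    "eog_block_counts"):
            d[key] = list(d[key])
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        d = yaml.safe_load(text)
        for key in ("eeg_stage_widths", "eeg_block_counts", "eog_stage_widths",
                    "eog_block_counts"):
            d[key] = tuple(d[key])
        return cls(**d).validate()


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class Stem(nn.Module):
    """Conv(k=7, s=2, p=3) -> BN -> ReLU -> MaxPool(k=3, s=2, p=1)."""

    def __init__(self, in_channels, width, rng):
        super().__init__()
        self.conv = nn.Conv1d(in_channels, width, 7, stride=2, padding=3, rng=rng)
        self.bn = nn.BatchNorm1d(width)
        self.pool = nn.MaxPool1d(3, 2, 1)

    def __call__(self, x):
        if x.data.shape[-1] < 7:
            raise ValueError(f"input length {x.data.shape[-1]} too short for the stem")
        return self.pool(nn.relu(self.bn(self.conv(x))))


class Bottleneck(nn.Module):
    def __init__(self, in_ch, out_ch, stride, expansion, rng):
        super().__init__()
        inner = max(out_ch // expansion, 1)
        self.conv1 = nn.Conv1d(in_ch, inner, 1, rng=rng)
        self.bn1 = nn.BatchNorm1d(inner)
        self.conv2 = nn.Conv1d(inner, inner, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm1d(inner)
        self.conv3 = nn.Conv1d(inner, out_ch, 1, rng=rng)
        self.bn3 = nn.BatchNorm1d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv1d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.proj_bn = nn.BatchNorm1d(out_ch)
        else:
            self.proj = None

    def __call__(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = nn.relu(self.bn2(self.conv2(h)))
        h = self.bn3(self.conv3(h))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return nn.relu(h + shortcut)


class BasicBlock(nn.Module):
    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv1d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm1d(out_ch)
        self.conv2 = nn.Conv1d(out_ch, out_ch, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm1d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv1d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.proj_bn = nn.BatchNorm1d(out_ch)
        else:
            self.proj = None

    def __call__(self, x):
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return nn.relu(h + shortcut)


class Backbone(nn.Module):
    """Stem plus four residual stages; stages 2-4 open with a stride-2 unit."""

    def __init__(self, in_channels, stem_width, stage_widths, block_counts,
                 block, rng, expansion=4):
        super().__init__()
        self.stem = Stem(in_channels, stem_width, rng)
        self.in_channels = in_channels
        stages = []
        ch = stem_width
        for stage_idx, (width, count) in enumerate(zip(stage_widths, block_counts)):
            blocks = []
            for b in range(count):
                stride = 2 if (stage_idx > 0 and b == 0) else 1
                if block is Bottleneck:
                    blocks.append(Bottleneck(ch, width, stride, expansion, rng))
                else:
                    blocks.append(BasicBlock(ch, width, stride, rng))
                ch = width
            stages.append(blocks)
        self.stages = stages
        self.out_channels = ch

    def __call__(self, x):
        if x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"backbone expected {self.in_channels} input channels, "
                f"got {x.data.shape[1]}")
        h = self.stem(x)
        for blocks in self.stages:
            for blk in blocks:
                h = blk(h)
        return h


class FusionModule(nn.Module):
    """Bidirectional cross-channel gating between the two branch embeddings.

    Each direction pools the counterpart modality over time and maps the
    descriptor through conv1x1 -> ReLU -> conv1x1 -> sigmoid; the weights
    modulate the opposite branch channel-wise before concatenation
    (EEG first).
    """

    def __init__(self, embed_dim, reduction, rng):
        super().__init__()
        inner = max(embed_dim // reduction, 1)
        self.eog_to_eeg_1 = nn.Conv1d(embed_dim, inner, 1, rng=rng)
        self.eog_to_eeg_2 = nn.Conv1d(inner, embed_dim, 1, rng=rng)
        self.eeg_to_eog_1 = nn.Conv1d(embed_dim, inner, 1, rng=rng)
        self.eeg_to_eog_2 = nn.Conv1d(inner, embed_dim, 1, rng=rng)

    def __call__(self, f_eeg, f_eog, bypass=False):
        if f_eeg.data.shape[0] != f_eog.data.shape[0] or \
                f_eeg.data.shape[2] != f_eog.data.shape[2]:
            raise ValueError(
                f"fusion requires equal batch and time axes, got "
                f"{f_eeg.data.shape} vs {f_eog.data.shape}")
        if bypass:
            return nn.concat([f_eeg, f_eog], axis=1), {}
        d_eeg = nn.mean_time(f_eeg)
        d_eog = nn.mean_time(f_eog)
        w_eog_to_eeg = nn.sigmoid(self.eog_to_eeg_2(nn.relu(self.eog_to_eeg_1(d_eog))))
        w_eeg_to_eog = nn.sigmoid(self.eeg_to_eog_2(nn.relu(self.eeg_to_eog_1(d_eeg))))
        mod_eeg = f_eeg * w_eog_to_eeg
        mod_eog = f_eog * w_eeg_to_eog
        fused = nn.concat([mod_eeg, mod_eog], axis=1)
        weights = {"w_eog_to_eeg": w_eog_to_eeg, "w_eeg_to_eog": w_eeg_to_eog}
        return fused, weights


class GatedTemporalChannelAttention(nn.Module):
    """Temporal attention, gated fusion and efficient channel attention."""

    def __init__(self, channels, ta_reduction, eca_kernel, rng,
                 eca_residual_add=False):
        super().__init__()
        inner = max(channels // ta_reduction, 1)
        self.ta_conv1 = nn.Conv1d(channels, inner, 1, rng=rng)
        self.ta_conv2 = nn.Conv1d(inner, channels, 1, rng=rng)
        self.bn = nn.BatchNorm1d(channels)
        self.gate_conv = nn.Conv1d(channels, channels, 1, rng=rng)
        self.eca_conv = nn.Conv1d(1, 1, eca_kernel, padding=(eca_kernel - 1) // 2,
                                  bias=False, rng=rng)
        self.eca_residual_add = eca_residual_add
        self.channels = channels

    def __call__(self, f_fused, bypass=False):
        if f_fused.data.shape[1] != self.channels:
            raise ValueError(
                f"attention block expected {self.channels} channels, "
                f"got {f_fused.data.shape[1]}")
        if bypass:
            return f_fused, {}
        # temporal attention over the pooled descriptor
        z = nn.mean_time(f_fused)
        a = nn.sigmoid(self.ta_conv2(nn.relu(self.ta_conv1(z))))
        f_temp = self.bn(f_fused * a + f_fused)
        # per-channel-per-timestep gate between original and enhanced paths
        g = nn.sigmoid(self.gate_conv(f_fused))
        f_gate = g * f_fused + (1.0 - g) * f_temp
        # efficient channel attention: 1-D conv across the channel axis
        pooled = nn.mean_time(f_gate).transpose_ct()          # (B, 1, C)
        eca_w = nn.sigmoid(self.eca_conv(pooled).transpose_ct())  # (B, C, 1)
        out = f_gate * eca_w
        if self.eca_residual_add:
            out = out + f_gate
        weights = {"a": a, "g": g, "eca_w": eca_w}
        return out, weights


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

@dataclass
class ForwardResult:
    probabilities: np.ndarray          # (B, n_classes)
    logits: Tensor                     # (B, n_classes)
    intermediates: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)


class MFSleepNet(nn.Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        m = config
        if m.modality in ("both", "eeg"):
            self.eeg_backbone = Backbone(
                m.eeg_in_channels, m.stem_width_s, m.eeg_widths_s,
                m.eeg_block_counts, Bottleneck, rng, m.bottleneck_expansion)
            self.eeg_embed = nn.Conv1d(self.eeg_backbone.out_channels,
                                       m.embed_dim_s, 1, rng=rng)
        if m.modality in ("both", "eog"):
            self.eog_backbone = Backbone(
                m.eog_in_channels, m.stem_width_s, m.eog_widths_s,
                m.eog_block_counts, BasicBlock, rng)
            self.eog_embed = nn.Conv1d(self.eog_backbone.out_channels,
                                       m.embed_dim_s, 1, rng=rng)
        if m.modality == "both":
            self.fusion = FusionModule(m.embed_dim_s, m.fusion_reduction, rng)
            self.gtca = GatedTemporalChannelAttention(
                m.fused_dim, m.ta_reduction, m.eca_kernel_effective(), rng,
                eca_residual_add=m.eca_residual_add)
        self.head = nn.Linear(m.fused_dim, m.n_classes, rng=rng)

    # -- individual stages (exposed for probing and tests) -----------------

    def embed_eeg(self, eeg) -> Tensor:
        return self.eeg_embed(self.eeg_backbone(nn.as_tensor(eeg)))

    def embed_eog(self, eog) -> Tensor:
        return self.eog_embed(self.eog_backbone(nn.as_tensor(eog)))

    def classify(self, features: Tensor) -> Tensor:
        """GAP over time, flatten, linear head -> logits."""
        pooled = nn.mean_time(features, keepdims=False)
        return self.head(pooled)

    def head_parameters(self):
        return [("head.weight", self.head.weight), ("head.bias", self.head.bias)]

    def backbone_parameters(self):
        head_ids = {id(p) for _, p in self.head_parameters()}
        return [(n, p) for n, p in self.named_parameters() if id(p) not in head_ids]

    def forward(self, eeg=None, eog=None, *, fusion_bypass=False,
                gtca_bypass=False) -> ForwardResult:
        cfg = self.config
        intermediates, weights = {}, {}
        if cfg.modality == "eeg":
            feats = self.embed_eeg(eeg)
            intermediates["eeg_branch"] = feats
        elif cfg.modality == "eog":
            feats = self.embed_eog(eog)
            intermediates["eog_branch"] = feats
        else:
            f_eeg = self.embed_eeg(eeg)
            f_eog = self.embed_eog(eog)
            intermediates["eeg_branch"] = f_eeg
            intermediates["eog_branch"] = f_eog
            fused, w_fusion = self.fusion(
                f_eeg, f_eog, bypass=fusion_bypass or not cfg.use_fusion)
            weights.update(w_fusion)
            intermediates["fused"] = fused
            feats, w_gtca = self.gtca(
                fused, bypass=gtca_bypass or not cfg.use_gtca)
            weights.update(w_gtca)
        intermediates["gated_output"] = feats
        logits = self.classify(feats)
        probs = nn.softmax(logits.data)
        return ForwardResult(probs, logits, intermediates, weights)

    __call__ = forward


def concat_baseline_forward(model: MFSleepNet, eeg, eog) -> ForwardResult:
    """Plain-concatenation pipeline sharing the model's weights.

    Independent code path used to check that the fusion/attention bypass
    switches reduce the full network to simple concatenation bit-exactly.
    """
    f_eeg = model.embed_eeg(eeg)
    f_eog = model.embed_eog(eog)
    fused = nn.concat([f_eeg, f_eog], axis=1)
    logits = model.classify(fused)
    return ForwardResult(nn.softmax(logits.data), logits,
                         {"eeg_branch": f_eeg, "eog_branch": f_eog,
                          "gated_output": fused}, {})
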