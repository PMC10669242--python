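"""CSAT: a lightweight hybrid convolution/attention backbone.

The network applies convolutional SAT blocks in all four stages and appends
Transformer encoder blocks in the last two, following the
convolutions-low / attention-high layout of recent lightweight hybrids.
Each SAT block extracts local features (depthwise 7x7 -> pointwise expand ->
GRN -> pointwise project) and re-scales them with a spatial attention map
computed by the SAT module: the feature map is summarised channel-wise
(average + max), pooled to a small fixed grid (default 7x7), abstracted by a
7x7 convolution, position-encoded by a depthwise PEG, passed through
single-head self-attention over the grid tokens, and the resulting one-channel
map is bilinearly upsampled and multiplied into the features.  Because both
the pooled grid and the PEG are resolution-agnostic, one set of weights runs
at any input size divisible by 32.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .nn import Tensor
from .nn.autograd import concat, adaptive_avg_pool2d, interpolate_bilinear

__all__ = ["CSATConfig", "SATModule", "SATBlock", "TransformerBlock", "Stem",
           "CSAT", "build_csat", "patchify_stem",
           "count_parameters", "count_macs", "format_gmac"]

count_parameters = nn.count_parameters
count_macs = nn.count_macs
format_gmac = nn.format_gmac


@dataclass
class CSATConfig:
    """Architectural hyperparameters.

    The defaults give the ImageNet configuration: stages of 2/2/6/4 SAT
    blocks with 0/0/2/2 trailing Transformer blocks at widths 32/48/96/176,
    a 7x7 pooled attention grid, and a 1000-class head.
    """

    stem_channels: int = 32
    stem_hidden: int = 16
    stem_variant: str = "conv2"          # "conv2" (two 3x3/2) or "patchify" (one 4x4/4)
    stage_depths: list = field(default_factory=lambda: [2, 2, 6, 4])
    stage_transformers: list = field(default_factory=lambda: [0, 0, 2, 2])
    stage_channels: list = field(default_factory=lambda: [32, 48, 96, 176])
    pooled_size: int = 7
    conv_expansion: int = 4
    transformer_mlp_ratio: object = (4, 4, 4, 5)   # int or per-stage sequence
    transformer_heads: int = 8
    sat_qk_dim: int = 5
    use_sat: bool = True
    attention_gate: bool = False          # optional sigmoid on the attention map
    num_classes: int = 1000

    def __post_init__(self):
        for name in ("stage_depths", "stage_transformers", "stage_channels"):
            v = list(getattr(self, name))
            if len(v) != 4:
                raise ValueError(f"{name} must have length 4, got {len(v)}")
            if any(int(x) < 0 for x in v):
                raise ValueError(f"{name} entries must be non-negative")
            setattr(self, name, [int(x) for x in v])
        if any(c < 1 for c in self.stage_channels):
            raise ValueError("stage channel counts must be >= 1")
        if any(d < 1 for d in self.stage_depths):
            raise ValueError("stage depths must be >= 1")
        if self.pooled_size < 1:
            raise ValueError("pooled_size must be >= 1")
        if self.stem_variant not in ("conv2", "patchify"):
            raise ValueError(f"unknown stem variant {self.stem_variant!r}")
        if isinstance(self.transformer_mlp_ratio, (int, float)):
            self.transformer_mlp_ratio = (self.transformer_mlp_ratio,) * 4
        else:
            self.transformer_mlp_ratio = tuple(self.transformer_mlp_ratio)
        if len(self.transformer_mlp_ratio) != 4:
            raise ValueError("transformer_mlp_ratio must be scalar or length 4")

    # -- YAML round trip ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "CSATConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unrecognized config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transformer_mlp_ratio"] = list(self.transformer_mlp_ratio)
        return d

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


class SATModule(nn.Module):
    """Spatial attention over a pooled token grid.

    Channel-wise average/max pooling -> adaptive average pooling to a
    ``pooled_size`` grid -> 7x7 convolution (2 -> 1 channel) -> PEG positional
    encoding (depthwise 3x3) -> single-head self-attention with small Q/K
    dimension and a scalar V -> bilinear upsampling to the input resolution.
    The 7x7 and PEG convolutions use replicate padding so that a spatially
    constant input yields identical tokens and hence a constant attention map.
    """

    def __init__(self, pooled_size=7, qk_dim=5, gate=False):
        super().__init__()
        self.pooled_size = pooled_size
        self.qk_dim = qk_dim
        self.gate = gate
        self.reduce = nn.Conv2d(2, 1, 7, padding=3, bias=False, pad_mode="edge")
        self.peg = nn.Conv2d(1, 1, 3, padding=1, groups=1, bias=False, pad_mode="edge")
        self.qkv = nn.Linear(1, 2 * qk_dim + 1, bias=True)

    def descriptor(self, x: Tensor) -> Tensor:
        """The pooled spatial summary M_S, always pooled_size x pooled_size."""
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        s = concat([avg, mx], axis=1)
        return self.reduce(adaptive_avg_pool2d(s, self.pooled_size, self.pooled_size))

    def attention(self, x: Tensor) -> Tensor:
        """The one-channel attention map at the input's spatial resolution."""
        N, _, H, W = x.shape
        p = self.pooled_size
        ms = self.descriptor(x)
        tokens = ms + self.peg(ms)                       # (N,1,p,p)
        t = tokens.reshape(N, 1, p * p).transpose(0, 2, 1)  # (N,L,1)
        qkv = self.qkv(t)                                # (N,L,2d+1)
        d = self.qk_dim
        q, k, v = qkv[:, :, :d], qkv[:, :, d:2 * d], qkv[:, :, 2 * d:]
        att = (q @ k.transpose(0, 2, 1) / math.sqrt(d)).softmax(axis=-1)
        out = att @ v                                    # (N,L,1)
        amap = out.transpose(0, 2, 1).reshape(N, 1, p, p)
        amap = interpolate_bilinear(amap, H, W)
        if self.gate:
            amap = amap.sigmoid()
        return amap

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention(x)


class SATBlock(nn.Module):
    """y = x + SAT(Conv1x1(GRN(Conv1x1(DWConv7x7(x)))))."""

    def __init__(self, dim, config: CSATConfig):
        super().__init__()
        e = config.conv_expansion * dim
        self.dwconv = nn.Conv2d(dim, dim, 7, padding=3, groups=dim, bias=False)
        self.norm = nn.ChannelLayerNorm(dim)
        self.expand = nn.Conv2d(dim, e, 1, bias=True)
        self.act = nn.GELU()
        self.grn = nn.GRN(e)
        self.project = nn.Conv2d(e, dim, 1, bias=True)
        self.sat = (SATModule(config.pooled_size, config.sat_qk_dim,
                              config.attention_gate)
                    if config.use_sat else nn.Identity())

    def forward(self, x: Tensor) -> Tensor:
        y = self.project(self.grn(self.act(self.expand(self.norm(self.dwconv(x))))))
        return x + self.sat(y)


class TransformerBlock(nn.Module):
    """Pre-norm Transformer encoder over the flattened spatial tokens."""

    def __init__(self, dim, heads, mlp_hidden):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads = dim, heads
        self.norm1 = nn.LayerNorm(dim)
        self.qkv = nn.Linear(dim, 3 * dim, bias=False)
        self.proj = nn.Linear(dim, dim, bias=False)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, mlp_hidden, bias=True)
        self.act = nn.GELU()
        self.fc2 = nn.Linear(mlp_hidden, dim, bias=True)

    def _attend(self, t: Tensor) -> Tensor:
        N, L, C = t.shape
        h, hd = self.heads, C // self.heads
        qkv = self.qkv(t).reshape(N, L, 3, h, hd).transpose(2, 0, 3, 1, 4)  # (3,N,h,L,hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2) / math.sqrt(hd)).softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(N, L, C)
        return self.proj(out)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        t = x.reshape(N, C, H * W).transpose(0, 2, 1)
        t = t + self._attend(self.norm1(t))
        t = t + self.fc2(self.act(self.fc1(self.norm2(t))))
        return t.transpose(0, 2, 1).reshape(N, C, H, W)


class Stem(nn.Module):
    """Patch embedding to a 4x-downsampled feature grid.

    Default form: two 3x3 stride-2 convolutions with normalisation and GELU.
    The single 4x4 stride-4 "patchify" convolution is available as a variant.
    """

    def __init__(self, config: CSATConfig):
        super().__init__()
        c = config.stem_channels
        if config.stem_variant == "patchify":
            self.body = nn.Sequential(nn.Conv2d(3, c, 4, stride=4, bias=True),
                                      nn.ChannelLayerNorm(c))
        else:
            h = config.stem_hidden
            self.body = nn.Sequential(
                nn.Conv2d(3, h, 3, stride=2, padding=1, bias=True),
                nn.ChannelLayerNorm(h), nn.GELU(),
                nn.Conv2d(h, c, 3, stride=2, padding=1, bias=True),
                nn.ChannelLayerNorm(c), nn.GELU())

    def forward(self, x: Tensor) -> Tensor:
        _, _, H, W = x.shape
        for axis, size in (("height", H), ("width", W)):
            if size % 4:
                raise ValueError(f"stem requires spatial size divisible by 4; "
                                 f"{axis} is {size}")
        return self.body(x)


def patchify_stem(image: Tensor, config: CSATConfig | None = None,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Embed an RGB image into the stem feature grid (H/4, W/4)."""
    config = config or CSATConfig()
    stem = Stem(config)
    stem.init_parameters(rng or np.random.default_rng(0))
    return stem(Tensor(image) if not isinstance(image, Tensor) else image)


class _Downsample(nn.Module):
    def __init__(self, cin, cout):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, stride=2, padding=1, bias=True)
        self.norm = nn.ChannelLayerNorm(cout)

    def forward(self, x):
        return self.norm(self.conv(x))


class _Stage(nn.Module):
    def __init__(self, dim, n_blocks, n_transformers, mlp_ratio, heads, config):
        super().__init__()
        blocks = [SATBlock(dim, config) for _ in range(n_blocks)]
        blocks += [TransformerBlock(dim, heads, int(mlp_ratio * dim))
                   for _ in range(n_transformers)]
        self.blocks = nn.Sequential(*blocks)

    def forward(self, x):
        return self.blocks(x)


class CSAT(nn.Module):
    """The assembled backbone with an optional task head.

    ``head`` is one of None (feature extractor), "classification"
    (global average pool + linear + softmax) or "segmentation" (U-Net-style
    decoder; see :mod:`rckd.heads`).
    """

    def __init__(self, config: CSATConfig | None = None, head: str | None = None):
        super().__init__()
        self.config = config = config or CSATConfig()
        ch = config.stage_channels
        if ch[0] != config.stem_channels:
            raise ValueError("stage 1 width must equal stem_channels")
        heads = config.transformer_heads
        self.stem = Stem(config)
        self.stage1 = _Stage(ch[0], config.stage_depths[0], config.stage_transformers[0],
                             config.transformer_mlp_ratio[0], heads, config)
        self.down1 = _Downsample(ch[0], ch[1])
        self.stage2 = _Stage(ch[1], config.stage_depths[1], config.stage_transformers[1],
                             config.transformer_mlp_ratio[1], heads, config)
        self.down2 = _Downsample(ch[1], ch[2])
        self.stage3 = _Stage(ch[2], config.stage_depths[2], config.stage_transformers[2],
                             config.transformer_mlp_ratio[2], heads, config)
        self.down3 = _Downsample(ch[2], ch[3])
        self.stage4 = _Stage(ch[3], config.stage_depths[3], config.stage_transformers[3],
                             config.transformer_mlp_ratio[3], heads, config)
        self.head_kind = head
        if head == "classification":
            self.fc = nn.Linear(ch[3], config.num_classes, bias=True)
        elif head == "segmentation":
            from .heads import UNetDecoder
            self.decoder = UNetDecoder(
                encoder_channels=ch, out_channels=config.num_classes,
                activation="softmax")
        elif head is not None:
            raise ValueError(f"unknown head {head!r}; use None, 'classification' "
                             "or 'segmentation'")

    def forward_features(self, x: Tensor) -> dict:
        """Pyramid of stage outputs at H/4, H/4, H/8, H/16, H/32."""
        feats = {}
        feats["stem"] = self.stem(x)
        feats["stage1"] = self.stage1(feats["stem"])
        feats["stage2"] = self.stage2(self.down1(feats["stage1"]))
        feats["stage3"] = self.stage3(self.down2(feats["stage2"]))
        feats["stage4"] = self.stage4(self.down3(feats["stage3"]))
        return feats

    def forward(self, x: Tensor) -> Tensor:
        feats = self.forward_features(x)
        if self.head_kind == "classification":
            pooled = feats["stage4"].mean(axis=(2, 3))
            # parameter-free normalisation keeps the logit scale bounded
            # (the residual stream itself carries no final norm)
            mu = pooled.mean(axis=-1, keepdims=True)
            var = ((pooled - mu) * (pooled - mu)).mean(axis=-1, keepdims=True)
            pooled = (pooled - mu) / ((var + 1e-6) ** 0.5)
            return self.fc(pooled).softmax(axis=-1)
        if self.head_kind == "segmentation":
            _, _, H, W = x.shape
            return self.decoder(feats, H, W)
        return feats["stage4"]

    def backbone_parameters(self):
        """Named parameters excluding any head."""
        for name, p in self.named_parameters():
            if not (name.startswith("fc.") or name.startswith("decoder.")):
                yield name, p

    def backbone_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for _, p in self.backbone_parameters()))


def build_csat(config: CSATConfig | None = None, head: str | None = None,
               seed: int = 0) -> CSAT:
    """Construct a CSAT model with seed-reproducible initialisation."""
    model = CSAT(config, head)
    model.init_parameters(np.random.default_rng(seed))
    return model
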