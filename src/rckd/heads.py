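"""Task heads attached to the CSAT backbone.

The segmentation decoder is U-Net-style: the bottom stage is upsampled
stepwise, concatenated with the skip feature of the matching resolution and
mixed by a 3x3 convolution; decoder widths mirror the encoder widths.
"""

from __future__ import annotations

from . import nn
from .nn import Tensor
from .nn.autograd import concat, interpolate_bilinear

__all__ = ["UNetDecoder"]


class _DecoderStage(nn.Module):
    def __init__(self, cin, cout):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, padding=1, bias=True)
        self.norm = nn.ChannelLayerNorm(cout)
        self.act = nn.GELU()

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class UNetDecoder(nn.Module):
    """Decode the backbone pyramid to a per-pixel map at input resolution.

    ``activation`` is "sigmoid" (single-channel foreground probability, used
    for distillation pretraining) or "softmax" (T-class per-pixel
    probabilities for downstream segmentation).
    """

    def __init__(self, encoder_channels, out_channels, activation="softmax"):
        super().__init__()
        if activation not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown activation {activation!r}")
        if activation == "softmax" and out_channels < 2:
            raise ValueError("softmax decoder needs at least 2 classes")
        c1, c2, c3, c4 = encoder_channels
        self.up3 = _DecoderStage(c4 + c3, c3)
        self.up2 = _DecoderStage(c3 + c2, c2)
        self.up1 = _DecoderStage(c2 + c1, c1)
        self.refine = _DecoderStage(c1, c1)
        self.out_conv = nn.Conv2d(c1, out_channels, 1, bias=True)
        self.activation = activation
        self.out_channels = out_channels

    def forward(self, feats: dict, H: int, W: int) -> Tensor:
        x = feats["stage4"]
        for skip, stage in ((feats["stage3"], self.up3),
                            (feats["stage2"], self.up2),
                            (feats["stage1"], self.up1)):
            x = interpolate_bilinear(x, skip.shape[-2], skip.shape[-1])
            x = stage(concat([x, skip], axis=1))
        x = self.refine(interpolate_bilinear(x, H, W))
        logits = self.out_conv(x)
        if self.activation == "sigmoid":
            return logits.sigmoid()
        return logits.softmax(axis=1)
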