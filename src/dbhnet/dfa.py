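"""Deep feature aggregation (DFA) decoder.

A lightweight per-branch decoder that uses only the three deepest pyramid
levels (1/8, 1/16, 1/32).  Each level is refined to 48 channels by a
receptive-field block with dilated branches (rates 1, 3, 5, 7); the refined
maps are fused by elementwise products and channel concatenation::

    AD1 = concat[ Up2( Up2(F3') ⊙ F2' ), Up4(F3') ]        (1/8 scale, 96 ch)
    AD2 = concat[ Up2(F2') ⊙ F1' , AD1 ]                   (1/8 scale, 144 ch)

and a two-conv head followed by bilinear ×8 restores full-resolution logits.
Aggregating only deep features keeps the decoder small (its parameter count
is independent of image size) while still localizing salient lesion regions.
"""

from __future__ import annotations

from . import nn
from .nn import Tensor
from .unet_encoder import ContractViolation


class _ConvBnRelu(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 dilation: int = 1):
        super().__init__()
        pad = dilation * (kernel - 1) // 2
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, padding=pad,
                              dilation=dilation)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class RFB48(nn.Module):
    """Receptive-field block reducing any input to 48 channels.

    Four parallel branches share a 1×1 bottleneck to ``in_ch // 8`` channels;
    branches with dilation rate r > 1 add a 3×3 conv at that rate (the rate-7
    branch extends the classic 1/3/5 pattern).  Branch outputs are
    concatenated, merged by a 1×1 conv to 48 channels and summed with a 1×1
    shortcut.
    """

    def __init__(self, in_ch: int, out_ch: int = 48,
                 dilations: tuple[int, ...] = (1, 3, 5, 7)):
        super().__init__()
        inter = max(in_ch // 8, 8)
        self.branches = nn.ModuleList()
        for rate in dilations:
            layers = [_ConvBnRelu(in_ch, inter, kernel=1)]
            if rate > 1:
                layers.append(_ConvBnRelu(inter, inter, 3))
                layers.append(_ConvBnRelu(inter, inter, 3, dilation=rate))
            self.branches.append(nn.Sequential(*layers))
        self.merge = _ConvBnRelu(inter * len(dilations), out_ch, kernel=1)
        self.shortcut = nn.Conv2d(in_ch, out_ch, 1)
        self.shortcut_bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        out = nn.cat([b(x) for b in self.branches], axis=1)
        out = self.merge(out)
        return (out + self.shortcut_bn(self.shortcut(x))).relu()


def aggregation_decode(f1: Tensor, f2: Tensor, f3: Tensor) -> Tensor:
    """Fuse the refined maps (scales 1/8, 1/16, 1/32) into AD2 at 1/8."""
    if not (f1.shape[1] == f2.shape[1] == f3.shape[1]):
        raise ContractViolation(
            "refined maps must share one channel width, got "
            f"{f1.shape[1]}, {f2.shape[1]}, {f3.shape[1]}")
    prod = nn.interpolate_bilinear(f3, 2) * f2
    ad1 = nn.cat([nn.interpolate_bilinear(prod, 2),
                  nn.interpolate_bilinear(f3, 4)], axis=1)
    ad2 = nn.cat([nn.interpolate_bilinear(f2, 2) * f1, ad1], axis=1)
    return ad2


class DFAHead(nn.Module):
    """Two 3×3 convs (BN+ReLU on the first) then bilinear ×8 to logits."""

    def __init__(self, in_ch: int = 144, mid_ch: int = 48,
                 num_classes: int = 2):
        super().__init__()
        self.conv1 = _ConvBnRelu(in_ch, mid_ch, 3)
        self.conv2 = nn.Conv2d(mid_ch, num_classes, 3, padding=1)

    def forward(self, ad2: Tensor) -> Tensor:
        x = self.conv2(self.conv1(ad2))
        return nn.interpolate_bilinear(x, 8)


class DFADecoder(nn.Module):
    """RFB refinement + aggregation + head over a four-level pyramid."""

    def __init__(self, embed_dim: int = 96, channels: int = 48,
                 dilations: tuple[int, ...] = (1, 3, 5, 7),
                 num_classes: int = 2):
        super().__init__()
        self.rfb1 = RFB48(embed_dim * 2, channels, dilations)
        self.rfb2 = RFB48(embed_dim * 4, channels, dilations)
        self.rfb3 = RFB48(embed_dim * 8, channels, dilations)
        self.head = DFAHead(channels * 3, channels, num_classes)

    def forward(self, pyramid: list[Tensor]) -> Tensor:
        f1 = self.rfb1(pyramid[1])
        f2 = self.rfb2(pyramid[2])
        f3 = self.rfb3(pyramid[3])
        return self.head(aggregation_decode(f1, f2, f3))
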