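"""Convolutional branch: a five-unit U-Net style encoder.

Each unit applies two 3×3 conv + batch-norm + ReLU layers and then a 2×2
max-pool, halving the spatial size.  The encoder therefore emits features at
1/2 … 1/32 of the input; the four deepest (units 2–5) form the feature
pyramid shared with the self-attention branch: scales 1/4, 1/8, 1/16, 1/32
with channel widths C, 2C, 4C, 8C (C defaults to 96, so the first unit runs
at C/2 = 48 channels).

A classic symmetric decoder (:class:`UNetDecoder`) is provided for the
stand-alone convolutional baseline: per level, bilinear ×2 upsampling, skip
concatenation, and two 3×3 conv units.
"""

from __future__ import annotations

from . import nn
from .nn import Tensor


class ContractViolation(ValueError):
    """A feature-map shape violates a documented architectural contract."""


def _check_even(x: Tensor) -> None:
    for axis, name in ((2, "height"), (3, "width")):
        if x.shape[axis] % 2:
            raise ContractViolation(
                f"conv unit requires an even {name}, got {x.shape[axis]}")


class ConvUnit(nn.Module):
    """(conv3×3 → BN → ReLU) ×2 → maxpool 2×2; halves the spatial size."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding=1)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        _check_even(x)
        x = self.bn1(self.conv1(x)).relu()
        x = self.bn2(self.conv2(x)).relu()
        return nn.max_pool2d(x, 2)


class UNetEncoder(nn.Module):
    """Five conv units; returns the outputs of units 2–5 as the pyramid."""

    def __init__(self, embed_dim: int = 96, in_ch: int = 3):
        super().__init__()
        base = embed_dim // 2
        widths = [base, base * 2, base * 4, base * 8, base * 16]
        self.embed_dim = embed_dim
        chans = [in_ch] + widths
        self.units = nn.ModuleList(
            [ConvUnit(chans[i], chans[i + 1]) for i in range(5)])

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.shape[1] != 3:
            raise ContractViolation(
                f"expected a 3-channel image, got {x.shape[1]} channels")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ContractViolation(
                "image height and width must be divisible by 32, got "
                f"{x.shape[2]}×{x.shape[3]}")
        feats = []
        for unit in self.units:
            x = unit(x)
            feats.append(x)
        return feats[1:]


class _UpBlock(nn.Module):
    """Bilinear ×2 upsample, concat with the skip, two conv+BN+ReLU."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch + skip_ch, out_ch, 3, padding=1)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = nn.interpolate_bilinear(x, 2)
        x = nn.cat([x, skip], axis=1)
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class UNetDecoder(nn.Module):
    """Classic symmetric decoder for the stand-alone convolutional baseline.

    Consumes all five encoder scales (the 1/2-scale unit-1 output serves as
    the shallowest skip) and emits full-resolution class logits.
    """

    def __init__(self, embed_dim: int = 96, num_classes: int = 2):
        super().__init__()
        base = embed_dim // 2
        w = [base, base * 2, base * 4, base * 8, base * 16]
        self.blocks = nn.ModuleList([
            _UpBlock(w[4], w[3], w[3]),
            _UpBlock(w[3], w[2], w[2]),
            _UpBlock(w[2], w[1], w[1]),
            _UpBlock(w[1], w[0], w[0]),
        ])
        self.head = nn.Conv2d(w[0], num_classes, 1)

    def forward(self, skips: list[Tensor]) -> Tensor:
        # skips: unit-1..unit-5 outputs, shallowest first
        x = skips[-1]
        for block, skip in zip(self.blocks, reversed(skips[:-1])):
            x = block(x, skip)
        x = self.head(x)
        return nn.interpolate_bilinear(x, 2)


class UNet(nn.Module):
    """Stand-alone convolutional baseline (encoder + symmetric decoder)."""

    def __init__(self, embed_dim: int = 96, num_classes: int = 2):
        super().__init__()
        self.encoder = UNetEncoder(embed_dim)
        self.decoder = UNetDecoder(embed_dim, num_classes)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ContractViolation(
                "image height and width must be divisible by 32")
        feats = []
        h = x
        for unit in self.encoder.units:
            h = unit(h)
            feats.append(h)
        return self.decoder(feats)
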