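"""Attention-gated fusion decoder.

Starting from the deepest fusion feature ff_4, the decoder walks up the
pyramid.  Each gate receives the skip feature ff_i (scale i) and the decoder
state from scale i+1; the state is bilinearly upsampled ×2 and 1×1-projected
to ff_i's width, then::

    T_i    = ReLU( W_f(ff_i) + W_up(up_aligned) )
    gate_i = Sigmoid( BN(1×1 conv(T_i)) )          in (0, 1)
    up_i   = up_aligned ⊙ gate_i                   (broadcast over channels)

so the skip decides, per location, how much of the upsampled context to keep.
After the last gate (scale 1/4) a three-conv head produces class logits that
a bilinear ×4 restores to input resolution.  The gate is single-channel and
broadcast across channels by default (the classic additive attention gate);
per-channel gating is available via ``per_channel_gate``.
"""

from __future__ import annotations

from . import nn
from .nn import Tensor
from .unet_encoder import ContractViolation


class AttentionGate(nn.Module):
    """Gate the upsampled decoder state with a skip feature one scale finer."""

    def __init__(self, skip_ch: int, up_ch: int,
                 per_channel_gate: bool = False):
        super().__init__()
        self.align = nn.Conv2d(up_ch, skip_ch, 1)
        self.w_f = nn.Conv2d(skip_ch, skip_ch, 1)
        self.w_up = nn.Conv2d(skip_ch, skip_ch, 1)
        gate_ch = skip_ch if per_channel_gate else 1
        self.sigma = nn.Conv2d(skip_ch, gate_ch, 1)
        self.sigma_bn = nn.BatchNorm2d(gate_ch)

    def forward(self, ff: Tensor, up_next: Tensor) -> Tensor:
        if up_next.shape[2] * 2 != ff.shape[2] or \
                up_next.shape[3] * 2 != ff.shape[3]:
            raise ContractViolation(
                f"decoder state {up_next.shape[2:]} must be exactly half of "
                f"the skip {ff.shape[2:]}")
        up = self.align(nn.interpolate_bilinear(up_next, 2))
        t = (self.w_f(ff) + self.w_up(up)).relu()
        gate = self.sigma_bn(self.sigma(t)).sigmoid()
        return up * gate


class GatedDecoder(nn.Module):
    """Three attention gates over ff_3..ff_1 plus a conv head and ×4 resize."""

    def __init__(self, embed_dim: int = 96, num_classes: int = 2,
                 per_channel_gate: bool = False):
        super().__init__()
        dims = [embed_dim * 2 ** i for i in range(4)]
        self.gates = nn.ModuleList([
            AttentionGate(dims[2], dims[3], per_channel_gate),
            AttentionGate(dims[1], dims[2], per_channel_gate),
            AttentionGate(dims[0], dims[1], per_channel_gate),
        ])
        half = embed_dim // 2
        self.head1 = nn.Conv2d(dims[0], half, 3, padding=1)
        self.bn1 = nn.BatchNorm2d(half)
        self.head2 = nn.Conv2d(half, half, 3, padding=1)
        self.bn2 = nn.BatchNorm2d(half)
        self.head3 = nn.Conv2d(half, num_classes, 3, padding=1)

    def forward(self, ff: list[Tensor]) -> Tensor:
        if len(ff) != 4:
            raise ContractViolation("decoder expects four fusion features")
        up = ff[3]
        for gate, skip in zip(self.gates, reversed(ff[:3])):
            up = gate(skip, up)
        x = self.bn1(self.head1(up)).relu()
        x = self.bn2(self.head2(x)).relu()
        x = self.head3(x)
        return nn.interpolate_bilinear(x, 4)
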