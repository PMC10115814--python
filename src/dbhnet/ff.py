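"""Feature fusion (FF) between the two encoder branches.

One FF module per pyramid scale.  At scale i the two branch features st_i and
u_i (same shape) — and, from scale 2 on, the previous fusion output ff_{i-1}
— are each refined by a 3×3 conv; the refined maps are combined by an
elementwise (Hadamard) product into an interaction map b_i, concatenated with
the raw branch features, and merged by a small residual block back to st_i's
channel width::

    b_i  = ω(st_i) ⊙ ω(u_i) [⊙ ω_ff(φ(ff_{i-1}))]
    ff_i = Residual(concat[st_i, u_i, b_i])

The refinement conv ω is shared between the two branch inputs; ff_{i-1} needs
its own conv since it carries half the channels and is first brought to scale
i by a 3×3/stride-2 max-pool φ.  Threading ff_{i-1} through successive scales
is what lets correlated evidence propagate across resolutions.
"""

from __future__ import annotations

from . import nn
from .nn import Tensor
from .unet_encoder import ContractViolation


class _ResidualMerge(nn.Module):
    """1×1 projection (3c→c) then 3×3 conv(s) with an identity shortcut.

    ``depth`` counts conv layers including the projection (default 2).
    """

    def __init__(self, in_ch: int, out_ch: int, depth: int = 2):
        super().__init__()
        if depth < 2:
            raise ValueError("residual merge needs depth >= 2")
        self.proj = nn.Conv2d(in_ch, out_ch, 1)
        self.proj_bn = nn.BatchNorm2d(out_ch)
        self.convs = nn.ModuleList(
            [nn.Conv2d(out_ch, out_ch, 3, padding=1)
             for _ in range(depth - 1)])
        self.bns = nn.ModuleList(
            [nn.BatchNorm2d(out_ch) for _ in range(depth - 1)])

    def forward(self, x: Tensor) -> Tensor:
        y = self.proj_bn(self.proj(x)).relu()
        h = y
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            h = bn(conv(h))
            if i < len(self.convs) - 1:
                h = h.relu()
        return (h + y).relu()


class FFModule(nn.Module):
    """Fuse one scale of the two pyramids (optionally with ff_{i-1})."""

    def __init__(self, channels: int, prev_channels: int | None = None,
                 residual_depth: int = 2):
        super().__init__()
        self.channels = channels
        self.omega = nn.Conv2d(channels, channels, 3, padding=1)
        if prev_channels is not None:
            # channel alignment for the pooled previous fusion output
            self.omega_ff = nn.Conv2d(prev_channels, channels, 1)
        else:
            self.omega_ff = None
        self.residual = _ResidualMerge(3 * channels, channels,
                                       residual_depth)

    def interaction(self, st: Tensor, u: Tensor,
                    ff_prev: Tensor | None = None) -> Tensor:
        """The Hadamard interaction map b_i of the refined inputs."""
        if st.shape != u.shape:
            raise ContractViolation(
                f"branch features disagree: {st.shape} vs {u.shape}")
        if (ff_prev is None) != (self.omega_ff is None):
            raise ContractViolation(
                "ff_prev must be supplied exactly when the module was built "
                "with prev_channels")
        b = self.omega(st) * self.omega(u)
        if ff_prev is not None:
            if ff_prev.shape[2] != 2 * st.shape[2] or \
                    ff_prev.shape[3] != 2 * st.shape[3]:
                raise ContractViolation(
                    f"ff_prev spatial size {ff_prev.shape[2:]} is not twice "
                    f"{st.shape[2:]}")
            pooled = nn.max_pool2d(ff_prev, 3, stride=2, padding=1)
            b = b * self.omega_ff(pooled)
        return b

    def forward(self, st: Tensor, u: Tensor,
                ff_prev: Tensor | None = None) -> Tensor:
        b = self.interaction(st, u, ff_prev)
        return self.residual(nn.cat([st, u, b], axis=1))


class FeatureFusion(nn.Module):
    """The four per-scale FF modules, threading ff_{i-1} into module i."""

    def __init__(self, embed_dim: int = 96, residual_depth: int = 2):
        super().__init__()
        dims = [embed_dim * 2 ** i for i in range(4)]
        self.blocks = nn.ModuleList(
            [FFModule(dims[0], residual_depth=residual_depth)] +
            [FFModule(dims[i], dims[i - 1], residual_depth)
             for i in range(1, 4)])

    def forward(self, st_pyr: list[Tensor],
                u_pyr: list[Tensor]) -> list[Tensor]:
        outs: list[Tensor] = []
        prev = None
        for i, block in enumerate(self.blocks):
            prev = block(st_pyr[i], u_pyr[i], prev)
            outs.append(prev)
        return outs
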