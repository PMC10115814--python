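"""Model registry: the six ablation variants and parameter accounting.

Variants mirror the ablation study:

======== ==============================================================
name      composition
======== ==============================================================
unet      convolutional encoder + classic symmetric decoder
st        attention encoder + minimal interpolation/conv head
unet_dfa  convolutional encoder + deep-feature-aggregation decoder
st_dfa    attention encoder + deep-feature-aggregation decoder
fusion_ff both encoders + feature fusion + attention-gated decoder
ours      fusion_ff plus the two per-branch DFA heads (three outputs)
======== ==============================================================

``ours`` returns the triple (M_ff, M_st, M_u) used by the weighted
three-head loss; every other variant returns a single logit map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .dfa import DFADecoder
from .ff import FeatureFusion
from .gated_decoder import GatedDecoder
from .nn import Tensor
from .swin_encoder import SwinConfig, SwinEncoder
from .unet_encoder import UNet, UNetEncoder

VARIANTS = ("unet", "st", "unet_dfa", "st_dfa", "fusion_ff", "ours")


@dataclass(frozen=True)
class ModelVariant:
    name: str
    unet_encoder: bool
    swin_encoder: bool
    unet_dfa: bool
    swin_dfa: bool
    fusion: bool
    n_outputs: int


VARIANT_FLAGS = {
    "unet": ModelVariant("unet", True, False, False, False, False, 1),
    "st": ModelVariant("st", False, True, False, False, False, 1),
    "unet_dfa": ModelVariant("unet_dfa", True, False, True, False, False, 1),
    "st_dfa": ModelVariant("st_dfa", False, True, False, True, False, 1),
    "fusion_ff": ModelVariant("fusion_ff", True, True, False, False, True, 1),
    "ours": ModelVariant("ours", True, True, True, True, True, 3),
}


class SwinSegBaseline(nn.Module):
    """Attention encoder with a minimal upsampling head (the 'st' baseline).

    The head is deliberately small: the deepest feature is reduced to C
    channels, upsampled, refined once and mapped to logits — the row's
    parameter count is encoder-dominated.
    """

    def __init__(self, config: SwinConfig | None = None, num_classes: int = 2):
        super().__init__()
        self.encoder = SwinEncoder(config)
        c = self.encoder.embed_dim
        self.reduce = nn.Conv2d(8 * c, c, 3, padding=1)
        self.reduce_bn = nn.BatchNorm2d(c)
        self.refine = nn.Conv2d(c, c // 2, 3, padding=1)
        self.refine_bn = nn.BatchNorm2d(c // 2)
        self.head = nn.Conv2d(c // 2, num_classes, 3, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        deep = self.encoder(x)[3]
        y = self.reduce_bn(self.reduce(deep)).relu()
        y = nn.interpolate_bilinear(y, 8)
        y = self.refine_bn(self.refine(y)).relu()
        y = self.head(y)
        return nn.interpolate_bilinear(y, 4)


class BranchDFA(nn.Module):
    """One encoder (either branch) driving a DFA decoder."""

    def __init__(self, encoder: nn.Module, num_classes: int = 2):
        super().__init__()
        self.encoder = encoder
        self.decoder = DFADecoder(encoder.embed_dim, num_classes=num_classes)

    def forward(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x))


class DBHNet(nn.Module):
    """The dual-branch hybrid network.

    Both encoders consume the same image; their pyramids are fused per scale
    and decoded by the attention-gated decoder.  When built ``with_dfa`` the
    two per-branch DFA heads are attached and the forward pass returns the
    triple (M_ff, M_st, M_u) for deep supervision.
    """

    def __init__(self, swin_config: SwinConfig | None = None,
                 num_classes: int = 2, with_dfa: bool = True,
                 per_channel_gate: bool = False):
        super().__init__()
        self.swin = SwinEncoder(swin_config)
        c = self.swin.embed_dim
        self.unet = UNetEncoder(c)
        self.fusion = FeatureFusion(c)
        self.decoder = GatedDecoder(c, num_classes, per_channel_gate)
        self.with_dfa = with_dfa
        if with_dfa:
            self.dfa_st = DFADecoder(c, num_classes=num_classes)
            self.dfa_u = DFADecoder(c, num_classes=num_classes)

    def forward(self, x: Tensor):
        st_pyr = self.swin(x)
        u_pyr = self.unet(x)
        ff = self.fusion(st_pyr, u_pyr)
        m_ff = self.decoder(ff)
        if not self.with_dfa:
            return m_ff
        return m_ff, self.dfa_st(st_pyr), self.dfa_u(u_pyr)


def build_model(variant: str, embed_dim: int = 96,
                swin_config: SwinConfig | None = None, num_classes: int = 2,
                per_channel_gate: bool = False, seed: int | None = None
                ) -> nn.Module:
    """Build one of the six named variants (seeds initialization if asked)."""
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; valid names: {', '.join(VARIANTS)}")
    if seed is not None:
        nn.manual_seed(seed)
    if swin_config is None:
        swin_config = SwinConfig(embed_dim=embed_dim)
    embed_dim = swin_config.embed_dim
    if variant == "unet":
        return UNet(embed_dim, num_classes)
    if variant == "st":
        return SwinSegBaseline(swin_config, num_classes)
    if variant == "unet_dfa":
        return BranchDFA(UNetEncoder(embed_dim), num_classes)
    if variant == "st_dfa":
        return BranchDFA(SwinEncoder(swin_config), num_classes)
    with_dfa = variant == "ours"
    return DBHNet(swin_config, num_classes, with_dfa, per_channel_gate)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable parameters."""
    return sum(p.size for p in model.parameters())


def millions(n: int) -> float:
    return round(n / 1e6, 2)


# ------------------------------------------------------------- checkpoints
_SWIN_RENAMES = [("layers.", "stages."), (".blocks.", "."),
                 (".downsample.", "@down@")]


def _map_swin_key(key: str) -> str | None:
    """Published tiny-checkpoint name -> this encoder's parameter name."""
    if key.startswith(("head.", "norm_head.")) or "attn_mask" in key:
        return None
    for old, new in _SWIN_RENAMES:
        key = key.replace(old, new)
    if "@down@" in key:
        stage, rest = key.split("@down@")
        key = f"downsamples.{stage.split('.')[1]}.{rest}"
    return key


def load_pretrained_swin(encoder: SwinEncoder,
                         state: dict[str, np.ndarray]) -> dict:
    """Map published ``swin_tiny_patch4_window7_224`` weights onto the encoder.

    ``state`` is a mapping of checkpoint names to arrays (e.g. ``np.load`` of
    an ``.npz`` converted once from the released file).  The 4×4 patch-embed
    convolution kernel is reshaped onto the linear embedding.  Returns the
    load report (missing / unexpected / mismatched key lists).
    """
    mapped: dict[str, np.ndarray] = {}
    for key, value in state.items():
        new = _map_swin_key(key)
        if new is None:
            continue
        value = np.asarray(value)
        if new == "patch_embed.proj.weight" and value.ndim == 4:
            value = value.reshape(value.shape[0], -1)
        mapped[new] = value
    return encoder.load_state_dict(mapped, strict=False)
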