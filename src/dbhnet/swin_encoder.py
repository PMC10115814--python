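"""Self-attention branch: a hierarchical shifted-window transformer encoder.

The image is tokenized into 4×4 patches and linearly embedded to C channels;
four stages of window-attention blocks, separated by patch-merging
downsamples, emit the same four-scale pyramid as the convolutional branch
(1/4 … 1/32 resolution, C … 8C channels).  Within a window of ``w×w`` tokens,
multi-head self-attention is computed densely with a learned relative
position bias; alternate blocks cyclically shift the grid by ``w//2`` and
mask attention across the wrap-around boundary so information propagates
between windows.

Block l and l+1 compute, with LN layer norm and a two-layer GELU MLP::

    z_hat = W-MSA(LN(z)) + z          z' = MLP(LN(z_hat)) + z_hat
    z_hat = SW-MSA(LN(z')) + z'       z'' = MLP(LN(z_hat)) + z_hat

Defaults (embed dim 96, depths [2, 2, 6, 2], heads [3, 6, 12, 24], window 7)
match the published tiny configuration so its ImageNet checkpoint can be
mapped onto this encoder; depths [2, 2, 2, 6] are selectable in config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .unet_encoder import ContractViolation

_NEG_INF = -1e9


@dataclass
class SwinConfig:
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    window: int = 7
    mlp_ratio: float = 4.0
    patch_size: int = 4
    in_ch: int = 3
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.depths) != 4 or len(self.heads) != 4:
            raise ValueError("depths and heads must each list 4 stages")


# --------------------------------------------------------------- token ops
def window_partition(x: Tensor, window: int) -> Tensor:
    """(B, H, W, D) grid -> (B·nW, window², D) blocks, row-major windows."""
    b, h, w, d = x.shape
    if h % window or w % window:
        raise ContractViolation(
            f"grid {h}×{w} is not divisible by window {window}")
    x = x.reshape(b, h // window, window, w // window, window, d)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(-1, window * window, d)


def window_reverse(blocks: Tensor, window: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    d = blocks.shape[-1]
    b = blocks.shape[0] // ((h // window) * (w // window))
    x = blocks.reshape(b, h // window, w // window, window, window, d)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, w, d)


def relative_position_index(window: int) -> np.ndarray:
    """(window², window²) index into the (2w-1)² relative-bias table."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                  indexing="ij"))
    coords = coords.reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]
    rel = rel + (window - 1)
    return rel[0] * (2 * window - 1) + rel[1]


def shift_attention_mask(h: int, w: int, window: int,
                         shift: int) -> np.ndarray:
    """Additive mask (nW, window², window²) forbidding cross-group pairs
    after a cyclic shift, following the standard region partition."""
    img = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift),
                   slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    ids = window_partition(Tensor(img[None, :, :, None]), window).data
    ids = ids.reshape(-1, window * window)
    mask = (ids[:, None, :] != ids[:, :, None]) * _NEG_INF
    return mask


# ----------------------------------------------------------------- modules
class PatchEmbed(nn.Module):
    """Non-overlapping patch flattening + linear embedding + layer norm."""

    def __init__(self, patch_size: int = 4, in_ch: int = 3,
                 embed_dim: int = 96):
        super().__init__()
        self.patch_size = patch_size
        self.proj = nn.Linear(in_ch * patch_size * patch_size, embed_dim)
        self.norm = nn.LayerNorm(embed_dim)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        p = self.patch_size
        if h % p or w % p:
            raise ContractViolation(
                f"image {h}×{w} not divisible by patch size {p}")
        # (B,C,H,W) -> (B, H/p, W/p, C·p·p) with channel-major patch layout,
        # matching a p×p stride-p convolution's weight flattening
        x = x.reshape(b, c, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5).reshape(b, h // p, w // p,
                                                  c * p * p)
        return self.norm(self.proj(x))


class WindowAttention(nn.Module):
    """Multi-head self-attention within windows, with relative position bias."""

    def __init__(self, dim: int, heads: int, window: int):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.window = dim, heads, window
        self.scale = (dim // heads) ** -0.5
        self.qkv = nn.Linear(dim, dim * 3)
        self.proj = nn.Linear(dim, dim)
        n = 2 * window - 1
        self.relative_position_bias_table = nn.Parameter(
            np.clip(nn.get_rng().normal(0, 0.02, (n * n, heads)), -0.04, 0.04)
            .astype(np.float32))
        self.register_buffer("relative_position_index",
                             relative_position_index(window))

    def forward(self, blocks: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bw, n, d = blocks.shape
        h = self.heads
        hd = d // h
        qkv = self.qkv(blocks).reshape(bw, n, 3, h, hd)
        qkv = qkv.transpose(2, 0, 3, 1, 4)          # (3, bw, h, n, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q * self.scale) @ k.transpose(0, 1, 3, 2)
        idx = self.relative_position_index.reshape(-1)
        bias = self.relative_position_bias_table[idx]
        bias = bias.reshape(n, n, h).transpose(2, 0, 1)
        attn = attn + bias.reshape(1, h, n, n)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(bw // nw, nw, h, n, n) + \
                Tensor(mask[None, :, None].astype(blocks.dtype))
            attn = attn.reshape(bw, h, n, n)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(bw, n, d)
        return self.proj(out)


class Mlp(nn.Module):
    def __init__(self, dim: int, hidden: int):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden)
        self.fc2 = nn.Linear(hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class SwinBlock(nn.Module):
    """One (shifted-)window attention block on a (B, H, W, D) token grid."""

    def __init__(self, dim: int, heads: int, window: int, shift: int,
                 mlp_ratio: float = 4.0):
        super().__init__()
        if shift >= window:
            raise ValueError(f"shift {shift} must be < window {window}")
        self.window, self.shift = window, shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio))
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def _mask(self, h: int, w: int) -> np.ndarray | None:
        if self.shift == 0:
            return None
        key = (h, w)
        if key not in self._mask_cache:
            self._mask_cache[key] = shift_attention_mask(
                h, w, self.window, self.shift)
        return self._mask_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, d = x.shape
        shortcut = x
        x = self.norm1(x)
        if self.shift:
            x = x.roll((-self.shift, -self.shift), (1, 2))
        blocks = window_partition(x, self.window)
        blocks = self.attn(blocks, self._mask(h, w))
        x = window_reverse(blocks, self.window, h, w)
        if self.shift:
            x = x.roll((self.shift, self.shift), (1, 2))
        x = shortcut + x
        return x + self.mlp(self.norm2(x))


class PatchMerging(nn.Module):
    """2×2 token concatenation (4D) + linear reduction to 2D channels."""

    def __init__(self, dim: int):
        super().__init__()
        self.norm = nn.LayerNorm(4 * dim)
        self.reduction = nn.Linear(4 * dim, 2 * dim, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, d = x.shape
        if h % 2 or w % 2:
            raise ContractViolation(
                f"patch merging requires an even grid, got {h}×{w}")
        x0 = x[:, 0::2, 0::2]
        x1 = x[:, 1::2, 0::2]
        x2 = x[:, 0::2, 1::2]
        x3 = x[:, 1::2, 1::2]
        x = nn.cat([x0, x1, x2, x3], axis=-1)
        return self.reduction(self.norm(x))


class SwinEncoder(nn.Module):
    """Four-stage windowed-attention encoder emitting the feature pyramid."""

    def __init__(self, config: SwinConfig | None = None):
        super().__init__()
        cfg = config or SwinConfig()
        self.config = cfg
        self.embed_dim = cfg.embed_dim
        self.patch_embed = PatchEmbed(cfg.patch_size, cfg.in_ch, cfg.embed_dim)
        self.stages = nn.ModuleList()
        self.downsamples = nn.ModuleList()
        for i, depth in enumerate(cfg.depths):
            dim = cfg.embed_dim * 2 ** i
            blocks = nn.ModuleList([
                SwinBlock(dim, cfg.heads[i], cfg.window,
                          0 if j % 2 == 0 else cfg.window // 2,
                          cfg.mlp_ratio)
                for j in range(depth)])
            self.stages.append(blocks)
            if i < 3:
                self.downsamples.append(PatchMerging(dim))
        self.norm = nn.LayerNorm(cfg.embed_dim * 8)

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.shape[1] != 3:
            raise ContractViolation(
                f"expected a 3-channel image, got {x.shape[1]}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ContractViolation(
                "image height and width must be divisible by 32")
        grid = self.patch_embed(x)
        pyramid = []
        for i, blocks in enumerate(self.stages):
            for block in blocks:
                grid = block(grid)
            out = self.norm(grid) if i == 3 else grid
            pyramid.append(out.transpose(0, 3, 1, 2))   # to NCHW
            if i < 3:
                grid = self.downsamples[i](grid)
        return pyramid
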