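"""Attention-branch encoder: dense-attention oracles and token-op indexing."""

import numpy as np
import pytest

from dbhnet import nn
from dbhnet.models import count_parameters
from dbhnet.nn import Tensor
from dbhnet.swin_encoder import (PatchEmbed, PatchMerging, SwinBlock,
                                 SwinConfig, SwinEncoder, WindowAttention,
                                 shift_attention_mask, window_partition,
                                 window_reverse)
from dbhnet.unet_encoder import ContractViolation


def dense_attention(tokens, attn, mask=None):
    """Explicit softmax(QKᵀ/√d + B [+ mask])V evaluation for one window."""
    w = attn.qkv.weight.data
    b = attn.qkv.bias.data
    qkv = tokens @ w.T + b
    n, d = tokens.shape
    h = attn.heads
    hd = d // h
    q, k, v = np.split(qkv, 3, axis=-1)
    out = np.zeros((n, d))
    idx = attn.relative_position_index.reshape(-1)
    bias = attn.relative_position_bias_table.data[idx].reshape(n, n, h)
    for head in range(h):
        qs = q[:, head * hd:(head + 1) * hd] / np.sqrt(hd)
        ks = k[:, head * hd:(head + 1) * hd]
        vs = v[:, head * hd:(head + 1) * hd]
        logits = qs @ ks.T + bias[:, :, head]
        if mask is not None:
            logits = logits + mask
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        out[:, head * hd:(head + 1) * hd] = (
            e / e.sum(axis=-1, keepdims=True)) @ vs
    return out @ attn.proj.weight.data.T + attn.proj.bias.data


# ------------------------------------------------------------- tokenization
def test_patch_embedding_grid_and_dim(rng):
    pe = PatchEmbed(4, 3, 96)
    out = pe(Tensor(rng.normal(size=(1, 3, 224, 224)).astype(np.float32)))
    assert out.shape == (1, 56, 56, 96)


def test_patch_embedding_constant_image_gives_identical_tokens(rng):
    pe = PatchEmbed(4, 3, 8)
    out = pe(Tensor(np.full((1, 3, 16, 16), 0.7, np.float32))).data
    assert np.abs(out - out[0, 0, 0]).max() < 1e-6


def test_patch_embedding_matches_hand_flattening(rng):
    """With an identity-like projection, tokens equal raw flattened patches."""
    pe = PatchEmbed(2, 1, 4)
    pe.proj.weight.data = np.eye(4, dtype=np.float32)
    pe.proj.bias.data = np.zeros(4, np.float32)
    x = rng.normal(size=(1, 1, 8, 8))
    raw = pe.proj(Tensor(
        x.reshape(1, 1, 4, 2, 4, 2).transpose(0, 2, 4, 1, 3, 5)
        .reshape(1, 4, 4, 4))).data
    got = pe(Tensor(x)).data
    # undo the layer norm by normalizing the oracle identically
    mu = raw.mean(-1, keepdims=True)
    sd = np.sqrt(((raw - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
    np.testing.assert_allclose(got, (raw - mu) / sd, atol=1e-5)


def test_window_partition_counts_and_roundtrip(rng):
    tokens = Tensor(rng.normal(size=(1, 56, 56, 3)))
    blocks = window_partition(tokens, 7)
    assert blocks.shape == (64, 49, 3)
    back = window_reverse(blocks, 7, 56, 56)
    assert (back.data == tokens.data).all()
    with pytest.raises(ContractViolation):
        window_partition(Tensor(rng.normal(size=(1, 6, 6, 3))), 4)


def test_window_partition_matches_index_enumeration():
    grid = np.arange(16).reshape(1, 4, 4, 1).astype(float)
    blocks = window_partition(Tensor(grid), 2).data[..., 0]
    expect = np.array([[0, 1, 4, 5], [2, 3, 6, 7],
                       [8, 9, 12, 13], [10, 11, 14, 15]])
    np.testing.assert_array_equal(blocks, expect)


# ---------------------------------------------------------------- attention
def test_wmsa_matches_dense_attention_oracle(rng):
    attn = WindowAttention(8, 1, 7)
    tokens = rng.normal(size=(49, 8)).astype(np.float32)
    got = attn(Tensor(tokens[None])).data[0]
    np.testing.assert_allclose(got, dense_attention(tokens, attn), atol=1e-5)


def test_wmsa_multihead_matches_oracle(rng):
    attn = WindowAttention(12, 3, 4)
    tokens = rng.normal(size=(16, 12)).astype(np.float32)
    got = attn(Tensor(tokens[None])).data[0]
    np.testing.assert_allclose(got, dense_attention(tokens, attn), atol=1e-5)


def test_single_token_window_reduces_to_value_projection(rng):
    attn = WindowAttention(6, 2, 1)
    t = rng.normal(size=(1, 1, 6)).astype(np.float32)
    got = attn(Tensor(t)).data
    w = attn.qkv.weight.data
    v = t[0] @ w[12:].T + attn.qkv.bias.data[12:]
    expect = v @ attn.proj.weight.data.T + attn.proj.bias.data
    np.testing.assert_allclose(got[0], expect, atol=1e-5)


def test_identical_tokens_give_identical_outputs(rng):
    attn = WindowAttention(8, 2, 2)
    t = np.tile(rng.normal(size=(1, 1, 8)), (1, 4, 1)).astype(np.float32)
    out = attn(Tensor(t)).data[0]
    assert np.abs(out - out[0]).max() < 1e-6


def test_shift_zero_equals_plain_window_attention(rng):
    blk = SwinBlock(8, 2, 2, shift=0)
    x = Tensor(rng.normal(size=(1, 4, 4, 8)).astype(np.float32))
    a = blk(x).data
    b = blk(x).data
    assert (a == b).all()


def test_shifted_attention_matches_groupwise_dense_oracle(rng):
    """Shifted windows equal dense attention on each shifted-partition group."""
    blk = SwinBlock(4, 1, 2, shift=1)
    # isolate the attention: make norms exact identities and the MLP zero
    blk.norm1.weight.data = np.ones(4); blk.norm1.bias.data = np.zeros(4)
    blk.mlp.fc2.weight.data = np.zeros_like(blk.mlp.fc2.weight.data)
    blk.mlp.fc2.bias.data = np.zeros_like(blk.mlp.fc2.bias.data)
    x = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
    out = blk(Tensor(x)).data[0]

    mu = x.mean(-1, keepdims=True)
    sd = np.sqrt(((x - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
    xn = ((x - mu) / sd)[0]
    shifted = np.roll(xn, (-1, -1), (0, 1))
    mask = shift_attention_mask(4, 4, 2, 1)
    attended = np.zeros_like(shifted)
    blocks = window_partition(Tensor(shifted[None]), 2).data
    for wi in range(blocks.shape[0]):
        attended_w = dense_attention(blocks[wi], blk.attn, mask[wi])
        attended[(wi // 2) * 2:(wi // 2) * 2 + 2,
                 (wi % 2) * 2:(wi % 2) * 2 + 2] = \
            attended_w.reshape(2, 2, 4)
    expect = x[0] + np.roll(attended, (1, 1), (0, 1))
    np.testing.assert_allclose(out, expect, atol=1e-5)


def test_shifted_attention_does_not_mix_mask_groups(rng):
    """Zeroing one shifted-partition group leaves other groups unchanged."""
    attn = WindowAttention(4, 1, 2)
    attn.qkv.bias.data = np.zeros_like(attn.qkv.bias.data)
    attn.proj.bias.data = np.zeros_like(attn.proj.bias.data)
    mask = shift_attention_mask(4, 4, 2, 1)
    grid = np.roll(rng.normal(size=(1, 4, 4, 4)).astype(np.float32),
                   (-1, -1), (1, 2))
    blocks = window_partition(Tensor(grid), 2)
    base = attn(blocks, mask).data

    img = np.zeros((4, 4))
    cnt = 0
    for hs in (slice(0, -2), slice(-2, -1), slice(-1, None)):
        for ws in (slice(0, -2), slice(-2, -1), slice(-1, None)):
            img[hs, ws] = cnt
            cnt += 1
    groups = window_partition(Tensor(img[None, :, :, None]), 2).data[..., 0]
    target_group = groups[3][0]      # one group in the wrapped corner window
    zeroed = blocks.data.copy()
    zeroed[3][groups[3] == target_group] = 0.0
    out = attn(Tensor(zeroed), mask).data
    keep = groups[3] != target_group
    np.testing.assert_allclose(out[3][keep], base[3][keep], atol=1e-6)


def test_block_with_zeroed_output_projections_is_identity(rng):
    blk = SwinBlock(8, 2, 2, shift=0)
    blk.attn.proj.weight.data = np.zeros_like(blk.attn.proj.weight.data)
    blk.attn.proj.bias.data = np.zeros_like(blk.attn.proj.bias.data)
    blk.mlp.fc2.weight.data = np.zeros_like(blk.mlp.fc2.weight.data)
    blk.mlp.fc2.bias.data = np.zeros_like(blk.mlp.fc2.bias.data)
    x = rng.normal(size=(1, 4, 4, 8)).astype(np.float32)
    np.testing.assert_allclose(blk(Tensor(x)).data, x, atol=1e-7)


# ------------------------------------------------------------- downsampling
def test_patch_merging_shapes(rng):
    pm = PatchMerging(96)
    out = pm(Tensor(rng.normal(size=(1, 56, 56, 96)).astype(np.float32)))
    assert out.shape == (1, 28, 28, 192)
    out = PatchMerging(4)(Tensor(rng.normal(size=(1, 2, 2, 4))
                                 .astype(np.float32)))
    assert out.shape == (1, 1, 1, 8)


def test_patch_merging_concatenation_order(rng):
    """2×2 neighborhoods concatenate as (top-left, bottom-left, top-right,
    bottom-right) before the linear reduction."""
    pm = PatchMerging(1)
    grid = np.arange(16).reshape(1, 4, 4, 1).astype(np.float32)
    pre = nn.cat([Tensor(grid[:, 0::2, 0::2]), Tensor(grid[:, 1::2, 0::2]),
                  Tensor(grid[:, 0::2, 1::2]), Tensor(grid[:, 1::2, 1::2])],
                 axis=-1).data
    expect = pm.reduction(pm.norm(Tensor(pre))).data
    np.testing.assert_allclose(pm(Tensor(grid)).data, expect, atol=1e-7)
    np.testing.assert_array_equal(pre[0, 0, 0, :], [0, 4, 1, 5])


# ------------------------------------------------------------ whole encoder
def test_encoder_pyramid_contract_at_desk_scale(tiny_swin_config, rng):
    enc = SwinEncoder(tiny_swin_config).eval()
    x = Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32))
    levels = enc(x)
    for i, lv in enumerate(levels):
        assert lv.shape == (1, 16 * 2 ** i, 64 // 2 ** (i + 2),
                            64 // 2 ** (i + 2))
    again = enc(x)
    for a, b in zip(levels, again):
        assert (a.data == b.data).all()


def swin_parameter_closed_form(c, depths, heads, window, mlp_ratio=4,
                               patch=4, in_ch=3):
    """Layer-by-layer arithmetic for the encoder parameter count."""
    total = (in_ch * patch * patch) * c + c + 2 * c     # embed + its norm
    for i, depth in enumerate(depths):
        d = c * 2 ** i
        per_block = (
            2 * (2 * d)                                  # two layer norms
            + d * 3 * d + 3 * d                          # qkv
            + d * d + d                                  # proj
            + (2 * window - 1) ** 2 * heads[i]           # relative bias
            + d * (mlp_ratio * d) + mlp_ratio * d        # mlp fc1
            + (mlp_ratio * d) * d + d                    # mlp fc2
        )
        total += depth * per_block
        if i < 3:
            total += 2 * (4 * d) + (4 * d) * (2 * d)     # merging norm+reduce
    total += 2 * (c * 8)                                 # final norm
    return total


def test_parameter_count_matches_closed_form(tiny_swin_config):
    cfg = tiny_swin_config
    assert count_parameters(SwinEncoder(cfg)) == swin_parameter_closed_form(
        cfg.embed_dim, cfg.depths, cfg.heads, cfg.window)


def test_tiny_backbone_parameter_count_near_published_28m():
    n = swin_parameter_closed_form(96, (2, 2, 6, 2), (3, 6, 12, 24), 7)
    assert count_parameters(SwinEncoder(SwinConfig())) == n
    assert 27e6 < n < 29e6
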