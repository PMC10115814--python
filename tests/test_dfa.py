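"""Deep-feature-aggregation decoder: shapes, toy-map oracles, receptive field."""

import numpy as np
import pytest

from dbhnet.dfa import RFB48, DFADecoder, DFAHead, aggregation_decode
from dbhnet.models import count_parameters
from dbhnet.nn import Tensor
from dbhnet.unet_encoder import ContractViolation

from conftest import set_bn_identity


def test_rfb_reduces_to_48_channels(rng):
    rfb = RFB48(768).eval()
    out = rfb(Tensor(rng.normal(size=(1, 768, 7, 7)).astype(np.float32)))
    assert out.shape == (1, 48, 7, 7)


@pytest.mark.parametrize("size", [(5, 9), (14, 14)])
def test_rfb_preserves_spatial_size(size, rng):
    rfb = RFB48(16, 8).eval()
    out = rfb(Tensor(rng.normal(size=(1, 16, *size)).astype(np.float32)))
    assert out.shape == (1, 8, *size)


def test_rfb_rate7_branch_receptive_field_spans_15_pixels():
    """A unit impulse through the dilation-7 branch spreads ≥15 px per axis."""
    rfb = set_bn_identity(RFB48(1, 8))
    branch = rfb.branches[-1]
    for layer in branch:
        layer.conv.weight.data = np.abs(layer.conv.weight.data) + 0.1
        layer.conv.bias.data = np.zeros_like(layer.conv.bias.data)
    x = np.zeros((1, 1, 33, 33), np.float32)
    x[0, 0, 16, 16] = 1.0
    out = branch(Tensor(x)).data[0].sum(axis=0)
    rows = np.nonzero(out.sum(axis=1))[0]
    cols = np.nonzero(out.sum(axis=0))[0]
    assert rows.max() - rows.min() + 1 >= 15
    assert cols.max() - cols.min() + 1 >= 15


def test_aggregation_shapes():
    f1 = Tensor(np.ones((1, 48, 28, 28)))
    f2 = Tensor(np.ones((1, 48, 14, 14)))
    f3 = Tensor(np.ones((1, 48, 7, 7)))
    assert aggregation_decode(f1, f2, f3).shape == (1, 144, 28, 28)
    with pytest.raises(ContractViolation):
        aggregation_decode(f1, Tensor(np.ones((1, 24, 14, 14))), f3)


def test_aggregation_ones_f3_passes_f2_through_product(rng):
    """All-ones F3' is the multiplicative identity of the product term."""
    f1 = Tensor(rng.normal(size=(1, 2, 8, 8)))
    f2 = Tensor(rng.normal(size=(1, 2, 4, 4)))
    f3 = Tensor(np.ones((1, 2, 2, 2)))
    ad2 = aggregation_decode(f1, f2, f3).data
    from dbhnet.nn import interpolate_bilinear
    up2_f2 = interpolate_bilinear(f2, 2).data
    # channels 2:4 hold Up2(Up2(F3')·F2') = Up2(F2')
    np.testing.assert_allclose(ad2[:, 2:4], up2_f2, atol=1e-6)


def test_aggregation_matches_pencil_and_paper_on_toy_maps():
    """Integer 1/2/4-pixel maps: products and concat computed by hand."""
    f1 = np.arange(1, 33, dtype=float).reshape(1, 2, 4, 4)
    f2 = np.array([[[[2.0, 3.0], [4.0, 5.0]], [[1.0, 1.0], [2.0, 2.0]]]])
    f3 = np.array([[[[3.0]], [[2.0]]]])
    ad2 = aggregation_decode(Tensor(f1), Tensor(f2), Tensor(f3)).data
    # Up2 of a 1×1 map is constant.  For a 2→4 bilinear resize with
    # half-pixel centers the source positions are -0.25, 0.25, 0.75, 1.25
    # (clamped), giving the hand-derived weight matrix below.
    a = np.array([[1.0, 0.0], [0.75, 0.25], [0.25, 0.75], [0.0, 1.0]])

    def up2(m):          # (1,2,2,2) -> (1,2,4,4)
        return np.einsum("oi,ncij,pj->ncop", a, m, a)

    prod = f2 * np.array([3.0, 2.0]).reshape(1, 2, 1, 1)     # Up2(F3')·F2'
    up_prod = up2(prod)
    up4_f3 = np.broadcast_to(np.array([3.0, 2.0]).reshape(1, 2, 1, 1),
                             (1, 2, 4, 4))
    expect = np.concatenate([up2(f2) * f1, up_prod, up4_f3], axis=1)
    np.testing.assert_allclose(ad2, expect, atol=1e-6)


def test_head_upsamples_eightfold(rng):
    head = DFAHead(6, 4, 2).eval()
    out = head(Tensor(rng.normal(size=(1, 6, 28, 28)).astype(np.float32)))
    assert out.shape == (1, 2, 224, 224)


def test_full_decoder_shape_and_size_independent_count(rng):
    dec = DFADecoder(8).eval()
    n_params = count_parameters(dec)
    for size in (32, 64):
        pyr = [Tensor(rng.normal(size=(1, 8 * 2 ** i, size // 2 ** (i + 2),
                                       size // 2 ** (i + 2)))
                      .astype(np.float32)) for i in range(4)]
        out = dec(pyr)
        assert out.shape == (1, 2, size, size)
    assert count_parameters(dec) == n_params


def test_decoder_parameter_count_matches_closed_form():
    def conv_bn(cin, cout, k):
        return k * k * cin * cout + cout + 2 * cout

    def rfb(cin, out=48):
        inter = max(cin // 8, 8)
        total = conv_bn(cin, inter, 1)                    # rate-1 branch
        for _ in (3, 5, 7):
            total += conv_bn(cin, inter, 1) + 2 * conv_bn(inter, inter, 3)
        total += conv_bn(4 * inter, out, 1)               # merge
        total += cin * out + out + 2 * out                # shortcut conv+BN
        return total

    expect = rfb(16) + rfb(32) + rfb(64)
    expect += conv_bn(144, 48, 3)                         # head conv1
    expect += 9 * 48 * 2 + 2                              # head logits conv
    assert count_parameters(DFADecoder(8)) == expect
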