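"""Adaptive deformable convolution: unit oracles and reduction properties."""

import numpy as np
import pytest
from scipy import ndimage

from polypvit import autodiff as ad
from polypvit.adcn import (AdaptiveKernel, AttentionMap, DeformableBackbone,
                           FeatureMap, OffsetField, adcn_forward,
                           attention_batched, average_kernel,
                           compute_attention_map, compute_offsets,
                           deformable_conv, deformable_conv_batched,
                           literal_kernel_update, modulate_kernel,
                           offsets_batched, pool_attention)


# ---------------------------------------------------------------------------
# attention map

def test_attention_constant_features_uniform():
    feats = np.full((4, 5, 3), 2.7)
    phi = compute_attention_map(feats)
    assert np.allclose(phi.values, 1.0 / 20)


def test_attention_normalization(rng):
    phi = compute_attention_map(rng.normal(size=(6, 7, 4)))
    assert abs(phi.values.sum() - 1.0) <= 1e-9
    assert (phi.values >= 0).all()


def test_attention_delta():
    feats = np.zeros((3, 3, 2))
    feats[1, 2, 0] = -5.0  # absolute value used
    phi = compute_attention_map(feats)
    expected = np.zeros((3, 3))
    expected[1, 2] = 1.0
    assert np.allclose(phi.values, expected)


def test_attention_all_zero_fallback():
    phi = compute_attention_map(np.zeros((2, 2, 1)))
    assert np.allclose(phi.values, 0.25)


def test_attention_batched_matches_single(rng):
    x = rng.normal(size=(2, 3, 4, 4))  # NCHW
    batched = attention_batched(x)
    for n in range(2):
        single = compute_attention_map(x[n].transpose(1, 2, 0))
        assert np.allclose(batched[n], single.values, atol=1e-9)


# ---------------------------------------------------------------------------
# kernel modulation / averaging

def test_modulate_delta_phi_selects_coefficient(rng):
    base = rng.normal(size=(2, 2))
    phi = np.zeros((2, 2))
    phi[1, 0] = 1.0
    assert modulate_kernel(base, phi) == pytest.approx(base[1, 0])


def test_modulate_all_ones_kernel_gives_one(rng):
    phi = rng.random((3, 3))
    phi /= phi.sum()
    assert modulate_kernel(np.ones((3, 3)), phi) == pytest.approx(1.0)


def test_modulate_frozen_example():
    k = np.array([[1.0, 2.0], [3.0, 4.0]])
    phi = np.array([[0.5, 0.5], [0.0, 0.0]])
    # oracle: direct double loop
    expected = sum(k[m, n] * phi[m, n] for m in range(2) for n in range(2))
    assert expected == pytest.approx(1.5)
    assert modulate_kernel(k, phi) == pytest.approx(expected, abs=1e-9)


def test_modulate_extent_mismatch():
    with pytest.raises(ValueError):
        modulate_kernel(np.ones((3, 3)), np.ones((2, 2)) / 4)


def test_average_zero_kernel():
    assert average_kernel(np.zeros((2, 2)), np.full((2, 2), 0.25)) == 0.0


def test_average_frozen_examples():
    k = np.array([[1.0, 2.0], [3.0, 4.0]])
    phi = np.full((2, 2), 0.25)
    assert average_kernel(k, phi) == pytest.approx(0.625, abs=1e-9)
    phi_delta = np.zeros((2, 2))
    phi_delta[0, 0] = 1.0
    k2 = np.zeros((2, 2))
    k2[0, 0] = 1.0
    assert average_kernel(k2, phi_delta) == pytest.approx(0.25, abs=1e-9)


def test_average_bound_property(rng):
    # |kbar| <= max|k| / (H*W) when phi is normalized
    for _ in range(20):
        k = rng.normal(size=(3, 3))
        phi = rng.random((3, 3))
        phi /= phi.sum()
        assert abs(average_kernel(k, phi)) <= np.abs(k).max() / 9 + 1e-12


def test_modulate_channelwise_kernel(rng):
    base = rng.normal(size=(2, 3, 3, 3))  # (out, in, M, N)
    phi = rng.random((3, 3))
    phi /= phi.sum()
    out = modulate_kernel(base, phi)
    assert out.shape == (2, 3)
    assert out[1, 2] == pytest.approx((base[1, 2] * phi).sum())


# ---------------------------------------------------------------------------
# offsets

def test_offsets_delta_on_matching_row():
    phi = np.zeros((3, 3))
    phi[1, 2] = 1.0
    off = compute_offsets(phi, (3, 3))
    assert off.u[1] == 0.0


def test_offsets_uniform_3x3_row0():
    phi = np.full((3, 3), 1.0 / 9)
    off = compute_offsets(phi, (3, 3))
    assert off.u[0] == pytest.approx(0.5, abs=1e-12)


def test_offsets_symmetric_center_zero():
    phi = np.array([[0.1, 0.2, 0.1], [0.05, 0.1, 0.05], [0.1, 0.2, 0.1]])
    phi /= phi.sum()
    off = compute_offsets(phi, (3, 3))
    assert off.u[1] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("m,n", [(3, 3), (5, 5), (3, 5)])
def test_offsets_uniform_closed_form(m, n):
    phi = np.full((m, n), 1.0 / (m * n))
    off = compute_offsets(phi, (m, n))
    mean_m = np.arange(m).mean()
    mean_n = np.arange(n).mean()
    # exact up to float64 summation order
    for i in range(m):
        assert off.u[i] == pytest.approx(0.5 * (mean_m - i), abs=1e-12)
    for j in range(n):
        assert off.v[j] == pytest.approx(0.5 * (mean_n - j), abs=1e-12)


def test_offsets_batched_matches_single(rng):
    phi = rng.random((2, 3, 3))
    phi /= phi.sum(axis=(1, 2), keepdims=True)
    u, v = offsets_batched(phi)
    for b in range(2):
        off = compute_offsets(phi[b], (3, 3))
        assert np.allclose(u[b], off.u, atol=1e-12)
        assert np.allclose(v[b], off.v, atol=1e-12)


# ---------------------------------------------------------------------------
# deformable convolution (reference op)

def _zero_offsets(k=3):
    return OffsetField(u=np.zeros(k), v=np.zeros(k))


def test_deformable_identity_kernel(rng):
    img = rng.random((8, 8))
    k = np.zeros((3, 3))
    k[1, 1] = 1.0
    out = deformable_conv(img, k, _zero_offsets(), mode="base_grid")
    assert np.allclose(out, img, atol=1e-12)


def test_deformable_1x1_integer_shift(rng):
    img = rng.random((6, 6))
    out = deformable_conv(img, np.ones((1, 1)),
                          OffsetField(u=[1.0], v=[0.0]))
    assert np.allclose(out[:-1, :], img[1:, :], atol=1e-12)


def test_deformable_1x1_bilinear_midpoint():
    img = np.array([[0.0, 1.0], [0.0, 1.0]])
    out = deformable_conv(img, np.ones((1, 1)), OffsetField(u=[0.0], v=[0.5]))
    assert out[0, 0] == pytest.approx(0.5)


def test_deformable_ramp_average():
    # 3x3 kernel all 1/9, zero offsets, I(x,y)=x: interior equals x
    img = np.tile(np.arange(8.0)[:, None], (1, 8))
    out = deformable_conv(img, np.full((3, 3), 1.0 / 9), _zero_offsets())
    # oracle: direct summation over the 3x3 window
    oracle = np.zeros_like(img)
    for x in range(8):
        for y in range(8):
            acc = 0.0
            for i in range(3):
                for j in range(3):
                    xx, yy = x + i - 1, y + j - 1
                    if 0 <= xx < 8 and 0 <= yy < 8:
                        acc += img[xx, yy] / 9.0
            oracle[x, y] = acc
    assert np.allclose(out, oracle, atol=1e-9)
    assert np.allclose(out[1:-1, 1:-1], img[1:-1, 1:-1], atol=1e-9)


def test_deformable_reduces_to_cross_correlation(rng):
    for _ in range(10):
        img = rng.normal(size=(16, 16))
        k = rng.normal(size=(3, 3))
        out = deformable_conv(img, k, _zero_offsets())
        ref = ndimage.correlate(img, k, mode="constant", cval=0.0)
        assert np.abs(out - ref).max() < 1e-6


def test_deformable_linearity(rng):
    k = rng.normal(size=(3, 3))
    off = OffsetField(u=rng.normal(size=3) * 0.5, v=rng.normal(size=3) * 0.5)
    a, b = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
    lhs = deformable_conv(2.0 * a + 3.0 * b, k, off)
    rhs = 2.0 * deformable_conv(a, k, off) + 3.0 * deformable_conv(b, k, off)
    assert np.allclose(lhs, rhs, atol=1e-10)


def test_deformable_literal_mode_no_grid(rng):
    img = rng.random((5, 5))
    k = np.full((3, 3), 1.0)
    # literal mode with zero offsets samples the center pixel for every tap
    out = deformable_conv(img, k, _zero_offsets(), mode="literal")
    assert np.allclose(out, 9.0 * img, atol=1e-12)


def test_deformable_rejects_nan_offsets(rng):
    with pytest.raises(ValueError):
        OffsetField(u=[np.nan, 0, 0], v=[0, 0, 0])


def test_deformable_batched_matches_reference(rng):
    # the trainable path and the reference op agree on single-channel inputs
    img = rng.normal(size=(7, 7))
    weight = rng.normal(size=(1, 1, 3, 3))
    phi = rng.random((3, 3))
    phi /= phi.sum()
    off = compute_offsets(phi, (3, 3))
    u = np.asarray(off.u)[None]
    v = np.asarray(off.v)[None]
    out = deformable_conv_batched(img[None, None], weight, phi[None], u, v)
    # reference: modulated taps w * 9 * phi, then deformable sampling
    ref = deformable_conv(img, weight[0, 0] * 9.0 * phi, off)
    assert np.allclose(out[0, 0], ref, atol=1e-9)


def test_deformable_batched_uniform_zero_equals_conv(rng):
    x = rng.normal(size=(2, 3, 8, 8))
    w = rng.normal(size=(4, 3, 3, 3))
    phi = np.full((2, 3, 3), 1.0 / 9)
    zeros = np.zeros((2, 3))
    out = deformable_conv_batched(x, w, phi, zeros, zeros)
    ref = ad.conv2d(x, w, stride=1, padding=1)
    assert np.abs(out - ref).max() < 1e-9


# ---------------------------------------------------------------------------
# literal kernel update

def test_literal_update_constant_phi_no_change(rng):
    k = rng.normal(size=(3, 3))
    phi = np.full((3, 3), 1.0 / 9)
    updated = literal_kernel_update(k, phi)
    assert np.allclose(updated.base, k)
    assert updated.weight_delta == pytest.approx(0.0)


def test_literal_update_zero_kernel():
    phi = np.random.default_rng(0).random((3, 3))
    phi /= phi.sum()
    updated = literal_kernel_update(np.zeros((3, 3)), phi)
    assert updated.weight_delta == pytest.approx(0.0)


def test_literal_update_hand_oracle():
    phi = np.zeros((3, 3))
    phi[1, 1] = 0.6
    phi[0, 1] = 0.2
    phi[2, 1] = 0.2
    k = np.arange(9.0).reshape(3, 3)
    updated = literal_kernel_update(k, phi, step=1.0)
    # oracle: explicit double loop with edge-replicated central differences
    pad = np.pad(phi, 1, mode="edge")
    gx = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2.0
    gy = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2.0
    dw = 0.0
    for m in range(3):
        for n in range(3):
            dw += k[m, n] * phi[m, n] * gx[m, n] * gy[m, n]
    expected = k - phi * dw
    assert updated.weight_delta == pytest.approx(dw, abs=1e-12)
    assert np.allclose(updated.base, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# backbone

def test_adcn_forward_stride_contract(rng):
    backbone = DeformableBackbone(widths=(4, 8, 8, 8), strides=(2, 2, 2, 2), seed=0)
    image = rng.random((64, 64, 3))
    fmap = adcn_forward(image, backbone)
    assert fmap.values.shape == (4, 4, 8)
    assert fmap.stride == 16


def test_adcn_forward_determinism(rng):
    image = rng.random((32, 32, 3))
    outs = []
    for _ in range(2):
        backbone = DeformableBackbone(widths=(4, 4), strides=(2, 2), seed=5)
        outs.append(adcn_forward(image, backbone).values)
    assert np.array_equal(outs[0], outs[1])


def test_adcn_ablation_matches_plain_conv_oracle(rng):
    """Ablated block == scipy-based residual forward within 1e-5."""
    backbone = DeformableBackbone(widths=(4,), strides=(2,), seed=3)
    block = backbone.blocks[0]
    image = rng.random((16, 16, 3))
    out = adcn_forward(image, backbone, ablation=True).values  # (8, 8, 4)

    def conv_ref(x_chw, w, stride, padding):
        cin = x_chw.shape[0]
        outs = []
        for o in range(w.shape[0]):
            acc = np.zeros_like(x_chw[0])
            for c in range(cin):
                acc += ndimage.correlate(x_chw[c], w[o, c], mode="constant")
            outs.append(acc[padding - 1::stride, padding - 1::stride]
                        if stride > 1 else acc)
        return np.stack(outs)

    x = image.transpose(2, 0, 1)
    h = conv_ref(x, block.w1.data, 2, 1) + block.b1.data[:, None, None]
    h = np.maximum(h, 0.0)
    y = conv_ref(h, block.w2.data, 1, 1) + block.b2.data[:, None, None]
    sc = np.einsum("oc,chw->ohw", block.wsc.data[:, :, 0, 0], x)[:, ::2, ::2]
    ref = np.maximum(y + sc, 0.0).transpose(1, 2, 0)
    assert np.abs(out - ref).max() < 1e-5


def test_pool_attention_preserves_normalization(rng):
    phi = rng.random((3, 10, 14))
    phi /= phi.sum(axis=(1, 2), keepdims=True)
    pooled = pool_attention(phi, (3, 3))
    assert np.allclose(pooled.sum(axis=(1, 2)), 1.0, atol=1e-9)
    assert (pooled >= 0).all()
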