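"""Encoder/decoder unit oracles, attention properties and mask construction."""

import numpy as np
import pytest

from polypvit import autodiff as ad
from polypvit import transformer as tf
from polypvit.model import ArchConfig, PolypViT


def _norm(d, gamma=1.0, beta=0.0, eps=1e-5):
    return tf.NormParams(gamma=np.full(d, float(gamma)),
                         beta=np.full(d, float(beta)), eps=eps)


def _attn(rng, d, heads=1, zero_out=False):
    std = 1.0 / np.sqrt(d)
    wo = np.zeros((d, d)) if zero_out else rng.normal(0, std, (d, d))
    return tf.AttentionParams(wq=rng.normal(0, std, (d, d)),
                              wk=rng.normal(0, std, (d, d)),
                              wv=rng.normal(0, std, (d, d)),
                              wo=wo, heads=heads)


def _mlp(rng, d, ratio=4, zero_out=False):
    hidden = ratio * d
    w2 = np.zeros((hidden, d)) if zero_out else rng.normal(0, 0.1, (hidden, d))
    return tf.MlpParams(w1=rng.normal(0, 0.1, (d, hidden)), b1=np.zeros(hidden),
                        w2=w2, b2=np.zeros(d))


def _block(rng, d, heads=1, zero_out=False):
    return tf.EncoderBlockParams(ln1=_norm(d), attn=_attn(rng, d, heads, zero_out),
                                 ln2=_norm(d), mlp=_mlp(rng, d, zero_out=zero_out))


# ---------------------------------------------------------------------------
# layer norm

def test_layer_norm_zero_mean_unit_sd_fixed_point():
    v = np.array([1.0, -1.0, 1.0, -1.0])
    out = tf.layer_norm(v, _norm(4))
    assert np.allclose(out, v, atol=1e-4)


def test_layer_norm_constant_input_gives_beta():
    v = np.full(5, 3.3)
    out = tf.layer_norm(v, _norm(5, beta=0.7))
    assert np.allclose(out, 0.7, atol=1e-3)


def test_layer_norm_frozen_example():
    v = np.array([0.0, 2.0])
    params = _norm(2, gamma=2.0, beta=1.0)
    out = tf.layer_norm(v, params)
    # brute-force oracle: scalar evaluation of the normalization formula
    mu = v.mean()
    sigma = np.sqrt(((v - mu) ** 2).mean())
    oracle = 2.0 * (v - mu) / (sigma + params.eps) + 1.0
    assert np.allclose(out, oracle, atol=1e-9)
    assert np.allclose(out, [-1.0, 3.0], atol=1e-4)  # eps-perturbed exact value


# ---------------------------------------------------------------------------
# attention

def test_mhsa_single_token(rng):
    d = 4
    params = _attn(rng, d)
    x = rng.normal(size=(1, d))
    out, weights = tf.mhsa(x, params, return_weights=True)
    assert weights.shape == (1, 1, 1)
    assert weights[0, 0, 0] == pytest.approx(1.0)
    expected = (x @ params.wv) @ params.wo
    assert np.allclose(out, expected, atol=1e-12)


def test_mhsa_zero_query_uniform_attention(rng):
    d, n = 6, 5
    params = _attn(rng, d, heads=2)
    params.wq = np.zeros((d, d))
    x = rng.normal(size=(n, d))
    out, weights = tf.mhsa(x, params, return_weights=True)
    assert np.allclose(weights, 1.0 / n, atol=1e-12)
    v = x @ params.wv
    # uniform attention averages values per head; heads concatenate back to v-mean
    expected = np.tile(v.mean(axis=0), (n, 1)) @ params.wo
    assert np.allclose(out, expected, atol=1e-12)


def test_mhsa_two_token_scalar_oracle():
    # n=2, h=1, d=d_k=1 with stated scalar weights; brute-force evaluation
    x = np.array([[1.0], [2.0]])
    wq, wk, wv, wo = 0.7, -0.3, 0.9, 1.1
    params = tf.AttentionParams(wq=np.array([[wq]]), wk=np.array([[wk]]),
                                wv=np.array([[wv]]), wo=np.array([[wo]]), heads=1)
    out = tf.mhsa(x, params)
    q, k, v = x * wq, x * wk, x * wv
    oracle = np.zeros((2, 1))
    for i in range(2):
        scores = np.array([q[i, 0] * k[0, 0], q[i, 0] * k[1, 0]])  # / sqrt(1)
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        oracle[i, 0] = (w[0] * v[0, 0] + w[1] * v[1, 0]) * wo
    assert np.allclose(out, oracle, atol=1e-9)


def test_mhsa_rejects_bad_heads(rng):
    with pytest.raises(ValueError):
        tf.mhsa(rng.normal(size=(3, 5)), _attn(rng, 5, heads=2))


def test_attention_rows_sum_to_one(rng):
    for _ in range(20):
        n = int(rng.integers(2, 12))
        heads = int(rng.choice([1, 2, 4]))
        d = heads * int(rng.integers(1, 5))
        x = rng.normal(size=(n, d)) * rng.uniform(0.1, 5.0)
        _, w = tf.mhsa(x, _attn(rng, d, heads), return_weights=True)
        assert np.abs(w.sum(axis=-1) - 1.0).max() < 1e-6


# ---------------------------------------------------------------------------
# encoder

def test_encoder_block_zeroed_is_identity(rng):
    d = 4
    block = _block(rng, d, zero_out=True)
    x = rng.normal(size=(5, d))
    out = tf.encoder_block(x, block)
    assert np.allclose(out, x, atol=1e-12)


def test_encoder_block_shape_contract(rng):
    for n, d in [(3, 4), (7, 8)]:
        out = tf.encoder_block(rng.normal(size=(n, d)), _block(rng, d))
        assert out.shape == (n, d)


def test_encoder_block_composition_oracle(rng):
    # equals the sequential composition of layer_norm / mhsa / mlp
    d = 4
    block = _block(rng, d)
    x = rng.normal(size=(2, d))
    z1 = tf.mhsa(tf.layer_norm(x, block.ln1), block.attn) + x
    z2 = tf.mlp(tf.layer_norm(z1, block.ln2), block.mlp) + z1
    assert np.allclose(tf.encoder_block(x, block), z2, atol=1e-12)


def test_encode_depth_two_composition(rng):
    d = 4
    blocks = [_block(rng, d), _block(rng, d)]
    x = rng.normal(size=(3, d))
    state = tf.encode(x, blocks)
    manual = tf.encoder_block(tf.encoder_block(x, blocks[0]), blocks[1])
    assert np.allclose(state.features, manual, atol=1e-12)
    assert len(state.intermediates) == 2


def test_encode_zeroed_blocks_identity(rng):
    d = 4
    blocks = [_block(rng, d, zero_out=True) for _ in range(4)]
    x = rng.normal(size=(5, d))
    assert np.allclose(tf.encode(x, blocks).features, x, atol=1e-12)


def test_encoder_permutation_equivariance(rng):
    d, n = 8, 10
    blocks = [_block(rng, d, heads=2) for _ in range(2)]
    x = rng.normal(size=(n, d))
    perm = rng.permutation(n)
    out = tf.encode(x, blocks).features
    out_p = tf.encode(x[perm], blocks).features
    assert np.allclose(out_p, out[perm], atol=1e-10)


# ---------------------------------------------------------------------------
# decoder

def _decoder(rng, d, heads=1, zero_out=False, cross_residual=True):
    return tf.DecoderParams(ln_q=_norm(d), self_attn=_attn(rng, d, heads, zero_out),
                            ln_cross=_norm(d), cross_attn=_attn(rng, d, heads, zero_out),
                            ln_mlp=_norm(d), mlp=_mlp(rng, d, zero_out=zero_out),
                            cross_residual=cross_residual)


def test_decode_zero_projections_all_zero(rng):
    d = 4
    params = _decoder(rng, d, zero_out=True)
    t = rng.normal(size=(2, d))
    f = rng.normal(size=(6, d))
    state = tf.decode(f, t, params)
    assert np.allclose(state.z3, 0.0, atol=1e-12)  # no residual on stage one
    assert np.allclose(state.z4, 0.0, atol=1e-12)
    assert np.allclose(state.z5, 0.0, atol=1e-12)


def test_decode_identical_queries_tie(rng):
    d = 4
    params = _decoder(rng, d)
    t = np.tile(rng.normal(size=(1, d)), (2, 1))
    f = rng.normal(size=(5, d))
    state = tf.decode(f, t, params)
    assert np.allclose(state.z5[0], state.z5[1], atol=1e-12)
    mask = tf.build_mask(f, state, (1, 5), out_size=(1, 5))
    assert mask.labels.sum() == 0  # ties go to background everywhere


def test_decode_brute_force_oracle(rng):
    # 2 patches, d=2, single head: independent scalar-level evaluation
    d = 2
    params = _decoder(rng, d)
    t = rng.normal(size=(2, d))
    f = rng.normal(size=(2, d))

    def ln(v, p):
        mu = v.mean(axis=-1, keepdims=True)
        sd = np.sqrt(((v - mu) ** 2).mean(axis=-1, keepdims=True))
        return p.gamma * (v - mu) / (sd + p.eps) + p.beta

    def attn(x, kv, p):
        q, k, v = x @ p.wq, kv @ p.wk, kv @ p.wv
        out = np.zeros_like(q)
        for i in range(q.shape[0]):
            s = q[i] @ k.T / np.sqrt(d)
            e = np.exp(s - s.max())
            w = e / e.sum()
            out[i] = w @ v
        return out @ p.wo

    def gelu_ref(x):
        return 0.5 * x * (1 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x ** 3)))

    z3 = attn(ln(t, params.ln_q), ln(t, params.ln_q), params.self_attn)
    z4 = attn(ln(z3, params.ln_cross), f, params.cross_attn) + z3
    hidden = gelu_ref(ln(z4, params.ln_mlp) @ params.mlp.w1 + params.mlp.b1)
    z5 = hidden @ params.mlp.w2 + params.mlp.b2 + z4

    state = tf.decode(f, t, params)
    assert np.allclose(state.z3, z3, atol=1e-9)
    assert np.allclose(state.z4, z4, atol=1e-9)
    assert np.allclose(state.z5, z5, atol=1e-9)


def test_decode_cross_attention_rows_sum(rng):
    for _ in range(10):
        d = int(rng.choice([2, 4, 8]))
        n = int(rng.integers(2, 10))
        params = _decoder(rng, d, heads=min(2, d))
        state = tf.decode(rng.normal(size=(n, d)), rng.normal(size=(2, d)), params)
        assert np.abs(state.cross_weights.sum(axis=-1) - 1.0).max() < 1e-6


# ---------------------------------------------------------------------------
# mask construction

def test_build_mask_aligned_query_wins(rng):
    f = np.array([[1.0, 0.0], [0.0, 2.0]])
    qe = np.array([[0.0, 1.0], [1.0, 0.0]])  # bg matches patch 1, polyp patch 0
    mask = tf.build_mask(f, qe, (1, 2), out_size=(1, 2))
    assert mask.labels.tolist() == [[1, 0]]


def test_build_mask_equal_logits_all_background():
    f = np.ones((4, 3))
    qe = np.tile(np.ones(3), (2, 1))
    mask = tf.build_mask(f, qe, (2, 2), out_size=(2, 2))
    assert mask.labels.sum() == 0


def test_build_mask_frozen_grid_example():
    # 2x2 grid, logits (bg, polyp) = [[(0,1),(1,0)],[(0,2),(3,0)]] -> [[1,0],[1,0]]
    logits = np.zeros((2, 2, 2))  # (C, gh, gw)
    logits[0] = [[0.0, 1.0], [0.0, 3.0]]
    logits[1] = [[1.0, 0.0], [2.0, 0.0]]
    up = tf.upsample_logits(logits, (2, 2))
    labels = (up[1] > up[0]).astype(int)
    assert labels.tolist() == [[1, 0], [1, 0]]


def test_upsample_matrix_identity_when_same_size():
    assert np.allclose(tf.upsample_matrix(8, 8), np.eye(8))


def test_upsample_matrix_rows_sum_to_one():
    mat = tf.upsample_matrix(64, 16)
    assert np.allclose(mat.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# full model properties

def test_full_forward_shapes_and_finite(tiny_arch):
    model = PolypViT(tiny_arch, seed=0)
    rng = np.random.default_rng(0)
    x = rng.random((2, 3, 64, 64))
    logits = model.forward(x)
    data = logits.data
    assert data.shape == (2, 2, 64, 64)
    assert np.isfinite(data).all()
    masks = model.predict(x)
    assert masks.shape == (2, 64, 64)
    assert set(np.unique(masks)) <= {0, 1}


def test_zero_weight_model_all_background(tiny_arch):
    model = PolypViT(tiny_arch, seed=0)
    state = model.state_dict()
    for k in state:
        state[k] = np.zeros_like(state[k])
    model.load_state_dict(state)
    rng = np.random.default_rng(1)
    masks = model.predict(rng.random((1, 3, 64, 64)))
    assert masks.sum() == 0
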