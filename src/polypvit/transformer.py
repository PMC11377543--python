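"""Transformer encoder-decoder with class query tokens for segmentation.

The encoder applies pre-norm blocks: Z1 = MHSA(LN(x)) + x followed by
Z2 = MLP(LN(Z1)) + Z1 with a two-layer GELU MLP (hidden dimension 4d).  The
decoder takes one learnable query token per class (background, polyp),
computes Z3 = MHSA(LN(T)) (no residual on this first stage), cross-attends
the queries to the encoded features, Z4 = MHCA(LN(Z3), F) + Z3, and produces
query embeddings Z5 = MLP(LN(Z4)) + Z4.  Per-patch class logits are the
inner products <f_i, qe_c>; logits are bilinearly upsampled to the requested
output size and argmax-ed, with ties broken toward background.

All functions accept plain arrays (oracle/evaluation use) or autodiff
tensors (training); shapes may be (n, d) or batched (N, n, d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

__all__ = [
    "NormParams",
    "AttentionParams",
    "MlpParams",
    "EncoderBlockParams",
    "DecoderParams",
    "QueryTokens",
    "EncoderState",
    "DecoderState",
    "SegmentationMask",
    "layer_norm",
    "mhsa",
    "mlp",
    "encoder_block",
    "encode",
    "decode",
    "upsample_matrix",
    "build_mask",
]


# ---------------------------------------------------------------------------
# parameter containers (values may be arrays or autodiff tensors)

@dataclass
class NormParams:
    gamma: object
    beta: object
    eps: float = 1e-5


@dataclass
class AttentionParams:
    """Q/K/V projections plus the output projection after head concatenation.

    The output projection is required for multi-head composition even though
    the source formulation omits it; initializing it to zero recovers the
    degenerate single-path reading.
    """

    wq: object
    wk: object
    wv: object
    wo: object
    heads: int = 1


@dataclass
class MlpParams:
    w1: object
    b1: object
    w2: object
    b2: object


@dataclass
class EncoderBlockParams:
    ln1: NormParams
    attn: AttentionParams
    ln2: NormParams
    mlp: MlpParams


@dataclass
class DecoderParams:
    ln_q: NormParams
    self_attn: AttentionParams
    ln_cross: NormParams
    cross_attn: AttentionParams
    ln_mlp: NormParams
    mlp: MlpParams
    cross_residual: bool = True  # residual on the cross-attention stage (Z4)


@dataclass
class QueryTokens:
    """Learnable class tokens; exactly one per class (background, polyp)."""

    tokens: object  # (C, d)
    n_classes: int = 2


@dataclass
class EncoderState:
    """Final features F plus the per-block intermediates."""

    features: object  # (..., n, d)
    intermediates: list = field(default_factory=list)


@dataclass
class DecoderState:
    z3: object
    z4: object
    z5: object
    cross_weights: object  # (..., heads, C, n) rows sum to 1

    @property
    def query_embeddings(self):
        return self.z5


@dataclass
class SegmentationMask:
    logits: np.ndarray  # (..., C, H, W)
    labels: np.ndarray  # (..., H, W) in {0, 1}


# ---------------------------------------------------------------------------
# operations

def layer_norm(v, params: NormParams):
    """gamma * (v - mu) / (sigma + eps) + beta, per-token over the last axis.

    ``sigma`` is the population standard deviation; ``eps`` is added to it
    (not to the variance), exactly as the normalization is stated.
    """
    mu = ad.tmean(v, axis=-1, keepdims=True)
    centered = ad.sub(v, mu)
    var = ad.tmean(ad.mul(centered, centered), axis=-1, keepdims=True)
    sigma = ad.sqrt(ad.add(var, 1e-24))  # tiny floor keeps gradients finite
    return ad.add(ad.mul(params.gamma, ad.div(centered, ad.add(sigma, params.eps))),
                  params.beta)


def _shape(x):
    return x.data.shape if ad.is_tensor(x) else np.asarray(x).shape


def _split_heads(x, n_batch, n_tok, heads, dk):
    x = ad.reshape(x, (n_batch, n_tok, heads, dk))
    return ad.transpose(x, (0, 2, 1, 3))  # (N, h, n, dk)


def mhsa(tokens, params: AttentionParams, kv=None, return_weights: bool = False):
    """Multi-head attention.  Self-attention by default; pass ``kv`` for
    cross-attention (queries from ``tokens``, keys/values from ``kv``).

    Per head: AS = softmax(Q K^T / sqrt(d_k)) V; heads are concatenated and
    output-projected.  Every attention row sums to 1 by construction.
    """
    src = tokens if kv is None else kv
    q_shape = _shape(tokens)
    batched = len(q_shape) == 3
    if not batched:
        tokens = ad.reshape(tokens, (1,) + tuple(q_shape))
        src = ad.reshape(src, (1,) + tuple(_shape(src))) if kv is not None else tokens
    nb, nq, d = _shape(tokens)
    nk = _shape(src)[1]
    h = params.heads
    if d % h:
        raise ValueError(f"model dimension {d} not divisible by {h} heads")
    dk = d // h
    q = _split_heads(ad.matmul(tokens, params.wq), nb, nq, h, dk)
    k = _split_heads(ad.matmul(src, params.wk), nb, nk, h, dk)
    v = _split_heads(ad.matmul(src, params.wv), nb, nk, h, dk)
    scores = ad.div(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), np.sqrt(dk))
    weights = ad.softmax(scores, axis=-1)  # (N, h, nq, nk)
    ctx = ad.matmul(weights, v)
    ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (nb, nq, d))
    out = ad.matmul(ctx, params.wo)
    if not batched:
        out = ad.reshape(out, (nq, d))
        weights = ad.reshape(weights, (h, nq, nk))
    if return_weights:
        return out, weights
    return out


def mlp(x, params: MlpParams):
    """Two-layer perceptron with GELU: W2 gelu(W1 x + b1) + b2."""
    hidden = ad.gelu(ad.add(ad.matmul(x, params.w1), params.b1))
    return ad.add(ad.matmul(hidden, params.w2), params.b2)


def encoder_block(tokens, params: EncoderBlockParams):
    """Z1 = MHSA(LN(x)) + x;  Z2 = MLP(LN(Z1)) + Z1."""
    z1 = ad.add(mhsa(layer_norm(tokens, params.ln1), params.attn), tokens)
    z2 = ad.add(mlp(layer_norm(z1, params.ln2), params.mlp), z1)
    return z2


def encode(tokens, blocks: list[EncoderBlockParams]) -> EncoderState:
    """Apply the encoder blocks sequentially; F is the final block output."""
    if len(blocks) < 1:
        raise ValueError("encoder depth must be >= 1")
    intermediates = []
    x = tokens
    for block in blocks:
        x = encoder_block(x, block)
        intermediates.append(x)
    return EncoderState(features=x, intermediates=intermediates)


def _broadcast_queries(queries, features):
    fs = _shape(features)
    qs = _shape(queries)
    if len(fs) == 3 and len(qs) == 2:
        n = fs[0]
        return ad.add(ad.reshape(queries, (1,) + tuple(qs)), np.zeros((n, 1, 1)))
    return queries


def decode(features, queries, params: DecoderParams) -> DecoderState:
    """Z3 = MHSA(LN(T)) (no residual, as stated); Z4 = MHCA(LN(Z3), F) + Z3;
    Z5 = MLP(LN(Z4)) + Z4.  Rows of Z5 are the per-class query embeddings."""
    f = features.features if isinstance(features, EncoderState) else features
    t = queries.tokens if isinstance(queries, QueryTokens) else queries
    t = _broadcast_queries(t, f)
    z3 = mhsa(layer_norm(t, params.ln_q), params.self_attn)
    cross, weights = mhsa(layer_norm(z3, params.ln_cross), params.cross_attn,
                          kv=f, return_weights=True)
    z4 = ad.add(cross, z3) if params.cross_residual else cross
    z5 = ad.add(mlp(layer_norm(z4, params.ln_mlp), params.mlp), z4)
    return DecoderState(z3=z3, z4=z4, z5=z5, cross_weights=weights)


def upsample_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Bilinear interpolation as an (n_out, n_in) matrix over pixel centers."""
    mat = np.zeros((n_out, n_in))
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        f = int(np.floor(src))
        a = src - f
        mat[o, f] += 1.0 - a
        mat[o, min(f + 1, n_in - 1)] += a
    return mat


def logits_to_grid(features, query_embeddings, grid_shape: tuple[int, int]):
    """Per-patch class scores <f_i, qe_c> arranged on the token grid (C-first)."""
    f = features.features if isinstance(features, EncoderState) else features
    qe = query_embeddings
    fs = _shape(f)
    batched = len(fs) == 3
    if not batched:
        f = ad.reshape(f, (1,) + tuple(fs))
        qe = ad.reshape(qe, (1,) + tuple(_shape(qe)))
    nb, n, d = _shape(f)
    nc = _shape(qe)[-2]
    gh, gw = grid_shape
    if gh * gw != n:
        raise ValueError(f"grid {grid_shape} incompatible with {n} patches")
    logits = ad.matmul(f, ad.transpose(qe, (0, 2, 1)))  # (N, n, C)
    logits = ad.transpose(ad.reshape(logits, (nb, gh, gw, nc)), (0, 3, 1, 2))
    return logits if batched else ad.reshape(logits, (nc, gh, gw))


def upsample_logits(logits, out_size: tuple[int, int]):
    """Bilinearly upsample (..., C, gh, gw) logits to (..., C, H, W)."""
    shape = _shape(logits)
    gh, gw = shape[-2], shape[-1]
    ur = upsample_matrix(out_size[0], gh)
    uc = upsample_matrix(out_size[1], gw).T
    return ad.matmul(ad.matmul(ur, logits), uc)


def build_mask(features, state, grid_shape: tuple[int, int],
               out_size: int | tuple[int, int]) -> SegmentationMask:
    """Score every patch against every class embedding and rasterize the mask.

    Ties in the upsampled logits go to background (label 0).
    """
    if isinstance(out_size, int):
        out_size = (out_size, out_size)
    qe = state.query_embeddings if isinstance(state, DecoderState) else state
    logits = logits_to_grid(features, qe, grid_shape)
    up = upsample_logits(logits, out_size)
    up_arr = up.data if ad.is_tensor(up) else np.asarray(up)
    bg, polyp = up_arr[..., 0, :, :], up_arr[..., 1, :, :]
    labels = (polyp > bg).astype(np.uint8)
    return SegmentationMask(logits=up_arr, labels=labels)
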