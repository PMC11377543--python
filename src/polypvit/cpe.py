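"""Conditional positional encoding: patch extraction and the PEG.

Tokens are cut from the backbone feature map as fixed-size non-overlapping
patches in row-major order.  The Position Encoding Generator (PEG) maps the
token sequence back onto its 2-D grid, applies a depthwise 3x3 convolution
with zero padding, and flattens the result back to one embedding per token.
Because the embeddings are computed from the token content, they are
conditional (they differ between images) and translation-aware (shifting the
grid shifts interior embeddings identically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .adcn import FeatureMap

__all__ = [
    "PatchSequence",
    "PositionalEmbedding",
    "patchify",
    "unpatchify",
    "depthwise_conv3x3",
    "peg_embed",
    "attach_positions",
]


@dataclass
class PatchSequence:
    """n tokens of dimension d on a (rows, cols) grid, row-major order."""

    tokens: np.ndarray  # (n, d)
    grid_shape: tuple[int, int]
    patch_size: int = 1

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float64)
        rows, cols = self.grid_shape
        if rows * cols != self.tokens.shape[0]:
            raise ValueError(
                f"grid {self.grid_shape} incompatible with {self.tokens.shape[0]} tokens")


@dataclass
class PositionalEmbedding:
    """One conditionally generated embedding per token (additive mode)."""

    embeddings: np.ndarray  # (n, d)
    generator_kernel: np.ndarray  # (d, 3, 3) depthwise weights

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)


def patchify(features, p: int = 1) -> PatchSequence:
    """Cut an H' x W' x C feature map into (H'/p)*(W'/p) flattened patches.

    Token i (row-major over the patch grid) is the raveled p x p x C block.
    """
    arr = features.values if isinstance(features, FeatureMap) else np.asarray(features)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    h, w, c = arr.shape
    if h % p or w % p:
        raise ValueError(f"grid {h}x{w} not divisible by patch size {p}")
    gh, gw = h // p, w // p
    blocks = arr.reshape(gh, p, gw, p, c).transpose(0, 2, 1, 3, 4)
    tokens = blocks.reshape(gh * gw, p * p * c)
    return PatchSequence(tokens=tokens, grid_shape=(gh, gw), patch_size=p)


def unpatchify(patches: PatchSequence, channels: int) -> np.ndarray:
    """Inverse of :func:`patchify` back to the H' x W' x C layout."""
    gh, gw = patches.grid_shape
    p = patches.patch_size
    blocks = patches.tokens.reshape(gh, gw, p, p, channels).transpose(0, 2, 1, 3, 4)
    return blocks.reshape(gh * p, gw * p, channels)


def depthwise_conv3x3(grid, kernel):
    """Depthwise 3x3 cross-correlation with zero padding on NCHW input.

    ``kernel`` has shape (C, 3, 3).  Works on arrays or autodiff tensors, so
    the same routine serves the plain-NumPy operations and the trainable
    model.
    """
    out = None
    for i in range(3):
        for j in range(3):
            tap = ad.reshape(ad.getitem(kernel, (slice(None), i, j)), (1, -1, 1, 1))
            term = ad.mul(tap, ad.translate2d(grid, i - 1, j - 1))
            out = term if out is None else ad.add(out, term)
    return out


def peg_embed(patches: PatchSequence, kernel: np.ndarray) -> PositionalEmbedding:
    """Generate conditional positional embeddings with a depthwise 3x3 PEG."""
    kernel = np.asarray(kernel, dtype=np.float64)
    d = patches.tokens.shape[1]
    if kernel.shape != (d, 3, 3):
        raise ValueError(f"generator kernel must be ({d}, 3, 3), got {kernel.shape}")
    gh, gw = patches.grid_shape
    grid = patches.tokens.reshape(gh, gw, d).transpose(2, 0, 1)[None]  # 1 x d x gh x gw
    emb_grid = depthwise_conv3x3(grid, kernel)
    embeddings = emb_grid[0].transpose(1, 2, 0).reshape(gh * gw, d)
    return PositionalEmbedding(embeddings=embeddings, generator_kernel=kernel)


def attach_positions(patches: PatchSequence, emb: PositionalEmbedding,
                     mode: str = "add",
                     projection: np.ndarray | None = None) -> PatchSequence:
    """Combine tokens with their positional embeddings.

    ``add`` (default) keeps the token dimension: token' = x + e.
    ``concat_project`` concatenates [x; e] (dimension 2d) and applies the
    supplied (2d, d) projection back to d.
    """
    x, e = patches.tokens, emb.embeddings
    if x.shape != e.shape:
        raise ValueError(f"token/embedding shape mismatch: {x.shape} vs {e.shape}")
    if mode == "add":
        combined = x + e
    elif mode == "concat_project":
        if projection is None:
            raise ValueError("concat_project mode requires a projection matrix")
        stacked = np.concatenate([x, e], axis=1)
        if projection.shape != (stacked.shape[1], x.shape[1]):
            raise ValueError(
                f"projection must be ({stacked.shape[1]}, {x.shape[1]}), got {projection.shape}")
        combined = stacked @ projection
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PatchSequence(tokens=combined, grid_shape=patches.grid_shape,
                         patch_size=patches.patch_size)
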