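"""Adaptive deformable convolutional feature extraction.

The mechanism has three ingredients, all driven by a nonnegative, sum-to-one
spatial attention map ``phi`` derived from backbone activations:

* kernel modulation — trainable kernel coefficients are reweighted by ``phi``;
* offsets — per-kernel-row/column displacements ``u_i``, ``v_j`` computed as
  attention-weighted index differences, ``u_i = 1/2 sum phi_mn (m - i)``;
* deformable sampling — the input is read at fractionally displaced
  positions with bilinear interpolation (zero outside the frame).

Two sampling modes are provided.  ``base_grid`` (default) adds the
conventional kernel-grid term ``(i - c)`` to each offset so that zero offsets
reduce exactly to ordinary cross-correlation.  ``literal`` applies the
offsets alone, exactly as the printed update rule states.

The auditable single-channel operations in this module are plain NumPy; the
trainable four-block backbone (:class:`DeformableBackbone`) composes the same
arithmetic from autodiff primitives so it can be trained end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .nn import Module, he_normal
from .synthetic import LabeledImage

__all__ = [
    "AttentionMap",
    "AdaptiveKernel",
    "OffsetField",
    "FeatureMap",
    "compute_attention_map",
    "modulate_kernel",
    "average_kernel",
    "compute_offsets",
    "deformable_conv",
    "literal_kernel_update",
    "DeformableBackbone",
    "adcn_forward",
    "export_heatmap",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class AttentionMap:
    """Nonnegative M x N map summing to one; extent (H, W) = (M, N)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("attention map must be 2-D")
        if (self.values < 0).any():
            raise ValueError("attention map entries must be nonnegative")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("attention map must sum to 1")

    @property
    def extent(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AdaptiveKernel:
    """Base coefficients plus the modulated/averaged views derived from them.

    ``base`` has spatial extent (M, N) in its last two axes; leading axes, if
    any, index output/input channels.
    """

    base: np.ndarray
    modulated: np.ndarray | None = None
    averaged: np.ndarray | None = None
    conv_weights: np.ndarray | None = None
    weight_delta: np.ndarray | None = None

    def __post_init__(self):
        self.base = np.asarray(self.base, dtype=np.float64)
        if not np.isfinite(self.base).all():
            raise ValueError("kernel coefficients must be finite")

    @property
    def extent(self) -> tuple[int, int]:
        return self.base.shape[-2:]


@dataclass
class OffsetField:
    """Per-kernel-row offsets u_i (pixels, rows) and per-column v_j (cols)."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.u = np.atleast_1d(np.asarray(self.u, dtype=np.float64))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=np.float64))
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("offsets must be finite")


@dataclass
class FeatureMap:
    """H' x W' x C activations with the downsampling stride vs the input."""

    values: np.ndarray
    stride: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("feature map must be finite")


def _as_feature_array(features) -> np.ndarray:
    if isinstance(features, FeatureMap):
        return features.values
    return np.asarray(features, dtype=np.float64)


def _as_phi(phi) -> np.ndarray:
    return phi.values if isinstance(phi, AttentionMap) else np.asarray(phi, dtype=np.float64)


def _as_kernel_base(kernel) -> np.ndarray:
    return kernel.base if isinstance(kernel, AdaptiveKernel) else np.asarray(kernel, dtype=np.float64)


# ---------------------------------------------------------------------------
# auditable operations (plain NumPy)

def compute_attention_map(features) -> AttentionMap:
    """Channel-wise mean of absolute activations, normalized to sum 1.

    ``features`` is H x W x C (or H x W).  An all-zero input falls back to a
    uniform map rather than raising.
    """
    arr = _as_feature_array(features)
    if arr.size == 0:
        raise ValueError("features must be non-empty")
    phi = np.abs(arr)
    if phi.ndim == 3:
        phi = phi.mean(axis=2)
    total = phi.sum()
    if total == 0.0:
        phi = np.full(phi.shape, 1.0 / phi.size)
    else:
        phi = phi / total
    return AttentionMap(values=phi)


def modulate_kernel(kernel, phi, at: tuple[int, int] | None = None):
    """Attention-modulated coefficients: k_ij = sum_mn k_ij^mn * phi_mn.

    The contraction is over the shared (M, N) spatial extent; any leading
    channel axes of the kernel are preserved.  ``at`` is accepted for
    interface completeness — the map carries no per-pixel dependence, so the
    result is the same at every position.
    """
    base = _as_kernel_base(kernel)
    phi_arr = _as_phi(phi)
    if base.shape[-2:] != phi_arr.shape:
        raise ValueError(
            f"kernel extent {base.shape[-2:]} does not match attention map {phi_arr.shape}")
    return (base * phi_arr).sum(axis=(-2, -1))


def average_kernel(kernel, phi):
    """Modulation averaged over the map extent: modulate(k, phi) / (H * W)."""
    phi_arr = _as_phi(phi)
    h, w = phi_arr.shape
    return modulate_kernel(kernel, phi) / float(h * w)


def compute_offsets(phi, kernel_extent: tuple[int, int]) -> OffsetField:
    """u_i = 1/2 sum_mn phi_mn (m - i);  v_j = 1/2 sum_mn phi_mn (n - j)."""
    phi_arr = _as_phi(phi)
    m_grid, n_grid = np.meshgrid(
        np.arange(phi_arr.shape[0]), np.arange(phi_arr.shape[1]), indexing="ij")
    m_bar = (phi_arr * m_grid).sum()
    n_bar = (phi_arr * n_grid).sum()
    rows, cols = kernel_extent
    u = 0.5 * (m_bar - np.arange(rows, dtype=np.float64))
    v = 0.5 * (n_bar - np.arange(cols, dtype=np.float64))
    return OffsetField(u=u, v=v)


def _bilinear_sample(image: np.ndarray, dr: float, dc: float) -> np.ndarray:
    """Whole-image fractional shift, zero outside the frame (single channel)."""
    x = image[None, None]
    out = ad.bilinear_shift2d(x, np.array([dr]), np.array([dc]))
    return out[0, 0]


def deformable_conv(image, kernel, offsets: OffsetField,
                    mode: str = "base_grid") -> np.ndarray:
    """Single-channel deformable cross-correlation (reference implementation).

    base_grid:  out(x,y) = sum_ij k_ij * I(x + (i-c_r) + u_i, y + (j-c_c) + v_j)
    literal:    out(x,y) = sum_ij k_ij * I(x + u_i, y + v_j)

    Fractional coordinates are resolved bilinearly; samples outside the frame
    read zero.  ``kernel`` holds the (already modulated/averaged) spatial tap
    coefficients.
    """
    img = np.asarray(image.values if isinstance(image, FeatureMap) else image,
                     dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("reference deformable_conv expects a 2-D single-channel input")
    k = _as_kernel_base(kernel)
    if isinstance(kernel, AdaptiveKernel) and kernel.averaged is not None:
        k = np.asarray(kernel.averaged, dtype=np.float64)
    if k.ndim != 2:
        raise ValueError("kernel must be a 2-D tap array")
    if not (np.isfinite(offsets.u).all() and np.isfinite(offsets.v).all()):
        raise ValueError("offsets contain NaN/Inf")
    kh, kw = k.shape
    if offsets.u.size != kh or offsets.v.size != kw:
        raise ValueError("offset field length must equal the kernel extent per axis")
    if mode not in ("base_grid", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    cr, cc = (kh - 1) / 2.0, (kw - 1) / 2.0
    out = np.zeros_like(img)
    for i in range(kh):
        for j in range(kw):
            dr = offsets.u[i] + ((i - cr) if mode == "base_grid" else 0.0)
            dc = offsets.v[j] + ((j - cc) if mode == "base_grid" else 0.0)
            out += k[i, j] * _bilinear_sample(img, dr, dc)
    return out


def _central_diff(phi: np.ndarray, axis: int) -> np.ndarray:
    """Central differences with replicated borders along one axis."""
    padded = np.pad(phi, [(1, 1) if ax == axis else (0, 0) for ax in range(phi.ndim)],
                    mode="edge")
    lo = [slice(None)] * phi.ndim
    hi = [slice(None)] * phi.ndim
    lo[axis] = slice(0, phi.shape[axis])
    hi[axis] = slice(2, phi.shape[axis] + 2)
    return (padded[tuple(hi)] - padded[tuple(lo)]) / 2.0


def literal_kernel_update(kernel, phi, step: float = 1.0) -> AdaptiveKernel:
    """The printed kernel update rule, exposed as a standalone auditable op.

    dW_ij = sum_mn k_ij^mn * phi_mn * (dphi/dx)_mn * (dphi/dy)_mn with
    central-difference map gradients (replicated borders), then
    k_ij^mn <- k_ij^mn - step * phi_mn * dW_ij (reading dk^mn/dW = phi_mn
    from the modulation linkage).  Not used by default gradient training.
    """
    base = _as_kernel_base(kernel)
    phi_arr = _as_phi(phi)
    if base.shape[-2:] != phi_arr.shape:
        raise ValueError("kernel extent does not match attention map")
    gx = _central_diff(phi_arr, axis=0)
    gy = _central_diff(phi_arr, axis=1)
    delta_w = (base * phi_arr * gx * gy).sum(axis=(-2, -1))
    new_base = base - step * phi_arr * np.expand_dims(delta_w, axis=(-2, -1)) \
        if base.ndim > 2 else base - step * phi_arr * delta_w
    return AdaptiveKernel(base=new_base, weight_delta=np.asarray(delta_w))


# ---------------------------------------------------------------------------
# trainable backbone (autodiff path)

def _pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Adaptive average-pooling as a constant (n_out, n_in) matrix."""
    mat = np.zeros((n_out, n_in))
    for b in range(n_out):
        lo = (b * n_in) // n_out
        hi = ((b + 1) * n_in) // n_out
        mat[b, lo:hi] = 1.0 / (hi - lo)
    return mat


def attention_batched(x, eps: float = 1e-12):
    """Per-image attention map for NCHW activations: mean |.| over channels,
    normalized to sum 1 per image.  Works on arrays or tensors."""
    a = ad.tmean(ad.absolute(x), axis=1)  # (N, H, W)
    total = ad.tsum(a, axis=(1, 2), keepdims=True)
    return ad.div(a, ad.add(total, eps))


def pool_attention(phi, extent: tuple[int, int] = (3, 3)):
    """Pool a per-image (N, H, W) map to the kernel extent and renormalize."""
    n, h, w = (phi.data.shape if ad.is_tensor(phi) else phi.shape)
    pr = _pool_matrix(h, extent[0])
    pc = _pool_matrix(w, extent[1]).T
    pooled = ad.matmul(ad.matmul(pr, phi), pc)  # (N, kh, kw)
    total = ad.tsum(pooled, axis=(1, 2), keepdims=True)
    return ad.div(pooled, ad.add(total, 1e-12))


def offsets_batched(phi_k):
    """Row/col offsets from per-image pooled maps: u = 1/2 (m_bar - i)."""
    shape = phi_k.data.shape if ad.is_tensor(phi_k) else phi_k.shape
    _, kh, kw = shape
    m_grid, n_grid = np.meshgrid(np.arange(kh, dtype=np.float64),
                                 np.arange(kw, dtype=np.float64), indexing="ij")
    m_bar = ad.tsum(ad.mul(phi_k, m_grid), axis=(1, 2), keepdims=True)  # (N,1,1)
    n_bar = ad.tsum(ad.mul(phi_k, n_grid), axis=(1, 2), keepdims=True)
    u = ad.mul(0.5, ad.sub(ad.reshape(m_bar, (-1, 1)), np.arange(kh, dtype=np.float64)))
    v = ad.mul(0.5, ad.sub(ad.reshape(n_bar, (-1, 1)), np.arange(kw, dtype=np.float64)))
    return u, v  # each (N, k)


def deformable_conv_batched(x, weight, phi_k, u, v, bias=None, mode: str = "base_grid"):
    """Batched multi-channel deformable convolution (differentiable).

    x: (N, C, H, W); weight: (O, C, kh, kw); phi_k: (N, kh, kw) pooled
    attention; u, v: (N, kh)/(N, kw) per-image offsets.  Tap coefficients are
    modulated per image as w * (kh*kw) * phi_k[i, j], so a uniform map leaves
    the weights unchanged and, with zero offsets in base_grid mode, the op
    reduces exactly to ordinary convolution (same-size, zero padded).
    """
    shape = x.data.shape if ad.is_tensor(x) else np.asarray(x).shape
    n, c, h, w_sz = shape
    wshape = weight.data.shape if ad.is_tensor(weight) else np.asarray(weight).shape
    o, c2, kh, kw = wshape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c} vs kernel {c2}")
    cr, cc = (kh - 1) / 2.0, (kw - 1) / 2.0
    scale = float(kh * kw)
    out = None
    for i in range(kh):
        for j in range(kw):
            du = ad.getitem(u, (slice(None), i))
            dv = ad.getitem(v, (slice(None), j))
            if mode == "base_grid":
                du = ad.add(du, i - cr)
                dv = ad.add(dv, j - cc)
            elif mode != "literal":
                raise ValueError(f"unknown mode {mode!r}")
            sx = ad.bilinear_shift2d(x, du, dv)  # (N, C, H, W)
            modulation = ad.reshape(
                ad.mul(ad.getitem(phi_k, (slice(None), i, j)), scale), (-1, 1, 1, 1))
            sxm = ad.reshape(ad.mul(sx, modulation), (n, c, h * w_sz))
            w_tap = ad.getitem(weight, (slice(None), slice(None), i, j))  # (O, C)
            term = ad.matmul(w_tap, sxm)  # (N, O, H*W)
            out = term if out is None else ad.add(out, term)
    out = ad.reshape(out, (n, o, h, w_sz))
    if bias is not None:
        out = ad.add(out, ad.reshape(bias, (1, -1, 1, 1)))
    return out


class _ResidualBlock(Module):
    """Conv-(deformable conv)-shortcut residual block with ReLU activations.

    With ``deformable=False`` the final convolution is a plain zero-offset,
    unmodulated convolution — the ablation configuration.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator, kernel: int = 3):
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.kernel = kernel
        k = kernel
        self.w1 = ad.parameter(he_normal(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.b1 = ad.parameter(np.zeros(out_ch))
        self.w2 = ad.parameter(he_normal(rng, (out_ch, out_ch, k, k), out_ch * k * k))
        self.b2 = ad.parameter(np.zeros(out_ch))
        if in_ch != out_ch or stride != 1:
            self.wsc = ad.parameter(he_normal(rng, (out_ch, in_ch, 1, 1), in_ch))
        else:
            self.wsc = None
        self.last_phi_k = None  # batch-mean pooled attention of the last pass

    def forward(self, x, deformable: bool = True, mode: str = "base_grid"):
        pad = self.kernel // 2
        h = ad.relu(ad.add(ad.conv2d(x, self.w1, stride=self.stride, padding=pad),
                           ad.reshape(self.b1, (1, -1, 1, 1))))
        if deformable:
            phi = attention_batched(h)
            phi_k = pool_attention(phi, (self.kernel, self.kernel))
            # batch-mean pooled map, kept for the optional literal update rule
            pk = (phi_k.data if ad.is_tensor(phi_k) else phi_k).mean(axis=0)
            total = pk.sum()
            self.last_phi_k = pk / total if total > 0 else np.full_like(pk, 1.0 / pk.size)
            u, v = offsets_batched(phi_k)
            y = deformable_conv_batched(h, self.w2, phi_k, u, v, bias=self.b2, mode=mode)
        else:
            y = ad.add(ad.conv2d(h, self.w2, stride=1, padding=pad),
                       ad.reshape(self.b2, (1, -1, 1, 1)))
        shortcut = x if self.wsc is None else ad.conv2d(x, self.wsc, stride=self.stride)
        return ad.relu(ad.add(y, shortcut))


class DeformableBackbone(Module):
    """Four residual blocks whose final convolutions are deformable.

    Channel widths and strides are configurable; the default
    (64, 128, 256, 512) at stride 2 each maps 256x256 inputs to a 16x16 grid
    (stride 16 overall).
    """

    def __init__(self, in_channels: int = 3,
                 widths: tuple[int, ...] = (64, 128, 256, 512),
                 strides: tuple[int, ...] = (2, 2, 2, 2),
                 seed: int = 0, deform_mode: str = "base_grid",
                 rng: np.random.Generator | None = None):
        if len(widths) != len(strides):
            raise ValueError("widths and strides must have equal length")
        if rng is None:
            rng = np.random.default_rng(seed)
        self.deform_mode = deform_mode
        self.blocks = []
        prev = in_channels
        for w_ch, s in zip(widths, strides):
            self.blocks.append(_ResidualBlock(prev, w_ch, s, rng))
            prev = w_ch
        self.out_channels = prev
        self.stride = int(np.prod(strides))

    def forward(self, x, deformable: bool = True):
        for block in self.blocks:
            x = block.forward(x, deformable=deformable, mode=self.deform_mode)
        return x


def adcn_forward(image, params: DeformableBackbone, ablation: bool = False) -> FeatureMap:
    """Run the backbone on one image and return the H' x W' x C feature map."""
    if isinstance(image, LabeledImage):
        arr = image.image
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected an H x W x 3 image")
    x = arr.transpose(2, 0, 1)[None]  # 1 x C x H x W
    out = params.forward(x, deformable=not ablation)
    values = (out.data if ad.is_tensor(out) else out)[0].transpose(1, 2, 0)
    return FeatureMap(values=values, stride=params.stride)


def export_heatmap(values: np.ndarray, path: str | Path) -> None:
    """Write a 2-D array as an 8-bit grayscale PNG heatmap."""
    from PIL import Image

    arr = np.asarray(values, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    norm = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    Image.fromarray((norm * 255).astype(np.uint8), mode="L").save(Path(path))
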