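"""Seeded generator of colonoscopy-like images with exact binary polyp masks.

Images are H x W x 3 floats in [0, 1]: a textured mucosa-like background with
vignetting and specular highlights, plus one to a few brighter, redder,
smooth-boundaried protrusions.  The ground-truth mask is the exact pixel
union of the generated protrusion regions; photometric effects (highlights,
vignette, noise) touch the image only, never the mask.

Each protrusion boundary is an ellipse whose radius is perturbed by a small
radial Fourier series r(theta) = r0 * (1 + sum_k a_k sin(k theta + phi_k)),
giving irregular but star-shaped (hence connected) regions.

Determinism: a single master seed drives everything; each image uses an
independent stream derived from ``(seed, index)``, so generation is
order-independent and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticConfig",
    "LabeledImage",
    "generate_polyp_mask",
    "render_labeled_image",
    "generate_dataset",
    "write_dataset",
]


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic colonoscopy-like image generator."""

    image_size: int = 256
    n_polyps_range: tuple[int, int] = (1, 3)
    radius_range: tuple[float, float] = (0.08, 0.25)  # fraction of image size
    boundary_harmonics: int = 4
    boundary_amplitude: float = 0.15
    axis_ratio_range: tuple[float, float] = (0.6, 1.0)
    polyp_color: tuple[float, float, float] = (0.82, 0.52, 0.45)
    background_color: tuple[float, float, float] = (0.52, 0.27, 0.22)
    texture_noise_sd: float = 0.04
    n_highlights: int = 3
    vignette_strength: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_polyps_range[0] > self.n_polyps_range[1]:
            raise ValueError("n_polyps_range must satisfy low <= high")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must satisfy low <= high")
        if self.axis_ratio_range[0] > self.axis_ratio_range[1]:
            raise ValueError("axis_ratio_range must satisfy low <= high")
        if not 0.0 <= self.boundary_amplitude < 1.0:
            raise ValueError("boundary_amplitude must be in [0, 1)")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must be in [0, 1]")


@dataclass
class LabeledImage:
    """An RGB image paired with its binary polyp mask."""

    image: np.ndarray  # H x W x 3 floats in [0, 1]
    mask: np.ndarray   # H x W uint8 in {0, 1}
    id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} sizes differ")
        if not np.isfinite(self.image).all():
            raise ValueError("image contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def generate_polyp_mask(size: int,
                        center: tuple[float, float],
                        radius: float,
                        harmonics: tuple[int, float] = (4, 0.15),
                        rng: np.random.Generator | None = None,
                        axis_ratio: float = 1.0,
                        orientation: float = 0.0) -> np.ndarray:
    """Rasterize one radially perturbed elliptical region on a size x size frame.

    The boundary in polar coordinates around ``center`` is
    ``rho(theta) <= 1 + sum_k a_k sin(k theta + phi_k)`` where ``rho`` is the
    ellipse-normalized distance (semi-axes ``radius`` and
    ``radius * axis_ratio`` rotated by ``orientation``).  Harmonic amplitudes
    ``a_k`` are drawn from ``rng`` and bounded so the perturbed radius stays
    positive, which keeps the region star-shaped and connected.

    A radius below one pixel yields an empty region.
    """
    mask = np.zeros((size, size), dtype=np.uint8)
    if radius < 1.0:
        return mask
    n_harm, amplitude = harmonics
    if rng is None:
        rng = np.random.default_rng(0)
    ks = np.arange(1, max(int(n_harm), 0) + 1)
    # 1/k falloff keeps sum|a_k| <= amplitude * H(n) < 1 for amplitude < ~0.4
    amps = amplitude * rng.uniform(0.3, 1.0, size=ks.size) / ks
    phases = rng.uniform(0.0, 2.0 * np.pi, size=ks.size)

    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    co, si = np.cos(orientation), np.sin(orientation)
    # coordinates in the rotated ellipse frame
    er = co * dr + si * dc
    ec = -si * dr + co * dc
    rho = np.hypot(er / radius, ec / (radius * axis_ratio))
    theta = np.arctan2(ec, er)
    boundary = np.ones_like(theta)
    for k, a, ph in zip(ks, amps, phases):
        boundary += a * np.sin(k * theta + ph)
    mask[rho <= boundary] = 1
    return mask


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean unit-scale low-frequency noise field."""
    raw = rng.normal(size=(size, size))
    sm = ndimage.gaussian_filter(raw, sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def render_labeled_image(config: SyntheticConfig,
                         rng: np.random.Generator,
                         image_id: str = "") -> LabeledImage:
    """Render one image/mask pair from the given stream."""
    s = config.image_size
    bg = np.asarray(config.background_color, dtype=np.float64)
    fg = np.asarray(config.polyp_color, dtype=np.float64)

    # mucosa-like background: base color + low-frequency texture + ripples
    image = np.empty((s, s, 3))
    tex = _smooth_noise(rng, s, sigma=s / 24.0)
    ripple = _smooth_noise(rng, s, sigma=s / 8.0)
    for ch in range(3):
        image[:, :, ch] = bg[ch] + config.texture_noise_sd * tex \
            + 0.5 * config.texture_noise_sd * ripple

    # polyps: exact union mask; image blended with a feathered edge
    n_polyps = int(rng.integers(config.n_polyps_range[0], config.n_polyps_range[1] + 1))
    mask = np.zeros((s, s), dtype=np.uint8)
    margin = 0.15 * s
    for _ in range(n_polyps):
        radius = s * rng.uniform(*config.radius_range)
        center = (rng.uniform(margin, s - margin), rng.uniform(margin, s - margin))
        axis_ratio = rng.uniform(*config.axis_ratio_range)
        orientation = rng.uniform(0.0, np.pi)
        region = generate_polyp_mask(
            s, center, radius, (config.boundary_harmonics, config.boundary_amplitude),
            rng, axis_ratio=axis_ratio, orientation=orientation)
        if not region.any():
            continue
        mask |= region
        feather = ndimage.gaussian_filter(region.astype(np.float64), max(1.0, radius / 12.0))
        feather = np.clip(feather, 0.0, 1.0)
        shade = 1.0 + 0.25 * _smooth_noise(rng, s, sigma=radius / 3.0)
        color_jitter = rng.normal(0.0, 0.02, size=3)
        for ch in range(3):
            poly_val = (fg[ch] + color_jitter[ch]) * shade
            image[:, :, ch] = image[:, :, ch] * (1.0 - feather) + poly_val * feather

    # specular highlights: small saturated gaussian blobs (image only)
    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    for _ in range(config.n_highlights):
        hr, hc = rng.uniform(0, s, size=2)
        sigma = rng.uniform(0.008, 0.02) * s
        blob = np.exp(-((rr - hr) ** 2 + (cc - hc) ** 2) / (2.0 * sigma ** 2))
        image += (rng.uniform(0.6, 1.0) * blob)[:, :, None]

    # vignette (image only)
    c0 = (s - 1) / 2.0
    rho2 = ((rr - c0) ** 2 + (cc - c0) ** 2) / (2.0 * c0 ** 2)
    image *= (1.0 - config.vignette_strength * rho2)[:, :, None]

    # pixel noise and clipping
    image += rng.normal(0.0, 0.3 * config.texture_noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return LabeledImage(image=image, mask=mask, id=image_id)


def _stream(seed: int, index: int) -> np.random.Generator:
    """Per-image generator derived from (seed, index); order-independent."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_dataset(n: int, config: SyntheticConfig,
                     seed: int | None = None) -> list[LabeledImage]:
    """Generate ``n`` labeled images, reproducible from ``(n, config, seed)``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if seed is None:
        seed = config.seed
    return [
        render_labeled_image(config, _stream(seed, i), image_id=f"synth_{i:05d}")
        for i in range(n)
    ]


def write_dataset(root: str | Path, dataset: list[LabeledImage],
                  image_format: str = "jpg") -> None:
    """Write a Kvasir-style layout: images/<id>.<fmt> and masks/<id>.png.

    Masks are 8-bit {0, 255} PNG.  ``image_format`` may be ``jpg`` (saved at
    maximum quality; still lossy) or ``png`` (exact up to 8-bit quantization).
    """
    from PIL import Image

    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for item in dataset:
        img8 = (np.clip(item.image, 0.0, 1.0) * 255.0).round().astype(np.uint8)
        im = Image.fromarray(img8)
        if image_format == "jpg":
            im.save(root / "images" / f"{item.id}.jpg", quality=100, subsampling=0)
        elif image_format == "png":
            im.save(root / "images" / f"{item.id}.png")
        else:
            raise ValueError(f"unsupported image format: {image_format!r}")
        mask8 = (np.asarray(item.mask, dtype=np.uint8) * 255)
        Image.fromarray(mask8, mode="L").save(root / "masks" / f"{item.id}.png")
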