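"""Paired image/mask dataset reading, resizing, affine augmentation and splits.

Coordinate convention (used consistently across the package): row-major,
0-based, origin at the top-left; affine transforms act on (row, col)
coordinates about the image center.  A positive 90-degree rotation maps the
pixel at (r, c) on an N x N frame to (c, N-1-r).

Masks are nominally 8-bit {0, 255}; binarization uses the midpoint threshold
(>= 128 is foreground).  Masks already on the {0, 1} scale binarize at 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .synthetic import LabeledImage

__all__ = [
    "DatasetSpec",
    "SplitIndices",
    "AffineParams",
    "MissingMaskError",
    "UnreadableFileError",
    "load_pairs",
    "preprocess_pair",
    "affine_augment",
    "sample_affine",
    "make_splits",
]

IMAGE_EXTENSIONS = (".jpg", ".jpeg", ".png", ".tif", ".tiff")


class MissingMaskError(FileNotFoundError):
    pass


class UnreadableFileError(OSError):
    pass


@dataclass
class DatasetSpec:
    """Location of a paired image/mask folder layout."""

    root: Path
    image_subdir: str = "images"
    mask_subdir: str = "masks"
    image_extensions: tuple[str, ...] = IMAGE_EXTENSIONS

    def __post_init__(self):
        self.root = Path(self.root)

    @property
    def image_dir(self) -> Path:
        return self.root / self.image_subdir

    @property
    def mask_dir(self) -> Path:
        return self.root / self.mask_subdir


@dataclass
class SplitIndices:
    """Train/validation indices plus k disjoint cross-validation folds."""

    train: np.ndarray
    val: np.ndarray
    folds: list[np.ndarray] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": [int(i) for i in self.train],
            "val": [int(i) for i in self.val],
            "folds": [[int(i) for i in f] for f in self.folds],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitIndices":
        payload = json.loads(Path(path).read_text())
        return cls(
            train=np.asarray(payload["train"], dtype=int),
            val=np.asarray(payload["val"], dtype=int),
            folds=[np.asarray(f, dtype=int) for f in payload["folds"]],
        )


def _read_image(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    except (OSError, ValueError) as exc:
        raise UnreadableFileError(f"cannot read image file: {path}") from exc


def _read_mask(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (OSError, ValueError) as exc:
        raise UnreadableFileError(f"cannot read mask file: {path}") from exc
    return (arr >= 128).astype(np.uint8)


def load_pairs(spec: DatasetSpec) -> list[LabeledImage]:
    """Load all image/mask pairs, sorted by stem; sizes are left untouched."""
    if not spec.image_dir.is_dir():
        raise FileNotFoundError(f"image directory does not exist: {spec.image_dir}")
    if not spec.mask_dir.is_dir():
        raise FileNotFoundError(f"mask directory does not exist: {spec.mask_dir}")
    images = sorted(
        (p for p in spec.image_dir.iterdir() if p.suffix.lower() in spec.image_extensions),
        key=lambda p: p.stem,
    )
    masks_by_stem: dict[str, Path] = {}
    for p in sorted(spec.mask_dir.iterdir()):
        if p.suffix.lower() in spec.image_extensions:
            masks_by_stem.setdefault(p.stem, p)
    pairs = []
    for img_path in images:
        mask_path = masks_by_stem.get(img_path.stem)
        if mask_path is None:
            raise MissingMaskError(f"no mask found for image stem {img_path.stem!r}")
        pairs.append(LabeledImage(
            image=_read_image(img_path),
            mask=_read_mask(mask_path),
            id=img_path.stem,
        ))
    return pairs


def _binarize(mask: np.ndarray) -> np.ndarray:
    # 8-bit scale masks threshold at the midpoint 128; {0,1} masks at 0.5
    threshold = 128.0 if mask.max(initial=0) > 1 else 0.5
    return (np.asarray(mask, dtype=np.float64) >= threshold).astype(np.uint8)


def preprocess_pair(pair: LabeledImage, target: int = 256) -> LabeledImage:
    """Resize to target x target: bilinear image in [0,1], nearest binarized mask."""
    if target < 32:
        raise ValueError("target size must be >= 32")
    mask = np.asarray(pair.mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    from skimage.transform import resize

    image = resize(np.asarray(pair.image, dtype=np.float64), (target, target),
                   order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    image = np.clip(image, 0.0, 1.0)
    mask_r = resize(mask.astype(np.float64), (target, target),
                    order=0, mode="edge", anti_aliasing=False, preserve_range=True)
    return LabeledImage(image=image, mask=_binarize(mask_r), id=pair.id)


@dataclass
class AffineParams:
    """Affine map about the image center in (row, col) coordinates.

    ``rotation_deg`` follows the package convention: +90 degrees maps
    (r, c) -> (c, N-1-r).  Scale > 1 enlarges content; shear is applied to the
    column coordinate; flips mirror rows/columns before the linear map.
    """

    rotation_deg: float = 0.0
    scale: float = 1.0
    shear_deg: float = 0.0
    translate: tuple[float, float] = (0.0, 0.0)
    flip_h: bool = False  # mirror columns
    flip_v: bool = False  # mirror rows

    def matrix(self) -> np.ndarray:
        """Forward 2x2 linear part acting on (row, col) offsets from center."""
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        sh = np.tan(np.deg2rad(self.shear_deg))
        shear = np.array([[1.0, sh], [0.0, 1.0]])
        flip = np.diag([-1.0 if self.flip_v else 1.0, -1.0 if self.flip_h else 1.0])
        return self.scale * rot @ shear @ flip


def affine_augment(pair: LabeledImage, transform: AffineParams,
                   fill: float = 0.0) -> LabeledImage:
    """Apply the same geometric map to image (bilinear) and mask (nearest).

    ``fill`` is the constant used for pixels mapped from outside the frame
    (the mask always fills with background).
    """
    fwd = transform.matrix()
    if abs(np.linalg.det(fwd)) < 1e-12:
        raise ValueError("singular affine transform")
    h, w = pair.mask.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    inv = np.linalg.inv(fwd)
    # scipy maps output coords -> input coords: in = inv @ (out - c - t) + c
    offset = center - inv @ (center + np.asarray(transform.translate, dtype=np.float64))

    image = np.empty_like(np.asarray(pair.image, dtype=np.float64))
    for ch in range(image.shape[2]):
        image[:, :, ch] = ndimage.affine_transform(
            pair.image[:, :, ch], inv, offset=offset, order=1, mode="constant",
            cval=fill)
    image = np.clip(image, 0.0, 1.0)
    mask = ndimage.affine_transform(
        pair.mask.astype(np.float64), inv, offset=offset, order=0,
        mode="constant", cval=0.0)
    return LabeledImage(image=image, mask=_binarize(mask), id=pair.id)


# default augmentation ranges; the source protocol names affine transforms
# without parameter ranges, so these are configurable conventions
DEFAULT_AUGMENT_RANGES = {
    "rotation_deg": (-30.0, 30.0),
    "scale": (0.8, 1.2),
    "shear_deg": (-10.0, 10.0),
    "flip_prob": 0.5,
}


def sample_affine(rng: np.random.Generator, ranges: dict | None = None) -> AffineParams:
    """Draw random augmentation parameters from the configured ranges."""
    r = dict(DEFAULT_AUGMENT_RANGES)
    if ranges:
        r.update(ranges)
    return AffineParams(
        rotation_deg=rng.uniform(*r["rotation_deg"]),
        scale=rng.uniform(*r["scale"]),
        shear_deg=rng.uniform(*r["shear_deg"]),
        flip_h=bool(rng.random() < r["flip_prob"]),
        flip_v=False,
    )


def make_splits(n: int, ratio: float = 0.8, k: int = 5, seed: int = 0) -> SplitIndices:
    """Shuffled train/val split at ``ratio`` plus k balanced disjoint folds."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} items")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * ratio))
    folds = [np.sort(f) for f in np.array_split(rng.permutation(n), k)]
    return SplitIndices(
        train=np.sort(perm[:n_train]),
        val=np.sort(perm[n_train:]),
        folds=folds,
    )
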