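"""Image/mask/annotation I/O, window cropping and dataset splitting.

Grayscale images are exchanged as 8- or 16-bit PNG/TIFF and held in memory
as float arrays in [0, 1] (scaled by bit depth).  Masks are strict 0/255
8-bit PNGs — any other value is an annotation error, never silently
thresholded.  Polygon annotations follow the LabelMe JSON dialect (only
``shapes[].label`` and ``shapes[].points`` are consumed; all labels merge
into one binary follicle class).  Pixel (i, j) covers the unit square whose
centre is (x, y) = (j + 0.5, i + 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "AnnotationError", "PolygonAnnotation", "DatasetManifest",
    "load_image", "save_image", "load_mask", "save_mask",
    "load_labelme", "polygons_to_mask", "crop_window",
    "split_dataset", "make_manifest",
]

_LUMA = (0.299, 0.587, 0.114)


class AnnotationError(ValueError):
    """Malformed mask or polygon annotation."""


@dataclass(frozen=True)
class PolygonAnnotation:
    """A labelled polygon: ordered (x, y) vertices, at least 3 of them."""

    label: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise AnnotationError(f"polygon '{self.label}' has {len(self.points)} < 3 vertices")


@dataclass(frozen=True)
class DatasetManifest:
    """Split assignment of (image, mask) path pairs."""

    entries: tuple[tuple[str, str, str], ...]  # (image_path, mask_path, split)
    split_seed: int
    ratios: tuple[float, float, float]

    def paths(self, split: str) -> list[tuple[str, str]]:
        return [(img, msk) for img, msk, s in self.entries if s == split]


def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF as a float image in [0, 1] (RGB collapsed by luminance)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = 1.0
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
        else:
            arr = arr[:, :, 0] * _LUMA[0] + arr[:, :, 1] * _LUMA[1] + arr[:, :, 2] * _LUMA[2]
    arr = arr.astype(float) / scale
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise IOError(f"unsupported pixel range in {path}")
    return arr


def save_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    img = np.asarray(img, dtype=float)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    q = np.round(img * 255.0).astype(np.uint8)
    Image.fromarray(q, mode="L").save(Path(path))


def load_mask(path) -> np.ndarray:
    """Load a strict {0, 255} PNG mask as a {0, 1} uint8 array."""
    path = Path(path)
    try:
        arr = np.asarray(Image.open(path))
    except Exception as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim != 2:
        raise AnnotationError(f"mask {path} is not single-channel")
    values = np.unique(arr)
    if not np.isin(values, (0, 255)).all():
        raise AnnotationError(
            f"mask {path} contains values other than 0/255: {values[:10]}")
    return (arr > 0).astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as 0/255 8-bit PNG."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(Path(path))


def load_labelme(path) -> list[PolygonAnnotation]:
    """Read polygon shapes from a LabelMe-style JSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    shapes = doc.get("shapes")
    if shapes is None:
        raise AnnotationError(f"{path}: no 'shapes' field")
    out = []
    for shape in shapes:
        pts = tuple((float(x), float(y)) for x, y in shape["points"])
        out.append(PolygonAnnotation(label=str(shape.get("label", "follicle")), points=pts))
    return out


def polygons_to_mask(annotations, height: int, width: int) -> np.ndarray:
    """Rasterise the union of filled polygons to a binary mask.

    Pixel (i, j) is foreground iff its centre (j + 0.5, i + 0.5) lies inside
    any polygon under the even-odd (crossing-number) rule.
    """
    mask = np.zeros((height, width), dtype=bool)
    if not annotations:
        return mask.astype(np.uint8)
    yy, xx = np.meshgrid(np.arange(height) + 0.5, np.arange(width) + 0.5, indexing="ij")
    for ann in annotations:
        pts = np.asarray(ann.points, dtype=float)
        inside = np.zeros((height, width), dtype=bool)
        n = len(pts)
        for k in range(n):
            x1, y1 = pts[k]
            x2, y2 = pts[(k + 1) % n]
            crosses = (y1 <= yy) != (y2 <= yy)
            with np.errstate(divide="ignore", invalid="ignore"):
                x_at = x1 + (yy - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (xx < x_at)
        mask |= inside
    return mask.astype(np.uint8)


def crop_window(img: np.ndarray, top_left: tuple[int, int],
                size: tuple[int, int] = (256, 512)) -> np.ndarray:
    """Exact sub-grid copy: rows [r, r+h), cols [c, c+w)."""
    img = np.asarray(img)
    r, c = top_left
    h, w = size
    if r < 0 or c < 0 or r + h > img.shape[0] or c + w > img.shape[1]:
        raise ValueError(
            f"window {top_left}+{size} out of bounds for image {img.shape}")
    return img[r:r + h, c:c + w].copy()


def split_dataset(n: int, ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int = 0) -> list[str]:
    """Deterministic shuffled train/val/test assignment of ``n`` items.

    Sizes are ``floor(n * r_train)`` and ``floor(n * r_val)``; the test set
    receives the remainder.  Returns one of "train"/"val"/"test" per index.
    """
    if n < 3:
        raise ValueError("need at least 3 items to split")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be three non-negative reals summing to 1, got {ratios}")
    n_train = int(np.floor(n * ratios[0]))
    n_val = int(np.floor(n * ratios[1]))
    order = np.random.default_rng(seed).permutation(n)
    labels = [""] * n
    for pos, idx in enumerate(order):
        if pos < n_train:
            labels[idx] = "train"
        elif pos < n_train + n_val:
            labels[idx] = "val"
        else:
            labels[idx] = "test"
    return labels


def make_manifest(pairs: list[tuple[str, str]],
                  ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int = 0) -> DatasetManifest:
    """Assign (image, mask) path pairs to splits."""
    labels = split_dataset(len(pairs), ratios, seed)
    entries = tuple((img, msk, lab) for (img, msk), lab in zip(pairs, labels))
    return DatasetManifest(entries=entries, split_seed=seed, ratios=tuple(ratios))
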