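"""Synthetic ultrasound-like speckle phantoms with exact follicle masks.

Ovarian follicles appear in B-mode ultrasound as dark (anechoic) roughly
elliptical regions embedded in brighter tissue, degraded by three stressors:
strong multiplicative speckle noise, blurred boundaries, and a variable
number of follicles per image.  The generator emulates exactly these:

1. a smooth low-frequency tissue background around ``tissue_level``;
2. ``k`` random ellipses (uniform count over ``follicle_count_range``),
   rejection-sampled to be near-disjoint (pairwise mask IoU at most
   ``overlap_max_iou``);
3. the ground-truth mask rasterised from the exact ellipse geometry
   (pixel centres at half-integer coordinates);
4. an intensity template with follicle interiors at ``anechoic_level``,
   blended into tissue through a Gaussian blur of the mask
   (``boundary_blur_sigma`` — the blurred edge);
5. multiplication by unit-mean gamma speckle with shape ``speckle_shape``
   (smaller shape = stronger noise; ``None`` disables speckle);
6. clipping to [0, 1].

The mask is the pre-blur geometry — the anatomical boundary a clinician
would trace — not the blurred image boundary.  Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import save_image, save_mask

__all__ = ["PhantomConfig", "Ellipse", "PhantomSample",
           "rasterize_ellipses", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class Ellipse:
    """Centre (row, col), semi-axes (a >= b, pixels), rotation (radians)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


@dataclass(frozen=True)
class PhantomConfig:
    height: int = 256
    width: int = 512
    follicle_count_range: tuple[int, int] = (1, 6)
    axis_range: tuple[float, float] = (10.0, 60.0)
    anechoic_level: float = 0.08
    tissue_level: float = 0.5
    background_amplitude: float = 0.05
    boundary_blur_sigma: float = 2.0
    speckle_shape: float | None = 3.0
    radial_perturbation: float = 0.0
    overlap_max_iou: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.follicle_count_range
        if not (1 <= lo <= hi):
            raise ValueError("follicle_count_range must satisfy 1 <= lo <= hi")
        alo, ahi = self.axis_range
        if not (0 < alo <= ahi):
            raise ValueError("axis_range must satisfy 0 < lo <= hi")
        if 2 * ahi >= min(self.height, self.width):
            raise ValueError(
                f"largest axis {ahi} does not fit in a {self.height}x{self.width} image")
        for name in ("anechoic_level", "tissue_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.boundary_blur_sigma < 0:
            raise ValueError("boundary_blur_sigma must be >= 0")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive (or None to disable)")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray          # (H, W) float in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    follicles: tuple[Ellipse, ...]


def _pixel_centers(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.meshgrid(np.arange(height) + 0.5, np.arange(width) + 0.5, indexing="ij")
    return yy, xx


def _ellipse_mask(e: Ellipse, yy: np.ndarray, xx: np.ndarray,
                  perturbation: float = 0.0, rng: np.random.Generator | None = None
                  ) -> np.ndarray:
    cy, cx = e.center
    a, b = e.semi_axes
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(e.rotation), np.sin(e.rotation)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    r2 = u * u + v * v
    if perturbation > 0.0 and rng is not None:
        # low-frequency radial wobble: r(phi) modulated by 2 harmonics
        phi = np.arctan2(v, u)
        amp = perturbation * rng.uniform(0.5, 1.0, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        wobble = 1.0 + amp[0] * np.cos(2 * phi + phase[0]) + amp[1] * np.cos(3 * phi + phase[1])
        return r2 <= wobble ** 2
    return r2 <= 1.0


def rasterize_ellipses(ellipses, height: int, width: int) -> np.ndarray:
    """Binary union mask of ellipses, pixel centres at half-integers."""
    yy, xx = _pixel_centers(height, width)
    mask = np.zeros((height, width), dtype=bool)
    for e in ellipses:
        mask |= _ellipse_mask(e, yy, xx)
    return mask.astype(np.uint8)


def _background_field(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field around tissue_level."""
    gh = max(cfg.height // 32, 2)
    gw = max(cfg.width // 32, 2)
    coarse = rng.standard_normal((gh, gw))
    field = ndimage.zoom(coarse, (cfg.height / gh, cfg.width / gw), order=3)
    field = field[:cfg.height, :cfg.width]
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    bg = cfg.tissue_level + cfg.background_amplitude * field
    return np.clip(bg, 0.0, 1.0)


def generate_phantom(cfg: PhantomConfig, rng: np.random.Generator | int) -> PhantomSample:
    """Draw one phantom sample; deterministic given (cfg, rng state)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    bg = _background_field(cfg, rng)
    yy, xx = _pixel_centers(cfg.height, cfg.width)

    k = int(rng.integers(cfg.follicle_count_range[0], cfg.follicle_count_range[1] + 1))
    accepted: list[Ellipse] = []
    accepted_masks: list[np.ndarray] = []
    retries = 0
    while len(accepted) < k and retries <= 100:
        a = float(rng.uniform(*cfg.axis_range))
        b = float(rng.uniform(cfg.axis_range[0], a))
        theta = float(rng.uniform(0.0, np.pi))
        margin = a  # bounding radius of the rotated ellipse
        cy = float(rng.uniform(margin, cfg.height - margin))
        cx = float(rng.uniform(margin, cfg.width - margin))
        cand = Ellipse(center=(cy, cx), semi_axes=(a, b), rotation=theta)
        m = _ellipse_mask(cand, yy, xx, cfg.radial_perturbation, rng)
        ok = True
        for prev in accepted_masks:
            inter = np.sum(m & prev)
            if inter:
                union = np.sum(m | prev)
                if inter / union > cfg.overlap_max_iou:
                    ok = False
                    break
        if ok:
            accepted.append(cand)
            accepted_masks.append(m)
        else:
            retries += 1

    mask = np.zeros((cfg.height, cfg.width), dtype=bool)
    for m in accepted_masks:
        mask |= m
    mask = mask.astype(np.uint8)

    if cfg.boundary_blur_sigma > 0:
        blend = ndimage.gaussian_filter(mask.astype(float), cfg.boundary_blur_sigma,
                                        mode="reflect")
    else:
        blend = mask.astype(float)
    template = bg * (1.0 - blend) + cfg.anechoic_level * blend

    if cfg.speckle_shape is not None:
        speckle = rng.gamma(cfg.speckle_shape, 1.0 / cfg.speckle_shape,
                            size=template.shape)
        image = template * speckle
    else:
        image = template
    image = np.clip(image, 0.0, 1.0)
    return PhantomSample(image=image, mask=mask, follicles=tuple(accepted))


def generate_dataset(cfg: PhantomConfig, n: int, seed: int, out_dir) -> dict:
    """Write ``n`` phantom image/mask PNG pairs plus a JSON manifest.

    Each sample gets its own integer seed drawn from a master generator, so
    the whole dataset is reproducible from (cfg, seed) and any single sample
    from its recorded per-sample seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    sample_seeds = [int(s) for s in master.integers(0, 2 ** 31, size=n)]
    entries = []
    for i, s in enumerate(sample_seeds):
        sample = generate_phantom(cfg, s)
        img_path = out_dir / "images" / f"{i:05d}.png"
        mask_path = out_dir / "masks" / f"{i:05d}.png"
        save_image(sample.image, img_path)
        save_mask(sample.mask, mask_path)
        entries.append({
            "image": str(img_path.relative_to(out_dir)),
            "mask": str(mask_path.relative_to(out_dir)),
            "seed": s,
            "follicles": [{"center": list(e.center), "semi_axes": list(e.semi_axes),
                           "rotation": e.rotation} for e in sample.follicles],
        })
    manifest = {"config": asdict(cfg), "seed": seed, "n": n, "entries": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
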