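"""Procedural grayscale test phantoms.

Restoration pipelines need ground-truth images with controlled structure:
sharp plateaus to expose blur, a dark background to expose noise, sparse
supports to exercise the l1 model. The ``chest`` phantom mimics the gross
intensity layout of an axial chest CT slice — dark air background, a bright
bony shell, dark lung fields, mid-gray mediastinum and a bright aorta-like
disc — composed from anti-aliased ellipses. No claim of anatomical accuracy
is made; the phantoms only reproduce the contrast structure that makes
restoration quality measurable.

All shapes are rasterized at 4x supersampling and block-averaged, so edges
are anti-aliased and blur/deblur effects are not confounded with
rasterization artifacts. Generation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import InvalidParameterError

PHANTOM_KINDS = ("chest", "shepp_like", "sparse_spots", "flat")

_SUPERSAMPLE = 4


@dataclass(frozen=True)
class PhantomSpec:
    """What phantom to generate.

    ``contrast_jitter`` perturbs each plateau intensity uniformly by up to
    its value (seeded), so repeated studies do not all use identical
    contrasts. ``n_spots`` only applies to the ``sparse_spots`` kind; the
    default scales with image size while keeping <= 5% of pixels nonzero.
    """

    size: int = 128
    kind: str = "chest"
    seed: int = 0
    contrast_jitter: float = 0.0
    n_spots: Optional[int] = None

    def __post_init__(self):
        if self.size < 8:
            raise InvalidParameterError("size must be >= 8")
        if self.contrast_jitter < 0:
            raise InvalidParameterError("contrast_jitter must be >= 0")
        if self.kind not in PHANTOM_KINDS:
            raise InvalidParameterError(
                f"kind must be one of {PHANTOM_KINDS}, got {self.kind!r}"
            )


def _grid(size: int):
    """Supersampled pixel-center coordinates normalized to [-1, 1]."""
    m = _SUPERSAMPLE
    c = (np.arange(m * size) + 0.5) / (m * size) * 2.0 - 1.0
    return np.meshgrid(c, c, indexing="xy")


def _paint_ellipse(canvas, xx, yy, cx, cy, a, b, angle_deg, value):
    """Overwrite canvas pixels inside the ellipse with ``value``."""
    t = np.deg2rad(angle_deg)
    xr = (xx - cx) * np.cos(t) + (yy - cy) * np.sin(t)
    yr = -(xx - cx) * np.sin(t) + (yy - cy) * np.cos(t)
    canvas[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] = value


def _downsample(canvas: np.ndarray, size: int) -> np.ndarray:
    m = _SUPERSAMPLE
    return canvas.reshape(size, m, size, m).mean(axis=(1, 3))


def _jitter(levels: dict, jitter: float, rng: np.random.Generator) -> dict:
    if jitter == 0.0:
        return dict(levels)
    return {
        k: float(np.clip(v + rng.uniform(-jitter, jitter), 0.0, 1.0))
        for k, v in levels.items()
    }


def _chest(size: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    levels = _jitter(
        {"bone": 0.9, "soft": 0.5, "lung": 0.15, "aorta": 0.9}, jitter, rng
    )
    xx, yy = _grid(size)
    c = np.zeros_like(xx)
    _paint_ellipse(c, xx, yy, 0.0, 0.0, 0.92, 0.72, 0, levels["bone"])  # rib shell
    _paint_ellipse(c, xx, yy, 0.0, 0.0, 0.82, 0.62, 0, levels["soft"])  # soft tissue
    _paint_ellipse(c, xx, yy, -0.40, -0.02, 0.30, 0.44, 8, levels["lung"])
    _paint_ellipse(c, xx, yy, 0.40, -0.02, 0.30, 0.44, -8, levels["lung"])
    _paint_ellipse(c, xx, yy, 0.0, 0.42, 0.14, 0.12, 0, levels["bone"])  # vertebra
    _paint_ellipse(c, xx, yy, 0.06, 0.08, 0.10, 0.10, 0, levels["aorta"])
    return _downsample(c, size)


def _shepp_like(size: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    levels = _jitter(
        {"shell": 1.0, "brain": 0.25, "vent": 0.08, "lesion": 0.7}, jitter, rng
    )
    xx, yy = _grid(size)
    c = np.zeros_like(xx)
    _paint_ellipse(c, xx, yy, 0.0, 0.0, 0.78, 0.92, 0, levels["shell"])
    _paint_ellipse(c, xx, yy, 0.0, 0.0, 0.70, 0.84, 0, levels["brain"])
    _paint_ellipse(c, xx, yy, -0.2, 0.0, 0.14, 0.35, 18, levels["vent"])
    _paint_ellipse(c, xx, yy, 0.2, 0.0, 0.14, 0.35, -18, levels["vent"])
    _paint_ellipse(c, xx, yy, 0.0, -0.5, 0.08, 0.08, 0, levels["lesion"])
    _paint_ellipse(c, xx, yy, 0.0, 0.45, 0.05, 0.09, 0, levels["lesion"])
    return _downsample(c, size)


def _spot_radius(size: int) -> float:
    """Disc radius in pixels, shrunk on small images so spots stay sparse."""
    return min(2.5, size / 16.0)


def default_spot_count(size: int) -> int:
    radius = _spot_radius(size)
    cap = int(0.05 * size * size / (np.pi * radius**2))
    return max(1, min(size // 16, cap))


def _sparse_spots(
    size: int, n_spots: Optional[int], jitter: float, rng: np.random.Generator
) -> np.ndarray:
    radius = _spot_radius(size)
    n = n_spots if n_spots is not None else default_spot_count(size)
    max_spots = int(0.05 * size * size / (np.pi * radius**2))
    if n > max_spots:
        raise InvalidParameterError(
            f"{n} spots of radius {radius} exceed 5% occupancy on a "
            f"{size}x{size} image (max {max_spots})"
        )
    m = _SUPERSAMPLE
    cx = (np.arange(m * size) + 0.5) / m  # pixel coordinates
    xx, yy = np.meshgrid(cx, cx, indexing="xy")
    canvas = np.zeros_like(xx)
    centers: list = []
    min_sep = 2 * radius + 3.0
    margin = radius + 1.0
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise InvalidParameterError(
                f"could not place {n} non-overlapping spots on a {size}x{size} image"
            )
        p = rng.uniform(margin, size - margin, size=2)
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in centers):
            centers.append(p)
            value = float(rng.uniform(0.5, 1.0))
            canvas[(xx - p[0]) ** 2 + (yy - p[1]) ** 2 <= radius**2] = value
    return _downsample(canvas, size)


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom described by ``spec`` as a [0, 1] float image."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "flat":
        return np.full((spec.size, spec.size), 0.5)
    if spec.kind == "chest":
        return _chest(spec.size, spec.contrast_jitter, rng)
    if spec.kind == "shepp_like":
        return _shepp_like(spec.size, spec.contrast_jitter, rng)
    if spec.kind == "sparse_spots":
        return _sparse_spots(spec.size, spec.n_spots, spec.contrast_jitter, rng)
    raise InvalidParameterError(f"unknown phantom kind {spec.kind!r}")
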