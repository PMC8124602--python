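"""Depth-image preprocessing: invert to heights, scale to 8-bit gray,
resize to the model's square input.

The chain is invert -> scale -> resize, deterministic, single channel
throughout; channel replication for the CNN input happens in the model,
not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pigdepth.units import CAMERA_DISTANCE_MM

__all__ = [
    "PreprocessConfig",
    "invert_depth",
    "scale_to_gray",
    "resize_gray",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    camera_distance_mm: float = CAMERA_DISTANCE_MM
    target_size: int = 224


def invert_depth(depth, camera_distance_mm: float = CAMERA_DISTANCE_MM) -> np.ndarray:
    """Map camera distances to heights above the platform:
    ``height = camera_distance - depth``.

    Pixels reading farther than the camera distance (negative height) are
    clipped to 0; the number clipped is logged as a warning.
    """
    arr = np.asarray(depth, dtype=np.float64)
    heights = camera_distance_mm - arr
    n_clipped = int(np.count_nonzero(heights < 0))
    if n_clipped:
        log.warning(
            "invert_depth: clipped %d pixel(s) with depth beyond the camera "
            "distance (%g mm) to zero height",
            n_clipped,
            camera_distance_mm,
        )
        heights = np.clip(heights, 0.0, None)
    return heights


def scale_to_gray(
    heights, camera_distance_mm: float = CAMERA_DISTANCE_MM
) -> np.ndarray:
    """Linearly map heights in [0, camera_distance] onto integers 0..255.

    Round-half-up, so the platform (0 mm) maps to 0 and the camera plane
    maps to 255 exactly, and the map is monotone non-decreasing.
    """
    arr = np.asarray(heights, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))
        raise ValueError(
            f"non-finite height(s) at coordinates {bad[:10].tolist()}"
            + ("..." if len(bad) > 10 else "")
        )
    scaled = arr * (255.0 / camera_distance_mm)
    gray = np.floor(scaled + 0.5)  # round half up
    return np.clip(gray, 0, 255).astype(np.uint8)


def _bilinear_coords(n_out: int, n_in: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source interpolation weights for one axis, half-pixel-centre aligned."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    i0 = np.floor(src).astype(np.int64)
    frac = src - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, frac


def resize_gray(image, target_size: int) -> np.ndarray:
    """Bilinear resize to (target_size, target_size), half-pixel-centre
    convention, no aspect-ratio preservation, output rounded half-up and
    clipped to [0, 255]."""
    if target_size < 8:
        raise ValueError(f"target_size must be >= 8, got {target_size}")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D gray image, got shape {img.shape}")
    h, w = img.shape
    r0, r1, rf = _bilinear_coords(target_size, h)
    c0, c1, cf = _bilinear_coords(target_size, w)
    top = img[r0][:, c0] * (1 - cf) + img[r0][:, c1] * cf
    bot = img[r1][:, c0] * (1 - cf) + img[r1][:, c1] * cf
    out = top * (1 - rf)[:, None] + bot * rf[:, None]
    out = np.floor(out + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def preprocess(depth, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Full chain: depth (mm) -> height (mm) -> gray -> square resize."""
    data = depth.data if hasattr(depth, "data") else depth
    heights = invert_depth(data, config.camera_distance_mm)
    gray = scale_to_gray(heights, config.camera_distance_mm)
    return resize_gray(gray, config.target_size)
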