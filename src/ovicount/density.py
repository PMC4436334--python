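"""Density ground truth: sparse dots -> dense per-pixel training target.

Each labelled egg contributes a unit-integral 2-D Gaussian kernel centred
on its pixel, so that summing the resulting density map over any region
estimates the number of eggs in that region.  The kernel is evaluated on
the pixel grid over a finite truncation window and normalised by its
window sum, which makes the per-dot mass exactly 1 for interior dots; mass
from the window falling outside the image is lost, not redistributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import tifffile

from .annotations import ROI, DotAnnotation


@dataclass(frozen=True)
class DensityConfig:
    """Kernel parameters for building density maps.

    sigma
        Gaussian width in pixels (default 1.0).  Should be smaller than the
        object so kernels of adjacent eggs barely overlap; scale with image
        resolution.
    truncation_radius
        Window half-size in units of sigma (default 4.0; at least 3 so the
        untruncated mass outside the window is < 1e-3).
    """

    sigma: float = 1.0
    truncation_radius: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.truncation_radius < 3:
            raise ValueError(
                f"truncation_radius must be >= 3, got {self.truncation_radius}")


@dataclass
class DensityMap:
    """Per-pixel density in objects/pixel; region sums are counts."""

    values: np.ndarray

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def _unit_kernel(cfg: DensityConfig) -> np.ndarray:
    """Discrete Gaussian patch normalised to sum exactly 1."""
    radius = int(math.ceil(cfg.truncation_radius * cfg.sigma))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(ax ** 2) / (2.0 * cfg.sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def make_density_map(ann: DotAnnotation, image_shape: Tuple[int, int],
                     cfg: Optional[DensityConfig] = None) -> DensityMap:
    """Sum of one unit-mass truncated Gaussian per dot, clipped at borders."""
    cfg = cfg or DensityConfig()
    h, w = int(image_shape[0]), int(image_shape[1])
    if h < 1 or w < 1:
        raise ValueError(f"image shape must be positive, got {(h, w)}")
    ann.validate_for_shape((h, w))
    out = np.zeros((h, w), dtype=np.float64)
    kernel = _unit_kernel(cfg)
    radius = kernel.shape[0] // 2
    for r, c in ann.dots:
        r0, r1 = max(0, r - radius), min(h, r + radius + 1)
        c0, c1 = max(0, c - radius), min(w, c + radius + 1)
        kr0 = r0 - (r - radius)
        kc0 = c0 - (c - radius)
        out[r0:r1, c0:c1] += kernel[kr0:kr0 + (r1 - r0), kc0:kc0 + (c1 - c0)]
    return DensityMap(values=out)


def count_from_density(d, roi: Optional[ROI] = None) -> float:
    """Sum of density values over ``roi`` (whole map if None).

    When ``d`` is a predicted map this sum is the raw predicted count (PC).
    """
    values = d.values if isinstance(d, DensityMap) else np.asarray(d)
    if roi is None:
        return float(values.sum())
    roi.validate_for_shape(values.shape)
    return float(values[roi.slices()].sum())


def save_density_tiff(d: DensityMap, path) -> None:
    """Export as 32-bit float TIFF for visual inspection."""
    tifffile.imwrite(path, d.values.astype(np.float32))
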