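"""Training-target generation from point annotations.

A point-annotated image is turned into two aligned labels:

* a **density map** — each flower centre x_i contributes an isotropic
  Gaussian bump G_σ(x − x_i) with σ = 4 px by default; the map's integral
  equals the flower count, so counting reduces to summing the map;
* a **binary mask** — 1 wherever the density is strictly positive
  (the flower foreground), optionally grown by morphological dilation
  with a small structuring element (3×3 by default) so the foreground
  covers the whole flower rather than just the Gaussian core.

Each bump is truncated at radius 4σ and renormalised to unit mass within
the image support.  Truncation keeps the positive support local (without
it the thresholded mask would be all-ones), and renormalisation makes the
sum equal the point count exactly even for flowers near the border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_io import PointAnnotationSet

TRUNCATION_RADIUS_SIGMAS = 4.0


@dataclass
class DensityMap:
    """Non-negative H×W grid; its sum is the flower count."""

    values: np.ndarray
    sigma: float = 4.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2-D")
        if (self.values < 0).any():
            raise ValueError("density map must be non-negative")

    @property
    def count(self) -> float:
        return float(self.values.sum())


@dataclass
class BinaryMask:
    """{0,1}-valued H×W grid."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(np.unique(self.values), (0, 1)).all():
            raise ValueError("mask must be binary")
        self.values = self.values.astype(np.uint8)


@dataclass
class StructuringElement:
    """k×k all-ones block, k odd (1 disables growth)."""

    size: int = 3

    def __post_init__(self):
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("structuring element size must be odd and ≥ 1")

    @property
    def footprint(self) -> np.ndarray:
        return np.ones((self.size, self.size), dtype=bool)


def generate_density_map(points: PointAnnotationSet, shape: tuple[int, int],
                         sigma: float = 4.0) -> DensityMap:
    """Superpose one truncated, unit-mass Gaussian bump per point.

    The result sums to ``len(points)`` to machine precision.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = shape
    density = np.zeros((h, w), dtype=np.float64)
    radius = int(np.ceil(TRUNCATION_RADIUS_SIGMAS * sigma))
    for idx, (pr, pc) in enumerate(points.points):
        if not (0 <= pr < h and 0 <= pc < w):
            raise ValueError(f"point {idx} at ({pr}, {pc}) out of bounds")
        r0, r1 = max(int(np.floor(pr)) - radius, 0), min(int(np.floor(pr)) + radius + 1, h)
        c0, c1 = max(int(np.floor(pc)) - radius, 0), min(int(np.floor(pc)) + radius + 1, w)
        rr = np.arange(r0, r1, dtype=np.float64) - pr
        cc = np.arange(c0, c1, dtype=np.float64) - pc
        bump = np.exp(-(rr[:, None] ** 2 + cc[None, :] ** 2) / (2.0 * sigma ** 2))
        bump /= bump.sum()  # unit mass within the truncated in-image support
        density[r0:r1, c0:c1] += bump
    return DensityMap(density, sigma=sigma)


def mask_from_density(density: DensityMap) -> BinaryMask:
    """Threshold at zero: foreground wherever the density is > 0."""
    return BinaryMask((density.values > 0).astype(np.uint8))


def dilate_mask(mask: BinaryMask,
                element: StructuringElement | int = 3) -> BinaryMask:
    """Morphological binary dilation with a square structuring element.

    A pixel becomes foreground if the element centred there overlaps any
    foreground pixel; outside-image pixels count as background.
    """
    if isinstance(element, int):
        element = StructuringElement(element)
    if element.size == 1:
        return BinaryMask(mask.values.copy())
    out = ndimage.binary_dilation(mask.values.astype(bool),
                                  structure=element.footprint)
    return BinaryMask(out.astype(np.uint8))


def rescale_targets(density: DensityMap, mask: BinaryMask, stride: int,
                    ) -> tuple[DensityMap, BinaryMask]:
    """Bring full-resolution labels to the network's output grid.

    The density is block-summed over stride×stride cells (count
    preserving); the mask is block-maxed (any foreground in a cell marks
    the cell).  Inputs are zero-padded on the bottom/right so the output
    grid is ⌈H/stride⌉ × ⌈W/stride⌉, matching the network's ceil-mode
    downsampling.
    """
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    if stride == 1:
        return DensityMap(density.values.copy(), density.sigma), \
            BinaryMask(mask.values.copy())
    d, m = density.values, mask.values
    h, w = d.shape
    ho, wo = -(-h // stride), -(-w // stride)
    ph, pw = ho * stride - h, wo * stride - w
    if ph or pw:
        d = np.pad(d, ((0, ph), (0, pw)))
        m = np.pad(m, ((0, ph), (0, pw)))
    d_lo = d.reshape(ho, stride, wo, stride).sum(axis=(1, 3))
    m_lo = m.reshape(ho, stride, wo, stride).max(axis=(1, 3))
    return DensityMap(d_lo, density.sigma), BinaryMask(m_lo)


def make_targets(points: PointAnnotationSet, shape: tuple[int, int],
                 sigma: float = 4.0, dilation: int = 3, stride: int = 1,
                 ) -> tuple[DensityMap, BinaryMask]:
    """Full label pipeline: density → threshold → dilate → rescale."""
    density = generate_density_map(points, shape, sigma=sigma)
    mask = mask_from_density(density)
    if dilation > 1:
        mask = dilate_mask(mask, dilation)
    if stride > 1:
        density, mask = rescale_targets(density, mask, stride)
    return density, mask
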