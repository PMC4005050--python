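"""Slope derivation and the mechanization mask (condition C).

Mechanized soybean farming requires gentle terrain: pixels whose percent
slope exceeds a threshold (12% by default) are excluded from classification.
The slope raster is computed from a DEM with Horn's 3×3 operator, the GIS
standard; the mask can then be aggregated from the DEM grid (typically 90 m)
onto the coarser composite grid (250 m) by majority rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# Horn 3x3 weights for the x-derivative; the y-kernel is its transpose.
_HORN_X = np.array(
    [[-1.0, 0.0, 1.0],
     [-2.0, 0.0, 2.0],
     [-1.0, 0.0, 1.0]]
) / 8.0


@dataclass
class DEMRaster:
    """Digital elevation model on a square-cell grid."""

    elevation: np.ndarray
    cell_size_m: float
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=np.float64)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D grid")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.elevation)
        else:
            self.nodata_mask = (
                np.asarray(self.nodata_mask, dtype=bool)
                | ~np.isfinite(self.elevation)
            )
        valid = self.elevation[~self.nodata_mask]
        if valid.size and (valid.min() < -500 or valid.max() > 9000):
            raise ValueError("elevations outside plausible bounds (-500..9000 m)")


def slope_percent(dem: DEMRaster) -> np.ndarray:
    """Percent slope from Horn's 3×3 finite-difference operator.

    ``slope = 100 · sqrt(gx² + gy²)`` with the gradients estimated from the
    weighted 3×3 neighbourhood divided by the cell size.  Borders replicate
    the edge row/column, which reduces to one-sided differences there.
    Pixels with any nodata cell in their 3×3 neighbourhood are NaN.
    """
    z = dem.elevation
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("slope requires a grid of at least 3x3")
    filled = np.where(dem.nodata_mask, np.nanmean(z[~dem.nodata_mask]), z)
    gx = ndimage.convolve(filled, _HORN_X, mode="nearest") / dem.cell_size_m
    gy = ndimage.convolve(filled, _HORN_X.T, mode="nearest") / dem.cell_size_m
    slope = 100.0 * np.hypot(gx, gy)
    touched = ndimage.binary_dilation(
        dem.nodata_mask, structure=np.ones((3, 3), bool)
    )
    return np.where(touched, np.nan, slope)


def mechanization_mask(slope: np.ndarray, threshold_pct: float = 12.0) -> np.ndarray:
    """True where terrain is mechanizable (slope ≤ threshold).

    Exclusion is strictly "slope > threshold", so a pixel at exactly the
    threshold remains mechanizable.  Nodata slope is not mechanizable.
    """
    slope = np.asarray(slope, dtype=float)
    return np.isfinite(slope) & (slope <= threshold_pct)


def resample_mask_to_grid(
    mask: np.ndarray,
    target_shape: tuple[int, int],
    min_fraction: float = 0.5,
) -> np.ndarray:
    """Aggregate a fine-grid boolean mask onto a coarser grid.

    A target pixel is True iff at least ``min_fraction`` of the overlapping
    fine cells are True (majority rule by default).  When the grids have
    identical shape the mask is returned unchanged (nearest-neighbour case).
    Fine cells are assigned to target pixels by proportional index ranges,
    which is exact for integer resolution ratios.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape == tuple(target_shape):
        return mask.copy()
    rows, cols = target_shape
    r_edges = np.linspace(0, mask.shape[0], rows + 1)
    c_edges = np.linspace(0, mask.shape[1], cols + 1)
    out = np.empty((rows, cols), dtype=bool)
    csum = np.pad(mask.astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    r_idx = np.round(r_edges).astype(int)
    c_idx = np.round(c_edges).astype(int)
    for i in range(rows):
        r0, r1 = r_idx[i], r_idx[i + 1]
        for j in range(cols):
            c0, c1 = c_idx[j], c_idx[j + 1]
            total = (r1 - r0) * (c1 - c0)
            true_count = (
                csum[r1, c1] - csum[r0, c1] - csum[r1, c0] + csum[r0, c0]
            )
            out[i, j] = total > 0 and true_count / total >= min_fraction
    return out
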