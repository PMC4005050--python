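"""Calendar-windowed compositing of 16-day EVI image stacks.

The crop-detection procedure reduces a stack of 16-day vegetation-index
composites to three images per crop year:

* ``MinMeanEVI`` — consecutive composites of the sowing window (day of year
  225–337) are averaged two by two and the per-pixel minimum over the pair
  means is taken.  This smooths single-composite noise while preserving the
  low pre-sowing EVI that distinguishes annual cropland.
* ``MaxMeanEVI`` — the four consecutive composites of the maximum-development
  window (DOY 353 through 033 of the following calendar year) are averaged
  per pixel.
* ``AmpEVI`` — the elementwise difference MaxMeanEVI − MinMeanEVI, the
  green-up amplitude that separates annual crops from evergreen cover.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: day-of-year start positions of the standard 16-day composite grid
STANDARD_DOYS = tuple(range(1, 366, 16))


class EmptyWindowError(ValueError):
    """Raised when a calendar window selects no composites."""


@dataclass
class EVIComposite:
    """One 16-day EVI composite on a regular grid.

    Parameters
    ----------
    values
        2-D float array of EVI, already scaled to physical units
        (nominal range −0.2…1.0).
    year, doy
        Calendar year and day-of-year of the composite start.
    nodata_mask
        Boolean grid, ``True`` where the pixel carries no observation.
    scale_factor
        Multiplier that was applied to the stored integers (1.0 if the
        source was already float).
    """

    values: np.ndarray
    year: int
    doy: int
    nodata_mask: np.ndarray | None = None
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("composite values must be a 2-D grid")
        if not 1 <= self.doy <= 366:
            raise ValueError(f"doy {self.doy} outside 1..366")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)
        if self.doy not in STANDARD_DOYS:
            logger.warning(
                "composite (%d, %d) is off the standard 16-day DOY grid",
                self.year, self.doy,
            )
        valid = self.values[~self.nodata_mask]
        if valid.size and (valid.min() < -0.3 or valid.max() > 1.1):
            warnings.warn(
                f"composite ({self.year}, {self.doy}) has EVI outside "
                "[-0.3, 1.1]; check the scale factor",
                stacklevel=2,
            )

    @property
    def tag(self) -> tuple[int, int]:
        return (self.year, self.doy)


@dataclass
class CompositeSeries:
    """An ordered stack of composites sharing one grid."""

    composites: list[EVIComposite]
    pixel_area_ha: float = 6.25  # 250 m MODIS pixel
    geotransform: tuple | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.composites:
            shape = self.composites[0].values.shape
            for c in self.composites:
                if c.values.shape != shape:
                    raise ValueError(
                        f"composite {c.tag} grid {c.values.shape} differs "
                        f"from series grid {shape}"
                    )
        tags = [c.tag for c in self.composites]
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate (year, doy) in composite series")
        self.composites = sorted(self.composites, key=lambda c: c.tag)

    def __len__(self) -> int:
        return len(self.composites)

    def __iter__(self):
        return iter(self.composites)

    @property
    def shape(self) -> tuple[int, int]:
        return self.composites[0].values.shape

    @property
    def tags(self) -> list[tuple[int, int]]:
        return [c.tag for c in self.composites]

    def years(self) -> list[int]:
        return sorted({c.year for c in self.composites})


@dataclass(frozen=True)
class CropYearWindows:
    """Calendar windows of one crop year.

    The sowing window lies entirely in the first calendar year of the crop
    year; the maximum-development window wraps the year boundary (DOY ≥ 353
    of year Y plus DOY ≤ 33 of year Y+1).
    """

    sowing_start_doy: int = 225
    sowing_end_doy: int = 337
    maxdev_start_doy: int = 353
    maxdev_end_doy: int = 33

    def __post_init__(self) -> None:
        if self.sowing_end_doy >= self.maxdev_start_doy:
            raise ValueError("sowing and max-development windows overlap")

    def in_sowing(self, year: int, doy: int, crop_year: int) -> bool:
        return year == crop_year and self.sowing_start_doy <= doy <= self.sowing_end_doy

    def in_maxdev(self, year: int, doy: int, crop_year: int) -> bool:
        if year == crop_year:
            return doy >= self.maxdev_start_doy
        if year == crop_year + 1:
            return doy <= self.maxdev_end_doy
        return False

    @staticmethod
    def label(crop_year: int) -> str:
        return f"{crop_year}/{crop_year + 1}"


@dataclass
class CompositeImage:
    """A derived per-crop-year image (min_mean, max_mean or amplitude)."""

    values: np.ndarray
    kind: str  # {"min_mean", "max_mean", "amplitude"}
    source_tags: list[tuple[int, int]] = field(default_factory=list)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"min_mean", "max_mean", "amplitude"}:
            raise ValueError(f"unknown image kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def select_window(
    series: CompositeSeries,
    windows: CropYearWindows,
    which: str,
    crop_year: int,
) -> CompositeSeries:
    """Return the composites of one calendar window of one crop year.

    ``which="sowing"`` selects DOY 225–337 of ``crop_year``;
    ``which="maxdev"`` selects DOY ≥ 353 of ``crop_year`` plus DOY ≤ 33 of
    ``crop_year + 1`` (the window wraps the calendar-year boundary).
    """
    if which not in {"sowing", "maxdev"}:
        raise ValueError(f"which must be 'sowing' or 'maxdev', got {which!r}")
    if len(series) == 0:
        raise EmptyWindowError("composite series is empty")
    member = windows.in_sowing if which == "sowing" else windows.in_maxdev
    chosen = [c for c in series if member(c.year, c.doy, crop_year)]
    if not chosen:
        raise EmptyWindowError(
            f"no composites in the {which} window of crop year "
            f"{CropYearWindows.label(crop_year)}"
        )
    return replace(series, composites=chosen)


def _stack(series: CompositeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Stack a series into (values, nodata) cubes of shape (t, rows, cols)."""
    values = np.stack([c.values for c in series])
    nodata = np.stack([c.nodata_mask for c in series])
    return values, nodata


def min_mean_evi(sowing_series: CompositeSeries) -> CompositeImage:
    """Per-pixel minimum over consecutive-pair means of the sowing window.

    Consecutive composites are averaged two by two; the output pixel is the
    minimum over those pair means.  A pixel masked in one member of a pair
    falls back to the unmasked member (the 16-day product is already
    maximum-value composited, so the surviving member is the best estimate);
    a pixel masked in every pair is nodata.
    """
    if len(sowing_series) < 2:
        raise ValueError("min_mean requires at least two composites")
    values, nodata = _stack(sowing_series)
    v = np.where(nodata, np.nan, values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
        pair_means = np.nanmean(np.stack([v[:-1], v[1:]]), axis=0)
        out = np.nanmin(pair_means, axis=0)
    out_nodata = np.all(np.isnan(pair_means), axis=0)
    out = np.where(out_nodata, np.nan, out)
    return CompositeImage(out, "min_mean", sowing_series.tags, out_nodata)


def max_mean_evi(
    maxdev_series: CompositeSeries, strict: bool = True
) -> CompositeImage:
    """Per-pixel mean of the four consecutive maximum-development composites.

    The window is fixed (DOY 353–033): when more than four composites fall
    inside it the first four are used and the extras are ignored with a
    warning.  With ``strict=True`` (default) fewer than four composites is an
    error; ``strict=False`` averages whatever exists and logs.
    """
    n = len(maxdev_series)
    if n == 0:
        raise ValueError("no usable images in the max-development window")
    if n > 4:
        logger.warning(
            "max-development window holds %d composites; using the first 4", n
        )
        maxdev_series = replace(
            maxdev_series, composites=maxdev_series.composites[:4]
        )
    elif n < 4:
        if strict:
            raise ValueError(
                f"max_mean requires 4 composites in the window, got {n}"
            )
        logger.warning("averaging %d < 4 max-development composites", n)
    values, nodata = _stack(maxdev_series)
    v = np.where(nodata, np.nan, values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(v, axis=0)
    out_nodata = np.all(nodata, axis=0)
    out = np.where(out_nodata, np.nan, out)
    return CompositeImage(out, "max_mean", maxdev_series.tags, out_nodata)


def amplitude(max_img: CompositeImage, min_img: CompositeImage) -> CompositeImage:
    """EVI amplitude: elementwise MaxMeanEVI − MinMeanEVI.

    Negative amplitudes are preserved (not clamped); nodata on either side
    propagates.
    """
    if max_img.kind != "max_mean" or min_img.kind != "min_mean":
        raise ValueError(
            f"expected kinds (max_mean, min_mean), got "
            f"({max_img.kind}, {min_img.kind})"
        )
    if max_img.shape != min_img.shape:
        raise ValueError(
            f"grid mismatch: {max_img.shape} vs {min_img.shape}"
        )
    out_nodata = max_img.nodata_mask | min_img.nodata_mask
    out = np.where(out_nodata, np.nan, max_img.values - min_img.values)
    return CompositeImage(
        out, "amplitude", max_img.source_tags + min_img.source_tags, out_nodata
    )
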