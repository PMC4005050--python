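"""Threshold calibration from paired min/max EVI samples.

The three thresholds are estimated from the joint distribution of paired
(MinMeanEVI, MaxMeanEVI) pixel samples over calibration sites (nominally
three 100×100-pixel test sites):

* ``Lmin`` — lower bound on the minimum image, separating cropland from
  cloud shadows and water bodies: a low quantile of the minimum values after
  excluding the sub-zero water/shadow mode.
* ``Umin`` — upper bound on the minimum image, set where the minimum and
  maximum mean images *converge*: scanning the min axis upward, the first
  histogram column whose mass concentrates in a band around the max = min
  diagonal.  Pixels above it keep high EVI year-round and are not annual
  crops.
* ``Amp`` — the smallest max − min amplitude at which the crop cluster
  separates from the diagonal convergence region; operationally a low
  quantile of the amplitudes of crop-candidate pixels lying outside the
  diagonal band.  It is the minimum amplitude at which a mixed field-border
  pixel is still accepted as soybean.

The convergence procedure is a deterministic histogram-band scan; every
constant (bin width, band width, density fraction, quantiles) is exposed.
Once frozen, one parameter set is applied to every crop year: parameters
represent physically driven components and are not re-tuned per year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: fewer paired samples than this triggers a low-confidence warning
MIN_CALIBRATION_SAMPLES = 1000


class CalibrationWarning(UserWarning):
    """Degenerate or under-sized calibration input."""


@dataclass
class CalibrationSample:
    """Paired per-pixel MinMeanEVI / MaxMeanEVI samples from one site."""

    site_id: str
    min_values: np.ndarray
    max_values: np.ndarray
    crop_year_label: str = ""

    def __post_init__(self) -> None:
        self.min_values = np.asarray(self.min_values, float).ravel()
        self.max_values = np.asarray(self.max_values, float).ravel()
        if self.min_values.shape != self.max_values.shape:
            raise ValueError("min_values and max_values must be paired")
        keep = np.isfinite(self.min_values) & np.isfinite(self.max_values)
        self.min_values = self.min_values[keep]
        self.max_values = self.max_values[keep]


def _pool(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, CalibrationSample):
        samples = [samples]
    mins = np.concatenate([s.min_values for s in samples])
    maxs = np.concatenate([s.max_values for s in samples])
    if mins.size == 0:
        raise ValueError("no finite calibration samples")
    if mins.size < MIN_CALIBRATION_SAMPLES:
        warnings.warn(
            f"insufficient calibration data ({mins.size} < "
            f"{MIN_CALIBRATION_SAMPLES} paired samples); result is "
            "low-confidence",
            CalibrationWarning,
            stacklevel=3,
        )
    return mins, maxs


def estimate_lmin(samples, quantile: float = 0.01) -> float:
    """Lower minimum-EVI bound: low quantile after dropping the water mode.

    Values below zero belong to the water / cloud-shadow mode and are
    excluded before taking the quantile, so the estimate tracks the lower
    edge of the cropland cluster rather than the water cluster.
    """
    mins, _ = _pool(samples)
    land = mins[mins >= 0.0]
    if land.size == 0:
        warnings.warn(
            "all minimum values below zero; falling back to full sample",
            CalibrationWarning, stacklevel=2,
        )
        land = mins
    return float(np.quantile(land, quantile))


def estimate_umin(
    samples,
    lmin: float | None = None,
    bin_width: float = 0.01,
    band_width: float = 0.05,
    density_fraction: float = 0.05,
    fallback_quantile: float = 0.99,
) -> float:
    """Upper minimum-EVI bound via min/max convergence.

    Paired values are binned on the min axis (``bin_width``); scanning
    upward from ``lmin``, the first column in which the mass within the
    diagonal band ``|max − min| < band_width`` exceeds ``density_fraction``
    of the column mass marks the convergence of the minimum and maximum
    images — evergreen cover whose EVI barely moves between the two windows.
    The returned value is that column's lower edge.

    A sample with no convergent column (pure cropland) is flagged and the
    ``fallback_quantile`` of the minimum values is returned instead.
    """
    mins, maxs = _pool(samples)
    if lmin is None:
        lmin = estimate_lmin(samples)
    lo = np.floor(mins.min() / bin_width) * bin_width
    hi = np.ceil(mins.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    in_band = np.abs(maxs - mins) < band_width
    col_total, _ = np.histogram(mins, bins=edges)
    col_band, _ = np.histogram(mins[in_band], bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(col_total > 0, col_band / np.maximum(col_total, 1), 0.0)
    for k in range(len(edges) - 1):
        if edges[k] < lmin or col_total[k] == 0:
            continue
        if frac[k] > density_fraction:
            return float(edges[k])
    warnings.warn(
        "no convergence between minimum and maximum images; returning the "
        f"{fallback_quantile:.0%} quantile of minimum values",
        CalibrationWarning, stacklevel=2,
    )
    return float(np.quantile(mins, fallback_quantile))


def estimate_amp(
    samples,
    umin: float | None = None,
    band_width: float = 0.05,
    quantile: float = 0.01,
) -> float:
    """Minimum crop amplitude from the scatter's convergence-region gap.

    Among crop-candidate pixels (min ≤ Umin), amplitudes inside the diagonal
    band ``|max − min| < band_width`` belong to the convergence region and
    are discarded; ``Amp`` is the low ``quantile`` of the remaining crop
    amplitudes — the smallest difference at which a mixed border pixel is
    still accepted as soybean.
    """
    mins, maxs = _pool(samples)
    if umin is None:
        umin = estimate_umin(samples)
    amps = (maxs - mins)[mins <= umin]
    if amps.size == 0:
        raise ValueError("no crop-candidate pixels below Umin")
    crop_amps = amps[amps >= band_width]
    if crop_amps.size == 0:
        warnings.warn(
            "single-population sample: no amplitudes beyond the diagonal "
            "band; falling back to the quantile of all candidate amplitudes",
            CalibrationWarning, stacklevel=2,
        )
        crop_amps = amps
    return float(np.quantile(crop_amps, quantile))


def freeze_parameters(
    per_year_estimates,
    pinned: tuple[float, float, float] | None = None,
    slope_threshold_pct: float = 12.0,
):
    """Collapse per-year (Lmin, Umin, Amp) estimates into one frozen set.

    One parameter set must serve every crop year — parameters cannot be
    re-adjusted per year after the fact.  The default rule is the per-
    component median across years; ``pinned`` overrides with user-chosen
    values (e.g. an operational set refined against official statistics).
    The per-year estimates are retained on the result for audit.

    Returns
    -------
    MCDAParameters
    """
    from .classifier import MCDAParameters

    est = [tuple(float(v) for v in e) for e in per_year_estimates]
    if pinned is not None:
        lmin, umin, amp = pinned
    else:
        if not est:
            raise ValueError("no per-year estimates to freeze")
        arr = np.asarray(est, float)
        lmin, umin, amp = (float(v) for v in np.median(arr, axis=0))
    params = MCDAParameters(
        lmin=lmin, umin=umin, amp=amp, slope_threshold_pct=slope_threshold_pct
    )
    object.__setattr__(params, "_per_year_estimates", tuple(est))
    return params
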