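"""Soybean classification from min/max EVI images (conditions A–D).

A pixel is mapped as soybean when it satisfies all four conditions:

* **A** — its MinMeanEVI lies in ``[Lmin, Umin]``: low enough to have been
  bare during the sowing window (excluding evergreen cover above Umin) but
  above the water/cloud-shadow floor Lmin.
* **B** — its green-up amplitude MaxMeanEVI − MinMeanEVI is at least
  ``Amp``, the signature of rapid annual-crop development.
* **C** — the terrain is mechanizable (slope ≤ 12%); see :mod:`mcda.terrain`.
* **D** — a management mask (agricultural land use); supplied externally
  and all-true by default.

Two release modes exist.  The *second forecast* (early February) uses the
current crop year's maximum-development images.  The *first forecast*
(early December) substitutes the most recent prior normal year's
MaxMeanEVI, trading timeliness for the assumption that peak EVI is stable
across years; the same substitution is applied by the second forecast when
the current peak window has no usable images or a water deficit is observed
(30 days without a rainfall event over 10 mm).

:class:`MCDAClassifier` wraps conditions A and B (the data-driven core) as
a scikit-learn estimator over paired (min, max) samples, with ``fit``
running the convergence calibration of :mod:`mcda.calibration`.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import calibration as _calib
from .composites import (
    CompositeImage,
    CompositeSeries,
    CropYearWindows,
    EmptyWindowError,
    amplitude,
    max_mean_evi,
    min_mean_evi,
    select_window,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCDAParameters:
    """The frozen classification thresholds (EVI units, percent slope).

    One set serves every crop year of a run; per-year re-tuning is
    deliberately unsupported.  Defaults are the operational Mato Grosso
    values; note ``Lmin < Umin`` by definition (the lower and upper bounds
    on the minimum image).
    """

    lmin: float = 0.05
    umin: float = 0.39
    amp: float = 0.36
    slope_threshold_pct: float = 12.0
    strict_inequalities: bool = False

    def __post_init__(self) -> None:
        if not self.lmin < self.umin:
            raise ValueError(f"Lmin ({self.lmin}) must be < Umin ({self.umin})")
        if self.amp <= 0:
            raise ValueError(f"Amp must be positive, got {self.amp}")

    # audit trail attached by calibration.freeze_parameters
    @property
    def per_year_estimates(self):
        return getattr(self, "_per_year_estimates", ())


@dataclass
class SoybeanMap:
    """Binary soybean classification for one crop year."""

    mask: np.ndarray
    crop_year_label: str
    forecast_mode: str  # {"first", "second"}
    fallback_used: bool = False
    condition_masks: dict = field(default_factory=dict)
    nodata_mask: np.ndarray | None = None
    params: MCDAParameters | None = None
    source_tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros_like(self.mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def area_ha(self, pixel_area_ha: float = 6.25) -> float:
        return float(self.mask.sum()) * pixel_area_ha


@dataclass
class RainfallSeries:
    """Ordered 10-day (dekadal) accumulated precipitation at one station."""

    station_id: str
    records: list  # of (datetime.date, accumulated mm over 10 days)

    def __post_init__(self) -> None:
        recs = [(d, float(mm)) for d, mm in self.records]
        for (d0, _), (d1, _) in zip(recs, recs[1:]):
            if d1 <= d0:
                raise ValueError("rainfall record dates must strictly increase")
        for _, mm in recs:
            if mm < 0:
                raise ValueError("accumulations must be >= 0")
        self.records = recs


def water_deficit(
    rain: RainfallSeries,
    start: dt.date,
    end: dt.date,
    event_mm: float = 10.0,
    span_days: int = 30,
) -> bool:
    """True iff the window contains ``span_days`` consecutive days with no
    dekadal accumulation above ``event_mm``.

    Rainfall *events* are the record dates whose accumulation exceeds
    ``event_mm``; a deficit exists when the gap between consecutive events
    (or between an event and the window edge) covers at least ``span_days``
    event-free days.
    """
    if not rain.records:
        raise ValueError("empty rainfall series")
    if end < start:
        raise ValueError("window end precedes start")
    events = [d for d, mm in rain.records if start <= d <= end and mm > event_mm]
    if not events:
        return (end - start).days + 1 >= span_days
    gaps = [(events[0] - start).days]
    gaps += [(b - a).days - 1 for a, b in zip(events, events[1:])]
    gaps.append((end - events[-1]).days)
    return max(gaps) >= span_days


def sowing_onset(
    rain: RainfallSeries,
    year: int,
    threshold_mm: float = 20.0,
) -> dt.date | None:
    """Date of the first dekadal accumulation ≥ threshold from 1 September.

    Advisory metadata only: the classification windows stay fixed at their
    DOY ranges unless overridden explicitly.  Returns ``None``
    ("undetermined") when no record qualifies.
    """
    sep1 = dt.date(year, 9, 1)
    for d, mm in rain.records:
        if d >= sep1 and mm >= threshold_mm:
            return d
    return None


def _thresholds(minv, ampv, params: MCDAParameters):
    """Boolean condition-A and condition-B arrays from min and amplitude."""
    if params.strict_inequalities:
        a = (minv > params.lmin) & (minv < params.umin)
        b = ampv > params.amp
    else:
        a = (minv >= params.lmin) & (minv <= params.umin)
        b = ampv >= params.amp
    return a, b


def condition_a(min_img: CompositeImage, params: MCDAParameters) -> np.ndarray:
    """Sowing-window test: Lmin ≤ MinMeanEVI ≤ Umin (closed interval).

    Pixels below Lmin are cloud shadows or water; above Umin, evergreen
    cover.  Nodata pixels are False.
    """
    if min_img.kind != "min_mean":
        raise ValueError(f"condition A expects a min_mean image, got {min_img.kind}")
    v = np.where(min_img.nodata_mask, np.nan, min_img.values)
    a, _ = _thresholds(v, np.zeros_like(v), params)
    return a & ~min_img.nodata_mask


def condition_b(amp_img: CompositeImage, params: MCDAParameters) -> np.ndarray:
    """Amplitude test: MaxMeanEVI − MinMeanEVI ≥ Amp.

    Closed at Amp so the calibrated value — the minimum amplitude at which a
    mixed border pixel is still soybean — is itself admissible.
    """
    if amp_img.kind != "amplitude":
        raise ValueError(f"condition B expects an amplitude image, got {amp_img.kind}")
    v = np.where(amp_img.nodata_mask, np.nan, amp_img.values)
    _, b = _thresholds(np.full_like(v, params.lmin), v, params)
    return b & ~amp_img.nodata_mask


def classify(
    min_img: CompositeImage,
    max_img: CompositeImage,
    terrain_mask: np.ndarray | None = None,
    management_mask: np.ndarray | None = None,
    params: MCDAParameters | None = None,
    mode: str = "second",
    crop_year_label: str = "",
    fallback_used: bool = False,
) -> SoybeanMap:
    """Conjunction of conditions A–D into a binary soybean map.

    ``terrain_mask`` (condition C) and ``management_mask`` (condition D)
    default to all-true.  Pure function of its inputs: re-running yields a
    bit-identical mask.
    """
    params = params or MCDAParameters()
    shape = min_img.shape
    if max_img.shape != shape:
        raise ValueError(f"grid mismatch: {shape} vs {max_img.shape}")
    if terrain_mask is None:
        terrain_mask = np.ones(shape, dtype=bool)
    if management_mask is None:
        management_mask = np.ones(shape, dtype=bool)
    terrain_mask = np.asarray(terrain_mask, dtype=bool)
    management_mask = np.asarray(management_mask, dtype=bool)
    for name, m in (("terrain", terrain_mask), ("management", management_mask)):
        if m.shape != shape:
            raise ValueError(f"{name} mask grid mismatch: {m.shape} vs {shape}")

    amp_img = amplitude(max_img, min_img)
    a = condition_a(min_img, params)
    b = condition_b(amp_img, params)
    nodata = min_img.nodata_mask | max_img.nodata_mask
    mask = a & b & terrain_mask & management_mask & ~nodata
    return SoybeanMap(
        mask=mask,
        crop_year_label=crop_year_label,
        forecast_mode=mode,
        fallback_used=fallback_used,
        condition_masks={"A": a, "B": b, "C": terrain_mask, "D": management_mask},
        nodata_mask=nodata,
        params=params,
        source_tags={
            "min": list(min_img.source_tags),
            "max": list(max_img.source_tags),
        },
    )


def _prior_normal_max(
    series: CompositeSeries,
    crop_year: int,
    windows: CropYearWindows,
    deficit_years,
    strict: bool,
) -> tuple[CompositeImage, int]:
    """MaxMeanEVI of the most recent prior crop year not flagged deficit."""
    for year in range(crop_year - 1, min(series.years(), default=crop_year) - 1, -1):
        if year in deficit_years:
            continue
        try:
            sel = select_window(series, windows, "maxdev", year)
            return max_mean_evi(sel, strict=strict), year
        except (EmptyWindowError, ValueError):
            continue
    raise EmptyWindowError(
        f"first forecast unavailable: no prior normal crop year with usable "
        f"max-development composites before {CropYearWindows.label(crop_year)}"
    )


def second_forecast(
    series: CompositeSeries,
    crop_year: int,
    windows: CropYearWindows | None = None,
    params: MCDAParameters | None = None,
    terrain_mask: np.ndarray | None = None,
    management_mask: np.ndarray | None = None,
    rain: RainfallSeries | None = None,
    deficit_years=(),
    strict: bool = True,
) -> SoybeanMap:
    """February release: current-year sowing and maximum-development images.

    Falls back to the most recent prior normal year's MaxMeanEVI — as in
    the first forecast — when the current peak window has no usable images
    or ``rain`` reveals a water deficit inside it; ``fallback_used`` records
    the substitution.
    """
    windows = windows or CropYearWindows()
    min_img = min_mean_evi(select_window(series, windows, "sowing", crop_year))

    fallback = False
    if rain is not None:
        w_start = dt.date(crop_year, 1, 1) + dt.timedelta(days=windows.maxdev_start_doy - 1)
        w_end = dt.date(crop_year + 1, 1, 1) + dt.timedelta(days=windows.maxdev_end_doy - 1)
        if water_deficit(rain, w_start, w_end):
            logger.info("water deficit in the peak window of %d; using prior year", crop_year)
            fallback = True
    if not fallback:
        try:
            max_img = max_mean_evi(
                select_window(series, windows, "maxdev", crop_year), strict=strict
            )
        except (EmptyWindowError, ValueError):
            logger.info("no usable peak images for %d; using prior year", crop_year)
            fallback = True
    if fallback:
        max_img, _ = _prior_normal_max(series, crop_year, windows, set(deficit_years), strict)

    return classify(
        min_img, max_img, terrain_mask, management_mask, params,
        mode="second",
        crop_year_label=CropYearWindows.label(crop_year),
        fallback_used=fallback,
    )


def first_forecast(
    series: CompositeSeries,
    crop_year: int,
    windows: CropYearWindows | None = None,
    params: MCDAParameters | None = None,
    terrain_mask: np.ndarray | None = None,
    management_mask: np.ndarray | None = None,
    deficit_years=(),
    strict: bool = True,
) -> SoybeanMap:
    """December release: current-year sowing images, prior-year peak images.

    Assumes peak EVI is stable across years; a pixel newly converted to
    soybean this year (low prior-year peak) is missed — a documented
    limitation.  Errors when no prior normal year exists (the situation of
    the earliest year in an archive).
    """
    windows = windows or CropYearWindows()
    min_img = min_mean_evi(select_window(series, windows, "sowing", crop_year))
    max_img, used_year = _prior_normal_max(
        series, crop_year, windows, set(deficit_years), strict
    )
    result = classify(
        min_img, max_img, terrain_mask, management_mask, params,
        mode="first",
        crop_year_label=CropYearWindows.label(crop_year),
        fallback_used=True,
    )
    result.source_tags["max_crop_year"] = used_year
    return result


class MCDAClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier over paired (MinMeanEVI, MaxMeanEVI) samples.

    Each sample is a pixel described by two features: its minimum-image EVI
    and its maximum-image EVI.  ``predict`` labels a sample 1 (soybean) when
    it passes condition A (``lmin ≤ min ≤ umin``) and condition B
    (``max − min ≥ amp``); terrain and management masks are raster-level
    concerns handled by :func:`classify`.

    With ``calibrate=True`` (default), :meth:`fit` estimates the thresholds
    from the training scatter by the convergence procedure of
    :mod:`mcda.calibration`; with ``calibrate=False`` the constructor values
    are frozen as-is, matching the operational fixed-parameter discipline.
    The target ``y`` is never used — calibration is unsupervised — and is
    accepted only for pipeline compatibility.

    Parameters
    ----------
    lmin, umin, amp : float
        Thresholds in EVI units (used directly when ``calibrate=False``,
        and as the defaults reported by ``get_params``).
    strict_inequalities : bool
        Use open instead of closed threshold comparisons.
    calibrate : bool
        Estimate thresholds in ``fit`` instead of freezing the constructor
        values.
    bin_width, band_width, density_fraction, lmin_quantile, amp_quantile :
        Convergence-scan constants, see :mod:`mcda.calibration`.

    Attributes
    ----------
    lmin_, umin_, amp_ : float
        The frozen thresholds after ``fit``.
    classes_ : ndarray of shape (2,)
        ``[0, 1]`` — non-soybean, soybean.

    Examples
    --------
    >>> import numpy as np
    >>> clf = MCDAClassifier(calibrate=False).fit(np.empty((0, 2)))
    >>> clf.predict([[0.20, 0.80], [0.55, 0.70], [0.01, 0.60]])
    array([1, 0, 0])
    """

    def __init__(
        self,
        lmin: float = 0.05,
        umin: float = 0.39,
        amp: float = 0.36,
        strict_inequalities: bool = False,
        calibrate: bool = True,
        bin_width: float = 0.01,
        band_width: float = 0.05,
        density_fraction: float = 0.05,
        lmin_quantile: float = 0.01,
        amp_quantile: float = 0.01,
    ):
        self.lmin = lmin
        self.umin = umin
        self.amp = amp
        self.strict_inequalities = strict_inequalities
        self.calibrate = calibrate
        self.bin_width = bin_width
        self.band_width = band_width
        self.density_fraction = density_fraction
        self.lmin_quantile = lmin_quantile
        self.amp_quantile = amp_quantile

    def fit(self, X, y=None):
        """Freeze the thresholds, calibrating from X when requested."""
        X = check_array(X, ensure_min_samples=0, ensure_min_features=2)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (min_evi, max_evi)")
        self.n_features_in_ = 2
        self.classes_ = np.array([0, 1])
        if self.calibrate:
            if X.shape[0] == 0:
                raise ValueError("calibrate=True requires training samples")
            sample = _calib.CalibrationSample("fit", X[:, 0], X[:, 1])
            self.lmin_ = _calib.estimate_lmin(sample, quantile=self.lmin_quantile)
            self.umin_ = _calib.estimate_umin(
                sample,
                lmin=self.lmin_,
                bin_width=self.bin_width,
                band_width=self.band_width,
                density_fraction=self.density_fraction,
            )
            self.amp_ = _calib.estimate_amp(
                sample,
                umin=self.umin_,
                band_width=self.band_width,
                quantile=self.amp_quantile,
            )
        else:
            self.lmin_, self.umin_, self.amp_ = self.lmin, self.umin, self.amp
        if not self.lmin_ < self.umin_:
            raise ValueError(
                f"calibration produced Lmin ({self.lmin_:.3f}) >= "
                f"Umin ({self.umin_:.3f})"
            )
        return self

    def predict(self, X):
        """Label paired (min, max) samples: 1 = soybean, 0 = non-soybean."""
        check_is_fitted(self, "lmin_")
        X = check_array(X, ensure_min_features=2)
        a, b = _thresholds(X[:, 0], X[:, 1] - X[:, 0], self.params_)
        return (a & b).astype(int)

    @property
    def params_(self) -> MCDAParameters:
        """The frozen thresholds as an :class:`MCDAParameters`."""
        check_is_fitted(self, "lmin_")
        return MCDAParameters(
            lmin=self.lmin_,
            umin=self.umin_,
            amp=self.amp_,
            strict_inequalities=self.strict_inequalities,
        )
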