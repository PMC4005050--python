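"""Area aggregation, expansion mapping and accuracy assessment.

Soybean maps are turned into per-zone (municipality) area tables, multi-year
expansion maps, and are validated two ways:

* against reference pixel samples with a stratified-random confusion matrix
  and its derived metrics (overall, user's and producer's accuracy, Kappa);
* against official area statistics with an ordinary least-squares regression
  (map estimate as predictor, official figure as response), reporting slope,
  intercept, R², the RMSD about the fitted line and the share of points
  inside the ±2·RMSD band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import SoybeanMap

#: zone id reserved for pixels outside every named zone
UNZONED = 0


@dataclass
class ZoneMap:
    """Integer zone raster aligned to the classification grid (0 = outside)."""

    zone_ids: np.ndarray
    zone_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zone_ids = np.asarray(self.zone_ids, dtype=np.int64)
        if self.zone_ids.min() < 0:
            raise ValueError("zone ids must be >= 0")
        present = set(np.unique(self.zone_ids)) - {UNZONED}
        missing = present - set(self.zone_names)
        if missing:
            raise ValueError(f"zones without names: {sorted(missing)}")


@dataclass
class ConfusionMatrix:
    """2×2 classified × reference counts; class order (soybean, non-soybean)."""

    soy_soy: int
    soy_non: int
    non_soy: int
    non_non: int

    def __post_init__(self) -> None:
        for c in (self.soy_soy, self.soy_non, self.non_soy, self.non_non):
            if c < 0:
                raise ValueError("counts must be >= 0")

    @property
    def counts(self) -> np.ndarray:
        """Rows = classified (soy, non), columns = reference (soy, non)."""
        return np.array(
            [[self.soy_soy, self.soy_non], [self.non_soy, self.non_non]],
            dtype=np.int64,
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class RegressionReport:
    """OLS diagnostics of map estimates against official statistics."""

    slope: float
    intercept_ha: float
    r_squared: float
    rmsd_ha: float
    fraction_within_2rmsd: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        if self.rmsd_ha < 0:
            raise ValueError("rmsd_ha must be >= 0")


def zonal_area(
    soy_map: SoybeanMap,
    zones: ZoneMap,
    pixel_area_ha: float = 6.25,
) -> pd.DataFrame:
    """Per-zone soybean pixel counts and areas for one crop year.

    Every named zone appears (0 ha when empty); soybean pixels outside all
    zones are conserved in a reserved ``unzoned`` row.  Area is exactly
    ``pixel_count × pixel_area_ha``.
    """
    if zones.zone_ids.shape != soy_map.shape:
        raise ValueError("zone grid does not match the classification grid")
    ids = zones.zone_ids[soy_map.mask]
    counts = np.bincount(ids, minlength=int(zones.zone_ids.max()) + 1)
    rows = []
    zone_order = sorted(set(zones.zone_names) | ({UNZONED} if counts[UNZONED] else set()))
    for zid in zone_order:
        n = int(counts[zid]) if zid < len(counts) else 0
        rows.append(
            {
                "zone_id": zid,
                "zone_name": zones.zone_names.get(zid, "unzoned"),
                "crop_year": soy_map.crop_year_label,
                "pixel_count": n,
                "area_ha": n * pixel_area_ha,
                "forecast_mode": soy_map.forecast_mode,
            }
        )
    return pd.DataFrame(rows)


def expansion_map(maps: list[SoybeanMap]) -> np.ndarray:
    """First-detection index per pixel over an ordered multi-year map stack.

    Returns an integer grid: 0 where soybean was never mapped, else the
    1-based index of the earliest crop year in which the pixel was soybean.
    The union area is the count of nonzero pixels times the pixel area.
    """
    if not maps:
        raise ValueError("no maps supplied")
    shape = maps[0].shape
    out = np.zeros(shape, dtype=np.int32)
    for idx, m in enumerate(maps, start=1):
        if m.shape != shape:
            raise ValueError("maps must share one grid")
        newly = m.mask & (out == 0)
        out[newly] = idx
    return out


def stratified_sample(
    reference: pd.DataFrame,
    n_per_class: int = 200,
    seed: int = 0,
    class_column: str = "class",
) -> pd.DataFrame:
    """Random per-class sample of reference pixels without replacement.

    ``reference`` carries one row per labelled pixel (columns ``row``,
    ``col``, ``class``).  Reproducible for a fixed seed; a class with fewer
    than ``n_per_class`` pixels is an error naming the class.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for cls, group in sorted(reference.groupby(class_column), key=lambda kv: str(kv[0])):
        if len(group) < n_per_class:
            raise ValueError(
                f"class {cls!r} has only {len(group)} reference pixels, "
                f"need {n_per_class}"
            )
        take = rng.choice(len(group), size=n_per_class, replace=False)
        parts.append(group.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)


def confusion(classified: SoybeanMap, sample: pd.DataFrame) -> ConfusionMatrix:
    """Tally classified-vs-reference pairs over a labelled pixel sample.

    ``sample`` rows carry ``row``, ``col`` and ``class`` (truthy /
    ``"soybean"`` = soybean reference).
    """
    r = sample["row"].to_numpy(int)
    c = sample["col"].to_numpy(int)
    ref = sample["class"].to_numpy()
    ref_soy = np.array(
        [str(v).lower() in {"1", "true", "soybean", "soy"} for v in ref]
    )
    cls_soy = classified.mask[r, c]
    return ConfusionMatrix(
        soy_soy=int(np.sum(cls_soy & ref_soy)),
        soy_non=int(np.sum(cls_soy & ~ref_soy)),
        non_soy=int(np.sum(~cls_soy & ref_soy)),
        non_non=int(np.sum(~cls_soy & ~ref_soy)),
    )


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Overall, per-class user's/producer's accuracy and Kappa.

    ``overall = trace/total``; user's accuracy divides each diagonal count
    by its classified-row total (commission side), producer's by its
    reference-column total (omission side); Kappa corrects the observed
    agreement for the chance agreement implied by the marginals:
    ``kappa = (p_o − p_e) / (1 − p_e)``.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    p_e = float(np.dot(row, col)) / total**2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)

    def _safe(num, den):
        return float(num / den) if den > 0 else float("nan")

    return {
        "overall_accuracy": float(p_o),
        "users_accuracy": {
            "soybean": _safe(counts[0, 0], row[0]),
            "non_soybean": _safe(counts[1, 1], row[1]),
        },
        "producers_accuracy": {
            "soybean": _safe(counts[0, 0], col[0]),
            "non_soybean": _safe(counts[1, 1], col[1]),
        },
        "kappa": float(kappa),
        "n": int(total),
    }


def regression_compare(
    estimates: pd.DataFrame,
    official: pd.DataFrame,
    about_identity_line: bool = False,
) -> RegressionReport:
    """OLS comparison of per-zone map areas against official statistics.

    Tables are joined on ``(zone_id, crop_year)``; the map estimate is the
    predictor and the official figure the response.  RMSD is the root mean
    square of the response-direction residuals about the fitted line (or,
    with ``about_identity_line=True``, about the 1:1 line);
    ``fraction_within_2rmsd`` is the share of points with
    ``|residual| ≤ 2·RMSD``.
    """
    merged = estimates.merge(
        official,
        on=["zone_id", "crop_year"],
        suffixes=("_est", "_official"),
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 matched (zone, year) points")
    x = merged["area_ha_est"].to_numpy(float)
    y = merged["area_ha_official"].to_numpy(float)
    fit = stats.linregress(x, y)
    if about_identity_line:
        resid = y - x
    else:
        resid = y - (fit.intercept + fit.slope * x)
    rmsd = float(np.sqrt(np.mean(resid**2)))
    within = float(np.mean(np.abs(resid) <= 2 * rmsd)) if rmsd > 0 else 1.0
    return RegressionReport(
        slope=float(fit.slope),
        intercept_ha=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmsd_ha=rmsd,
        fraction_within_2rmsd=within,
        n=len(merged),
    )
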