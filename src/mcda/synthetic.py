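"""Synthetic scenes with the temporal structure the crop detector assumes.

The generator renders a full set of inputs — a 16-day EVI composite stack,
a DEM, a zone map, rainfall series and per-pixel ground truth — for a
landscape tiled into rectangular fields.  Class phenologies follow the
double-logistic curve family standard for vegetation-index time series:
soybean rises sharply from a low pre-sowing baseline to a high summer peak
and senesces after a short cycle; double-cropping systems superpose a
second, calendar-shifted crop curve (cotton peaking around June, maize in
autumn); cerrado and forest keep a high EVI floor year-round; water stays
near zero.  Mixed pixels are emulated by blending a one-pixel band at field
borders with the neighbouring fields' profiles.

What this emulates — and what it does not: the statistical separations the
thresholds rely on (sowing-window minima, green-up amplitudes, the
confusion classes), on a clean grid with Gaussian radiometric noise.  It
does not simulate clouds beyond nodata masking, atmospheric artifacts, or
within-class calendar spread beyond the configured shifts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .classifier import RainfallSeries
from .composites import (
    STANDARD_DOYS,
    CompositeSeries,
    EVIComposite,
)
from .terrain import DEMRaster, mechanization_mask, resample_mask_to_grid, slope_percent
from .validation import ZoneMap

#: classes whose pixels count as soybean ground truth
SOYBEAN_CLASSES = frozenset({"soybean_single", "soybean_cotton", "soybean_maize"})

CLASS_CODES = {
    "soybean_single": 1,
    "soybean_cotton": 2,
    "soybean_maize": 3,
    "cotton_single": 4,
    "cerrado": 5,
    "forest": 6,
    "water": 7,
}


def _abs_day(year: int, doy: int) -> int:
    return dt.date(year, 1, 1).toordinal() + doy - 1


@dataclass(frozen=True)
class Phenology:
    """Double-logistic seasonal curve parameters (DOY, EVI units)."""

    base_evi: float
    peak_evi: float
    sowing_doy: int
    peak_doy: int
    season_length_days: int

    def __post_init__(self) -> None:
        if not 0 <= self.base_evi < self.peak_evi <= 1:
            raise ValueError("need 0 <= base_evi < peak_evi <= 1")

    def contribution(self, t: np.ndarray, sow_t: float) -> np.ndarray:
        """Shape factor in [0, 1] of the season anchored at ``sow_t``."""
        days_to_peak = (self.peak_doy - self.sowing_doy) % 365
        t0 = sow_t + days_to_peak / 2.0  # green-up midpoint
        r1 = max(days_to_peak / 6.0, 3.0)
        t1 = sow_t + self.season_length_days  # senescence midpoint
        return np.clip(expit((t - t0) / r1) - expit((t - t1) / 10.0), 0.0, 1.0)


@dataclass(frozen=True)
class LandCoverSpec:
    """One land-cover class: phenology, noise level and scene share."""

    class_name: str
    phenology: Phenology
    noise_sd: float = 0.02
    fraction: float = 0.0
    second: Phenology | None = None  # second crop of a double-cropping system
    calendar_shift_days: int = 0  # positive anticipates the calendar

    def shifted(self, days: int) -> "LandCoverSpec":
        """A copy whose calendar is anticipated by ``days`` more days."""
        return replace(self, calendar_shift_days=self.calendar_shift_days + days)


def default_specs() -> list[LandCoverSpec]:
    """The default landscape: a soybean frontier with its confusion classes.

    Shares: 45% soybean systems (30% single, 10% soybean→cotton, 5%
    soybean→maize), 10% single cotton, 40% natural cover (25% cerrado, 15%
    forest) and 5% water.  Soybean sows mid-October and peaks mid-January;
    the double-crop calendars are anticipated (14 days before cotton, 7
    before maize) to free the second crop's window; single cotton sows in
    December and is harvested around June; cerrado and forest keep EVI
    floors of 0.48 and 0.56.
    """
    return [
        LandCoverSpec(
            "soybean_single",
            Phenology(0.18, 0.85, sowing_doy=289, peak_doy=20, season_length_days=120),
            noise_sd=0.02, fraction=0.30,
        ),
        LandCoverSpec(
            "soybean_cotton",
            Phenology(0.18, 0.85, sowing_doy=275, peak_doy=1, season_length_days=115),
            noise_sd=0.02, fraction=0.10,
            second=Phenology(0.18, 0.80, sowing_doy=35, peak_doy=150,
                             season_length_days=180),
        ),
        LandCoverSpec(
            "soybean_maize",
            Phenology(0.18, 0.85, sowing_doy=282, peak_doy=10, season_length_days=112),
            noise_sd=0.02, fraction=0.05,
            second=Phenology(0.18, 0.75, sowing_doy=37, peak_doy=105,
                             season_length_days=110),
        ),
        LandCoverSpec(
            "cotton_single",
            Phenology(0.15, 0.80, sowing_doy=340, peak_doy=75, season_length_days=200),
            noise_sd=0.02, fraction=0.10,
        ),
        LandCoverSpec(
            "cerrado",
            Phenology(0.48, 0.65, sowing_doy=280, peak_doy=15, season_length_days=230),
            noise_sd=0.025, fraction=0.25,
        ),
        LandCoverSpec(
            "forest",
            Phenology(0.56, 0.72, sowing_doy=280, peak_doy=15, season_length_days=230),
            noise_sd=0.02, fraction=0.15,
        ),
        LandCoverSpec(
            "water",
            Phenology(0.00, 0.02, sowing_doy=280, peak_doy=15, season_length_days=230),
            noise_sd=0.02, fraction=0.05,
        ),
    ]


@dataclass
class SceneTruth:
    """Ground truth of a generated scene."""

    class_grid: np.ndarray  # CLASS_CODES values
    class_names: dict[int, str]
    soybean_mask: np.ndarray
    interior_mask: np.ndarray  # away from mixed field borders
    mechanizable_mask: np.ndarray  # condition-C truth on the composite grid
    field_rects: list = field(default_factory=list)  # (r0, r1, c0, c1, class)

    def reference_pixels(self, interior_only: bool = True):
        """Labelled (row, col, class) table for the validation sampler."""
        import pandas as pd

        sel = self.interior_mask if interior_only else np.ones_like(self.soybean_mask)
        rows, cols = np.nonzero(sel)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "class": np.where(self.soybean_mask[rows, cols], "soybean", "non_soybean"),
            }
        )


def evi_profile(
    spec: LandCoverSpec,
    dates: list[tuple[int, int]],
    seed: int | None = None,
    n_pixels: int = 1,
) -> np.ndarray:
    """EVI of one class at the given (year, doy) composite dates.

    Returns an array of shape ``(len(dates),)`` (or ``(len(dates),
    n_pixels)``) holding the double-logistic curve plus Gaussian noise with
    ``spec.noise_sd``, clipped to [−0.2, 1.0].  ``seed=None`` or
    ``noise_sd=0`` gives the deterministic curve.
    """
    t = np.array([_abs_day(y, d) for y, d in dates], dtype=float)
    years = range(min(y for y, _ in dates) - 1, max(y for y, _ in dates) + 1)
    shape = np.zeros_like(t)
    span = 0.0
    for phen in filter(None, (spec.phenology, spec.second)):
        part_span = phen.peak_evi - spec.phenology.base_evi
        for y in years:
            sow_t = _abs_day(y, phen.sowing_doy) - spec.calendar_shift_days
            shape = np.maximum(shape, phen.contribution(t, sow_t) * part_span)
        span = max(span, part_span)
    clean = spec.phenology.base_evi + shape
    if seed is None or spec.noise_sd == 0:
        out = clean if n_pixels == 1 else np.repeat(clean[:, None], n_pixels, axis=1)
        return np.clip(out, -0.2, 1.0)
    rng = np.random.default_rng(seed)
    noisy = clean[:, None] + rng.normal(0.0, spec.noise_sd, size=(t.size, n_pixels))
    if n_pixels == 1:
        noisy = noisy[:, 0]
    return np.clip(noisy, -0.2, 1.0)


def scene_dates(crop_year: int) -> list[tuple[int, int]]:
    """Standard 16-day composite dates from the prior year's sowing window
    through the crop year's wrap-around peak window."""
    dates = [(crop_year - 1, d) for d in STANDARD_DOYS if d >= 225]
    dates += [(crop_year, d) for d in STANDARD_DOYS]
    dates += [(crop_year + 1, d) for d in STANDARD_DOYS if d <= 33]
    return dates


def _tile_fields(rows, cols, field_rows, field_cols, specs, rng):
    """Tile the grid into rectangular fields and assign classes by share."""
    class_grid = np.zeros((rows, cols), dtype=np.int16)
    rects = []
    blocks = [
        (r0, min(r0 + field_rows, rows), c0, min(c0 + field_cols, cols))
        for r0 in range(0, rows, field_rows)
        for c0 in range(0, cols, field_cols)
    ]
    order = rng.permutation(len(blocks))
    fractions = np.array([s.fraction for s in specs], float)
    bounds = np.round(np.cumsum(fractions) / fractions.sum() * len(blocks)).astype(int)
    spec_of_block = np.empty(len(blocks), dtype=int)
    start = 0
    for k, stop in enumerate(bounds):
        spec_of_block[start:stop] = k
        start = stop
    spec_of_block[start:] = len(specs) - 1
    for rank, b in enumerate(order):
        r0, r1, c0, c1 = blocks[b]
        s = specs[spec_of_block[rank]]
        class_grid[r0:r1, c0:c1] = CLASS_CODES[s.class_name]
        rects.append((r0, r1, c0, c1, s.class_name))
    return class_grid, rects


def _border_mask(class_grid: np.ndarray) -> np.ndarray:
    """Pixels with a 4-neighbour of a different class."""
    g = class_grid
    border = np.zeros(g.shape, dtype=bool)
    border[:-1] |= g[:-1] != g[1:]
    border[1:] |= g[1:] != g[:-1]
    border[:, :-1] |= g[:, :-1] != g[:, 1:]
    border[:, 1:] |= g[:, 1:] != g[:, :-1]
    return border


def generate_scene(
    specs: list[LandCoverSpec] | None = None,
    grid_size: tuple[int, int] = (200, 200),
    field_size_ha: float = 182.7,
    seed: int = 0,
    crop_year: int = 2006,
    pixel_area_ha: float = 6.25,
    dem_factor: int = 3,
    steep_fraction: float = 0.05,
    n_zones: tuple[int, int] = (2, 2),
) -> tuple[CompositeSeries, SceneTruth, DEMRaster, ZoneMap]:
    """Render a complete synthetic scene for one crop year.

    The composite stack spans the prior year's sowing window through the
    crop year's wrap-around peak window, so both forecast modes are
    exercisable.  The DEM is flat except for a steep stripe
    (``steep_fraction`` of its columns, slope ≈ 30% > 12%) on a
    ``dem_factor``-times finer grid; zones split the scene into
    ``n_zones[0] × n_zones[1]`` municipalities.  Field footprints are
    rectangles sized to ``field_size_ha``; a one-pixel band at field
    borders is blended with neighbouring profiles to emulate mixed pixels.
    Bit-identical for a fixed seed.
    """
    specs = specs if specs is not None else default_specs()
    total = sum(s.fraction for s in specs)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class fractions must sum to 1, got {total}")
    rows, cols = grid_size
    rng = np.random.default_rng(seed)

    pixels_per_field = field_size_ha / pixel_area_ha
    field_rows = max(int(round(np.sqrt(pixels_per_field))), 1)
    field_cols = max(int(round(pixels_per_field / field_rows)), 1)
    class_grid, rects = _tile_fields(rows, cols, field_rows, field_cols, specs, rng)

    dates = scene_dates(crop_year)
    spec_by_code = {CLASS_CODES[s.class_name]: s for s in specs}
    profiles = {
        code: evi_profile(s, dates)  # noise added per pixel below
        for code, s in spec_by_code.items()
    }
    noise_sd_grid = np.zeros((rows, cols))
    cube = np.empty((len(dates), rows, cols))
    for code, prof in profiles.items():
        sel = class_grid == code
        cube[:, sel] = prof[:, None]
        noise_sd_grid[sel] = spec_by_code[code].noise_sd

    # mixed border pixels: blend with the 4-neighbour mean profile
    border = _border_mask(class_grid)
    for k in range(len(dates)):
        v = cube[k]
        nm = np.pad(v, 1, mode="edge")
        neigh = (nm[:-2, 1:-1] + nm[2:, 1:-1] + nm[1:-1, :-2] + nm[1:-1, 2:]) / 4.0
        cube[k] = np.where(border, 0.55 * v + 0.45 * neigh, v)

    cube += rng.normal(0.0, 1.0, size=cube.shape) * noise_sd_grid[None]
    np.clip(cube, -0.2, 1.0, out=cube)

    series = CompositeSeries(
        [
            EVIComposite(cube[k], year=y, doy=d)
            for k, (y, d) in enumerate(dates)
        ],
        pixel_area_ha=pixel_area_ha,
    )

    # DEM: flat 400 m plateau with a steep north-south ramp stripe
    dem_rows, dem_cols = rows * dem_factor, cols * dem_factor
    cell = 250.0 / dem_factor
    elev = np.full((dem_rows, dem_cols), 400.0)
    stripe_w = max(int(round(steep_fraction * dem_cols)), 1)
    c0 = int(0.7 * dem_cols)
    # 30% slope sawtooth; folds every 40 cells keep elevations plausible
    ramp = 0.30 * cell * (np.arange(dem_rows) % 40)
    elev[:, c0 : c0 + stripe_w] += ramp[:, None]
    dem = DEMRaster(elev, cell_size_m=cell)
    mech = resample_mask_to_grid(
        mechanization_mask(slope_percent(dem)), (rows, cols)
    )

    zone_ids = np.zeros((rows, cols), dtype=np.int64)
    zr, zc = n_zones
    r_edges = np.linspace(0, rows, zr + 1).astype(int)
    c_edges = np.linspace(0, cols, zc + 1).astype(int)
    names = {}
    zid = 0
    for i in range(zr):
        for j in range(zc):
            zid += 1
            zone_ids[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]] = zid
            names[zid] = f"Municipio {zid}"
    zones = ZoneMap(zone_ids, names)

    soy = np.isin(
        class_grid,
        [CLASS_CODES[c] for c in SOYBEAN_CLASSES if c in CLASS_CODES],
    )
    truth = SceneTruth(
        class_grid=class_grid,
        class_names={v: k for k, v in CLASS_CODES.items()},
        soybean_mask=soy,
        interior_mask=~border,
        mechanizable_mask=mech,
        field_rects=rects,
    )
    return series, truth, dem, zones


def generate_rainfall(
    deficit: bool,
    seed: int = 0,
    year: int = 2006,
    station_id: str = "station-1",
) -> RainfallSeries:
    """Dekadal rainfall from 1 September to late February.

    ``deficit=False`` guarantees an event above 10 mm in every 30-day span
    (all accumulations 12–60 mm); ``deficit=True`` embeds a dry spell of six
    dekads (1 December – 30 January, all ≤ 8 mm) covering the peak-growth
    window.  Identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    start = dt.date(year, 9, 1)
    end = dt.date(year + 1, 2, 28)
    records = []
    d = start
    dry0, dry1 = dt.date(year, 12, 1), dt.date(year + 1, 1, 30)
    while d <= end:
        if deficit and dry0 <= d <= dry1:
            mm = float(rng.uniform(0.0, 8.0))
        else:
            mm = float(rng.uniform(12.0, 60.0))
        records.append((d, mm))
        d += dt.timedelta(days=10)
    return RainfallSeries(station_id, records)
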