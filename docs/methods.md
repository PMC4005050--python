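# Methods

## Model and assumptions

The detector is a fixed-threshold classifier on two per-crop-year summary
images of a 16-day EVI composite stack.  It assumes:

1. **A regional crop calendar.**  Soybean is sown inside a fixed sowing
   window (DOY 225–337) and reaches maximum development inside a fixed
   peak window (DOY 353–033, wrapping the calendar year).  The windows are
   calendar constants, not per-pixel estimates; rainfall-derived sowing
   onset is computed as advisory metadata only, because no quantitative
   window-shifting rule is part of the procedure.
2. **Separable profile statistics.**  During the sowing window soybean
   pixels are bare (low EVI), unlike evergreen cerrado/forest (high floor)
   and water/cloud shadow (near or below zero); during the peak window they
   are fully green.  The green-up amplitude therefore separates annual
   crops from stable cover.
3. **Inter-annual threshold stability.**  The thresholds represent
   physically driven components (soil background, canopy development) and
   are frozen across all crop years of a run; `freeze_parameters` and the
   immutable `MCDAParameters` enforce this discipline in code.

### Summary images

*MinMeanEVI*: consecutive sowing-window composites are averaged two by two
("averaged two by two" is read as consecutive-pair means) and the per-pixel
minimum over pair means is taken.  This smooths single-composite noise over
a short time window while staying deterministic; it is the only mode
exposed.  A pixel masked in one pair member falls back to the surviving
member — the composite product is already gap-filled by maximum-value
compositing, so the survivor is the best available estimate.  Pair order
matters (consecutive pairing), which is documented and tested.

*MaxMeanEVI*: the mean of the four consecutive peak-window composites.
The window is fixed; when more than four composites fall inside it the
first four are used and extras ignored with a warning (no per-scene
maximization, which would break determinism and inter-year comparability).
Fewer than four is an error in strict mode (default); lenient mode averages
what exists and logs.

*AmpEVI* = MaxMeanEVI − MinMeanEVI.  Negative amplitudes are preserved,
not clamped — they flag inverted seasonality or artifacts and must remain
visible to diagnostics.

### Conditions

- **A**: `Lmin ≤ MinMeanEVI ≤ Umin`, **B**: `AmpEVI ≥ Amp`.  Closed
  bounds, so the calibrated value itself is admissible (Amp is defined as
  the *minimum* amplitude at which a mixed border pixel still counts as
  soybean).  A strict-inequality switch exists in the config.
- **C**: percent slope ≤ 12, from Horn's 3×3 operator (the GIS standard)
  with replicated edges (one-sided differences at borders) and nodata
  propagated to the 3×3 neighbourhood.  Exclusion is strictly "> 12 %".
  The slope is thresholded at DEM resolution first, then aggregated to the
  composite grid by majority rule (≥ 50 % of overlapping cells, exposed as
  `min_fraction`); thresholding before aggregation keeps the mask
  conservative on mixed steep/flat coarse pixels.
- **D**: an externally supplied management mask, all-true by default.  Its
  construction (land-use masking) is site-specific and out of scope, so it
  is a pluggable input.

### Forecast modes and rainfall rules

The second forecast uses current-year images for both summaries.  The first
forecast replaces MaxMeanEVI with the most recent prior *normal* year's
(not flagged as deficit, with usable peak composites); the same
substitution serves the second forecast when the current peak window is
unusable or a water deficit is detected.  Fallback provenance is recorded
on the output map.  The first forecast misses pixels newly converted to
soybean (their prior-year peak is low) — an inherent, tested limitation.

Water deficit: a 30-consecutive-day span inside the window with no dekadal
accumulation above 10 mm.  Events are record dates with > 10 mm; a deficit
exists when the gap between consecutive events (or an event and a window
edge) covers ≥ 30 event-free days.  The scan is applied per supplied
station series and treated as scene-wide — station zones of influence are
not modelled.

## Parameters

| parameter | unit | default | meaning |
|---|---|---|---|
| `lmin` | EVI | 0.05 | floor of condition A: below it, water/cloud shadow |
| `umin` | EVI | 0.39 | ceiling of condition A: above it, evergreen cover |
| `amp` | EVI | 0.36 | minimum green-up amplitude (condition B) |
| `slope_threshold_pct` | % | 12 | mechanization limit (condition C) |
| sowing window | DOY | 225–337 | pre-sowing/sowing period |
| peak window | DOY | 353–033 | maximum crop development |
| `pixel_area_ha` | ha | 6.25 | 250 m pixel |
| deficit rule | — | 30 d / 10 mm | water-deficit fallback trigger |

The operational threshold triple is quoted in its source with the labels
Umin and Lmin interchanged (an ordering that would violate Lmin < Umin by
definition); this package uses the only physically consistent assignment,
Lmin = 0.05, Umin = 0.39, Amp = 0.36.

## Calibration

The convergence procedure is described verbally in the source; the
implementation is a concrete, deterministic operationalization with every
constant exposed:

- `estimate_lmin`: a low quantile (default 1st percentile) of minimum-image
  values after excluding the sub-zero water/shadow mode.
- `estimate_umin`: paired (min, max) samples are binned on the min axis
  (`bin_width` 0.01); scanning upward from Lmin, Umin is the first column
  whose mass within the diagonal band `|max − min| < band_width` exceeds
  `density_fraction` (5 %) of the column — where the minimum and maximum
  images converge.  No convergent column → flagged, 99th percentile
  fallback.
- `estimate_amp`: among crop candidates (min ≤ Umin), amplitudes inside the
  diagonal band are discarded and Amp is the 1st percentile of the rest —
  the lower edge of the crop cluster, which is where mixed border pixels
  sit.

The `band_width` default (0.05 EVI) describes strictly evergreen
convergence classes whose EVI barely moves between the two windows.  Where
the convergence class itself greens up seasonally — savanna gains roughly
0.15 EVI in the wet season, in synthetic scenes as in the field — the band
must cover that swing (≈ 0.2) or no column converges; the parameter exists
precisely for this landscape dependence.  Calibration sites are user input:
they are meant to be placed in crop regions (the recovery tests place them
over soybean systems and their natural confusion classes), not sampled
blindly over the whole scene.

Fewer than 1,000 paired samples flags the result low-confidence.  The
manual multi-year adjustment of thresholds against official statistics has
no stated objective function and is supported only as user-pinned values in
`freeze_parameters` (default rule otherwise: per-component median across
per-year estimates, retained for audit).

## Validation protocol

Stratified sampling draws `n_per_class` (default 200) reference pixels per
class without replacement, reproducibly from a seed.  Accuracy metrics come
from the 2×2 classified × reference counts: overall = trace/total, user's
accuracy per classified row, producer's per reference column, and Kappa
`(p_o − p_e)/(1 − p_e)` with chance agreement from the marginal products.

The regression diagnostic takes the map estimate as predictor and the
official figure as response (the map "explains" the official variation);
RMSD is computed about the fitted line — matching the double-RMSD band
convention — with a switch for the 1:1 line.  `fraction_within_2rmsd` is
the share of points with |residual| ≤ 2·RMSD (≈ 0.954 for Gaussian
residuals).

A published 400-pixel campaign matrix with cells (153, 0, 47, 200) serves
as a fixed-point test: it must yield 88.25 % overall accuracy, Kappa 0.765
and 100 % soybean user's accuracy.  The printed per-class accuracies
accompanying that table are internally transposed relative to its cells
(200/247 = 80.97 % is the non-soybean user's accuracy, 153/200 = 76.5 % the
soybean producer's); all metrics here are computed from the cells, which
reproduce the printed overall accuracy and Kappa exactly.

## Synthetic scenes

The generator tiles the grid into rectangular fields (default 182.7 ha,
about 5×6 pixels at 6.25 ha) and assigns classes by share — defaults: 30 %
single soybean, 10 % soybean→cotton, 5 % soybean→maize, 10 % single
cotton, 25 % cerrado, 15 % forest, 5 % water.  Profiles are double-logistic
curves (the standard vegetation-index family): soybean rises from a 0.18
baseline to a ~0.8 peak in January over a ~120-day cycle; double-crop
calendars are anticipated (14 days before cotton, 7 before maize) with the
second crop's curve superposed; single cotton sows in December and peaks
around March–April, keeping its peak-window EVI too low for condition B;
cerrado (floor 0.48) and forest (0.56) stay above Umin; water stays near
zero.  Gaussian noise (σ 0.02–0.025 EVI) is added per pixel and composite;
a one-pixel border band is blended 55/45 with the 4-neighbour mean to
emulate mixed pixels.  The DEM is a flat 400 m plateau with a stripe
(default 5 % of columns) of 30 % sawtooth slope on a 3× finer grid; zones
split the scene 2×2.

The "calendar detuning" experiment anticipates the soybean→cotton calendar
by a further 30 days, which pulls soybean senescence into the peak window
and drops its amplitude below Amp — reproducing, qualitatively, the
omission-dominated error structure (user's accuracy stays ~100 %, soybean
producer's accuracy falls by ~15–25 points).  The anticipation direction
follows the agronomy: producers sow soybean earlier to free the cotton
window, so the detuning shortens, not delays, the observed peak.

What passing tests show — and what they do not: the thresholds separate
the generator's class geometry under Gaussian noise and fixed calendars.
Real composites add cloud-contaminated residuals, within-class calendar
spread, irrigation, field-size diversity and registration error; accuracy
numbers on synthetic scenes are upper bounds, not forecasts, for real
scenes.

## Numerical choices

- EVI grids are float64 internally; rasters serialize as float32 (NaN
  nodata) or uint8 (255 nodata).  Stored integers are scaled ×10⁻⁴,
  auto-detected by dtype/range, overridable.
- Pair means and four-image means use NaN-aware reductions; a pixel masked
  everywhere is nodata, and classification returns False (never soybean) on
  nodata with the nodata grid kept separately.
- All randomness (scene, noise, sampling) flows from explicit integer
  seeds through `numpy.random.default_rng`; reruns are byte-identical,
  including serialized output (JSON keys sorted, floats at 6 significant
  digits).
- Grid convention: row-major, origin top-left, 0-based indices;
  geotransform and CRS are carried as opaque metadata (no reprojection —
  inputs must share a grid).
- Problem sizes: unit tests run on ≤ 8×8 stacks and 120×120 scenes;
  end-to-end recovery and the acceptance script use 200×200 scenes
  (40,000 pixels, 35 composites), sizes at which class statistics are
  stable to well under a percentage point across seeds.

## Known limitations

- Condition D is a pass-through mask; no land-use modelling.
- No time-series smoothing or QA-layer screening; the nodata mask is the
  only cloud mechanism.
- The first forecast structurally misses newly converted fields and
  inherits any prior-year anomaly not flagged as deficit.
- Calibration assumes the scatter contains both a crop cluster and a
  convergence class; single-population samples fall back to quantiles with
  warnings.
- Second crops are not identified as such — double-cropping affects
  detection only through the soybean calendar shift.
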