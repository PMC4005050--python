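"""Raster and table I/O, run configuration.

Rasters travel as single-band TIFF with a JSON metadata payload in the
ImageDescription tag (year/doy tags, nodata value, scale factor, image
kind).  Composite stacks are read from a directory of files named
``evi_<year>_<doy>.tif`` or from a manifest CSV (``filename,year,doy``)
for sources with opaque names.  Stored integers are scaled by 1e-4 (the
convention of the 16-day product) unless a scale factor is given; floats
pass through.  Tables are CSV, metric reports JSON with floats at six
significant digits, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classifier import MCDAParameters, SoybeanMap
from .composites import CompositeImage, CompositeSeries, EVIComposite
from .validation import ConfusionMatrix, RegressionReport, accuracy_metrics

_FILENAME_RE = re.compile(r"(\d{4})_(\d{1,3})\.tiff?$", re.IGNORECASE)

#: nodata code of uint8 classification rasters
NODATA_UINT8 = 255

DEFAULT_CONFIG = {
    "lmin": 0.05,
    "umin": 0.39,
    "amp": 0.36,
    "slope_threshold_pct": 12.0,
    "strict_inequalities": False,
    "pixel_area_ha": 6.25,
    "sowing_start_doy": 225,
    "sowing_end_doy": 337,
    "maxdev_start_doy": 353,
    "maxdev_end_doy": 33,
    "scale_factor": None,
    "seed": 0,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Flat key-value run configuration, validated against the known keys."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update(overrides)
    return cfg


def params_from_config(cfg: dict) -> MCDAParameters:
    return MCDAParameters(
        lmin=cfg["lmin"],
        umin=cfg["umin"],
        amp=cfg["amp"],
        slope_threshold_pct=cfg["slope_threshold_pct"],
        strict_inequalities=cfg["strict_inequalities"],
    )


def _round6(x):
    """Six significant digits for stable serialized output."""
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def write_raster(
    path: str | Path,
    values: np.ndarray,
    nodata_mask: np.ndarray | None = None,
    metadata: dict | None = None,
) -> None:
    """Single-band TIFF; float32 with NaN nodata, or uint8 with 255 nodata."""
    values = np.asarray(values)
    meta = dict(metadata or {})
    if values.dtype == bool:
        values = values.astype(np.uint8)
    if np.issubdtype(values.dtype, np.floating):
        out = values.astype(np.float32)
        if nodata_mask is not None:
            out = np.where(nodata_mask, np.float32(np.nan), out)
        meta["nodata"] = "nan"
    else:
        out = values.astype(np.uint8)
        if nodata_mask is not None:
            out[np.asarray(nodata_mask, bool)] = NODATA_UINT8
        meta["nodata"] = NODATA_UINT8
    tifffile.imwrite(path, out, description=json.dumps(meta, sort_keys=True))


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a single-band TIFF and its JSON ImageDescription metadata."""
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {"description": desc}
    return values, meta


def write_composite_image(path: str | Path, img: CompositeImage) -> None:
    write_raster(
        path,
        img.values,
        img.nodata_mask,
        {"kind": img.kind, "source_tags": [list(t) for t in img.source_tags]},
    )


def read_composite_image(path: str | Path) -> CompositeImage:
    values, meta = read_raster(path)
    return CompositeImage(
        values.astype(np.float64),
        kind=meta["kind"],
        source_tags=[tuple(t) for t in meta.get("source_tags", [])],
    )


def _apply_scale(values: np.ndarray, scale: float | None) -> tuple[np.ndarray, float]:
    """Scale stored integers to EVI floats; auto-detect by dtype/range."""
    if scale is None:
        if np.issubdtype(values.dtype, np.integer):
            scale = 1e-4
        else:
            finite = values[np.isfinite(values)]
            scale = 1e-4 if finite.size and np.abs(finite).max() > 2.0 else 1.0
    return values.astype(np.float64) * scale, float(scale)


def write_composite_stack(
    directory: str | Path, series: CompositeSeries
) -> list[Path]:
    """One ``evi_<year>_<doy>.tif`` per composite."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for comp in series:
        p = directory / f"evi_{comp.year}_{comp.doy:03d}.tif"
        write_raster(
            p, comp.values, comp.nodata_mask, {"year": comp.year, "doy": comp.doy}
        )
        paths.append(p)
    return paths


def read_composite_stack(
    path: str | Path,
    manifest: str | Path | None = None,
    scale_factor: float | None = None,
    pixel_area_ha: float = 6.25,
) -> CompositeSeries:
    """Read a composite stack from a directory or a manifest CSV.

    Without a manifest, (year, doy) are parsed from filenames ending in
    ``_<year>_<doy>.tif``.  A manifest CSV with columns
    ``filename,year,doy`` overrides filename parsing.  Duplicate
    (year, doy) pairs and grid mismatches are errors.
    """
    path = Path(path)
    entries: list[tuple[Path, int, int]] = []
    if manifest is not None:
        table = pd.read_csv(manifest)
        for _, row in table.iterrows():
            entries.append((path / str(row["filename"]), int(row["year"]), int(row["doy"])))
    else:
        for p in sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff")):
            m = _FILENAME_RE.search(p.name)
            if not m:
                raise ValueError(
                    f"cannot parse (year, doy) from filename {p.name!r}; "
                    "use a manifest CSV"
                )
            entries.append((p, int(m.group(1)), int(m.group(2))))
    if not entries:
        raise ValueError(f"no composites found under {path}")
    composites = []
    for p, year, doy in entries:
        raw, meta = read_raster(p)
        nodata = None
        if np.issubdtype(raw.dtype, np.floating):
            nodata = ~np.isfinite(raw)
        elif meta.get("nodata") is not None and meta["nodata"] != "nan":
            nodata = raw == meta["nodata"]
        values, used_scale = _apply_scale(raw, scale_factor)
        composites.append(
            EVIComposite(values, year=year, doy=doy, nodata_mask=nodata,
                         scale_factor=used_scale)
        )
    return CompositeSeries(composites, pixel_area_ha=pixel_area_ha)


def write_soybean_map(path: str | Path, soy_map: SoybeanMap) -> None:
    """uint8 raster (1 soybean, 0 other, 255 nodata) + JSON sidecar."""
    path = Path(path)
    write_raster(path, soy_map.mask.astype(np.uint8), soy_map.nodata_mask)
    sidecar = {
        "crop_year": soy_map.crop_year_label,
        "forecast_mode": soy_map.forecast_mode,
        "fallback_used": soy_map.fallback_used,
        "parameters": dataclasses.asdict(soy_map.params) if soy_map.params else None,
        "source_tags": soy_map.source_tags,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_round6(sidecar), sort_keys=True, indent=2) + "\n"
    )


def read_soybean_map(path: str | Path) -> SoybeanMap:
    path = Path(path)
    values, _ = read_raster(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    params = sidecar.get("parameters")
    return SoybeanMap(
        mask=values == 1,
        nodata_mask=values == NODATA_UINT8,
        crop_year_label=sidecar.get("crop_year", ""),
        forecast_mode=sidecar.get("forecast_mode", "second"),
        fallback_used=sidecar.get("fallback_used", False),
        params=MCDAParameters(**params) if params else None,
    )


def read_rainfall_csv(path: str | Path):
    """CSV with columns date, station, accumulated_mm (10-day totals)."""
    from .classifier import RainfallSeries

    table = pd.read_csv(path, parse_dates=["date"])
    series = []
    for station, group in table.groupby("station"):
        records = [
            (d.date(), float(mm))
            for d, mm in zip(group["date"], group["accumulated_mm"])
        ]
        series.append(RainfallSeries(str(station), sorted(records)))
    return series


def write_report(obj, path: str | Path) -> Path:
    """CSV for tables, JSON for metric reports; deterministic formatting."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        out = obj.copy()
        for col in out.select_dtypes(include=float):
            out[col] = out[col].map(lambda v: float(f"{v:.6g}"))
        out.to_csv(path, index=False)
        return path
    if isinstance(obj, ConfusionMatrix):
        obj = {"counts": obj.counts.tolist(), **accuracy_metrics(obj)}
    elif isinstance(obj, RegressionReport):
        obj = dataclasses.asdict(obj)
    path.write_text(json.dumps(_round6(obj), sort_keys=True, indent=2) + "\n")
    return path
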