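"""File formats: single-band TIFF rasters with JSON sidecars, and CSVs.

Rasters are written one band per variable per time slice as
``bio_<var>_<age>ka.tif`` (plus ``dem.tif``), with a JSON sidecar
carrying the grid geometry and slice age.  Categorical maps get a
``*_legend.csv`` (id, label).  Occurrences, CO2 series, correction
tables and pollen records travel as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import NO_ANALOG, ClimateStack, GridGeometry, SuitabilitySurface, VegetationUnitMap
from .projection import CorrectionTable
from .synthetic import CO2Series, OccurrenceSet
from .pollen import PollenRecord


def format_age(age_ka: float) -> str:
    return f"{age_ka:g}"


def _geometry_to_dict(g: GridGeometry) -> dict:
    return {
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "cell_size_km": g.cell_size_km,
        "x_origin": g.x_origin,
        "y_origin": g.y_origin,
        "registration": "cell-center",
    }


def _geometry_from_dict(d: dict) -> GridGeometry:
    return GridGeometry(
        n_rows=int(d["n_rows"]),
        n_cols=int(d["n_cols"]),
        cell_size_km=float(d["cell_size_km"]),
        x_origin=float(d.get("x_origin", 0.0)),
        y_origin=float(d.get("y_origin", 0.0)),
    )


def write_raster(path, array: np.ndarray, geometry: GridGeometry, **meta) -> Path:
    """Single-band TIFF plus a `<name>.json` sidecar with geometry/meta."""
    path = Path(path)
    arr = np.asarray(array)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    sidecar = {"geometry": _geometry_to_dict(geometry), **meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_raster(path) -> tuple[np.ndarray, GridGeometry, dict]:
    path = Path(path)
    arr = np.asarray(tifffile.imread(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    geometry = _geometry_from_dict(meta.pop("geometry"))
    return arr, geometry, meta


def write_climate_stack(stack: ClimateStack, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    age = format_age(stack.age_ka)
    for var, layer in stack.variables.items():
        write_raster(
            out_dir / f"bio_{var}_{age}ka.tif", layer, stack.geometry,
            age_ka=stack.age_ka, variable=var,
        )
    if stack.elevation is not None:
        write_raster(out_dir / "dem.tif", stack.elevation, stack.geometry, variable="elevation")
    return out_dir


def read_climate_stack(stack_dir, age_ka: float) -> ClimateStack:
    stack_dir = Path(stack_dir)
    age = format_age(age_ka)
    suffix = f"_{age}ka.tif"
    variables = {}
    geometry = None
    for path in sorted(stack_dir.glob(f"bio_*{suffix}")):
        var = path.name[len("bio_") : -len(suffix)]
        arr, geometry, _ = read_raster(path)
        variables[var] = arr.astype(float)
    if not variables:
        raise FileNotFoundError(f"no layers for age {age} ka in {stack_dir}")
    elevation = None
    dem = stack_dir / "dem.tif"
    if dem.exists():
        elevation = read_raster(dem)[0].astype(float)
    return ClimateStack(geometry=geometry, age_ka=age_ka, variables=variables, elevation=elevation)


def available_stack_ages(stack_dir) -> list[float]:
    ages = set()
    for path in Path(stack_dir).glob("bio_*ka.tif"):
        ages.add(float(path.stem.rsplit("_", 1)[-1][:-2]))
    return sorted(ages, reverse=True)


def write_vumap(vumap: VegetationUnitMap, path) -> Path:
    path = Path(path)
    write_raster(
        path,
        vumap.codes.astype(np.int32),
        vumap.geometry,
        age_ka=vumap.age_ka,
        no_analog_threshold=vumap.no_analog_threshold,
        units=list(vumap.units),
        provenance=list(vumap.provenance),
    )
    legend = pd.DataFrame(
        {"id": list(range(len(vumap.units))) + [NO_ANALOG],
         "label": list(vumap.units) + ["no_analog"]}
    )
    legend.to_csv(path.with_name(path.stem + "_legend.csv"), index=False)
    return path


def read_vumap(path) -> VegetationUnitMap:
    arr, geometry, meta = read_raster(path)
    return VegetationUnitMap(
        geometry=geometry,
        codes=arr.astype(np.int64),
        units=tuple(meta["units"]),
        age_ka=float(meta.get("age_ka", 0.0)),
        no_analog_threshold=float(meta.get("no_analog_threshold", 0.1)),
        provenance=tuple(meta.get("provenance", ())),
    )


def surface_filename(surface: SuitabilitySurface) -> str:
    corr = "_corr" if surface.corrected else ""
    return f"suit_{surface.vu_id}_{format_age(surface.age_ka)}ka{corr}.tif"


def write_surface(surface: SuitabilitySurface, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / surface_filename(surface)
    write_raster(
        path, surface.values, surface.geometry,
        vu_id=surface.vu_id, age_ka=surface.age_ka, corrected=surface.corrected,
    )
    return path


def read_surface(path) -> SuitabilitySurface:
    arr, geometry, meta = read_raster(path)
    return SuitabilitySurface(
        vu_id=meta["vu_id"],
        age_ka=float(meta["age_ka"]),
        geometry=geometry,
        values=arr.astype(float),
        corrected=bool(meta.get("corrected", False)),
    )


def write_occurrences(occ: OccurrenceSet, path) -> Path:
    path = Path(path)
    occ.to_frame().to_csv(path, index=False)
    return path


def read_occurrences(path, vu_id: str | None = None) -> OccurrenceSet:
    df = pd.read_csv(path)
    if vu_id is not None:
        df = df[df["vu_id"] == vu_id]
    ids = df["vu_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"occurrence file holds {len(ids)} units; pass vu_id")
    return OccurrenceSet(
        vu_id=str(ids[0]),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        provenance="file",
    )


def write_co2(series: CO2Series, path) -> Path:
    series.to_frame().to_csv(path, index=False)
    return Path(path)


def read_co2(path) -> CO2Series:
    df = pd.read_csv(path).sort_values("age_ka", ascending=False)
    return CO2Series(
        ages_ka=tuple(df["age_ka"].astype(float)),
        co2_ppm=tuple(df["co2_ppm"].astype(float)),
    )


def write_correction_table(table: CorrectionTable, path) -> Path:
    table.to_frame().to_csv(path, index=False)
    return Path(path)


def write_pollen_record(record: PollenRecord, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record.counts.rename_axis("sample_id").to_csv(out_dir / "counts.csv")
    record.chronology.to_csv(out_dir / "chronology.csv", index=False)
    pd.DataFrame(
        [{"site_id": record.site_id, "x": record.x, "y": record.y,
          "elevation": record.elevation}]
    ).to_csv(out_dir / "site.csv", index=False)
    return out_dir


def read_pollen_record(record_dir) -> PollenRecord:
    record_dir = Path(record_dir)
    counts = pd.read_csv(record_dir / "counts.csv", index_col="sample_id")
    chron = pd.read_csv(record_dir / "chronology.csv")
    site = pd.read_csv(record_dir / "site.csv").iloc[0]
    return PollenRecord(
        site_id=str(site["site_id"]),
        x=float(site["x"]),
        y=float(site["y"]),
        elevation=float(site.get("elevation", 0.0)),
        chronology=chron,
        counts=counts,
    )
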