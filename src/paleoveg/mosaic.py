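"""Compositing suitability surfaces into vegetation maps and summaries.

For each time slice the per-unit probability surfaces are composited
cell by cell: the unit with the highest suitability claims the cell,
unless every unit falls below the no-analog threshold (default 0.1), in
which case the cell is left unassigned.  Areas and robust elevation
limits per unit are then tracked through time.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryMismatchError
from .grids import (
    NO_ANALOG,
    NO_ANALOG_LABEL,
    SuitabilitySurface,
    VegetationUnitMap,
)

DEFAULT_NO_ANALOG_THRESHOLD = 0.1
DEFAULT_LOWER_PCT = 2.0
DEFAULT_UPPER_PCT = 98.0


def composite(
    surfaces: Mapping[str, SuitabilitySurface] | Sequence[SuitabilitySurface],
    threshold: float = DEFAULT_NO_ANALOG_THRESHOLD,
    unit_order: Sequence[str] | None = None,
) -> VegetationUnitMap:
    """Cell-by-cell argmax over unit suitabilities with a no-analog floor.

    Ties are broken in favour of the earlier unit in ``unit_order``
    (default: the order the surfaces are supplied in), which is recorded
    in the map's unit tuple.
    """
    if isinstance(surfaces, Mapping):
        by_unit = dict(surfaces)
    else:
        by_unit = {s.vu_id: s for s in surfaces}
    if not by_unit:
        raise ValueError("at least one surface is required")
    order = tuple(unit_order) if unit_order is not None else tuple(by_unit)
    missing = [u for u in order if u not in by_unit]
    if missing:
        raise ValueError(f"no surface supplied for units: {missing}")
    ref = by_unit[order[0]]
    for s in by_unit.values():
        if s.geometry != ref.geometry:
            raise GeometryMismatchError("surfaces do not share geometry")
        if s.age_ka != ref.age_ka:
            raise GeometryMismatchError("surfaces do not share the time slice")
    stack = np.stack([by_unit[u].values for u in order])
    best = stack.argmax(axis=0)  # first maximum wins: documented tie-break
    codes = np.where(stack.max(axis=0) >= threshold, best, NO_ANALOG)
    return VegetationUnitMap(
        geometry=ref.geometry,
        codes=codes.astype(np.int64),
        units=order,
        age_ka=ref.age_ka,
        no_analog_threshold=threshold,
        provenance=tuple(f"{u}@{by_unit[u].age_ka}ka" for u in order),
    )


def area_by_vu(vumap: VegetationUnitMap, cell_area_km2: float | None = None) -> pd.Series:
    """Area (km2) per label plus no-analog and total land area."""
    if cell_area_km2 is None:
        cell_area_km2 = vumap.geometry.cell_area_km2
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    counts = vumap.counts()
    areas = {label: n * cell_area_km2 for label, n in counts.items()}
    areas["total"] = vumap.geometry.n_cells * cell_area_km2
    return pd.Series(areas, name=vumap.age_ka)


def elevation_limits(
    vumap: VegetationUnitMap,
    dem: np.ndarray,
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
) -> pd.DataFrame:
    """Robust lower/upper elevation limit per unit (percentiles of its cells).

    Percentiles (default 2nd/98th) are used instead of min/max so single
    outlying cells do not define a belt boundary.  Units absent from the
    map are reported missing.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.shape != vumap.geometry.shape:
        raise GeometryMismatchError("DEM does not share the map grid")
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValueError("percentiles must satisfy 0 <= lower < upper <= 100")
    rows = []
    for unit in vumap.units:
        elev = dem[vumap.mask(unit)]
        if elev.size == 0:
            rows.append((unit, np.nan, np.nan, 0))
        else:
            rows.append(
                (
                    unit,
                    float(np.percentile(elev, lower_pct)),
                    float(np.percentile(elev, upper_pct)),
                    int(elev.size),
                )
            )
    df = pd.DataFrame(rows, columns=["unit", "lower_m", "upper_m", "n_cells"])
    df.attrs["lower_pct"] = lower_pct
    df.attrs["upper_pct"] = upper_pct
    df.attrs["age_ka"] = vumap.age_ka
    return df


def timeseries_summary(
    vumaps: Sequence[VegetationUnitMap],
    dem: np.ndarray,
    cell_area_km2: float | None = None,
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
) -> pd.DataFrame:
    """Tidy per-(age, label) table of areas and elevation limits.

    One row per age per label (units plus the no-analog class; limits for
    the latter are reported missing), sorted oldest to youngest.
    """
    if not vumaps:
        raise ValueError("at least one vegetation map is required")
    records = []
    for vm in sorted(vumaps, key=lambda v: -v.age_ka):
        areas = area_by_vu(vm, cell_area_km2)
        lims = elevation_limits(vm, dem, lower_pct, upper_pct).set_index("unit")
        for unit in vm.units:
            records.append(
                {
                    "age_ka": vm.age_ka,
                    "unit": unit,
                    "area_km2": areas[unit],
                    "lower_m": lims.loc[unit, "lower_m"],
                    "upper_m": lims.loc[unit, "upper_m"],
                }
            )
        records.append(
            {
                "age_ka": vm.age_ka,
                "unit": NO_ANALOG_LABEL,
                "area_km2": areas[NO_ANALOG_LABEL],
                "lower_m": np.nan,
                "upper_m": np.nan,
            }
        )
    df = pd.DataFrame.from_records(records)
    df.attrs["lower_pct"] = lower_pct
    df.attrs["upper_pct"] = upper_pct
    return df
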