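"""Grid geometry and the core gridded containers.

Everything downstream of the landscape generator works on simple
row/column rasters with cell-center registration: a :class:`ClimateStack`
of named bioclimatic layers for one time slice, a per-unit
:class:`SuitabilitySurface`, and the categorical :class:`VegetationUnitMap`
produced by compositing.  Coordinates are planar kilometres; ``x`` grows
with column index, ``y`` with row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import GeometryMismatchError, OffGridError

#: Canonical names for the nine default predictors.
NINE_PREDICTORS = (
    "annual_mean_temp",
    "max_temp_warmest_month",
    "min_temp_coldest_month",
    "temp_wettest_quarter",
    "temp_driest_quarter",
    "annual_precip",
    "precip_wettest_month",
    "precip_driest_month",
    "precip_warmest_quarter",
)

#: The ten remaining layers of the 19-variable bioclim set.
EXTRA_BIOCLIM = (
    "mean_diurnal_range",
    "isothermality",
    "temp_seasonality",
    "temp_annual_range",
    "temp_warmest_quarter",
    "temp_coldest_quarter",
    "precip_seasonality",
    "precip_wettest_quarter",
    "precip_driest_quarter",
    "precip_coldest_quarter",
)

#: Fixed candidate ordering used for deterministic tie-breaking downstream
#: (conventional bioclim order, bio1..bio19).
FULL_BIOCLIM = (
    "annual_mean_temp",
    "mean_diurnal_range",
    "isothermality",
    "temp_seasonality",
    "max_temp_warmest_month",
    "min_temp_coldest_month",
    "temp_annual_range",
    "temp_wettest_quarter",
    "temp_driest_quarter",
    "temp_warmest_quarter",
    "temp_coldest_quarter",
    "annual_precip",
    "precip_wettest_month",
    "precip_driest_month",
    "precip_seasonality",
    "precip_wettest_quarter",
    "precip_driest_quarter",
    "precip_warmest_quarter",
    "precip_coldest_quarter",
)

#: Absolute temperature layers in deg C; an additive temperature anomaly
#: shifts exactly these.
TEMPERATURE_VARS = (
    "annual_mean_temp",
    "max_temp_warmest_month",
    "min_temp_coldest_month",
    "temp_wettest_quarter",
    "temp_driest_quarter",
    "temp_warmest_quarter",
    "temp_coldest_quarter",
)

#: Precipitation layers in mm; must be non-negative and scale with a
#: precipitation anomaly factor.
PRECIPITATION_VARS = (
    "annual_precip",
    "precip_wettest_month",
    "precip_driest_month",
    "precip_wettest_quarter",
    "precip_driest_quarter",
    "precip_warmest_quarter",
    "precip_coldest_quarter",
)

NO_ANALOG = -1
NO_ANALOG_LABEL = "no_analog"


@dataclass(frozen=True)
class GridGeometry:
    """Regular grid in planar km with cell-center registration."""

    n_rows: int
    n_cols: int
    cell_size_km: float
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size_km

    def y_centers(self) -> np.ndarray:
        return self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size_km

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_rows, n_cols) arrays of cell-center x and y."""
        xs, ys = np.meshgrid(self.x_centers(), self.y_centers())
        return xs, ys

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_origin <= x < self.x_origin + self.n_cols * self.cell_size_km
            and self.y_origin <= y < self.y_origin + self.n_rows * self.cell_size_km
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point; raises off grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size_km).astype(int)
        row = np.floor((y - self.y_origin) / self.cell_size_km).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            raise OffGridError("coordinates fall outside the grid")
        return row, col


def _require_same_geometry(a: GridGeometry, b: GridGeometry, what: str) -> None:
    if a != b:
        raise GeometryMismatchError(f"{what}: geometries differ ({a} vs {b})")


@dataclass
class ClimateStack:
    """Named bioclimatic layers plus elevation for one time slice.

    ``age_ka`` is the slice age in thousand years before present
    (0 = present day).  All layers share the grid geometry; precipitation
    layers are non-negative and the warmest-month maximum never falls below
    the coldest-month minimum in any cell.
    """

    geometry: GridGeometry
    age_ka: float
    variables: dict[str, np.ndarray]
    elevation: np.ndarray | None = None

    def __post_init__(self):
        if not self.variables:
            raise ValueError("ClimateStack needs at least one variable layer")
        for name, layer in self.variables.items():
            layer = np.asarray(layer, dtype=float)
            if layer.shape != self.geometry.shape:
                raise GeometryMismatchError(
                    f"layer {name!r} has shape {layer.shape}, expected {self.geometry.shape}"
                )
            self.variables[name] = layer
        if self.elevation is not None:
            self.elevation = np.asarray(self.elevation, dtype=float)
            if self.elevation.shape != self.geometry.shape:
                raise GeometryMismatchError("elevation layer shape mismatch")
        for name in PRECIPITATION_VARS:
            if name in self.variables and np.nanmin(self.variables[name]) < 0:
                raise ValueError(f"precipitation layer {name!r} has negative values")
        hi = self.variables.get("max_temp_warmest_month")
        lo = self.variables.get("min_temp_coldest_month")
        if hi is not None and lo is not None and np.any(hi < lo):
            raise ValueError("max temp of warmest month below min temp of coldest month")

    @property
    def var_names(self) -> tuple[str, ...]:
        return tuple(self.variables)

    def layer(self, name: str) -> np.ndarray:
        if name == "elevation" and self.elevation is not None:
            return self.elevation
        try:
            return self.variables[name]
        except KeyError:
            raise KeyError(f"variable {name!r} not in stack {sorted(self.variables)}")

    def matrix(self, variables: tuple[str, ...] | list[str]) -> np.ndarray:
        """(n_cells, k) matrix of the requested layers, row-major cells."""
        return np.column_stack([self.layer(v).ravel() for v in variables])


@dataclass
class SuitabilitySurface:
    """Per-cell probability of occurrence of one unit on one time slice."""

    vu_id: str
    age_ka: float
    geometry: GridGeometry
    values: np.ndarray
    corrected: bool = False
    clamp_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise GeometryMismatchError("suitability values shape mismatch")
        if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
            raise ValueError("suitability values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def with_values(self, values: np.ndarray, corrected: bool | None = None) -> "SuitabilitySurface":
        return SuitabilitySurface(
            vu_id=self.vu_id,
            age_ka=self.age_ka,
            geometry=self.geometry,
            values=values,
            corrected=self.corrected if corrected is None else corrected,
            clamp_mask=None if self.clamp_mask is None else self.clamp_mask.copy(),
        )


@dataclass
class VegetationUnitMap:
    """Categorical per-cell unit assignment with a no-analog class.

    ``codes`` holds an index into ``units`` or :data:`NO_ANALOG` (-1) where
    no unit reached the suitability threshold.
    """

    geometry: GridGeometry
    codes: np.ndarray
    units: tuple[str, ...]
    age_ka: float = 0.0
    no_analog_threshold: float = 0.1
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.geometry.shape:
            raise GeometryMismatchError("unit-map codes shape mismatch")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("unit-map codes must be integers")
        if self.codes.min() < NO_ANALOG or self.codes.max() >= len(self.units):
            raise ValueError("unit-map codes out of range")
        self.units = tuple(self.units)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.units + (NO_ANALOG_LABEL,)

    def code_of(self, vu_id: str) -> int:
        if vu_id == NO_ANALOG_LABEL:
            return NO_ANALOG
        try:
            return self.units.index(vu_id)
        except ValueError:
            raise KeyError(f"unit {vu_id!r} not among {self.units}")

    def mask(self, vu_id: str) -> np.ndarray:
        return self.codes == self.code_of(vu_id)

    def counts(self) -> dict[str, int]:
        """Cell count per label, including units absent from the map (0)."""
        out = {u: int(np.sum(self.codes == i)) for i, u in enumerate(self.units)}
        out[NO_ANALOG_LABEL] = int(np.sum(self.codes == NO_ANALOG))
        return out
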