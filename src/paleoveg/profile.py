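"""Climatic characterization of vegetation units and predictor screening.

A unit's climate envelope is read directly off the present-day stack by
extracting every cell whose center falls inside the unit's extent, and
summarized as per-variable frequency histograms.  Collinearity between
candidate predictor layers is screened with pairwise Spearman rank
correlation; a greedy elimination with explicit keep/drop overrides
reduces the candidate set to a below-threshold subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry
import shapely

from .errors import EmptyExtentError
from .grids import NINE_PREDICTORS, ClimateStack, VegetationUnitMap

#: Default |rho| cut above which two predictors are considered redundant.
DEFAULT_CORR_THRESHOLD = 0.85

#: Default keep-overrides: the nine predictors retained for modelling even
#: where mutually correlated, because they carry complementary ecological
#: information (e.g. annual mean vs. coldest-month minimum temperature).
DEFAULT_KEEP_OVERRIDES = NINE_PREDICTORS


@dataclass
class ClimateSample:
    """Per-variable vectors extracted from the cells of one unit."""

    vu_id: str
    data: pd.DataFrame  # rows = cells, columns = variables

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def values(self, variable: str) -> np.ndarray:
        if variable not in self.data.columns:
            raise KeyError(f"variable {variable!r} not extracted")
        return self.data[variable].to_numpy()


class Histogram(NamedTuple):
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho matrix with unit diagonal."""

    matrix: pd.DataFrame

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)

    def rho(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


@dataclass
class PredictorSet:
    retained: tuple[str, ...]
    discarded: tuple[str, ...]
    rationale: dict[str, str]  # per retained variable

    def __post_init__(self):
        if not self.retained:
            raise ValueError("screening retained no predictors")


def _extent_mask(stack: ClimateStack, extent, vu_id: str | None) -> np.ndarray:
    if isinstance(extent, VegetationUnitMap):
        if vu_id is None:
            raise ValueError("vu_id is required with a categorical extent map")
        if extent.geometry != stack.geometry:
            raise EmptyExtentError("extent map does not share the stack grid")
        return extent.mask(vu_id)
    geom = extent
    if isinstance(geom, dict):  # GeoJSON-like mapping
        if geom.get("type") == "Feature":
            geom = geom["geometry"]
        geom = geojson_shape(geom)
    if not isinstance(geom, BaseGeometry):
        raise TypeError("extent must be a VegetationUnitMap, geometry or GeoJSON dict")
    xs, ys = stack.geometry.center_grids()
    return shapely.contains_xy(geom, xs, ys)


def extract_climate_values(
    stack: ClimateStack,
    extent,
    vu_id: str | None = None,
    variables: Sequence[str] | None = None,
) -> ClimateSample:
    """Values of every cell whose center lies inside the unit's extent.

    ``extent`` may be a categorical :class:`VegetationUnitMap` (cells
    labelled ``vu_id``), a shapely geometry, or a GeoJSON mapping.  Cells
    carrying a missing value in any requested layer are dropped jointly.
    """
    variables = tuple(variables) if variables is not None else stack.var_names
    mask = _extent_mask(stack, extent, vu_id)
    if not mask.any():
        raise EmptyExtentError("extent overlaps zero grid cells")
    data = pd.DataFrame({v: stack.layer(v)[mask] for v in variables})
    data = data.dropna(axis=0, how="any").reset_index(drop=True)
    if data.empty:
        raise EmptyExtentError("all overlapping cells carry missing values")
    label = vu_id if vu_id is not None else "extent"
    return ClimateSample(vu_id=label, data=data)


def climate_frequency_profile(
    sample: ClimateSample, variable: str, n_bins: int = 30
) -> Histogram:
    """Equal-width frequency histogram of one extracted variable."""
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    v = sample.values(variable)
    counts, edges = np.histogram(v, bins=n_bins)
    return Histogram(bin_edges=edges, counts=counts)


def spearman_matrix(
    stack_or_frame, variables: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Spearman rho over jointly valid cells, average ranks for ties.

    Constant layers yield undefined coefficients for their pairs; these are
    reported as missing (NaN) with a warning.  The diagonal is 1 by
    definition.
    """
    if isinstance(stack_or_frame, ClimateStack):
        variables = tuple(variables) if variables else stack_or_frame.var_names
        data = pd.DataFrame(
            {v: stack_or_frame.layer(v).ravel() for v in variables}
        )
    else:
        data = pd.DataFrame(stack_or_frame)
        if variables:
            data = data[list(variables)]
        variables = tuple(data.columns)
    if len(variables) < 2:
        raise ValueError("at least two variables are required")
    data = data.dropna(axis=0, how="any")
    if len(data) < 3:
        raise ValueError("at least 3 jointly valid cells are required")

    constant = [v for v in variables if data[v].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant layer(s) {constant}: Spearman rho undefined for their pairs",
            UserWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(data.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape == (1, 1):  # scipy collapses the 2-variable case to a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(pd.DataFrame(rho, index=variables, columns=variables))


def select_predictors(
    corr: CorrelationMatrix,
    threshold: float = DEFAULT_CORR_THRESHOLD,
    keep_overrides: Iterable[str] = (),
    drop_overrides: Iterable[str] = (),
) -> PredictorSet:
    """Greedy collinearity elimination with explicit overrides.

    Repeatedly drops the non-override variable with the most above-threshold
    partners (ties broken by dropping the later name in the candidate
    ordering) until no resolvable pair exceeds the threshold.  Variables in
    ``keep_overrides`` are always retained, ``drop_overrides`` always
    discarded.  Undefined (NaN) coefficients never count as violations.
    """
    candidates = list(corr.variables)
    keep = [v for v in keep_overrides]
    drop = [v for v in drop_overrides]
    unknown = [v for v in keep + drop if v not in candidates]
    if unknown:
        raise ValueError(f"override variables not among candidates: {unknown}")
    clash = sorted(set(keep) & set(drop))
    if clash:
        raise ValueError(f"variables in both keep and drop overrides: {clash}")

    retained = [v for v in candidates if v not in drop]
    keep_set = set(keep)

    def n_violations(v: str) -> int:
        return sum(
            1
            for u in retained
            if u != v and abs(corr.matrix.loc[v, u]) > threshold
            and np.isfinite(corr.matrix.loc[v, u])
        )

    while True:
        droppable = [v for v in retained if v not in keep_set]
        counts = {v: n_violations(v) for v in droppable}
        worst = max(counts.values(), default=0)
        if worst == 0:
            break
        # ties: drop the later name in the fixed candidate ordering
        victim = max(
            (v for v in droppable if counts[v] == worst), key=candidates.index
        )
        retained.remove(victim)

    rationale = {
        v: ("kept-override" if v in keep_set else "below-threshold") for v in retained
    }
    discarded = tuple(v for v in candidates if v not in retained)
    return PredictorSet(tuple(retained), discarded, rationale)
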