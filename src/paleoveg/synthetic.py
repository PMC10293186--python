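"""Synthetic landscapes with the statistical structure the analysis assumes.

The generator produces a desk-scale analog of a tropical mountain region:
a smoothed random relief with one deterministic ridge, temperature layers
that decrease linearly with elevation at a configurable lapse rate,
precipitation following a planar gradient, vegetation units arranged in
altitudinal belts, colder/drier glacial time slices, a rising CO2 ramp and
pollen assemblages whose group proportions decay with the distance from
the depositional site to the nearest modelled habitat.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import EmptyExtentError, InvalidSpecError, OffGridError
from .grids import (
    NO_ANALOG,
    NINE_PREDICTORS,
    ClimateStack,
    GridGeometry,
    VegetationUnitMap,
)

#: The seven vegetation units of the default landscape, ordered from the
#: highest altitudinal belt to the lowest: Afroalpine belt, Ericaceous
#: belt, dry and moist Afromontane forest, Combretum-Terminalia woodland,
#: Acacia-Commiphora bushland, desert/semi-desert scrub.
DEFAULT_UNITS = ("AA", "EB", "DAF", "MAF", "CTW", "ACB", "DSS")

#: Units occupying narrow high-altitude belts (small extents).
NARROW_BELT_UNITS = ("AA", "EB")

#: The forest-analog unit whose elevation limits track the
#: forest-savanna ecotone in summaries.
FOREST_UNIT = "DAF"

DEFAULT_PAST_AGES = tuple(range(22, 0, -1))  # 22..1 ka, oldest first

LGM_AGE_KA = 22.0
LGM_CO2_PPM = 185.0
PREINDUSTRIAL_CO2_PPM = 280.0


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the synthetic landscape.

    lapse_rate is the temperature decrease per 100 m of elevation (deg C);
    the regional default of 0.6 sits at the midpoint of the 0.5-0.7 range
    typical of East African mountains.  precip_gradient is the planar
    (per-row, per-col) precipitation trend in mm/cell.  roughness scales
    the smoothed random component of the relief; 0 leaves only the
    deterministic ridge.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size_km: float = 1.0
    lapse_rate: float = 0.6
    sea_level_temp: float = 28.0
    precip_base: float = 150.0
    precip_gradient: tuple[float, float] = (1.5, 8.0)
    precip_noise: float = 60.0
    roughness: float = 1.0
    max_elevation: float = 4500.0
    ridge_col_frac: float = 0.62
    ridge_width_frac: float = 0.16
    ridge_height: float = 2.5
    tilt: float = 1.0
    hypsometry_exp: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 8 or self.n_cols < 8:
            raise InvalidSpecError("grid must be at least 8 x 8 cells")
        if self.cell_size_km <= 0:
            raise InvalidSpecError("cell_size_km must be positive")
        if self.lapse_rate <= 0:
            raise InvalidSpecError("lapse_rate must be positive")
        if self.max_elevation <= 0:
            raise InvalidSpecError("max_elevation must be positive")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.n_rows, self.n_cols, self.cell_size_km)

    @classmethod
    def for_grid(cls, n_rows: int, n_cols: int, **kwargs) -> "LandscapeSpec":
        """Spec for a non-default grid size with the same climatic span.

        The per-cell precipitation gradient is rescaled so the rainfall
        range across the grid matches the default 200 x 200 landscape;
        otherwise small grids would lose their wet-belt units.
        """
        base = cls(**{k: v for k, v in kwargs.items() if k != "precip_gradient"})
        g_row, g_col = kwargs.get("precip_gradient", base.precip_gradient)
        grad = (g_row * 200.0 / n_rows, g_col * 200.0 / n_cols)
        return cls(n_rows=n_rows, n_cols=n_cols, precip_gradient=grad,
                   **{k: v for k, v in kwargs.items() if k != "precip_gradient"})


@dataclass(frozen=True)
class NicheDefinition:
    """Gaussian climate envelope used as ground truth for one unit."""

    vu_id: str
    optima: Mapping[str, float]
    tolerances: Mapping[str, float]

    def __post_init__(self):
        if set(self.optima) != set(self.tolerances):
            raise InvalidSpecError("optima and tolerances must share variables")
        if any(t <= 0 for t in self.tolerances.values()):
            raise InvalidSpecError("tolerances must be positive")

    def suitability(self, stack: ClimateStack) -> np.ndarray:
        """Product-Gaussian suitability of every cell, in (0, 1]."""
        z2 = np.zeros(stack.geometry.shape)
        for var, mu in self.optima.items():
            z = (stack.layer(var) - mu) / self.tolerances[var]
            z2 += z * z
        return np.exp(-0.5 * z2)


#: Altitudinal-belt ground truth on mean annual temperature (deg C) and
#: annual precipitation (mm).  Optima follow the default lapse rate: the
#: Afroalpine belt sits near 3700 m, the forest belts at 1700-2200 m, the
#: scrubland at sea level on the dry margin.
DEFAULT_NICHES = (
    NicheDefinition("AA", {"annual_mean_temp": 5.5, "annual_precip": 900.0},
                    {"annual_mean_temp": 2.5, "annual_precip": 450.0}),
    NicheDefinition("EB", {"annual_mean_temp": 9.5, "annual_precip": 1000.0},
                    {"annual_mean_temp": 1.5, "annual_precip": 450.0}),
    NicheDefinition("DAF", {"annual_mean_temp": 15.0, "annual_precip": 900.0},
                    {"annual_mean_temp": 3.0, "annual_precip": 350.0}),
    NicheDefinition("MAF", {"annual_mean_temp": 18.0, "annual_precip": 1500.0},
                    {"annual_mean_temp": 3.0, "annual_precip": 300.0}),
    NicheDefinition("CTW", {"annual_mean_temp": 23.0, "annual_precip": 1100.0},
                    {"annual_mean_temp": 3.0, "annual_precip": 300.0}),
    NicheDefinition("ACB", {"annual_mean_temp": 24.5, "annual_precip": 550.0},
                    {"annual_mean_temp": 3.0, "annual_precip": 250.0}),
    NicheDefinition("DSS", {"annual_mean_temp": 27.5, "annual_precip": 150.0},
                    {"annual_mean_temp": 3.0, "annual_precip": 220.0}),
)


@dataclass
class OccurrenceSet:
    """Presence coordinates of one unit in grid CRS (km)."""

    vu_id: str
    x: np.ndarray
    y: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"vu_id": self.vu_id, "x": self.x, "y": self.y})


@dataclass(frozen=True)
class CO2Series:
    """Atmospheric CO2 concentration by age, oldest slice first."""

    ages_ka: tuple[float, ...]
    co2_ppm: tuple[float, ...]

    def __post_init__(self):
        ages = np.asarray(self.ages_ka, dtype=float)
        conc = np.asarray(self.co2_ppm, dtype=float)
        if ages.size != conc.size or ages.size == 0:
            raise ValueError("ages and concentrations must match and be non-empty")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(ages).size != ages.size:
            raise ValueError("ages must be unique")
        if np.any(np.diff(ages) >= 0):
            raise ValueError("ages must be in descending order (oldest first)")

    def at(self, age_ka: float) -> float:
        """Concentration at an age, linearly interpolated between points."""
        asc_ages = np.asarray(self.ages_ka)[::-1]
        asc_conc = np.asarray(self.co2_ppm)[::-1]
        return float(np.interp(age_ka, asc_ages, asc_conc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_ka": self.ages_ka, "co2_ppm": self.co2_ppm})


def default_temp_anomaly(age_ka: float) -> float:
    """Temperature offset (deg C), linear from -6 at 22 ka to 0 at present."""
    return -6.0 * float(age_ka) / LGM_AGE_KA


def default_precip_scale(age_ka: float) -> float:
    """Precipitation scale factor, 0.8 at 22 ka rising to 1.0 at present."""
    return 1.0 - 0.2 * float(age_ka) / LGM_AGE_KA


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Spectrally smoothed unit-variance Gaussian noise."""
    z = rng.standard_normal(shape)
    sigma = max(2.0, min(shape) / 12.0)
    f = gaussian_filter(z, sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_elevation(spec: LandscapeSpec) -> np.ndarray:
    """Relief: smoothed noise plus one ridge, rescaled to [0, max_elevation].

    A gentle tilt aligned with the precipitation gradient keeps the dry
    margin of the landscape low-lying, so an arid lowland belt exists the
    way it does on real mountain forelands.
    """
    rng = np.random.default_rng(spec.seed)
    noise = _smooth_field(rng, (spec.n_rows, spec.n_cols))
    cols = np.arange(spec.n_cols, dtype=float)
    center = spec.ridge_col_frac * spec.n_cols
    width = spec.ridge_width_frac * spec.n_cols
    ridge = np.exp(-(((cols - center) / width) ** 2))
    rows2 = np.arange(spec.n_rows, dtype=float)[:, None]
    g_row, g_col = spec.precip_gradient
    grad = g_row * rows2 + g_col * cols[None, :]
    span = np.ptp(grad)
    tilt_fld = spec.tilt * (grad - grad.min()) / span if span > 0 else 0.0
    fld = spec.ridge_height * ridge[None, :] + spec.roughness * noise + tilt_fld
    # Monotone rank transform to a fixed hypsometric curve: the elevation
    # histogram (hence belt areas) is identical across seeds while the
    # spatial pattern varies.  Exponent > 1 makes lowlands more common
    # than summits, as on real mountain forelands.
    order = fld.ravel().argsort().argsort()
    u = (order + 0.5) / order.size
    E = spec.max_elevation * u**spec.hypsometry_exp
    return E.reshape(fld.shape)


def generate_climate_stack(
    spec: LandscapeSpec,
    age_ka: float = 0.0,
    temp_anomaly: float | None = None,
    precip_scale: float | None = None,
    full_bioclim: bool = False,
) -> ClimateStack:
    """Build the bioclimatic stack for one time slice.

    With ``temp_anomaly``/``precip_scale`` unset, the default glacial
    anomaly schedule is applied (linear cooling to -6 deg C and drying to
    0.8x at 22 ka).  ``full_bioclim=True`` adds the ten remaining layers
    of the 19-variable bioclim set; the range/ratio indices among them are
    stylized monotone functions of relief or annual precipitation rather
    than recomputations from monthly series.
    """
    if temp_anomaly is None:
        temp_anomaly = default_temp_anomaly(age_ka)
    if precip_scale is None:
        precip_scale = default_precip_scale(age_ka)
    if precip_scale <= 0:
        raise InvalidSpecError("precipitation scale factor must be positive")

    elev = generate_elevation(spec)
    # second, independent stream for the precipitation texture
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    pnoise = _smooth_field(rng, (spec.n_rows, spec.n_cols))

    t_mean = spec.sea_level_temp + temp_anomaly - spec.lapse_rate * (elev / 100.0)

    rows = np.arange(spec.n_rows, dtype=float)[:, None]
    cols = np.arange(spec.n_cols, dtype=float)[None, :]
    g_row, g_col = spec.precip_gradient
    p_base = spec.precip_base + g_row * rows + g_col * cols + spec.precip_noise * pnoise
    precip = np.maximum(p_base * precip_scale, 0.0)

    layers: dict[str, np.ndarray] = {
        "annual_mean_temp": t_mean,
        "max_temp_warmest_month": t_mean + 6.0,
        "min_temp_coldest_month": t_mean - 6.0,
        "temp_wettest_quarter": t_mean + 2.0,
        "temp_driest_quarter": t_mean - 2.0,
        "annual_precip": precip,
        "precip_wettest_month": 0.28 * precip,
        "precip_driest_month": 0.015 * precip,
        "precip_warmest_quarter": 0.32 * precip,
    }
    if full_bioclim:
        diurnal = 3.0 + elev / 1000.0
        annual_range = 8.0 + elev / 500.0
        layers.update(
            {
                "mean_diurnal_range": diurnal,
                "isothermality": 100.0 * diurnal / annual_range,
                "temp_seasonality": 12.5 * annual_range,
                "temp_annual_range": annual_range,
                "temp_warmest_quarter": t_mean + 4.0,
                "temp_coldest_quarter": t_mean - 4.0,
                "precip_seasonality": 100.0 * np.exp(-precip / 1000.0),
                "precip_wettest_quarter": 0.55 * precip,
                "precip_driest_quarter": 0.06 * precip,
                "precip_coldest_quarter": 0.10 * precip,
            }
        )
    return ClimateStack(
        geometry=spec.geometry, age_ka=float(age_ka), variables=layers, elevation=elev
    )


def generate_true_vegetation(
    stack: ClimateStack,
    niches: Sequence[NicheDefinition] = DEFAULT_NICHES,
    no_analog_threshold: float = 0.1,
) -> VegetationUnitMap:
    """Ground-truth map: per-cell argmax of product-Gaussian suitabilities.

    Cells where every unit's suitability falls below the threshold are
    assigned the no-analog class.
    """
    if not niches:
        raise ValueError("at least one niche definition is required")
    units = tuple(n.vu_id for n in niches)
    suits = np.stack([n.suitability(stack) for n in niches])
    best = suits.argmax(axis=0)
    codes = np.where(suits.max(axis=0) >= no_analog_threshold, best, NO_ANALOG)
    return VegetationUnitMap(
        geometry=stack.geometry,
        codes=codes.astype(np.int64),
        units=units,
        age_ka=stack.age_ka,
        no_analog_threshold=no_analog_threshold,
        provenance=("true-vegetation",),
    )


def sample_presences(
    vumap: VegetationUnitMap, vu_id: str, n: int, seed: int = 0
) -> OccurrenceSet:
    """Uniform presence sample within the unit's cells.

    Cells are drawn with replacement and each point is jittered uniformly
    within its cell, so coordinates never degenerate to duplicates.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rows, cols = np.nonzero(vumap.mask(vu_id))
    if rows.size == 0:
        raise EmptyExtentError(f"unit {vu_id!r} occupies no cells")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, rows.size, size=n)
    g = vumap.geometry
    x = g.x_origin + (cols[pick] + rng.random(n)) * g.cell_size_km
    y = g.y_origin + (rows[pick] + rng.random(n)) * g.cell_size_km
    return OccurrenceSet(vu_id=vu_id, x=x, y=y, provenance="synthetic")


def generate_co2_series(
    ages_ka: Sequence[float],
    lgm_ppm: float = LGM_CO2_PPM,
    present_ppm: float = PREINDUSTRIAL_CO2_PPM,
) -> CO2Series:
    """Piecewise-linear CO2 ramp from ~185 ppm at 22 ka to 280 ppm today.

    Ages older than 22 ka saturate at the glacial value.
    """
    if len(ages_ka) == 0:
        raise ValueError("ages must be non-empty")
    ages = np.asarray(sorted(set(float(a) for a in ages_ka), reverse=True))
    conc = np.interp(ages, [0.0, LGM_AGE_KA], [present_ppm, lgm_ppm])
    return CO2Series(ages_ka=tuple(ages), co2_ppm=tuple(conc))


def generate_pollen_record(
    site: tuple[float, float],
    vumaps: Sequence[VegetationUnitMap],
    grouping,
    counts_per_sample: int = 300,
    seed: int = 0,
    decay_km: float = 20.0,
    wetland_prop: float = 0.08,
    ambiguous_prop: float = 0.05,
    site_id: str = "synthetic_site",
):
    """Simulate a dated pollen record at a depositional site.

    One sample per time slice; expected group proportions are proportional
    to exp(-d_g / decay_km) where d_g is the distance from the site to the
    nearest cell currently mapped as the group's unit.  Wetland and
    ambiguous taxa receive fixed background proportions.  Counts are
    multinomial draws of ``counts_per_sample`` grains.
    """
    from .pollen import EXCLUDED_WETLAND, PollenRecord, habitat_distance

    if counts_per_sample < 1:
        raise ValueError("counts_per_sample must be at least 1")
    if not vumaps:
        raise ValueError("at least one vegetation map is required")
    geom = vumaps[0].geometry
    for vm in vumaps:
        if vm.geometry != geom:
            raise ValueError("all vegetation maps must share geometry")
    if not geom.contains(*site):
        raise OffGridError("pollen site falls outside the grid")

    units = [u for u in grouping.units]
    unit_taxa = {u: grouping.taxa_for(u) for u in units}
    wet_taxa = grouping.wetland_taxa
    amb_taxa = [
        t
        for t, a in grouping.assignments.items()
        if a not in units and a != EXCLUDED_WETLAND
    ]
    w_bg = wetland_prop if wet_taxa else 0.0
    a_bg = ambiguous_prop if amb_taxa else 0.0
    assignable_mass = 1.0 - w_bg - a_bg

    taxa = sorted(grouping.assignments)
    rng = np.random.default_rng(seed)
    rows = []
    ages = []
    for i, vm in enumerate(vumaps):
        weights = np.zeros(len(units))
        for j, u in enumerate(units):
            if u not in vm.units:
                continue
            d = habitat_distance(vm, site, u)
            if math.isfinite(d):
                weights[j] = math.exp(-d / decay_km)
        total = weights.sum()
        if total > 0:
            group_p = assignable_mass * weights / total
        else:  # no habitat anywhere: spread the assignable mass evenly
            group_p = np.full(len(units), assignable_mass / len(units))
        p = {}
        for j, u in enumerate(units):
            tx = unit_taxa[u]
            for t in tx:
                p[t] = group_p[j] / len(tx) if tx else 0.0
        for t in wet_taxa:
            p[t] = w_bg / len(wet_taxa)
        for t in amb_taxa:
            p[t] = a_bg / len(amb_taxa)
        pvec = np.array([p.get(t, 0.0) for t in taxa])
        pvec = pvec / pvec.sum()
        counts = rng.multinomial(counts_per_sample, pvec)
        rows.append(counts)
        ages.append(vm.age_ka)

    counts_df = pd.DataFrame(
        rows, columns=taxa, index=[f"s{i}" for i in range(len(vumaps))]
    )
    chron = pd.DataFrame({"sample_id": counts_df.index, "age_ka": ages})
    x, y = site
    row, col = geom.cell_of(x, y)
    elev = 0.0
    return PollenRecord(
        site_id=site_id,
        x=float(x),
        y=float(y),
        elevation=elev,
        chronology=chron,
        counts=counts_df,
    )
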