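"""Pollen-based validation of hindcast vegetation maps.

Fossil pollen taxa are grouped by the vegetation unit they characterize;
taxa tied to several units, of unclear ecological significance, or
sourced from local wetlands are excluded from the grouping.  Percentages
are computed on the pollen sum of assigned taxa only, plotted against
age, and compared with the modelled maps through the distance from the
depositional site to the nearest cell of each unit.  Concordance between
a group's abundance series and the (negated) habitat distance series is
quantified with Spearman rank correlation; the comparison in the source
analyses of this kind is usually visual, so the statistic is an
operationalized extension, not a reimplementation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import OffGridError
from .grids import VegetationUnitMap

EXCLUDED_AMBIGUOUS = "excluded_ambiguous"
EXCLUDED_MULTIGROUP = "excluded_multigroup"
EXCLUDED_WETLAND = "excluded_wetland"
EXCLUDED_LABELS = (EXCLUDED_AMBIGUOUS, EXCLUDED_MULTIGROUP, EXCLUDED_WETLAND)

#: Maximum |age difference| (ka) when matching sample ages to slice ages.
AGE_MATCH_TOLERANCE_KA = 0.5


@dataclass
class TaxaGrouping:
    """Per-taxon assignment to a unit group or an exclusion class."""

    assignments: dict[str, str]
    units: tuple[str, ...]

    def __post_init__(self):
        if not self.assignments:
            raise ValueError("taxa grouping must not be empty")
        bad = {
            t: a
            for t, a in self.assignments.items()
            if a not in self.units and a not in EXCLUDED_LABELS
        }
        if bad:
            raise ValueError(f"unknown unit label(s) in grouping: {bad}")

    def taxa_for(self, unit: str) -> list[str]:
        return [t for t, a in self.assignments.items() if a == unit]

    @property
    def wetland_taxa(self) -> list[str]:
        return self.taxa_for(EXCLUDED_WETLAND)

    @property
    def assigned_taxa(self) -> list[str]:
        return [t for t, a in self.assignments.items() if a in self.units]

    @property
    def excluded_taxa(self) -> list[str]:
        return [t for t, a in self.assignments.items() if a in EXCLUDED_LABELS]

    def summary(self) -> dict[str, int]:
        return {
            "n_taxa": len(self.assignments),
            "n_assigned": len(self.assigned_taxa),
            "n_excluded": len(self.excluded_taxa),
        }


def load_taxa_grouping(table, units: Sequence[str] | None = None) -> TaxaGrouping:
    """Validate a taxon/assignment table (CSV path or DataFrame).

    Columns: ``taxon`` and ``assignment`` (a unit label or one of the
    exclusion classes).  Duplicate taxa and unknown labels are rejected.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    cols = {c.lower(): c for c in df.columns}
    if "taxon" not in cols or "assignment" not in cols:
        raise ValueError("grouping table needs 'taxon' and 'assignment' columns")
    if df.empty:
        raise ValueError("grouping table is empty")
    taxa = df[cols["taxon"]].astype(str)
    dup = taxa[taxa.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate taxa in grouping table: {sorted(set(dup))}")
    assignments = dict(zip(taxa, df[cols["assignment"]].astype(str)))
    if units is None:
        units = tuple(
            sorted({a for a in assignments.values() if a not in EXCLUDED_LABELS})
        )
    else:
        units = tuple(units)
        for i, (t, a) in enumerate(assignments.items()):
            if a not in units and a not in EXCLUDED_LABELS:
                raise ValueError(f"row for taxon {t!r}: unknown unit label {a!r}")
    return TaxaGrouping(assignments=assignments, units=units)


@dataclass
class PollenRecord:
    """Dated samples x taxa count matrix for one depositional site."""

    site_id: str
    x: float
    y: float
    elevation: float
    chronology: pd.DataFrame  # columns: sample_id, age_ka
    counts: pd.DataFrame  # index: sample_id, columns: taxa

    def __post_init__(self):
        if not {"sample_id", "age_ka"} <= set(self.chronology.columns):
            raise ValueError("chronology needs sample_id and age_ka columns")
        if self.chronology["age_ka"].duplicated().any():
            raise ValueError("sample ages must be unique within a site")
        if set(self.counts.index) != set(self.chronology["sample_id"]):
            raise ValueError("counts and chronology disagree on sample ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("pollen counts must be non-negative")

    @property
    def ages(self) -> pd.Series:
        return self.chronology.set_index("sample_id")["age_ka"]


@dataclass
class GroupedPollenSeries:
    """Per-sample unit-group percentages on the assigned-taxa pollen sum."""

    site_id: str
    percentages: pd.DataFrame  # index sample_id, columns unit groups (%)
    pollen_sum: pd.Series  # grains of assigned taxa per sample
    excluded: pd.Series  # grains of excluded taxa per sample
    ages: pd.Series  # age_ka per sample


def group_percentages(record: PollenRecord, grouping: TaxaGrouping) -> GroupedPollenSeries:
    """Group percentages per sample; the pollen sum is assigned taxa only.

    Taxa counted but missing from the grouping are treated as ambiguous
    (excluded) with a warning.  Samples whose pollen sum is zero are
    reported missing.
    """
    counts = record.counts.copy()
    unknown = [t for t in counts.columns if t not in grouping.assignments]
    if unknown:
        warnings.warn(
            f"taxa missing from grouping treated as excluded: {unknown}",
            UserWarning,
            stacklevel=2,
        )
    assigned_cols = [t for t in counts.columns if t in set(grouping.assigned_taxa)]
    pollen_sum = counts[assigned_cols].sum(axis=1)
    excluded = counts.sum(axis=1) - pollen_sum

    pct = pd.DataFrame(index=counts.index, columns=list(grouping.units), dtype=float)
    for unit in grouping.units:
        tx = [t for t in grouping.taxa_for(unit) if t in counts.columns]
        pct[unit] = counts[tx].sum(axis=1) if tx else 0.0
    zero = pollen_sum == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) with zero pollen sum reported missing",
            UserWarning,
            stacklevel=2,
        )
    pct = pct.div(pollen_sum.where(~zero), axis=0) * 100.0
    return GroupedPollenSeries(
        site_id=record.site_id,
        percentages=pct,
        pollen_sum=pollen_sum,
        excluded=excluded,
        ages=record.ages.loc[counts.index],
    )


def habitat_distance(
    vumap: VegetationUnitMap, site: tuple[float, float], vu_id: str
) -> float:
    """Distance (km) from a site to the nearest cell mapped as the unit.

    Zero when the site's own cell carries the unit; infinite when the
    unit is absent from the map.
    """
    x, y = site
    if not vumap.geometry.contains(x, y):
        raise OffGridError("site falls outside the grid")
    row, col = vumap.geometry.cell_of(x, y)
    mask = vumap.mask(vu_id)
    if mask[row, col]:
        return 0.0
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return math.inf
    g = vumap.geometry
    cx = g.x_origin + (cols + 0.5) * g.cell_size_km
    cy = g.y_origin + (rows + 0.5) * g.cell_size_km
    return float(np.sqrt((cx - x) ** 2 + (cy - y) ** 2).min())


def match_ages(
    sample_ages: Sequence[float],
    slice_ages: Sequence[float],
    tolerance_ka: float = AGE_MATCH_TOLERANCE_KA,
) -> dict[float, float]:
    """Nearest-neighbor mapping sample age -> slice age within tolerance."""
    slices = np.asarray(sorted(slice_ages))
    out: dict[float, float] = {}
    for a in sample_ages:
        j = int(np.argmin(np.abs(slices - a)))
        if abs(slices[j] - a) <= tolerance_ka:
            out[float(a)] = float(slices[j])
    return out


def concordance(percentages: pd.Series, distances: pd.Series) -> float:
    """Spearman rho between group abundance and negated habitat distance.

    Both series are indexed by age (ka); only ages present in both enter.
    Higher abundance when the habitat is nearer gives rho > 0.  With a
    constant series the statistic is undefined and NaN is returned with a
    warning.  Fewer than 3 paired ages is an error.
    """
    pct = pd.Series(percentages).dropna()
    dist = pd.Series(distances).replace(math.inf, np.nan).dropna()
    common = pct.index.intersection(dist.index)
    if len(common) < 3:
        raise ValueError("at least 3 paired ages are required")
    p = pct.loc[common].to_numpy(dtype=float)
    d = dist.loc[common].to_numpy(dtype=float)
    if np.unique(d).size == 1 or np.unique(p).size == 1:
        warnings.warn(
            "constant series: concordance undefined, reported missing",
            UserWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(stats.spearmanr(p, -d).statistic)


def plot_percentages(series: GroupedPollenSeries, path=None):
    """Simple percentage-vs-age diagram, one panel per unit group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    units = list(series.percentages.columns)
    fig, axes = plt.subplots(
        1, len(units), figsize=(2.2 * len(units), 4), sharey=True
    )
    axes = np.atleast_1d(axes)
    order = series.ages.sort_values().index
    for ax, unit in zip(axes, units):
        ax.fill_betweenx(
            series.ages.loc[order],
            0,
            series.percentages.loc[order, unit].fillna(0.0),
            step="mid",
        )
        ax.set_title(unit, fontsize=9)
        ax.set_xlabel("%")
    axes[0].set_ylabel("age (ka)")
    axes[0].invert_yaxis()
    fig.suptitle(series.site_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
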