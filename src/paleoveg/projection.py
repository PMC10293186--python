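"""Hindcast projection of fitted models and the CO2 physiological correction.

Models trained on present-day climate are projected onto each past
climate slice (with out-of-range predictors clamped to the training
range).  Because low glacial CO2 suppressed woody vegetation relative to
what climate alone would allow and favoured C4-dominated open habitats,
each unit's probability surface is multiplied by a correction factor that
interpolates linearly between a unit-specific glacial base factor
``f_LGM`` (at the LGM reference concentration) and 1 (no effect) at the
pre-industrial reference concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlreadyCorrectedError
from .grids import SuitabilitySurface, ClimateStack
from .maxent import NicheModel, predict_suitability
from .synthetic import CO2Series, LGM_CO2_PPM, PREINDUSTRIAL_CO2_PPM

#: Synthetic default base factors: forest-analog belts are suppressed at
#: glacial CO2 (f_LGM < 1), open-vegetation analogs are favoured (> 1).
DEFAULT_CORRECTION_FACTORS = {
    "AA": 0.85,
    "EB": 0.85,
    "DAF": 0.70,
    "MAF": 0.75,
    "CTW": 1.25,
    "ACB": 1.30,
    "DSS": 1.20,
}


@dataclass(frozen=True)
class CorrectionTable:
    """Per-unit LGM base factors plus the CO2 endpoints of the linear model."""

    base_factors: Mapping[str, float]
    c_lgm: float = LGM_CO2_PPM
    c_ref: float = PREINDUSTRIAL_CO2_PPM

    def __post_init__(self):
        if not self.base_factors:
            raise ValueError("correction table must not be empty")
        if any(f <= 0 for f in self.base_factors.values()):
            raise ValueError("base factors must be positive")
        if not self.c_lgm < self.c_ref:
            raise ValueError("c_lgm must be below c_ref")
        object.__setattr__(self, "base_factors", dict(self.base_factors))

    @classmethod
    def default(cls) -> "CorrectionTable":
        return cls(DEFAULT_CORRECTION_FACTORS)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vu_id": list(self.base_factors),
                "f_lgm": list(self.base_factors.values()),
                "c_lgm": self.c_lgm,
                "c_ref": self.c_ref,
            }
        )

    @classmethod
    def from_csv(cls, path) -> "CorrectionTable":
        df = pd.read_csv(path)
        if not {"vu_id", "f_lgm"} <= set(df.columns):
            raise ValueError("correction CSV needs vu_id and f_lgm columns")
        kwargs = {}
        if "c_lgm" in df.columns:
            kwargs["c_lgm"] = float(df["c_lgm"].iloc[0])
        if "c_ref" in df.columns:
            kwargs["c_ref"] = float(df["c_ref"].iloc[0])
        return cls(dict(zip(df["vu_id"], df["f_lgm"].astype(float))), **kwargs)


def correction_factor(table: CorrectionTable, vu_id: str, c_ppm: float) -> float:
    """Correction factor at a CO2 concentration.

    Linear in c between (c_lgm, f_LGM) and (c_ref, 1); exactly 1 at and
    above c_ref; extrapolated below c_lgm but floored at 0.
    """
    if c_ppm <= 0:
        raise ValueError("CO2 concentration must be positive")
    try:
        f_lgm = table.base_factors[vu_id]
    except KeyError:
        raise KeyError(f"unit {vu_id!r} not in correction table")
    if c_ppm >= table.c_ref:
        return 1.0
    factor = 1.0 + (f_lgm - 1.0) * (table.c_ref - c_ppm) / (table.c_ref - table.c_lgm)
    return max(factor, 0.0)


def apply_correction(surface: SuitabilitySurface, factor: float) -> SuitabilitySurface:
    """Scale a probability surface by the CO2 factor, clipped to [0, 1].

    Refuses to correct a surface twice.
    """
    if factor < 0:
        raise ValueError("correction factor must be non-negative")
    if surface.corrected:
        raise AlreadyCorrectedError(
            f"surface {surface.vu_id}@{surface.age_ka} ka already corrected"
        )
    return surface.with_values(np.minimum(1.0, factor * surface.values), corrected=True)


def project_model(
    model: NicheModel, past_stack: ClimateStack, clamp: bool = True
) -> SuitabilitySurface:
    """Cloglog suitability of a past slice under training-time scaling.

    Predictor values outside the training min/max are clamped to the
    range boundary and the affected cells flagged in the clamping mask.
    Projection onto the training stack reproduces the present-day
    prediction exactly.
    """
    return predict_suitability(model, past_stack, output_form="cloglog", clamp=clamp)


@dataclass
class HindcastResult:
    """Per-(unit, age) suitability surfaces from a full hindcast run."""

    uncorrected: dict[tuple[str, float], SuitabilitySurface]
    corrected: dict[tuple[str, float], SuitabilitySurface] | None
    factors: dict[tuple[str, float], float]
    ages: tuple[float, ...]
    units: tuple[str, ...]

    @property
    def n_projections(self) -> int:
        return len(self.uncorrected)

    def surfaces_at(self, age_ka: float, corrected: bool = False) -> dict[str, SuitabilitySurface]:
        src = self.corrected if corrected else self.uncorrected
        if src is None:
            raise ValueError("hindcast was run without the CO2 correction")
        return {vu: src[(vu, age_ka)] for vu in self.units}


def run_hindcast(
    models: Mapping[str, NicheModel] | Sequence[NicheModel],
    stacks_by_age: Mapping[float, ClimateStack],
    co2: CO2Series | None = None,
    table: CorrectionTable | None = None,
    correction_on: bool = True,
    ages: Sequence[float] | None = None,
    clamp: bool = True,
) -> HindcastResult:
    """Project every model onto every requested slice, optionally corrected.

    With the correction enabled, both the uncorrected and the corrected
    surfaces are kept and the per-(unit, age) factors are recorded.  The
    CO2 value for a slice is linearly interpolated from the input series.
    """
    if not isinstance(models, Mapping):
        models = {m.vu_id: m for m in models}
    if ages is None:
        ages = sorted(stacks_by_age, reverse=True)
    missing = [a for a in ages if a not in stacks_by_age]
    if missing:
        raise ValueError(f"no climate stack for requested ages: {missing}")
    if correction_on and (co2 is None or table is None):
        raise ValueError("the CO2 correction requires a CO2 series and a table")

    uncorrected: dict[tuple[str, float], SuitabilitySurface] = {}
    corrected: dict[tuple[str, float], SuitabilitySurface] | None = (
        {} if correction_on else None
    )
    factors: dict[tuple[str, float], float] = {}
    for age in ages:
        stack = stacks_by_age[age]
        c = co2.at(age) if co2 is not None else None
        for vu, model in models.items():
            surf = project_model(model, stack, clamp=clamp)
            uncorrected[(vu, age)] = surf
            if correction_on:
                f = correction_factor(table, vu, c)
                factors[(vu, age)] = f
                corrected[(vu, age)] = apply_correction(surf, f)
    return HindcastResult(
        uncorrected=uncorrected,
        corrected=corrected,
        factors=factors,
        ages=tuple(ages),
        units=tuple(models),
    )
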