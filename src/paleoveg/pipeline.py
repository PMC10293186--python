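"""End-to-end synthetic hindcast: landscape -> models -> maps -> summaries.

This is the orchestration used by the command line, the acceptance
script and the integration tests: generate a present-day landscape and
its ground-truth vegetation, sample presences, fit one presence-
background model per unit with a 25% holdout, project all models onto
every past slice (plus a present-day control projection), apply the CO2
correction, composite each slice into a vegetation map, and summarize
areas and elevation limits through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .grids import NINE_PREDICTORS, ClimateStack, SuitabilitySurface, VegetationUnitMap
from .maxent import (
    DEFAULT_BETA,
    DEFAULT_N_BACKGROUND,
    BackgroundSample,
    EvaluationResult,
    NicheModel,
    evaluate_auc,
    fit_maxent,
    sample_background,
    split_occurrences,
)
from .mosaic import DEFAULT_NO_ANALOG_THRESHOLD, composite, timeseries_summary
from .projection import CorrectionTable, HindcastResult, project_model, run_hindcast
from .synthetic import (
    DEFAULT_NICHES,
    DEFAULT_PAST_AGES,
    CO2Series,
    LandscapeSpec,
    NicheDefinition,
    generate_climate_stack,
    generate_co2_series,
    generate_true_vegetation,
    sample_presences,
)


@dataclass
class PipelineResult:
    """Everything a full synthetic hindcast produces."""

    spec: LandscapeSpec
    present: ClimateStack
    truth: VegetationUnitMap
    models: dict[str, NicheModel]
    evaluations: dict[str, EvaluationResult]
    background: BackgroundSample
    hindcast: HindcastResult
    present_surfaces: dict[str, SuitabilitySurface]
    past_maps: dict[float, VegetationUnitMap]
    past_maps_corrected: dict[float, VegetationUnitMap] | None
    present_map: VegetationUnitMap
    co2: CO2Series
    correction_table: CorrectionTable | None
    summary: pd.DataFrame
    summary_corrected: pd.DataFrame | None

    @property
    def aucs(self) -> dict[str, float]:
        return {vu: ev.auc for vu, ev in self.evaluations.items()}


def run_synthetic_hindcast(
    spec: LandscapeSpec | None = None,
    seed: int = 0,
    ages=DEFAULT_PAST_AGES,
    niches=DEFAULT_NICHES,
    n_presence: int = 1000,
    n_background: int = DEFAULT_N_BACKGROUND,
    test_fraction: float = 0.25,
    beta: float = DEFAULT_BETA,
    threshold: float = DEFAULT_NO_ANALOG_THRESHOLD,
    correction: bool = True,
    correction_table: CorrectionTable | None = None,
    variables=NINE_PREDICTORS,
    n_hinge_knots: int = 31,
) -> PipelineResult:
    """Run the full synthetic study under one top-level seed.

    All randomness (landscape texture, presence sampling, holdout split,
    background sample) derives from ``seed`` by fixed offsets, so the run
    is reproducible end to end.
    """
    if spec is None:
        spec = LandscapeSpec(seed=seed)
    present = generate_climate_stack(spec, age_ka=0.0)
    truth = generate_true_vegetation(present, niches, no_analog_threshold=threshold)
    background = sample_background(
        present, n_background=n_background, seed=seed + 1, variables=variables
    )

    models: dict[str, NicheModel] = {}
    evaluations: dict[str, EvaluationResult] = {}
    for i, niche in enumerate(niches):
        vu = niche.vu_id
        occ = sample_presences(truth, vu, n_presence, seed=seed + 100 + i)
        train, test = split_occurrences(occ, test_fraction, seed=seed + 200 + i)
        model = fit_maxent(
            train,
            background,
            present,
            beta=beta,
            variables=variables,
            n_hinge_knots=n_hinge_knots,
            seed=seed,
        )
        models[vu] = model
        evaluations[vu] = evaluate_auc(model, test, background, present)

    stacks = {float(a): generate_climate_stack(spec, age_ka=float(a)) for a in ages}
    co2 = generate_co2_series(list(stacks) + [0.0])
    table = correction_table or (CorrectionTable.default() if correction else None)
    if table is not None and correction:
        missing = [vu for vu in models if vu not in table.base_factors]
        if missing:
            raise ValueError(f"correction table lacks units: {missing}")
    hindcast = run_hindcast(
        models, stacks, co2=co2, table=table, correction_on=correction
    )

    present_surfaces = {vu: project_model(m, present) for vu, m in models.items()}
    unit_order = tuple(models)
    present_map = composite(present_surfaces, threshold=threshold, unit_order=unit_order)

    past_maps = {
        age: composite(hindcast.surfaces_at(age), threshold, unit_order)
        for age in hindcast.ages
    }
    past_maps_corrected = None
    if correction:
        past_maps_corrected = {
            age: composite(hindcast.surfaces_at(age, corrected=True), threshold, unit_order)
            for age in hindcast.ages
        }

    dem = present.elevation
    all_maps = list(past_maps.values()) + [present_map]
    summary = timeseries_summary(all_maps, dem)
    summary_corrected = None
    if past_maps_corrected is not None:
        summary_corrected = timeseries_summary(
            list(past_maps_corrected.values()) + [present_map], dem
        )

    return PipelineResult(
        spec=spec,
        present=present,
        truth=truth,
        models=models,
        evaluations=evaluations,
        background=background,
        hindcast=hindcast,
        present_surfaces=present_surfaces,
        past_maps=past_maps,
        past_maps_corrected=past_maps_corrected,
        present_map=present_map,
        co2=co2,
        correction_table=table,
        summary=summary,
        summary_corrected=summary_corrected,
    )
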