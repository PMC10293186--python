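# Methods

## Overview

`paleoveg` reconstructs past distributions of potential-vegetation units
from presence-background niche models. The workflow is:

1. characterize each vegetation unit (VU) climatically by extracting all
   grid cells within its extent and screening predictor collinearity;
2. fit one penalized maximum-entropy model per unit from presence
   locations sampled inside the unit's extent, against a uniform
   background sample of the landscape (no absence data);
3. project each model onto a stack of past climate slices, applying a
   CO2 physiological correction to the predicted probability of
   occurrence;
4. composite the per-unit probability surfaces cell by cell into a
   categorical vegetation map per slice, with a no-analog class where no
   unit is sufficiently suitable;
5. summarize unit areas and elevation limits through time and validate
   the maps against pollen records via habitat-distance concordance.

Everything runs on synthetic landscapes generated by the package itself,
so the full pipeline is testable without external rasters.

## The niche model

For unit *u* with feature expansion `f(x)` (values in [0, 1]) the model
is the Gibbs distribution over background cells,

    q(x) = exp(lambda . f(x)) / Z,   Z = sum_background exp(lambda . f(x)).

Weights maximize the penalized presence log-likelihood

    mean_presence(lambda . f(x)) - log Z - beta * sum_j s_j |lambda_j|,

with `s_j` the presence-sample standard deviation of feature *j*,
floored at 0.01 on the [0, 1] feature scale so presence-constant
features cannot drive weights to infinity. The objective is convex; it
is solved by L-BFGS-B on the positive/negative weight split (an exact
reformulation of the L1 term) to a projected-gradient tolerance of
1e-6. At the optimum the KKT conditions bound every feature's
presence/background mean gap by `beta * s_j`; the fitted residuals are
stored on the model and checked in the tests. The solver's objective
trace is recorded and must be non-increasing.

Feature classes default to linear, quadratic, pairwise products and
two-sided hinges with 31 evenly spaced knots per variable — the
conventional large-sample configuration for this model family.
`beta = 1.0`, background = 10,000 cells (all valid cells when the grid
is smaller). These settings are package defaults, configurable per fit.

Outputs: `raw` is q(x) normalized over the training background (sums to
1 there); `cloglog` is `1 - exp(-e^H q(x))` with `H` the entropy of the
fitted background distribution, clipped to [0, 1] and used downstream as
the probability of occurrence. Models are evaluated with the exact rank
AUC (ties count 1/2) of a 25% random holdout (floor rule) against the
background sample.

## Hindcast projection and CO2 correction

Projection reuses the training-time min/max scaling; predictor values
outside the training range are clamped to the boundary and flagged in a
clamping mask (on by default — a standard hindcasting safeguard).
Projecting onto the training stack reproduces the present-day
prediction exactly, which serves as the control test.

Low glacial CO2 suppresses woody vegetation relative to what climate
alone would allow and favours C4-dominated open habitats. Each unit
carries a base factor `f_LGM` (fraction-cover ratio at glacial vs
reference CO2, supplied as input); the correction factor at
concentration `c` is linear between `(c_LGM, f_LGM)` and `(c_ref, 1)`:

    factor(c) = 1 + (f_LGM - 1) (c_ref - c) / (c_ref - c_LGM)

with `factor = 1` for `c >= c_ref` and linear extrapolation floored at 0
below `c_LGM`. Defaults: `c_LGM = 185 ppm`, `c_ref = 280 ppm`
(pre-industrial). The factor multiplies the cloglog probability, clipped
to [0, 1]; surfaces are corrected at most once (guarded) and no
cross-unit renormalization is applied afterwards — per-unit clipping
keeps probability semantics and leaves the compositing argmax
interpretable. Per-slice CO2 is linearly interpolated from the input
series, consistent with the assumed linear effect model.

The synthetic default factor table uses `f_LGM < 1` for the forest and
high-belt analogs (AA 0.85, EB 0.85, DAF 0.70, MAF 0.75) and
`f_LGM > 1` for the open-vegetation analogs (CTW 1.25, ACB 1.30,
DSS 1.20). Real applications supply their own table as CSV.

## Compositing and summaries

Per slice and cell, the unit with the highest corrected (or uncorrected)
probability claims the cell; if the maximum falls below the no-analog
threshold (default 0.1) the cell is left unassigned. Ties break toward
the earlier unit in the configured order, which is recorded in the map
metadata. Elevation limits per unit use the 2nd/98th percentiles of the
unit's cell elevations rather than min/max, so single outlying cells do
not define a belt boundary; the convention is recorded in the output.
Areas are cell counts times the cell area; no geodesic correction is
applied on the planar synthetic grids (a real-CRS input would need one).

## Predictor screening

Pairwise Spearman rank correlation (average ranks for ties) is computed
over jointly valid cells of all candidate layers; constant layers yield
undefined coefficients, reported missing with a warning. Selection is a
greedy elimination: repeatedly drop the non-override variable with the
most above-threshold partners (ties: the later name in the fixed
candidate ordering) until no resolvable pair exceeds the threshold.
The default threshold is |rho| = 0.85 with the nine standard predictors
(annual mean temperature; warmest-month maximum; coldest-month minimum;
wettest/driest-quarter mean temperatures; annual precipitation;
wettest/driest-month precipitation; warmest-quarter precipitation) as
keep-overrides: several of them are mutually rank-correlated yet carry
complementary ecological information, so they are retained by design and
the greedy pass removes the redundant remainder of the 19-layer set.
The threshold and overrides are configuration, not constants.

## The synthetic landscape

The generator emulates the statistical structure the analysis assumes,
not any real topography:

- **Relief** — spectrally smoothed Gaussian noise plus one deterministic
  north-south ridge and a gentle tilt aligned with the rainfall
  gradient (so the dry margin is low-lying, as on real mountain
  forelands). The composite field is rank-transformed to a fixed
  hypsometric curve `E = 4500 m * u^2`, making belt areas identical
  across seeds while the spatial pattern varies.
- **Temperature** — `T = T0 + dT(age) - L * E / 100` with sea-level
  temperature `T0 = 28 deg C` and lapse rate `L = 0.6 deg C / 100 m`,
  the midpoint of the 0.5-0.7 range typical of tropical East African
  mountains. Seasonal layers add constant offsets, so regressing any
  absolute temperature layer on elevation recovers the lapse rate
  exactly. In the extended 19-layer stack the range/ratio indices
  (diurnal range, isothermality, seasonality, annual range) are
  stylized monotone functions of relief, and the extra precipitation
  layers monotone in annual precipitation — deliberately so, since their
  role is to exercise the collinearity screen, not to be physically
  recomputed from monthly series.
- **Precipitation** — a planar gradient (default 1.5 and 8 mm/cell on a
  200 x 200 km grid, base 150 mm) plus smooth seeded texture, floored at
  0. `LandscapeSpec.for_grid` rescales the per-cell gradient so smaller
  grids keep the same climatic span.
- **Past slices** — temperature anomaly linear in age (-6 deg C at
  22 ka -> 0 today) and precipitation scale 0.8 -> 1.0, a stylized
  cold-and-dry glacial signal; CO2 ramps piecewise-linearly from
  185 ppm at 22 ka to 280 ppm today.
- **Ground truth** — seven units (AA, EB, DAF, MAF, CTW, ACB, DSS)
  defined as product-Gaussian envelopes on mean annual temperature and
  annual precipitation, arranged as altitudinal belts from the
  Afroalpine zone (optimum 5.5 deg C) down to desert scrub
  (27.5 deg C, 150 mm). Cells where every envelope falls below 0.1 are
  no-analog. Presences are drawn uniformly from a unit's cells with
  uniform within-cell jitter (duplicate coordinates would degrade
  feature scaling).
- **Pollen** — one sample per slice; expected group proportions decay as
  `exp(-d/20 km)` in the distance to the nearest mapped habitat, with
  fixed wetland (8%) and ambiguous (5%) background proportions, split
  evenly among each group's taxa, drawn multinomially.

What passing tests on these landscapes do **not** show: skill on real
rasters with observation error, spatially biased sampling, non-Gaussian
niches, disequilibrium vegetation dynamics, or orographic rainfall —
none of which the generator emulates.

## Pollen validation

Taxa are assigned to one unit each or excluded (ambiguous, multi-group,
or wetland-sourced). The pollen sum is the grains of assigned taxa only;
excluded taxa sit outside both numerator and denominator, so adding
grains to them changes no group percentage. Sample ages are matched to
slice ages by nearest neighbour within 0.5 ka (slices are millennial).
Concordance between a group's percentage series and the negated
habitat-distance series is Spearman's rho (> 0 means more pollen when
the habitat is closer). The underlying model-proxy comparison in this
literature is visual; the rho statistic is this package's
operationalization of it and is labelled as such.

## Numerical choices and degenerate inputs

- Holdout size uses floor(fraction * n): deterministic and documented.
- Compositing ties break by configured unit order; argmax is invariant
  under any common strictly monotone rescaling of all surfaces.
- Histogram edges span [min, max] with equal widths; a degenerate
  all-equal sample receives numpy's padded unit range.
- `fit_maxent` accepts as few as 10 background cells (warning below
  100) so that tiny closed-form/oracle problems remain runnable.
- Raw-output surfaces are clipped to [0, 1] when stored as probability
  surfaces; a projected cell can in principle exceed the training
  normalization.
- Seeds: every generator and sampler is a pure function of its seed;
  the pipeline derives all stage seeds from one top-level seed by fixed
  offsets.

## Problem sizes

The default study runs on a 200 x 200 grid of 1 km cells, 1000
presences per unit, 10,000 background cells, 22 past slices (22..1 ka)
plus a present-day control, which completes in a couple of minutes on
one CPU. Tests exercising model quality across replicate seeds use
120 x 120 grids with 4000 background cells; unit tests run on 48 x 48
grids with the same climatic span via `LandscapeSpec.for_grid`.

## Known limitations

- The maximum-entropy fit reproduces the model family's objective and
  defaults, not any specific third-party implementation bit for bit.
- Correction base factors for the synthetic units are plausible
  defaults, not derived from a dynamical vegetation model.
- No age-depth modelling: pollen chronologies are inputs.
- No patch/connectivity analysis of the composited maps; corridor-style
  interpretation is out of scope.
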