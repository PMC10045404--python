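# Methods

This note documents the models implemented in `ecoclim`, the choices made
where the underlying methods are under-specified in the literature, and what
the synthetic test world does and does not establish.

## Weekly climate representation

The mechanistic engine operates on a 364-day year of 52 exact 7-day weeks, so
stress and growth rates expressed per week are applied exactly. Calendar
months are rescaled onto that year (boundaries × 364/365). Temperatures and
relative humidity are interpolated linearly between month midpoints with
periodic wrap-around; commercial mechanistic-niche tools use an undocumented
internal scheme, so linear interpolation is a deliberate, documented
surrogate. Monthly rainfall is redistributed by week/month day-overlap, which
conserves the annual total exactly (the test suite asserts conservation for
arbitrary inputs). The engine's humidity input is the mean of the 09:00 and
15:00 observations; the two series are collected separately in standard
climatologies but no combination rule is published, so the mean is used and
exposed here as a single series.

## Soil-moisture bucket and irrigation

Weekly soil moisture (fraction of a 100 mm holding capacity; configurable) is

    sm_w = clip(sm_{w−1} + (rain_w + irr_w − E_w) / capacity, 0, sm_cap)

with evapotranspiration E = max(0, c_et·tmean)·(1 − rh/100)·7 mm/week
(c_et default 0.8 mm·°C⁻¹·day⁻¹). This linear, humidity-modulated ET is a
surrogate for the unpublished internal evaporation model of CLIMEX-class
tools; c_et and capacity are configuration knobs for calibration. The hard
cap sm_cap = 3.0 sits just above the wet-stress threshold (2.5) so wet stress
can engage; values above 1 represent waterlogging. The annual cycle is spun
up from sm = 0.5 until successive years differ by < 1e-6 (max 500 years); the
dynamics are contracting under the cap, and a test verifies independence from
the initial store. Irrigation is added to rainfall *before* the balance:
weeks under 10.5 mm are topped up to 10.5 mm, never more than 1.5 mm/day.
Whether the original tool applies irrigation before or after evaporation is
unknown; before-balance is the simpler reading of "top-up".

## Growth, stress and the Ecoclimatic Index

Temperature and moisture indices are piecewise-linear trapezoids over
DV0–DV3 and SM0–SM3; weekly growth is their product and the annual growth
index GI_A is 100 × the weekly mean. All indices evaluate on weekly mean
temperature (midpoint of tmin/tmax); the original tool integrates a diurnal
cycle it does not document. Each single stress accumulates
100·|rate|·exceedance per week, capped at 100; rates are taken by absolute
value because published parameter tables mix signs. Later versions of
commercial tools use exponential stress accumulation; linear accumulation is
used here because it keeps worked examples hand-checkable and is what the
published parameterization was described with. Hot-wet stress accrues on the
product of the temperature and moisture exceedances, only when both are
positive. EI multiplies GI_A by one (1 − S/100) factor per stress (floored at
0, so a stress above 100 cannot flip signs), and is set to 0 wherever annual
degree-days above DV0 fall short of PDD. The packaged raisin-moth file
follows the published parameter table (DV0 = 13 °C) where the accompanying
text says 11 °C; the table is taken as authoritative. The table's "(°C)"
units on SM0–SM3 are treated as a typo for dimensionless fractions. The
diapause, radiation and substrate indices are out of scope (the published
model excluded diapause explicitly).

Binary suitability uses a closed lower cut EI ≥ ei_min, default 10. No
published EI threshold backs the reported km² totals, so every area figure
in this package is explicitly threshold-dependent and ei_min is prominent in
the configuration.

## Maxent implementation

The SDM is the background-normalized exponential density
p(x) ∝ exp(Σ coef_j f_j(x)), fit by maximizing the presence log-likelihood
minus an L1 penalty — the published maxent ≡ penalized-GLM equivalence —
using cyclic coordinate descent with soft thresholding and damped Newton
steps. Features: linear, quadratic, product, threshold and hinge
(forward + reverse at background quantile knots, 20 per variable by default;
count configurable), all rescaled to [0, 1] over the background sample.
Per-feature penalty: RM · βclass · sd(presence feature)/√n_presence with
βclass = 1 (0.5 for hinge), a simplified version of the original tool's
sample-size-interpolated tables. Output uses the cloglog transform
1 − exp(−e^H · raw), H the background entropy of the raw density.

Percent contribution attributes positive objective increments during
coordinate descent to each feature's source variable (products split evenly),
normalized to 100 — an approximation of the original tool's fitting trace.
Permutation importance is the training-AUC drop when one predictor is
shuffled, clipped at zero and normalized. AICc uses the presence likelihood
under the background-normalized density with k = nonzero coefficients and
n = presences, and is reported undefined when n ≤ k + 1 (such combinations
are excluded from selection). OR10 uses the ceiling rule on the lowest 10% of
training-presence scores and counts test presences strictly below the
threshold. Spatial-block cross-validation assigns quadrants at the presence
coordinate medians (background reuses the presence-derived split); the
quadrant split balances each median dimension to ±1 but cannot guarantee
four exactly equal groups for arbitrary point patterns. Quadratic and product
features make predictions exactly invariant to positive rescaling of raw
predictors; under affine shifts the penalty weights of quadratic features
change slightly, so exact invariance is asserted for linear/hinge models and
scale-invariance for the full feature set.

The greedy |r| > 0.8 collinearity filter visits variables in descending
contribution and drops the lower-contribution member of each offending pair;
the "biological relevance" judgement that accompanied the published variable
selection is subjective and not encoded. Occurrence thinning removes, at each
step, the point with the most neighbours within the minimum great-circle
distance (seeded tie-break); on small instances it matches the exhaustive
maximum independent set in the test suite. Latitude can be used as a
predictor directly (the synthetic latitude raster is signed; callers wanting
absolute latitude can transform the column — published usage is internally
inconsistent between the two conventions, so neither is hard-coded).

## Synthetic world

The generator produces monthly climate with an annual-mean gradient
(equator mean 27 °C, lapse 0.6 °C per degree latitude), a seasonal cycle
(amplitude 8 °C, phase flipped between hemispheres), a fixed diurnal range,
and a uniform / winter-wet / summer-wet rainfall regime. The default study
region for scenario experiments is a 24–72° latitude band with winter-wet
800 mm/year and 70% humidity. That combination was chosen at design time so
that, under the raisin-moth parameters, the region's suitable band is
temperature-limited on its poleward side (growth collapses via the
temperature index and the PDD gate) while the equatorward side of the domain
remains suitable — the configuration in which warming should, and does, both
shift the EI > 0 boundary poleward and enlarge the suitable area. On a
uniform sphere a band that merely translates poleward *loses* area (cosine
weighting), so the area-growth property is only expected for such
temperature-limited regions; the package treats it as a property of this
study design, not of warming in general.

Predictor rasters are Gaussian-smoothed white noise mapped onto plausible
bioclim magnitudes; they reproduce the smooth spatial structure of climate
summaries but not their mutual correlations, so passing recovery tests shows
the estimator works under known truth, not that real predictors are this
well-behaved. Presences are drawn without replacement, cell-weighted by a
known logistic suitability surface (mimicking one record per location after
thinning). The recovery suite uses a two-variable truth with standardized
coefficients +5/−4 and intercept −4: strong enough that the truth surface
itself separates presences from background at AUC ≈ 0.84 — the ceiling any
estimator can reach under presence-versus-background evaluation — leaving the
fitted model's held-out AUC above 0.8. The end-to-end pipeline samples SDM
presences from the predictor truth surface, which is independent of the EI
world; its coverage statistic therefore demonstrates the metric, and is not a
cross-model validation.

## Problem sizes and numerics

The test suite and acceptance script run the engine on grids of a few hundred
cells, tune the full 48-combination grid on a 2-predictor fixture
(60 presences, 600 background, 6 hinge knots) and fit recovery models with
200 presences against 5,000 background points — sizes chosen so the whole
study re-runs in about a minute while exercising every code path at full
protocol width. Coordinate descent converges at tolerance 1e-7 (max 10,000
updates); near-constant features get a 1e-3 standard-deviation floor in the
penalty. Suitability-grid points on cell boundaries snap to the nearest cell
center with ties toward the lower index. Published area/percent figures for
this species are mutually inconsistent at printed precision (rounded area
pairs do not reproduce the printed percentages exactly); the scenario module
always reports percent change from unrounded areas.

## Known limitations

- The hydrology is a one-bucket, ET-linear surrogate; no Penman–Monteith,
  snow, runoff or sub-weekly dynamics.
- Stress accumulation is linear with a hard cap; no exponential accumulation
  option.
- The maxent implementation is not bit-compatible with MaxEnt-java: penalty
  defaults are simplified, hinge knots are quantile-based, and no clamping or
  MESS extrapolation diagnostics are provided.
- GeoTIFF rasters are not read; predictor stacks are NetCDF or CSV.
- Synthetic predictors are mutually independent fields; collinearity
  behaviour on real bioclim stacks is exercised only through constructed
  duplicated-column tests.
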