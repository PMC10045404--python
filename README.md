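# ecoclim

Dual-model climatic-suitability analysis for the raisin moth (*Cadra
figulilella*), an invasive pest of fresh and stored fruit. The package
implements, as tested open-source code, the two complementary species
distribution modelling approaches used for this species:

1. **A mechanistic Ecoclimatic Index (EI) engine.** Each grid cell's monthly
   climate is interpolated to 52 weeks; a soil-moisture bucket converts
   rainfall and evapotranspiration into weekly soil moisture; weekly growth is
   the product of trapezoidal temperature and moisture suitability indices
   (thresholds DV0–DV3 and SM0–SM3); cold, heat, dry, wet and interactive
   hot-wet stresses accumulate linearly beyond their thresholds; and

   EI = GI_A · (1−CS/100)(1−HS/100)(1−DS/100)(1−WS/100)(1−HW/100),

   forced to 0 where annual degree-days above DV0 fall short of PDD (one
   generation). An irrigation scenario tops weekly water up to 10.5 mm
   (≤ 1.5 mm/day), and a composite map takes the irrigated EI on irrigated
   cells. The packaged raisin-moth parameter file sets DV0–DV3 =
   13/15/30/36 °C, SM0–SM3 = 0.25/0.8/1.5/2.5, PDD = 292, and the hot-wet
   triple TTHW = 23 °C, MTHW = 1.35, PHW = 0.075 week⁻¹.

2. **A presence-only maximum-entropy SDM.** An exponential density over
   background points with L/Q/H/P/T features, fit by L1-penalized
   coordinate descent (penalty ∝ RM · βclass · sd/√n). Model tuning follows
   the standard presence-only protocol: 8 regularization multipliers
   (0.5–4 step 0.5) × 6 feature-class sets (L, LQ, H, LQH, LQHP, LQHPT) =
   48 combinations, scored by AICc with spatial-block cross-validated
   AUC difference and 10% training omission rate (OR10); the AICc minimum is
   selected. Percent contribution, permutation importance, jackknife gains
   and response curves summarize the fitted model.

Scenario accounting (spherical-zone cell areas, suitable-area percent change,
occurrence coverage, multi-model ensemble means) and a fully synthetic world
(seeded climate grids with latitudinal gradient and seasonal cycle, smooth
bioclim-style predictor rasters, presences drawn from a known suitability
surface, irrigation masks) make every stage runnable and testable offline.

## Worked example

```python
from ecoclim.config import RunConfig
from ecoclim.pipeline import run_pipeline

cfg = RunConfig(seed=42)
cfg.sdm = {**cfg.sdm, "rm_values": [0.5, 1.0], "feature_sets": ["L", "LQ"]}
report = run_pipeline(cfg, "demo_run")
print(report["current"]["suitable_km2"])          # 1621046.75
print(report["futures"][1]["label"],
      report["futures"][1]["percent_change_vs_reference"])  # ssp585-like 147.51
print(report["tuning"])
# {'n_combinations': 4, 'selected_rm': 0.5, 'selected_fc': 'L',
#  'selected_delta_aicc': 0.0}
```

The run writes, under `demo_run/`: the synthetic fixtures, rainfed/irrigated/
composite EI NetCDF grids for the current climate and each warming scenario,
the SDM tuning table, the selected model (JSON), variable importance, and
`run_summary.json`. On the default synthetic world (a 24–72° N, winter-wet
study region), the current suitable area at EI ≥ 10 is ~1.62 × 10⁶ km²; a
+2 °C scenario raises it by ~40% and +5 °C by ~148%, with the poleward EI > 0
boundary moving to higher latitude — warming opens formerly
temperature-limited latitudes faster than it degrades the warm edge of this
region. All numbers above are what the code prints at seed 42.

The same stages are scriptable from the shell:

```bash
ecoclim fixtures --out fix --seed 42
ecoclim run --climate fix/climate_current.nc --out ei.nc
ecoclim sdm tune --occurrences fix/occurrences.csv --rasters fix/predictors.nc --out tuning.csv
ecoclim report --current ei.nc --occurrences fix/occurrences.csv --out report.json
```

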