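"""End-to-end pipeline: synthetic world → mechanistic EI maps → SDM → report.

Chains the package stages the way a full study would: generate (or load) the
current-climate grid, run the Ecoclimatic Index engine under rainfed and
irrigated regimes for the current climate and each warming scenario, fit and
tune the maxent SDM on presences sampled from a known truth surface, and write
the suitable-area / coverage report.  Every output embeds the package version,
the resolved configuration hash and the global seed; each stage draws its
randomness from a seed derived stably from the global one, so stages are
individually reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import SyntheticClimateSpec, apply_scenario, generate_climate_grid, write_climate
from .config import RunConfig, derive_seed
from .ecoclimatic import run_compare_locations
from .growth_stress import cfigulilella_params, load_params
from .hydrology import IrrigationRule
from .maxent import build_env_table, fit_maxent, tune_models, variable_contributions
from .scenario import build_report, suitable_area
from .synthetic import TruthSurface, make_irrigation_mask, make_predictor_rasters, sample_presences

__all__ = ["run_pipeline", "write_fixtures"]

log = logging.getLogger("ecoclim")


def _provenance(cfg: RunConfig) -> dict:
    return {"version": __version__, "config_hash": cfg.hash, "seed": cfg.seed}


def write_fixtures(cfg: RunConfig, outdir: Path) -> dict:
    """Generate and write the synthetic world; returns the in-memory objects."""
    outdir.mkdir(parents=True, exist_ok=True)
    spec = SyntheticClimateSpec(seed=derive_seed(cfg.seed, "climate"), **cfg.climate)
    grid = generate_climate_grid(spec)
    write_climate(grid, outdir / "climate_current.nc")

    rasters = make_predictor_rasters(grid.lats, grid.lons,
                                     seed=derive_seed(cfg.seed, "rasters"))
    rasters.astype(np.float32).to_netcdf(outdir / "predictors.nc", engine="scipy")

    truth = TruthSurface(cfg.sdm["truth"], seed=derive_seed(cfg.seed, "presences"))
    occurrences = sample_presences(truth, rasters, cfg.sdm["n_presence"])
    occurrences.to_csv(outdir / "occurrences.csv", index=False)

    mask = make_irrigation_mask(grid.lats, grid.lons, cfg.irrigation_fraction,
                                seed=derive_seed(cfg.seed, "irrigation"))
    np.savetxt(outdir / "irrigation_mask.csv", mask.astype(int), fmt="%d", delimiter=",")
    return {"grid": grid, "rasters": rasters, "truth": truth,
            "occurrences": occurrences, "irrigation_mask": mask}


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the summary dict written to ``run_summary.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    prov = _provenance(cfg)

    log.info("stage 1/4: fixtures")
    fx = write_fixtures(cfg, outdir / "fixtures")
    grid, occurrences = fx["grid"], fx["occurrences"]

    log.info("stage 2/4: mechanistic engine")
    params = load_params(cfg.species_params) if cfg.species_params else cfigulilella_params()
    rule = IrrigationRule(**cfg.irrigation)
    soil = {"capacity": cfg.soil["capacity"], "sm_cap": cfg.soil["sm_cap"],
            "c_et": cfg.soil["c_et"]}
    ei_grids = {}
    scenarios = [{"label": "current", "delta_t": 0.0, "rain_factor": 1.0}] + list(cfg.scenarios)
    for sc in scenarios:
        g = apply_scenario(grid, sc["delta_t"], sc["rain_factor"])
        rainfed, irrigated, composite = run_compare_locations(
            g, params, fx["irrigation_mask"], rule=rule, scenario=sc, **soil)
        for tag, sg in (("rainfed", rainfed), ("irrigated", irrigated),
                        ("composite", composite)):
            sg.write(outdir / f"ei_{sc['label']}_{tag}.nc")
        ei_grids[sc["label"]] = composite

    log.info("stage 3/4: maxent SDM")
    predictors = list(cfg.sdm["predictors"])
    env = build_env_table(fx["rasters"], occurrences, predictors,
                          n_background=cfg.sdm["n_background"],
                          seed=derive_seed(cfg.seed, "background"))
    rm_values = cfg.sdm.get("rm_values") or None
    feature_sets = cfg.sdm.get("feature_sets") or None
    tune_kwargs = {"n_hinge_knots": cfg.sdm["n_hinge_knots"]}
    if rm_values is not None:
        tune_kwargs["rm_values"] = rm_values
    if feature_sets is not None:
        tune_kwargs["feature_sets"] = feature_sets
    tuning, best = tune_models(env, predictors, **tune_kwargs)
    tuning.to_csv(outdir / "sdm_tuning.csv", index=False)
    model = fit_maxent(env, predictors, classes=best["fc"], rm=best["rm"],
                       n_hinge_knots=cfg.sdm["n_hinge_knots"])
    model.save(outdir / "sdm_model.json")
    importance = variable_contributions(model, env, seed=derive_seed(cfg.seed, "perm"))
    importance.to_csv(outdir / "sdm_importance.csv", index=False)

    log.info("stage 4/4: scenario report")
    current = ei_grids["current"]
    futures = [ei_grids[sc["label"]] for sc in cfg.scenarios]
    report = build_report(current, futures, cfg.ei_min, occurrences)
    report.update(prov)
    report["tuning"] = {"n_combinations": int(len(tuning)),
                        "selected_rm": float(best["rm"]), "selected_fc": best["fc"],
                        "selected_delta_aicc": float(best["delta_aicc"])}
    report["suitable_area_current_km2"] = suitable_area(current, cfg.ei_min)
    (outdir / "run_summary.json").write_text(json.dumps(report, indent=1))
    return report
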