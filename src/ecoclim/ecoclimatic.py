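"""Ecoclimatic Index: combining growth and stress into 0-100 suitability grids.

EI multiplies the annual growth index by one discount factor per stress,
``EI = GI_A * prod(1 - S/100)``, with each factor floored at zero, and is
forced to 0 wherever the annual degree-day total falls short of PDD (the
population cannot complete a generation).  The grid runner evaluates every
valid cell under both the rainfed and the irrigated water regime and builds
the composite map used for agricultural scenarios: irrigated EI where a cell
is irrigated, rainfed EI elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from . import growth_stress as gs
from .climate import ClimateGrid, weekly_fields
from .hydrology import IrrigationRule, soil_moisture_cycle

__all__ = [
    "LocationResult",
    "SuitabilityGrid",
    "ecoclimatic_index",
    "location_result",
    "run_compare_locations",
    "classify_suitability",
]


@dataclass
class LocationResult:
    """Engine outputs for one location: growth, the five stress totals,
    degree-days and the Ecoclimatic Index."""

    GI_A: float
    CS: float
    HS: float
    DS: float
    WS: float
    HW: float
    annual_dd: float
    EI: float


@dataclass
class SuitabilityGrid:
    """Lat/lon raster of EI (0-100) or SDM probability (0-1).

    ``kind`` is "EI" or "probability"; ``scenario`` records the transform that
    produced the underlying climate (label, delta_t, rain_factor).
    """

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray
    kind: str = "EI"
    mask: np.ndarray = None
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, float)
        self.lons = np.asarray(self.lons, float)
        self.values = np.asarray(self.values, float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, bool)
        hi = 100.0 if self.kind == "EI" else 1.0
        vals = self.values[self.mask]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > hi):
            raise ValueError(f"{self.kind} values outside [0, {hi}]")

    @property
    def resolution(self) -> float:
        return float(self.lats[1] - self.lats[0]) if self.lats.size > 1 else 1.0

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"suitability": (("lat", "lon"), self.values.astype(np.float32)),
             "mask": (("lat", "lon"), self.mask.astype(np.int8))},
            coords={"lat": self.lats, "lon": self.lons},
        )
        ds.attrs["kind"] = self.kind
        for k, v in self.scenario.items():
            ds.attrs[f"scenario_{k}"] = v
        return ds

    def write(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def read(cls, path: str | Path) -> "SuitabilityGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        scenario = {k[len("scenario_"):]: v for k, v in ds.attrs.items()
                    if k.startswith("scenario_")}
        return cls(ds["lat"].values, ds["lon"].values,
                   ds["suitability"].values.astype(float),
                   kind=str(ds.attrs.get("kind", "EI")),
                   mask=ds["mask"].values.astype(bool) if "mask" in ds else None,
                   scenario=scenario)


def ecoclimatic_index(gi_a, cs, hs, ds, ws, hw, annual_dd, p: gs.SpeciesParams):
    """Compose EI from growth and stresses; zero below the PDD degree-day gate.

    Accepts scalars or aligned arrays; result clamped to [0, 100].
    """
    gi_a = np.asarray(gi_a, float)
    ei = gi_a.astype(float)
    for s in (cs, hs, ds, ws, hw):
        ei = ei * np.maximum(0.0, 1.0 - np.asarray(s, float) / 100.0)
    ei = np.where(np.asarray(annual_dd, float) < p.PDD, 0.0, ei)
    ei = np.clip(ei, 0.0, 100.0)
    return ei if ei.ndim else float(ei)


def location_result(tmean, sm, p: gs.SpeciesParams):
    """Growth, stresses, degree-days and EI from aligned weekly series.

    ``tmean``/``sm`` may be (52,) or (52, n); returns arrays (or scalars) per
    component, packed as a dict to keep the vectorized path allocation-free.
    """
    ti = gs.temperature_index(tmean, p)
    mi = gs.moisture_index(sm, p)
    gi_a = gs.annual_growth_index(gs.weekly_growth_index(ti, mi))
    cs = gs.accumulate_stress(tmean, p.TTCS, p.THCS, "below")
    hs = gs.accumulate_stress(tmean, p.TTHS, p.THHS, "above")
    dsx = gs.accumulate_stress(sm, p.SMDS, p.HDS, "below")
    ws = gs.accumulate_stress(sm, p.SMWS, p.HWS, "above")
    hw = gs.hot_wet_stress(tmean, sm, p)
    dd = gs.annual_degree_days(tmean, p.DV0)
    ei = ecoclimatic_index(gi_a, cs, hs, dsx, ws, hw, dd, p)
    return {"GI_A": gi_a, "CS": cs, "HS": hs, "DS": dsx, "WS": ws, "HW": hw,
            "annual_dd": dd, "EI": ei}


def run_compare_locations(
    grid: ClimateGrid,
    p: gs.SpeciesParams,
    irrigation_mask: np.ndarray | None = None,
    rule: IrrigationRule = IrrigationRule(),
    scenario: dict | None = None,
    **soil_kwargs,
) -> tuple[SuitabilityGrid, SuitabilityGrid, SuitabilityGrid]:
    """Run the engine over every valid cell under both water regimes.

    Returns (rainfed, irrigated, composite) EI grids; the composite takes the
    irrigated EI where ``irrigation_mask`` is true and the rainfed EI elsewhere.
    Extra keyword arguments are passed to the soil-moisture model
    (capacity, c_et, sm_cap, ...).
    """
    if irrigation_mask is None:
        irrigation_mask = np.zeros(grid.shape, bool)
    irrigation_mask = np.asarray(irrigation_mask, bool)
    if irrigation_mask.shape != grid.shape:
        raise ValueError(
            f"irrigation mask shape {irrigation_mask.shape} != grid shape {grid.shape}")

    tmean, rain, rh = weekly_fields(grid)
    valid = grid.mask.ravel()
    tm = tmean.reshape(52, -1)[:, valid]
    ra = rain.reshape(52, -1)[:, valid]
    rhv = rh.reshape(52, -1)[:, valid]

    scenario = dict(scenario or {})
    out = {}
    for label, irrig in (("rainfed", False), ("irrigated", True)):
        sm = soil_moisture_cycle(ra, tm, rhv, irrigated=irrig, rule=rule, **soil_kwargs)
        ei_cells = location_result(tm, sm, p)["EI"]
        values = np.full(grid.shape, np.nan).ravel()
        values[valid] = ei_cells
        out[label] = SuitabilityGrid(
            grid.lats, grid.lons, values.reshape(grid.shape), kind="EI",
            mask=grid.mask.copy(), scenario={**scenario, "water": label})

    composite_vals = np.where(irrigation_mask, out["irrigated"].values, out["rainfed"].values)
    composite = SuitabilityGrid(
        grid.lats, grid.lons, composite_vals, kind="EI", mask=grid.mask.copy(),
        scenario={**scenario, "water": "composite"})
    return out["rainfed"], out["irrigated"], composite


DEFAULT_BANDS = {"unsuitable": 0.0, "marginal": 10.0, "suitable": 30.0}


def classify_suitability(values, ei_min: float = 10.0, bands: dict | None = None):
    """Label EI values as suitable/unsuitable at the ``ei_min`` cut (closed lower
    bound), or into named bands when ``bands`` maps label -> lower edge."""
    values = np.asarray(values, float)
    if bands is not None:
        items = sorted(bands.items(), key=lambda kv: kv[1])
        labels = np.full(values.shape, items[0][0], dtype=object)
        for name, lo in items[1:]:
            labels[values >= lo] = name
        return labels
    return np.where(values >= ei_min, "suitable", "unsuitable")
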