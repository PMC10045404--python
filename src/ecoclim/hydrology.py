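"""Weekly soil-moisture bucket and the irrigation top-up scenario.

The moisture index of the mechanistic engine is driven by soil moisture
expressed as a fraction of soil-moisture-holding capacity (default 100 mm);
values above 1 represent waterlogging, capped at ``sm_cap`` (default 3.0,
just above the wet-stress threshold so wet stress can engage).  Weekly
evapotranspiration is a linear surrogate, proportional to temperature and to
the saturation deficit: ``E = max(0, c_et * tmean) * (1 - rh/100) * 7`` mm/week.

The irrigation scenario tops weekly water input up to a 10.5 mm threshold,
never adding more than 1.5 mm/day (10.5 mm/week): weeks already receiving more
than 10.5 mm of rain get nothing.

The annual cycle is spun up from a fixed initial store until it converges to a
periodic steady state; the bucket dynamics are contracting under the cap, so
the converged cycle does not depend on the starting store.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import WeeklyClimate

__all__ = [
    "IrrigationRule",
    "SoilMoistureSeries",
    "irrigation_topup",
    "weekly_evapotranspiration",
    "soil_moisture_series",
    "soil_moisture_cycle",
]


@dataclass(frozen=True)
class IrrigationRule:
    """Top-up irrigation: fill weekly water input to ``threshold_mm``, at most
    ``daily_cap_mm`` per day (7x per week)."""

    threshold_mm: float = 10.5
    daily_cap_mm: float = 1.5


@dataclass
class SoilMoistureSeries:
    """Converged periodic 52-week soil-moisture cycle (fractions of capacity)."""

    sm: np.ndarray
    capacity: float


def irrigation_topup(rain_week: float | np.ndarray, rule: IrrigationRule = IrrigationRule()):
    """Water added (mm) to a week with ``rain_week`` mm of rainfall.

    Weeks above the threshold receive nothing; below it, the deficit is made up
    but never more than 7 x the daily cap.
    """
    rain_week = np.asarray(rain_week, float)
    if np.any(rain_week < 0):
        raise ValueError("negative weekly rainfall")
    added = np.clip(rule.threshold_mm - rain_week, 0.0, 7.0 * rule.daily_cap_mm)
    return added if added.ndim else float(added)


def weekly_evapotranspiration(tmean, rh, c_et: float = 0.8):
    """Surrogate weekly evapotranspiration (mm): linear in temperature, scaled by
    the relative-humidity deficit; zero for tmean <= 0 and at saturation."""
    tmean = np.asarray(tmean, float)
    rh = np.asarray(rh, float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity outside [0, 100]")
    e = np.maximum(0.0, c_et * tmean) * (1.0 - rh / 100.0) * 7.0
    return e if e.ndim else float(e)


def soil_moisture_cycle(
    rain: np.ndarray,
    tmean: np.ndarray,
    rh: np.ndarray,
    irrigated: bool = False,
    rule: IrrigationRule = IrrigationRule(),
    capacity: float = 100.0,
    c_et: float = 0.8,
    sm_cap: float = 3.0,
    sm_init: float = 0.5,
    tol: float = 1e-6,
    max_years: int = 500,
) -> np.ndarray:
    """Converged periodic soil-moisture cycle for (52,) or (52, n) weekly inputs.

    The weekly balance is
    ``sm_w = clip(sm_{w-1} + (rain_w + irr_w - E_w) / capacity, 0, sm_cap)``,
    iterated over whole years from ``sm_init`` until the largest change between
    successive years is below ``tol``.
    """
    rain = np.atleast_2d(np.asarray(rain, float).T).T  # (52,) -> (52, 1)
    tmean = np.atleast_2d(np.asarray(tmean, float).T).T
    rh = np.atleast_2d(np.asarray(rh, float).T).T
    if rain.shape[0] != 52:
        raise ValueError("weekly series must have 52 entries")
    water = rain + (irrigation_topup(rain, rule) if irrigated else 0.0)
    delta = (water - weekly_evapotranspiration(tmean, rh, c_et)) / capacity

    sm = np.full(rain.shape[1], sm_init, float)
    cycle = np.full_like(rain, np.inf)
    for _ in range(max_years):
        prev = cycle.copy()
        for w in range(52):
            sm = np.clip(sm + delta[w], 0.0, sm_cap)
            cycle[w] = sm
        if np.max(np.abs(cycle - prev)) < tol:
            return cycle
    raise RuntimeError(f"soil-moisture spin-up did not converge within {max_years} years")


def soil_moisture_series(
    wc: WeeklyClimate,
    irrigated: bool = False,
    rule: IrrigationRule = IrrigationRule(),
    capacity: float = 100.0,
    c_et: float = 0.8,
    sm_cap: float = 3.0,
    sm_init: float = 0.5,
    tol: float = 1e-6,
    max_years: int = 500,
) -> SoilMoistureSeries:
    """Converged soil-moisture cycle for one cell's weekly climate."""
    cycle = soil_moisture_cycle(
        wc.rain, wc.tmean, wc.rh, irrigated=irrigated, rule=rule, capacity=capacity,
        c_et=c_et, sm_cap=sm_cap, sm_init=sm_init, tol=tol, max_years=max_years,
    )
    return SoilMoistureSeries(cycle[:, 0], capacity)
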