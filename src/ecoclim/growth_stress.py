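"""Weekly growth indices, annual stress accumulation and degree-days.

This is the mechanistic core of the Ecoclimatic Index engine.  Each week the
population grows in proportion to a temperature index (TI) and a moisture
index (MI), both piecewise-linear trapezoids over the species' thresholds
(DV0..DV3 for temperature, SM0..SM3 for soil moisture).  The annual growth
index GI_A is 100 x the mean weekly product.  Outside the growth window,
stresses accumulate linearly whenever a driver exceeds (or falls below) its
threshold, at a species-specific weekly rate; a fifth, interactive hot-wet
stress accrues only when temperature and soil moisture exceed their thresholds
simultaneously.  Degree-days above the development threshold DV0 gate
persistence: a site that cannot accumulate one generation's worth (PDD) is
unsuitable regardless of growth.

All functions accept weekly series shaped (52,) or (52, n) and operate along
axis 0, so a whole grid can be evaluated in one call.  Stress rates are taken
by absolute value: published parameter tables mix signs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

__all__ = [
    "SpeciesParams",
    "load_params",
    "cfigulilella_params",
    "temperature_index",
    "moisture_index",
    "weekly_growth_index",
    "annual_growth_index",
    "accumulate_stress",
    "hot_wet_stress",
    "annual_degree_days",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Full species parameter set for the mechanistic engine.

    Temperature thresholds DV0..DV3 (°C), soil-moisture thresholds SM0..SM3
    (fractions of capacity), four single-stress threshold/rate pairs, the
    hot-wet triple (TTHW °C, MTHW fraction, PHW week^-1) and PDD, the
    degree-days above DV0 needed to complete one generation.
    """

    DV0: float
    DV1: float
    DV2: float
    DV3: float
    SM0: float
    SM1: float
    SM2: float
    SM3: float
    TTCS: float
    THCS: float
    TTHS: float
    THHS: float
    SMDS: float
    HDS: float
    SMWS: float
    HWS: float
    TTHW: float
    MTHW: float
    PHW: float
    PDD: float

    def __post_init__(self) -> None:
        if not (self.DV0 < self.DV1 <= self.DV2 < self.DV3):
            raise ValueError("temperature thresholds must satisfy DV0 < DV1 <= DV2 < DV3")
        if not (self.SM0 < self.SM1 <= self.SM2 < self.SM3):
            raise ValueError("moisture thresholds must satisfy SM0 < SM1 <= SM2 < SM3")
        if self.PDD < 0:
            raise ValueError("PDD must be non-negative")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


def load_params(path: str | Path) -> SpeciesParams:
    """Read a flat ``NAME = value`` species parameter file."""
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = float(val)
    names = {f.name for f in fields(SpeciesParams)}
    missing = names - values.keys()
    if missing:
        raise ValueError(f"parameter file missing: {', '.join(sorted(missing))}")
    return SpeciesParams(**{k: v for k, v in values.items() if k in names})


def cfigulilella_params() -> SpeciesParams:
    """The packaged *Cadra figulilella* (raisin moth) parameter set."""
    ref = importlib.resources.files("ecoclim") / "data" / "cfigulilella.params"
    with importlib.resources.as_file(ref) as path:
        return load_params(path)


def _trapezoid(x, lo, opt_lo, opt_hi, hi):
    x = np.asarray(x, float)
    out = np.zeros_like(x)
    rising = (x > lo) & (x < opt_lo)
    out[rising] = (x[rising] - lo) / (opt_lo - lo)
    out[(x >= opt_lo) & (x <= opt_hi)] = 1.0
    falling = (x > opt_hi) & (x < hi)
    out[falling] = (hi - x[falling]) / (hi - opt_hi)
    return out


def temperature_index(tmean, p: SpeciesParams):
    """Weekly temperature suitability in [0, 1]: trapezoid over DV0..DV3."""
    return _trapezoid(tmean, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(sm, p: SpeciesParams):
    """Weekly moisture suitability in [0, 1]: trapezoid over SM0..SM3."""
    return _trapezoid(sm, p.SM0, p.SM1, p.SM2, p.SM3)


def weekly_growth_index(ti, mi):
    """Weekly growth index: product of temperature and moisture suitability."""
    return np.asarray(ti, float) * np.asarray(mi, float)


def annual_growth_index(gi_weekly):
    """Annual growth index in [0, 100]: 100 x the mean of 52 weekly values."""
    gi_weekly = np.asarray(gi_weekly, float)
    if gi_weekly.shape[0] != 52:
        raise ValueError("weekly growth index series must have 52 entries")
    return 100.0 * gi_weekly.mean(axis=0)


def accumulate_stress(driver, threshold: float, rate: float, side: str):
    """Annual stress total in [0, 100].

    Accumulates ``100 * |rate| * exceedance`` per week, where the exceedance is
    (threshold - driver) for ``side='below'`` (cold, dry) or (driver - threshold)
    for ``side='above'`` (heat, wet), floored at zero and capped at 100.
    """
    driver = np.asarray(driver, float)
    if side == "below":
        exc = threshold - driver
    elif side == "above":
        exc = driver - threshold
    else:
        raise ValueError(f"unknown side {side!r}; use 'above' or 'below'")
    total = 100.0 * abs(rate) * np.maximum(0.0, exc).sum(axis=0)
    return np.minimum(100.0, total)


def hot_wet_stress(tmean, sm, p: SpeciesParams):
    """Interactive hot-wet stress: accrues only in weeks where tmean > TTHW and
    sm > MTHW simultaneously, at rate PHW on the product of the two exceedances."""
    tmean = np.asarray(tmean, float)
    sm = np.asarray(sm, float)
    exc = np.maximum(0.0, tmean - p.TTHW) * np.maximum(0.0, sm - p.MTHW)
    return np.minimum(100.0, 100.0 * abs(p.PHW) * exc.sum(axis=0))


def annual_degree_days(tmean, dv0: float):
    """Degree-days above the development threshold: sum of 7 x max(0, tmean - DV0)."""
    tmean = np.asarray(tmean, float)
    return 7.0 * np.maximum(0.0, tmean - dv0).sum(axis=0)
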