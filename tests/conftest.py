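import numpy as np
import pytest

from ecoclim.climate import SyntheticClimateSpec, generate_climate_grid
from ecoclim.growth_stress import cfigulilella_params


@pytest.fixture(scope="session")
def params():
    return cfigulilella_params()


@pytest.fixture(scope="session")
def small_grid():
    """Tiny noise-free synthetic grid used across engine tests."""
    spec = SyntheticClimateSpec(lat_min=20, lat_max=44, lon_min=0, lon_max=8,
                                resolution=4, rain_regime="winter-wet",
                                annual_rain_mm=800, rh_baseline=70, seed=11, noise_sd=0)
    return generate_climate_grid(spec)


def naive_location_result(tmean, sm, p):
    """Independent per-week reference for the growth/stress/EI pipeline.

    Plain Python loop over the 52 weeks, written directly from the index
    definitions: trapezoidal suitability, linear capped stress accumulation,
    multiplicative EI with a degree-day gate.
    """
    def trap(x, lo, a, b, hi):
        if x <= lo or x >= hi:
            return 0.0
        if x < a:
            return (x - lo) / (a - lo)
        if x <= b:
            return 1.0
        return (hi - x) / (hi - b)

    gi_sum = cs = hs = ds = ws = hw = dd = 0.0
    for w in range(52):
        t, s = float(tmean[w]), float(sm[w])
        gi_sum += trap(t, p.DV0, p.DV1, p.DV2, p.DV3) * trap(s, p.SM0, p.SM1, p.SM2, p.SM3)
        cs += 100.0 * abs(p.THCS) * max(0.0, p.TTCS - t)
        hs += 100.0 * abs(p.THHS) * max(0.0, t - p.TTHS)
        ds += 100.0 * abs(p.HDS) * max(0.0, p.SMDS - s)
        ws += 100.0 * abs(p.HWS) * max(0.0, s - p.SMWS)
        hw += 100.0 * abs(p.PHW) * max(0.0, t - p.TTHW) * max(0.0, s - p.MTHW)
        dd += 7.0 * max(0.0, t - p.DV0)
    gi_a = 100.0 * gi_sum / 52.0
    cs, hs, ds, ws, hw = (min(100.0, v) for v in (cs, hs, ds, ws, hw))
    ei = gi_a
    for s in (cs, hs, ds, ws, hw):
        ei *= max(0.0, 1.0 - s / 100.0)
    if dd < p.PDD:
        ei = 0.0
    ei = min(100.0, max(0.0, ei))
    return {"GI_A": gi_a, "CS": cs, "HS": hs, "DS": ds, "WS": ws, "HW": hw,
            "annual_dd": dd, "EI": ei}
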