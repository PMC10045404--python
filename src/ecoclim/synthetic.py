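"""Synthetic fixture world: predictor rasters, known suitability surfaces,
seeded presence samplers and irrigation masks.

Every function here is pure given (arguments, seed), so test fixtures are
regenerated rather than stored.  Predictor fields are spatially autocorrelated
Gaussian-smoothed white noise rescaled to plausible bioclim magnitudes; they
emulate the smooth spatial structure of real climate summaries, not their
physical covariances.  A :class:`TruthSurface` defines a logistic suitability
over named predictors from which presences are drawn, enabling
parameter-recovery tests of the SDM stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .maxent import derive_topography

__all__ = [
    "TruthSurface",
    "make_predictor_rasters",
    "sample_presences",
    "make_irrigation_mask",
]

#: plausible (low, high) magnitudes per emulated bioclim-style predictor
VARIABLE_RANGES = {
    "bio2": (4.0, 18.0),      # mean diurnal range, °C
    "bio4": (50.0, 1500.0),   # temperature seasonality, sd x100
    "bio8": (-10.0, 28.0),    # mean temperature of wettest quarter, °C
    "bio13": (10.0, 400.0),   # precipitation of wettest month, mm
    "bio15": (5.0, 120.0),    # precipitation seasonality, CV %
    "bio17": (0.0, 300.0),    # precipitation of driest quarter, mm
    "bio18": (0.0, 500.0),    # precipitation of warmest quarter, mm
    "bio19": (0.0, 600.0),    # precipitation of coldest quarter, mm
    "elev": (0.0, 2500.0),    # m
}


def make_predictor_rasters(lats, lons, seed: int = 0, smooth: float = 2.0,
                           variables: list[str] | None = None) -> xr.Dataset:
    """Seeded stack of smooth synthetic predictor rasters on a lat/lon lattice.

    Each variable is Gaussian-smoothed white noise (sd ``smooth`` cells),
    re-standardized and affinely mapped into its plausible range; ``smooth=0``
    gives plain white noise.  ``latitude`` equals the cell latitude exactly,
    and ``slope``/``aspect`` are derived from the synthetic elevation.
    """
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    rng = np.random.default_rng(seed)
    if variables is None:
        variables = list(VARIABLE_RANGES)
    shape = (lats.size, lons.size)
    data = {}
    for v in variables:
        lo, hi = VARIABLE_RANGES[v]
        f = rng.normal(0.0, 1.0, shape)
        if smooth > 0:
            f = gaussian_filter(f, smooth, mode="nearest")
            sd = f.std() or 1.0
            f = f / sd
        # map mean±2.5 sd onto the variable's plausible range (tails may spill over)
        f = (f + 2.5) / 5.0 * (hi - lo) + lo
        data[v] = (("lat", "lon"), f)
    data["latitude"] = (("lat", "lon"), np.broadcast_to(lats[:, None], shape).copy())
    if "elev" in variables:
        slope, aspect = derive_topography(data["elev"][1], lats, lons)
        data["slope"] = (("lat", "lon"), slope)
        data["aspect"] = (("lat", "lon"), aspect)
    return xr.Dataset(data, coords={"lat": lats, "lon": lons})


@dataclass
class TruthSurface:
    """Known logistic suitability surface: p = sigmoid(intercept + Σ c_v z_v)
    with z_v the standardized predictor fields."""

    coefficients: dict
    intercept: float = 0.0
    seed: int = 0

    def suitability(self, rasters: xr.Dataset) -> np.ndarray:
        eta = np.full(rasters[next(iter(self.coefficients))].shape, self.intercept, float)
        for v, c in self.coefficients.items():
            x = rasters[v].values.astype(float)
            sd = x.std() or 1.0
            eta = eta + c * (x - x.mean()) / sd
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700.0, 700.0)))


def sample_presences(truth: TruthSurface, rasters: xr.Dataset, n: int,
                     seed: int | None = None) -> pd.DataFrame:
    """Draw ``n`` presence cells (without replacement) with probability
    proportional to the truth surface; returns their cell-center (lon, lat)."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    p = truth.suitability(rasters).ravel()
    if p.sum() <= 0:
        raise ValueError("degenerate truth surface: zero total weight")
    if n > p.size:
        raise ValueError(f"cannot draw {n} cells from {p.size}")
    idx = rng.choice(p.size, size=n, replace=False, p=p / p.sum())
    i, j = np.unravel_index(idx, rasters[next(iter(truth.coefficients))].shape)
    return pd.DataFrame({"lon": rasters["lon"].values[j], "lat": rasters["lat"].values[i]})


def make_irrigation_mask(lats, lons, fraction: float, seed: int = 0) -> np.ndarray:
    """Seeded boolean mask with round(fraction x n_cells) cells set true."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    lats = np.asarray(lats)
    lons = np.asarray(lons)
    n = lats.size * lons.size
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    mask = np.zeros(n, bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask.reshape(lats.size, lons.size)
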