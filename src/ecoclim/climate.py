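"""Synthetic monthly climate grids and the weekly series the mechanistic engine runs on.

The mechanistic suitability engine consumes 52-week series of mean temperature,
rainfall and relative humidity at each grid cell.  Real applications would feed
it gridded monthly station climatologies; this module provides (a) a seeded
synthetic generator with a latitudinal temperature gradient, seasonal cycle and
configurable rainfall regime, (b) the monthly→weekly interpolation, (c) additive
warming / rainfall-scaling scenario transforms, and (d) NetCDF / long-CSV IO.

The year is modelled as 52 exact 7-day weeks (364 days); calendar months are
rescaled onto that year so that rainfall redistribution conserves the annual
total exactly.  Temperatures and humidity are interpolated linearly between
month midpoints with periodic wrap-around; the engine's humidity input is the
mean of the 09:00 and 15:00 observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "MonthlyClimate",
    "WeeklyClimate",
    "ClimateGrid",
    "SyntheticClimateSpec",
    "generate_climate_grid",
    "monthly_to_weekly",
    "apply_scenario",
    "read_climate",
    "write_climate",
]

CLIMATE_VARS = ("tmin", "tmax", "rain", "rh09", "rh15")

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)
#: month boundaries rescaled to the 364-day model year
_BOUNDS = np.concatenate([[0.0], np.cumsum(_MONTH_DAYS)]) * 364.0 / 365.0
_MIDS = 0.5 * (_BOUNDS[:-1] + _BOUNDS[1:])
_WEEK_MIDS = np.arange(52) * 7.0 + 3.5


def _overlap_matrix() -> np.ndarray:
    """52x12 matrix of week/month overlap fractions (rows sum to 1 within the year).

    W[w, m] is the fraction of month m's total that falls in week w, so
    ``weekly = W @ monthly`` conserves the annual sum exactly.
    """
    w_lo = np.arange(52)[:, None] * 7.0
    w_hi = w_lo + 7.0
    m_lo = _BOUNDS[None, :-1]
    m_hi = _BOUNDS[None, 1:]
    ov = np.clip(np.minimum(w_hi, m_hi) - np.maximum(w_lo, m_lo), 0.0, None)
    return ov / (m_hi - m_lo)


def _interp_matrix() -> np.ndarray:
    """52x12 matrix mapping monthly midpoint values to weekly midpoints (periodic linear)."""
    xp = np.concatenate([[_MIDS[-1] - 364.0], _MIDS, [_MIDS[0] + 364.0]])
    A = np.zeros((52, 12))
    for w, t in enumerate(_WEEK_MIDS):
        j = np.searchsorted(xp, t) - 1
        frac = (t - xp[j]) / (xp[j + 1] - xp[j])
        A[w, (j - 1) % 12] += 1.0 - frac
        A[w, j % 12] += frac
    return A


_W_RAIN = _overlap_matrix()
_A_INTERP = _interp_matrix()


@dataclass
class MonthlyClimate:
    """One cell's 12-month climatology.

    tmin/tmax in °C, rain in mm per month, rh09/rh15 in % relative humidity
    at 09:00 and 15:00.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray

    def __post_init__(self) -> None:
        for name in CLIMATE_VARS:
            setattr(self, name, np.asarray(getattr(self, name), float))

    def validate(self) -> None:
        for name in CLIMATE_VARS:
            a = getattr(self, name)
            if a.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values, got shape {a.shape}")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.tmin > self.tmax):
            raise ValueError("tmin exceeds tmax in at least one month")
        if np.any(self.rain < 0):
            raise ValueError("negative monthly rainfall")
        for name in ("rh09", "rh15"):
            a = getattr(self, name)
            if np.any((a < 0) | (a > 100)):
                raise ValueError(f"{name} outside [0, 100]")


@dataclass
class WeeklyClimate:
    """52-week series consumed by the mechanistic engine (tmean = midpoint of tmin/tmax)."""

    tmin: np.ndarray
    tmax: np.ndarray
    tmean: np.ndarray
    rain: np.ndarray
    rh: np.ndarray


@dataclass
class ClimateGrid:
    """Regular lat/lon grid of monthly climate, latitude ascending, cell-centered.

    Data arrays are shaped (12, nlat, nlon); ``mask`` flags valid (land) cells.
    """

    lats: np.ndarray
    lons: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray
    resolution: float
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, float)
        self.lons = np.asarray(self.lons, float)
        for name in CLIMATE_VARS:
            setattr(self, name, np.asarray(getattr(self, name), float))
        if self.mask is None:
            self.mask = np.ones((self.lats.size, self.lons.size), bool)
        else:
            self.mask = np.asarray(self.mask, bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lats.size, self.lons.size

    def cell(self, i: int, j: int) -> MonthlyClimate:
        return MonthlyClimate(*(getattr(self, v)[:, i, j] for v in CLIMATE_VARS))

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for coord, name in ((self.lats, "lats"), (self.lons, "lons")):
            if coord.size > 1:
                d = np.diff(coord)
                if np.any(d <= 0) or not np.allclose(d, d[0], atol=1e-6):
                    raise ValueError(f"{name} must be regular and ascending")
        shape = (12,) + self.shape
        for name in CLIMATE_VARS:
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")
        sub = self.mask
        if np.any(self.tmin[:, sub] > self.tmax[:, sub]):
            raise ValueError("tmin exceeds tmax on a valid cell")
        if np.any(self.rain[:, sub] < 0):
            raise ValueError("negative rainfall on a valid cell")

    def to_dataset(self) -> xr.Dataset:
        coords = {"month": np.arange(1, 13), "lat": self.lats, "lon": self.lons}
        data = {v: (("month", "lat", "lon"), getattr(self, v).astype(np.float32))
                for v in CLIMATE_VARS}
        data["mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["resolution"] = float(self.resolution)
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimateGrid":
        missing = [v for v in CLIMATE_VARS if v not in ds]
        if missing:
            raise ValueError(f"climate dataset missing variable(s): {', '.join(missing)}")
        if ds.sizes.get("month") != 12:
            raise ValueError(f"expected 12 months, got {ds.sizes.get('month')}")
        lats = ds["lat"].values.astype(float)
        lons = ds["lon"].values.astype(float)
        res = float(ds.attrs.get("resolution", lats[1] - lats[0] if lats.size > 1 else 1.0))
        mask = ds["mask"].values.astype(bool) if "mask" in ds else None
        grid = cls(lats, lons, *(ds[v].values.astype(float) for v in CLIMATE_VARS),
                   resolution=res, mask=mask)
        grid.validate()
        return grid


@dataclass
class SyntheticClimateSpec:
    """Controls for the synthetic climate generator.

    Annual-mean temperature falls off linearly with |latitude| at ``lapse_c_per_deg``
    from ``equator_mean_c``; the seasonal cycle has the given amplitude with its
    phase flipped between hemispheres (warm peak in July north, January south).
    ``rain_regime`` is one of uniform / winter-wet / summer-wet with the stated
    annual total.  Identical seeds give bit-identical grids.
    """

    lat_min: float = -60.0
    lat_max: float = 60.0
    lon_min: float = 0.0
    lon_max: float = 20.0
    resolution: float = 2.0
    equator_mean_c: float = 27.0
    lapse_c_per_deg: float = 0.6
    seasonal_amplitude_c: float = 8.0
    diurnal_range_c: float = 8.0
    rain_regime: str = "uniform"
    annual_rain_mm: float = 1000.0
    rh_baseline: float = 60.0
    seed: int = 0
    noise_sd: float = 0.0


def generate_climate_grid(spec: SyntheticClimateSpec) -> ClimateGrid:
    """Generate a deterministic synthetic monthly climate grid from ``spec``."""
    if spec.resolution <= 0:
        raise ValueError("resolution must be positive")
    res = spec.resolution
    lats = np.arange(spec.lat_min + res / 2.0, spec.lat_max, res)
    lons = np.arange(spec.lon_min + res / 2.0, spec.lon_max, res)
    if lats.size == 0:
        raise ValueError("empty latitude range")
    if lons.size == 0:
        raise ValueError("empty longitude range")
    if spec.rain_regime not in ("uniform", "winter-wet", "summer-wet"):
        raise ValueError(f"unknown rain regime {spec.rain_regime!r}")

    rng = np.random.default_rng(spec.seed)
    nlat, nlon = lats.size, lons.size
    m_frac = (np.arange(12) + 0.5) / 12.0
    # northern-hemisphere seasonal shape: minimum in January, maximum in July
    season = -np.cos(2.0 * np.pi * m_frac)
    hemi = np.where(lats >= 0, 1.0, -1.0)

    annual_mean = spec.equator_mean_c - spec.lapse_c_per_deg * np.abs(lats)
    tmean = (annual_mean[None, :, None]
             + spec.seasonal_amplitude_c * season[:, None, None] * hemi[None, :, None]
             + np.zeros((12, nlat, nlon)))
    if spec.noise_sd > 0:
        tmean = tmean + rng.normal(0.0, spec.noise_sd, tmean.shape)
    half = spec.diurnal_range_c / 2.0
    tmin, tmax = tmean - half, tmean + half

    # month weight ∝ days × seasonal factor, normalized to the annual total
    if spec.rain_regime == "uniform":
        shape = np.ones((12, nlat))
    else:
        winter = 1.0 + np.cos(2.0 * np.pi * m_frac)  # peaks in January (north)
        summer = 2.0 - winter
        north = winter if spec.rain_regime == "winter-wet" else summer
        south = 2.0 - north
        shape = np.where(hemi[None, :] > 0, north[:, None], south[:, None])
    w = shape * _MONTH_DAYS[:, None]
    w = w / w.sum(axis=0, keepdims=True)
    rain = np.repeat((spec.annual_rain_mm * w)[:, :, None], nlon, axis=2)
    if spec.noise_sd > 0:
        rain = np.clip(rain * (1.0 + rng.normal(0.0, 0.02 * spec.noise_sd, rain.shape)), 0.0, None)

    rh09 = np.full((12, nlat, nlon), spec.rh_baseline + 5.0)
    rh15 = np.full((12, nlat, nlon), spec.rh_baseline - 5.0)
    if spec.noise_sd > 0:
        rh09 = rh09 + rng.normal(0.0, spec.noise_sd, rh09.shape)
        rh15 = rh15 + rng.normal(0.0, spec.noise_sd, rh15.shape)
    rh09 = np.clip(rh09, 0.0, 100.0)
    rh15 = np.clip(rh15, 0.0, 100.0)

    grid = ClimateGrid(lats, lons, tmin, tmax, rain, rh09, rh15, resolution=res)
    grid.validate()
    return grid


def monthly_to_weekly(mc: MonthlyClimate) -> WeeklyClimate:
    """Interpolate a 12-month record to the engine's 52-week series.

    Temperatures and humidity are interpolated linearly between month midpoints
    (periodic); monthly rain is split among weeks by day overlap, conserving the
    annual total.
    """
    mc.validate()
    tmin = _A_INTERP @ mc.tmin
    tmax = _A_INTERP @ mc.tmax
    rain = _W_RAIN @ mc.rain
    rh = np.clip(_A_INTERP @ (0.5 * (mc.rh09 + mc.rh15)), 0.0, 100.0)
    return WeeklyClimate(tmin, tmax, 0.5 * (tmin + tmax), rain, rh)


def weekly_fields(grid: ClimateGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized monthly→weekly transform for a whole grid.

    Returns (tmean, rain, rh) each shaped (52, nlat, nlon); identical cell-wise
    to :func:`monthly_to_weekly`.
    """
    flat = lambda a: a.reshape(12, -1)
    tmean_m = 0.5 * (grid.tmin + grid.tmax)
    tmean = (_A_INTERP @ flat(tmean_m)).reshape((52,) + grid.shape)
    rain = (_W_RAIN @ flat(grid.rain)).reshape((52,) + grid.shape)
    rh_m = 0.5 * (grid.rh09 + grid.rh15)
    rh = np.clip((_A_INTERP @ flat(rh_m)).reshape((52,) + grid.shape), 0.0, 100.0)
    return tmean, rain, rh


def apply_scenario(grid: ClimateGrid, delta_t: float, rain_factor: float) -> ClimateGrid:
    """Shift temperatures by ``delta_t`` °C and scale rainfall; humidity unchanged."""
    if rain_factor < 0:
        raise ValueError("rain_factor must be non-negative")
    out = replace(
        grid,
        tmin=grid.tmin + delta_t,
        tmax=grid.tmax + delta_t,
        rain=grid.rain * rain_factor,
        rh09=grid.rh09.copy(),
        rh15=grid.rh15.copy(),
        mask=grid.mask.copy(),
    )
    out.validate()
    return out


def write_climate(grid: ClimateGrid, path: str | Path, format: str = "netcdf") -> None:
    """Write a grid as CF-style NetCDF (float32) or long CSV (lat,lon,month,var,value)."""
    path = Path(path)
    if format == "netcdf":
        grid.to_dataset().to_netcdf(path, engine="scipy")
    elif format == "csv":
        frames = []
        for v in CLIMATE_VARS:
            arr = getattr(grid, v)
            month, lat, lon = np.meshgrid(np.arange(1, 13), grid.lats, grid.lons, indexing="ij")
            frames.append(pd.DataFrame({
                "lat": lat.ravel(), "lon": lon.ravel(), "month": month.ravel(),
                "var": v, "value": arr.ravel().astype(np.float32),
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown climate format {format!r}")


def read_climate(path: str | Path, format: str = "netcdf") -> ClimateGrid:
    """Read a grid written by :func:`write_climate`."""
    path = Path(path)
    if format == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            return ClimateGrid.from_dataset(ds.load())
    if format != "csv":
        raise ValueError(f"unknown climate format {format!r}")
    df = pd.read_csv(path)
    need = {"lat", "lon", "month", "var", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"climate CSV missing column(s): {', '.join(sorted(need - set(df.columns)))}")
    missing = [v for v in CLIMATE_VARS if v not in set(df["var"])]
    if missing:
        raise ValueError(f"climate CSV missing variable(s): {', '.join(missing)}")
    months = np.sort(df["month"].unique())
    if months.size != 12:
        raise ValueError(f"expected 12 months, got {months.size}")
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    arrays = {}
    for v in CLIMATE_VARS:
        sub = df[df["var"] == v].pivot_table(index=["month", "lat"], columns="lon", values="value")
        arrays[v] = sub.values.reshape(12, lats.size, lons.size)
    res = float(lats[1] - lats[0]) if lats.size > 1 else float(lons[1] - lons[0])
    grid = ClimateGrid(lats, lons, *(arrays[v] for v in CLIMATE_VARS), resolution=res)
    grid.validate()
    return grid
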