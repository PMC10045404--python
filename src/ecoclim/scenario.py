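"""Scenario accounting over suitability grids.

Latitude-corrected suitable areas (spherical-zone cell areas), percent change
between scenarios, multi-model ensemble means, occurrence-coverage validation
and cumulative variable-importance summaries.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .ecoclimatic import SuitabilityGrid

__all__ = [
    "EARTH_RADIUS_KM",
    "AreaReport",
    "cell_area",
    "suitable_area",
    "area_change",
    "occurrence_coverage",
    "ensemble_mean",
    "cumulative_importance",
    "build_report",
]

EARTH_RADIUS_KM = 6371.0088


def cell_area(lat_center, resolution: float, lon_resolution: float | None = None):
    """Area (km²) of a cell centered at ``lat_center`` on a regular grid.

    Spherical zone formula: R² Δλ (sin(lat+Δφ/2) − sin(lat−Δφ/2)).
    """
    if lon_resolution is None:
        lon_resolution = resolution
    lat = np.radians(np.asarray(lat_center, float))
    half = np.radians(resolution) / 2.0
    area = (EARTH_RADIUS_KM ** 2 * np.radians(lon_resolution)
            * (np.sin(lat + half) - np.sin(lat - half)))
    return area if area.ndim else float(area)


def suitable_area(grid: SuitabilityGrid, threshold: float) -> float:
    """Total km² of valid cells with suitability >= threshold."""
    areas = cell_area(grid.lats, grid.resolution)[:, None]
    hit = grid.mask & (np.where(np.isfinite(grid.values), grid.values, -np.inf) >= threshold)
    return float((areas * hit).sum())


def area_change(current_km2: float, future_km2: float) -> float:
    """Percent change of suitable area, 100 x (future - current) / current."""
    if current_km2 == 0:
        raise ValueError("current area is zero; percent change undefined")
    return 100.0 * (future_km2 - current_km2) / current_km2


def occurrence_coverage(grid: SuitabilityGrid, occurrences: pd.DataFrame,
                        threshold: float) -> tuple[float, int, int]:
    """Share of occurrence points falling in suitable cells.

    Points snap to the nearest cell center (ties toward the lower index).
    Returns (percent to 2 decimals, n_inside, n_total).
    """
    if occurrences.empty:
        raise ValueError("empty occurrence set: coverage undefined")
    i = np.abs(occurrences["lat"].values[:, None] - grid.lats[None, :]).argmin(axis=1)
    j = np.abs(occurrences["lon"].values[:, None] - grid.lons[None, :]).argmin(axis=1)
    vals = grid.values[i, j]
    inside = int(((vals >= threshold) & grid.mask[i, j] & np.isfinite(vals)).sum())
    total = len(occurrences)
    return round(100.0 * inside / total, 2), inside, total


def ensemble_mean(grids: list):
    """Cell-wise mean of grids on identical lattices (NaN-propagating on masks).

    Works for SuitabilityGrid and for ClimateGrid-like objects exposing the
    five monthly climate fields.
    """
    if not grids:
        raise ValueError("empty ensemble")
    first = grids[0]
    if isinstance(first, SuitabilityGrid):
        for g in grids[1:]:
            if g.kind != first.kind or g.values.shape != first.values.shape:
                raise ValueError("ensemble members must share lattice and kind")
            if not (np.array_equal(g.lats, first.lats) and np.array_equal(g.lons, first.lons)):
                raise ValueError("ensemble members must share coordinates")
        stack = np.stack([g.values for g in grids])
        mask = np.logical_and.reduce([g.mask for g in grids])
        return SuitabilityGrid(first.lats, first.lons, stack.mean(axis=0),
                               kind=first.kind, mask=mask,
                               scenario={"label": "ensemble-mean", "n_members": len(grids)})
    from dataclasses import replace
    from .climate import CLIMATE_VARS
    for g in grids[1:]:
        if not (np.array_equal(g.lats, first.lats) and np.array_equal(g.lons, first.lons)):
            raise ValueError("ensemble members must share coordinates")
    fields = {v: np.mean([getattr(g, v) for g in grids], axis=0) for v in CLIMATE_VARS}
    mask = np.logical_and.reduce([g.mask for g in grids])
    return replace(first, mask=mask, **fields)


def cumulative_importance(table: pd.DataFrame, column: str, k: int = 6,
                          by: str | None = None) -> float:
    """Cumulative importance of the k most influential predictors.

    Ranks rows by ``by`` (default: ``column`` itself) and sums ``column`` over
    the top k — e.g. the permutation importance accounted for by the k
    largest-contribution variables.
    """
    ranked = table.sort_values(by or column, ascending=False).head(k)
    return float(ranked[column].astype(float).sum())


@dataclass
class AreaReport:
    """Suitable-area accounting for one scenario against a reference."""

    label: str
    threshold: float
    suitable_km2: float
    percent_change_vs_reference: float | None = None
    class_areas_km2: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def build_report(current: SuitabilityGrid, futures: list, threshold: float,
                 occurrences: pd.DataFrame | None = None,
                 bands: dict | None = None) -> dict:
    """Area + coverage report across scenarios, as a JSON-ready dict."""
    from .ecoclimatic import classify_suitability

    def class_areas(g):
        if bands is None:
            return {}
        labels = classify_suitability(g.values, bands=bands)
        areas = cell_area(g.lats, g.resolution)[:, None] * g.mask
        return {name: float(areas[(labels == name) & g.mask].sum()) for name in bands}

    cur_area = suitable_area(current, threshold)
    report = {
        "threshold": threshold,
        "current": AreaReport(current.scenario.get("label", "current"), threshold,
                              cur_area, None, class_areas(current)).to_dict(),
        "futures": [],
    }
    for g in futures:
        fut_area = suitable_area(g, threshold)
        report["futures"].append(AreaReport(
            g.scenario.get("label", "future"), threshold, fut_area,
            area_change(cur_area, fut_area) if cur_area else None,
            class_areas(g)).to_dict())
    if occurrences is not None and not occurrences.empty:
        pct, inside, total = occurrence_coverage(current, occurrences, threshold)
        report["occurrence_coverage"] = {"percent": pct, "inside": inside, "total": total}
    return report
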