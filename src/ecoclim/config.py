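"""Layered run configuration with stable seed fan-out and provenance hashing."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "derive_seed", "config_hash"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed (< 2^31) derived from the global seed and stage name."""
    return (int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully serializable for provenance.

    The synthetic-world block feeds the climate generator; ``scenarios`` are
    (label, delta_t, rain_factor) transforms applied to the current climate.
    """

    seed: int = 42
    climate: dict = field(default_factory=lambda: {
        "lat_min": 24.0, "lat_max": 72.0, "lon_min": 0.0, "lon_max": 40.0,
        "resolution": 2.0, "equator_mean_c": 27.0, "lapse_c_per_deg": 0.6,
        "seasonal_amplitude_c": 8.0, "diurnal_range_c": 8.0,
        "rain_regime": "winter-wet", "annual_rain_mm": 800.0,
        "rh_baseline": 70.0, "noise_sd": 0.3,
    })
    scenarios: list = field(default_factory=lambda: [
        {"label": "ssp126-like", "delta_t": 2.0, "rain_factor": 1.0},
        {"label": "ssp585-like", "delta_t": 5.0, "rain_factor": 1.0},
    ])
    species_params: str | None = None  # packaged raisin-moth file when None
    irrigation_fraction: float = 0.25
    soil: dict = field(default_factory=lambda: {
        "capacity": 100.0, "sm_cap": 3.0, "c_et": 0.8})
    irrigation: dict = field(default_factory=lambda: {
        "threshold_mm": 10.5, "daily_cap_mm": 1.5})
    ei_min: float = 10.0
    sdm: dict = field(default_factory=lambda: {
        "n_presence": 150, "n_background": 2000, "n_hinge_knots": 8,
        "predictors": ["bio4", "bio8", "bio19", "elev", "latitude", "bio15"],
        "truth": {"bio4": -1.5, "bio8": -1.0, "bio19": -1.0, "elev": -0.5},
        "rm_values": None, "feature_sets": None,  # None -> full default grid
    })

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown configuration key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                merged = {**getattr(cfg, key), **value}
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())
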