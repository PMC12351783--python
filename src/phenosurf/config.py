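"""Analysis configuration.

One flat dataclass holds every fixed constant of the pipeline, mirrored 1:1
by the YAML config file.  Defaults encode the study's published rules
(0 deg C thresholds, 2-week cumulative window, 50 % snow cover, 5-km buffers,
strict >2-day stopovers, day-of-year 30-240 phenology window, VIF < 10,
2,000 posterior draws); everything else is an explicit package choice
documented in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # thresholding
    zero_threshold: float = 0.0          # deg C crossing level
    cum_window: int = 14                 # trailing window (days) for Tcum
    snow_threshold: float = 0.5          # snow-cover fraction
    ndvi_amplitude_threshold: float = 0.5  # SOS/EOS level as fraction of amplitude
    autumn_start_doy: int = 183          # autumn crossings searched from here

    # buffers and spatial rules
    buffer_radius_km: float = 5.0
    residency_radius_km: float = 30.0    # run clustering radius for residency
    isotherm_boundary_lat: float = 33.0  # January 0-degree isotherm (Qinling-Huai)
    moult_min_km: float = 100.0          # summer relocation => moult migration
    masked_landcover: tuple = (0, 2, 13)  # water, forest, urban class codes

    # segmentation
    stopover_min_days: float = 2.0       # strict: duration must exceed this
    min_fixes_per_day: float = 2.0
    max_fixes_per_day: float = 288.0
    fix_rate_policy: str = "record_mean"  # record-level mean daily fix count

    # QC windows
    doy_min: int = 30
    doy_max: int = 240
    ndvi_min_annual_mean: float = 0.1
    lst_max_error: float = 2.0           # deg C; pixels at/above are dropped

    # NDVI season fitting
    whittaker_lambda: float = 2.0   # on the 16-day composite grid
    whittaker_order: int = 2
    buffer_pheno_agg: str = "median"     # aggregation of pixel dates in buffer
    snow_spring_rule: str = "after_max"  # or "from_year_start"

    # probability records
    approach_window_days: int = 10       # y=0 days preceding a spring arrival

    # statistics
    vif_limit: float = 10.0
    n_posterior_draws: int = 2000
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.doy_min >= self.doy_max:
            raise ValueError("doy_min must be < doy_max")
        for name in ("cum_window", "buffer_radius_km", "stopover_min_days",
                     "snow_threshold", "vif_limit", "n_posterior_draws"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "masked_landcover" in raw:
            raw["masked_landcover"] = tuple(raw["masked_landcover"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["masked_landcover"] = list(d["masked_landcover"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
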