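"""Shared domain types.

The analysis revolves around a small set of containers:

* :class:`Fix` / :class:`Track` — timestamped GPS positions of a tagged bird.
* :class:`EnvGrid` — one environmental variable on a (time, lat, lon) lattice.
* :class:`StationarySite` / :class:`MigrationEvent` — output of track
  segmentation: residency runs and the migration events they delimit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column or attribute is missing from an input file."""


class EmptyInputError(ValueError):
    """An input file contained no usable rows."""


class FormatError(ValueError):
    """An input file violates a structural requirement (axes, units...)."""


# Environmental variables on grids.
GRID_VARIABLES = ("LST_avg", "LST_night", "T_air", "NDVI", "snow_fraction", "landcover")

# The nine node-level onset metrics (SOS/Greenup are spring-side, EOS/Dormancy
# autumn-side readings of the same vegetation season).
METRICS_SPRING = ("LSTa", "LSTn", "Ta", "Tcum", "SOS", "Greenup", "Snow")
METRICS_AUTUMN = ("LSTa", "LSTn", "Ta", "Tcum", "EOS", "Dormancy", "Snow")
ALL_METRICS = ("LSTa", "LSTn", "Ta", "Tcum", "SOS", "EOS", "Greenup", "Dormancy", "Snow")


@dataclass(frozen=True)
class Fix:
    individual_id: str
    timestamp: pd.Timestamp
    lon: float
    lat: float

    def __post_init__(self):
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")


@dataclass
class Track:
    """All fixes of one tagged individual, time-sorted.

    ``species`` is a free label (``SG`` Swan Goose, ``GG`` Greylag Goose in
    the study system); ``group`` labels the geographic breeding group
    (W1/W2/C/E convention).
    """

    individual_id: str
    species: str
    group: str
    fixes: list[Fix] = field(default_factory=list)

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise ValueError("a track needs at least 2 fixes")
        for f in self.fixes:
            if f.individual_id != self.individual_id:
                raise ValueError("all fixes must share the track's individual_id")

    def __len__(self) -> int:
        return len(self.fixes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual_id": self.individual_id,
            "species": self.species,
            "group": self.group,
            "timestamp": [f.timestamp for f in self.fixes],
            "lon": [f.lon for f in self.fixes],
            "lat": [f.lat for f in self.fixes],
        })

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([f.timestamp for f in self.fixes])

    @property
    def lons(self) -> np.ndarray:
        return np.array([f.lon for f in self.fixes])

    @property
    def lats(self) -> np.ndarray:
        return np.array([f.lat for f in self.fixes])


@dataclass
class EnvGrid:
    """One environmental variable on a (time, lat, lon) lattice.

    ``times`` are composite-period start dates (``datetime64[D]``); daily
    products simply have daily spacing.  ``quality`` optionally carries a
    same-shaped per-pixel quality value (e.g. LST retrieval error in deg C).
    The static land-cover class map is stored with a single time step.
    """

    variable: str
    times: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray
    quality: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[D]")
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.times), len(self.lats), len(self.lons)):
            raise FormatError("values shape must be (time, lat, lon)")
        for name, ax in (("times", self.times.astype("int64")),
                         ("lats", self.lats), ("lons", self.lons)):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise FormatError(f"{name} axis must be strictly increasing")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape != self.values.shape:
                raise FormatError("quality must match values shape")
        if self.variable == "snow_fraction":
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() < 0.0 or v.max() > 1.0):
                raise FormatError("snow_fraction values must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Indices of the grid cell whose center is closest in lat/lon."""
        return (int(np.argmin(np.abs(self.lats - lat))),
                int(np.argmin(np.abs(self.lons - lon))))

    def series_at(self, lon: float, lat: float) -> np.ndarray:
        i, j = self.nearest_cell(lon, lat)
        return self.values[:, i, j]

    def years(self) -> np.ndarray:
        return np.unique(self.times.astype("datetime64[Y]").astype(int) + 1970)


@dataclass
class StationarySite:
    """A residency run: consecutive fixes within a radius of their centroid."""

    site_id: str
    lon: float
    lat: float
    first_date: pd.Timestamp
    last_date: pd.Timestamp
    n_fixes: int
    role: str = "brief_stop"  # wintering|breeding|moulting|stopover|brief_stop

    @property
    def duration_days(self) -> float:
        return (self.last_date - self.first_date) / pd.Timedelta(days=1)


@dataclass
class MigrationEvent:
    """One spring or autumn migration of one individual.

    ``nodes`` runs origin, stopovers..., destination.  Incomplete events
    (transmitter lost mid-migration) have ``complete=False`` and no
    arrival date / destination node.
    """

    individual_id: str
    species: str
    group: str
    season: str  # spring | autumn
    year: int
    departure_date: Optional[pd.Timestamp]
    arrival_date: Optional[pd.Timestamp]
    complete: bool
    nodes: list[StationarySite] = field(default_factory=list)
    mean_daily_fixes: float = float("nan")

    @property
    def duration_days(self) -> Optional[float]:
        if self.departure_date is None or self.arrival_date is None:
            return None
        return (self.arrival_date - self.departure_date) / pd.Timedelta(days=1)

    @property
    def n_stopovers(self) -> int:
        return sum(1 for s in self.nodes if s.role == "stopover")


def doy(ts) -> float:
    """1-based day of year, fractional if the timestamp has a time of day."""
    ts = pd.Timestamp(ts)
    start = pd.Timestamp(year=ts.year, month=1, day=1, tz=ts.tz)
    return 1.0 + (ts - start) / pd.Timedelta(days=1)
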