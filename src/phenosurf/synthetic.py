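"""Synthetic world: environment grids and agent geese with known ground truth.

The study's tracking data are not public, so every downstream stage is
exercised against a simulated world whose onset dates are known in closed
form.  The world is a lat/lon lattice over a migration corridor with:

* a **temperature wave**: daily temperature
  ``T(lat, d) = M(lat) - A cos(2*pi*(d - phi0)/365)`` with the latitudinal
  mean ``M`` chosen so the spring 0 deg C upcrossing falls exactly on
  ``a0 + b*(lat - lat_ref)`` — a south-to-north wave advancing ``1/b``
  degrees per day — and the autumn downcrossing correspondingly earlier in
  the north;
* **vegetation seasons** (double-logistic NDVI) that are either latitudinally
  graded (a classic green wave) or near-synchronous along the corridor, the
  regime reported for the Mongolian Plateau flyway;
* **snow cover** that is a logistic function of the local temperature, so
  the 50 % melt/onset dates track the temperature wave; in ``patchy`` mode a
  fraction of cells never reach 50 % cover and in ``absent`` mode none do;
* a static **land-cover** map with water/forest patches (masked for
  foraging-buffer extraction).

Agent geese winter in the south, climb the corridor through a fixed number
of stopovers, and time their movements either by a *cue + lag* rule (depart
a node at the node's metric onset plus a lagged offset, scaled by a
surfing slope) or by a daily logistic *hazard* on days-since-onset
covariates.  Both modes emit GPS fixes at a configurable rate and a ground
truth table of true node dates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import AnalysisConfig
from .geo import haversine_km
from .io import write_env_grid, write_tracks
from .types import EnvGrid, Fix, Track

DAYS_PER_YEAR = 365.0

_VAR_SEED_OFFSET = {"T_air": 11, "LST_avg": 12, "LST_night": 13,
                    "NDVI": 14, "snow_fraction": 15, "landcover": 16}


@dataclass
class WorldSpec:
    """Parameters of the synthetic environment.

    ``temp_onset_intercept`` is the spring 0 deg C upcrossing day-of-year at
    ``lat_ref``; ``temp_onset_slope`` is the wave speed in days per degree
    latitude (2 d/deg means the 0 deg C line moves north at 0.5 deg/day).
    """

    lat_range: tuple = (30.0, 50.0)
    lon_range: tuple = (100.0, 112.0)
    n_lat: int = 40
    n_lon: int = 24
    years: tuple = (2021,)
    lat_ref: float = 40.0
    temp_onset_intercept: float = 80.0   # DOY at lat_ref
    temp_onset_slope: float = 2.0        # days per degree latitude
    temp_amplitude: float = 20.0         # deg C seasonal half-range
    temp_noise_sd: float = 1.0           # deg C daily noise
    lstn_offset: float = -6.0            # nighttime LST below daily average
    ndvi_mode: str = "synchronous"       # or "graded"
    ndvi_sos_doy: float = 130.0          # 50%-amplitude green-up DOY at lat_ref
    ndvi_sos_slope: float = 2.0          # d/deg, used only in graded mode
    ndvi_eos_doy: float = 270.0
    ndvi_amplitude: float = 0.5
    ndvi_baseline: float = 0.15
    ndvi_rise_tau: float = 8.0
    ndvi_fall_tau: float = 10.0
    ndvi_noise_sd: float = 0.02
    snow_mode: str = "patchy"            # persistent | patchy | absent
    snow_max_cover: float = 0.95
    snow_t_half: float = 1.0             # deg C at which cover halves
    snow_temp_width: float = 2.0         # deg C logistic width
    snow_covered_fraction: float = 0.72  # patchy: share of cells with snowpack
    landcover_water_fraction: float = 0.10
    landcover_forest_fraction: float = 0.05

    def __post_init__(self):
        if self.temp_onset_slope < 0:
            raise ValueError("temp_onset_slope must be >= 0")
        if self.n_lat < 2 or self.n_lon < 2:
            raise ValueError("n_lat and n_lon must be >= 2")
        if self.temp_amplitude <= 0:
            raise ValueError("temp_amplitude must be positive")

    # --- closed-form environment -----------------------------------------
    @property
    def phi0(self) -> float:
        return self.temp_onset_intercept - DAYS_PER_YEAR / 4.0

    def temp_mean(self, lat):
        """Annual-mean temperature; decreases with latitude so the autumn
        downcrossing moves south while the spring upcrossing moves north."""
        d = np.asarray(lat, dtype=float) - self.lat_ref
        return -self.temp_amplitude * np.sin(2.0 * np.pi * self.temp_onset_slope * d
                                             / DAYS_PER_YEAR)

    def temp_noiseless(self, lat, doy):
        doy = np.asarray(doy, dtype=float)
        return (self.temp_mean(lat)
                - self.temp_amplitude * np.cos(2.0 * np.pi * (doy - self.phi0)
                                               / DAYS_PER_YEAR))

    def _temp_crossing(self, lat, level, season):
        c = (self.temp_mean(lat) - level) / self.temp_amplitude
        if abs(c) > 1.0:
            return None
        theta = np.arccos(c) * DAYS_PER_YEAR / (2.0 * np.pi)
        if season == "spring":
            return self.phi0 + theta
        return self.phi0 + DAYS_PER_YEAR - theta

    def sos_doy(self, lat):
        d = np.asarray(lat, dtype=float) - self.lat_ref
        slope = self.ndvi_sos_slope if self.ndvi_mode == "graded" else 0.0
        return self.ndvi_sos_doy + slope * d

    def eos_doy(self, lat):
        d = np.asarray(lat, dtype=float) - self.lat_ref
        slope = self.ndvi_sos_slope if self.ndvi_mode == "graded" else 0.0
        return self.ndvi_eos_doy - slope * d

    def ndvi_noiseless(self, lat, doy):
        doy = np.asarray(doy, dtype=float)
        rise = expit((doy - self.sos_doy(lat)) / self.ndvi_rise_tau)
        fall = expit((self.eos_doy(lat) - doy) / self.ndvi_fall_tau)
        return self.ndvi_baseline + self.ndvi_amplitude * (rise + fall - 1.0)

    def snow_level_temp(self) -> Optional[float]:
        """Temperature at which snow cover crosses the 0.5 fraction."""
        if self.snow_mode == "absent" or self.snow_max_cover <= 0.5:
            return None
        frac = 0.5 / self.snow_max_cover
        return self.snow_t_half - self.snow_temp_width * logit(frac)

    def true_onset(self, metric: str, lat: float, season: str) -> Optional[float]:
        """Closed-form (noiseless) onset DOY of a metric at a latitude.

        Spring metrics are upcrossings / green-up dates; autumn metrics are
        downcrossings / senescence dates.  Returns None where the metric has
        no crossing (e.g. snow in absent mode).
        """
        if metric in ("LSTa", "Ta"):
            return self._temp_crossing(lat, 0.0, season)
        if metric == "LSTn":
            return self._temp_crossing(lat, -self.lstn_offset, season)
        if metric == "Tcum":
            return self._tcum_onset(lat, season)
        if metric in ("SOS", "Greenup"):
            return float(self.sos_doy(lat))
        if metric in ("EOS", "Dormancy"):
            return float(self.eos_doy(lat))
        if metric == "Snow":
            level = self.snow_level_temp()
            if level is None:
                return None
            return self._temp_crossing(lat, level, season)
        raise ValueError(f"unknown metric {metric!r}")

    def _tcum_onset(self, lat, season, window: int = 14):
        days = np.arange(1, 366, dtype=float)
        t = self.temp_noiseless(lat, days)
        csum = np.cumsum(t)
        trailing = csum[window - 1:] - np.concatenate([[0.0], csum[:-window]])
        doys = days[window - 1:]
        if season == "spring":
            hit = np.nonzero(trailing > 0.0)[0]
        else:
            mask = doys >= 183
            hit = np.nonzero(mask & (trailing < 0.0))[0]
        return float(doys[hit[0]]) if hit.size else None


def _year_days(year: int) -> np.ndarray:
    return np.arange(np.datetime64(f"{year}-01-01"),
                     np.datetime64(f"{year + 1}-01-01"))


def _composite(dates: np.ndarray, values: np.ndarray, period: int):
    """Average daily values into fixed-length periods restarting each year."""
    n = len(dates)
    starts = np.arange(0, n, period)
    out_dates = dates[starts]
    out = np.add.reduceat(values, starts, axis=0)
    counts = np.diff(np.append(starts, n)).astype(float)
    out = out / counts[(slice(None),) + (None,) * (values.ndim - 1)]
    return out_dates, out


def generate_env_grid(world: WorldSpec, variable: str, seed: int) -> EnvGrid:
    """Generate one environmental grid for all years of the world spec."""
    if variable not in _VAR_SEED_OFFSET:
        raise ValueError(f"unsupported variable {variable!r}")
    rng = np.random.default_rng([int(seed) % (2 ** 31), _VAR_SEED_OFFSET[variable]])
    lats = np.linspace(world.lat_range[0], world.lat_range[1], world.n_lat)
    lons = np.linspace(world.lon_range[0], world.lon_range[1], world.n_lon)

    if variable == "landcover":
        classes = np.ones((1, world.n_lat, world.n_lon))
        u = rng.random((world.n_lat, world.n_lon))
        classes[0][u < world.landcover_water_fraction] = 0.0
        classes[0][(u >= world.landcover_water_fraction)
                   & (u < world.landcover_water_fraction
                      + world.landcover_forest_fraction)] = 2.0
        return EnvGrid("landcover", np.array([f"{world.years[0]}-01-01"],
                                             dtype="datetime64[D]"),
                       lats, lons, classes)

    all_dates, all_values, all_quality = [], [], []
    # per-cell snowpack indicator is identical across years
    snow_cell = rng.random((world.n_lat, world.n_lon))
    for year in world.years:
        dates = _year_days(year)
        doys = np.arange(1, len(dates) + 1, dtype=float)
        # broadcast (time, lat) -> (time, lat, lon)
        base = world.temp_noiseless(lats[None, :, None], doys[:, None, None])
        base = np.broadcast_to(base, (len(doys), world.n_lat, world.n_lon)).copy()

        if variable == "T_air":
            vals = base + rng.normal(0.0, world.temp_noise_sd, base.shape)
            all_dates.append(dates)
            all_values.append(vals)
        elif variable in ("LST_avg", "LST_night"):
            off = 0.0 if variable == "LST_avg" else world.lstn_offset
            daily = base + off + rng.normal(0.0, world.temp_noise_sd, base.shape)
            cd, cv = _composite(dates, daily, 8)
            q = np.abs(rng.normal(0.8, 0.5, cv.shape))
            all_dates.append(cd)
            all_values.append(cv)
            all_quality.append(q)
        elif variable == "NDVI":
            curve = world.ndvi_noiseless(lats[None, :, None], doys[:, None, None])
            curve = np.broadcast_to(curve, base.shape).copy()
            curve += rng.normal(0.0, world.ndvi_noise_sd, curve.shape)
            cd, cv = _composite(dates, np.clip(curve, -1.0, 1.0), 16)
            all_dates.append(cd)
            all_values.append(cv)
        elif variable == "snow_fraction":
            cover = world.snow_max_cover * expit(
                (world.snow_t_half - base) / world.snow_temp_width)
            if world.snow_mode == "absent":
                cover = cover * (0.45 / world.snow_max_cover)
            elif world.snow_mode == "patchy":
                bare = snow_cell >= world.snow_covered_fraction
                cover[:, bare] *= 0.45 / world.snow_max_cover
            cover += rng.normal(0.0, 0.01, cover.shape)
            cd, cv = _composite(dates, np.clip(cover, 0.0, 1.0), 8)
            all_dates.append(cd)
            all_values.append(cv)
    times = np.concatenate(all_dates)
    values = np.concatenate(all_values, axis=0)
    quality = np.concatenate(all_quality, axis=0) if all_quality else None
    return EnvGrid(variable, times, lats, lons, values, quality)


def generate_grids(world: WorldSpec, seed: int) -> dict[str, EnvGrid]:
    return {v: generate_env_grid(world, v, seed) for v in _VAR_SEED_OFFSET}


@dataclass
class AgentSpec:
    """Behavioural parameters of a cohort of simulated geese.

    ``timing_mode`` selects between deterministic *cue + lag* scheduling
    (node date = local cue onset + lag, scaled by ``surf_slope``) and a daily
    logistic *hazard* whose linear predictor is built from days-since-onset
    covariates (``spring_hazard`` / ``autumn_hazard`` map metric names to
    coefficients, with an ``intercept`` entry).  ``cue="none"`` departs on a
    fixed calendar schedule regardless of the environment.
    """

    n_individuals: int = 20
    species: str = "SG"
    group: str = "E"
    timing_mode: str = "cue_lag"         # cue_lag | hazard
    cue: str = "LSTa"                    # LSTa | Ta | Tcum | SOS | none
    cue_lag_mean: float = 5.0
    cue_lag_sd: float = 3.0
    autumn_cue: str = "LSTn"
    autumn_lag_mean: float = -5.0
    autumn_lag_sd: float = 3.0
    surf_slope: float = 1.0
    n_stopovers: int = 2
    stopover_stay: float = 6.0           # days; calendar spacing for cue=none
    fix_rate: float = 6.0                # fixes per day
    position_jitter_sd: float = 0.3      # km
    breeding_lat: float = 48.0
    wintering_lat: float = 31.0
    corridor_lon: Optional[float] = None
    site_lat_jitter: float = 0.45        # deg, per individual per site
    site_lon_jitter: float = 0.8         # deg
    depart_doy: float = 75.0             # cue=none spring departure
    autumn_depart_doy: float = 265.0
    moult_fraction: float = 0.0
    moult_distance_km: float = 200.0
    flight_speed_kmh: float = 60.0
    min_stay_days: float = 2.5
    spring_hazard: dict = field(default_factory=lambda: {
        "intercept": -4.5, "LSTa": 0.75})
    autumn_hazard: dict = field(default_factory=lambda: {
        "intercept": -5.0, "LSTn": 0.6, "EOS": -0.15})

    def __post_init__(self):
        if not (2.0 <= self.fix_rate <= 288.0):
            raise ValueError("fix_rate must lie in [2, 288]")
        if self.n_stopovers > 0 and self.stopover_stay <= 2.0:
            raise ValueError("stopover_stay must exceed the 2-day stopover rule")

    def required_grid_vars(self) -> set[str]:
        need = set()
        cues = {self.cue, self.autumn_cue}
        if self.timing_mode == "hazard":
            cues |= set(self.spring_hazard) | set(self.autumn_hazard)
        for c in cues:
            if c in ("LSTa",):
                need.add("LST_avg")
            elif c in ("LSTn",):
                need.add("LST_night")
            elif c in ("Ta", "Tcum"):
                need.add("T_air")
            elif c in ("SOS", "EOS", "Greenup", "Dormancy"):
                need.add("NDVI")
            elif c == "Snow":
                need.add("snow_fraction")
        return need


def _onset(world: WorldSpec, metric: str, lat: float, season: str) -> float:
    v = world.true_onset(metric, lat, season)
    if v is None:
        raise ValueError(f"metric {metric} has no onset at lat {lat}")
    return v


def _hazard_departure(world, hazard, lat, season, start_doy, rng,
                      max_doy=360.0) -> float:
    """First day >= start_doy on which the daily logistic hazard fires."""
    d = float(np.ceil(start_doy))
    while d < max_doy:
        eta = hazard.get("intercept", 0.0)
        for metric, beta in hazard.items():
            if metric == "intercept":
                continue
            eta += beta * (d - _onset(world, metric, lat, season))
        if rng.random() < expit(eta):
            return d
        d += 1.0
    return max_doy


@dataclass
class _Visit:
    lat: float
    lon: float
    role: str
    arrive: float   # DOY (fractional)
    depart: float   # DOY; np.inf for the final visit


def _schedule_individual(world, agents, ind_idx, rng):
    """Build one individual's itinerary of visits for spring + autumn."""
    lon0 = agents.corridor_lon
    if lon0 is None:
        lon0 = 0.5 * (world.lon_range[0] + world.lon_range[1])
    lon = lon0 + rng.normal(0.0, 0.5)
    n_sites = agents.n_stopovers + 2
    lats_up = np.linspace(agents.wintering_lat, agents.breeding_lat, n_sites)
    lats_up = lats_up + np.concatenate([[0.0],
                                        rng.normal(0.0, agents.site_lat_jitter,
                                                   n_sites - 2), [0.0]])
    lons_up = lon + np.concatenate([[0.0], rng.normal(0.0, agents.site_lon_jitter, n_sites - 2), [0.0]])
    travel_days = np.array([
        haversine_km(lons_up[i], lats_up[i], lons_up[i + 1], lats_up[i + 1])
        / agents.flight_speed_kmh / 24.0 for i in range(n_sites - 1)])

    visits: list[_Visit] = []
    season_cue = agents.cue

    # ---- spring (northward) ----
    if agents.timing_mode == "hazard":
        arrive = 1.0
        for i in range(n_sites - 1):
            role = "wintering" if i == 0 else "stopover"
            start = max(arrive + agents.min_stay_days, 15.0)
            dep = _hazard_departure(world, agents.spring_hazard, lats_up[i],
                                    "spring", start, rng)
            visits.append(_Visit(lats_up[i], lons_up[i], role, arrive, dep))
            arrive = dep + travel_days[i]
        visits.append(_Visit(lats_up[-1], lons_up[-1], "breeding", arrive, np.inf))
    elif season_cue == "none":
        dep0 = agents.depart_doy + rng.normal(0.0, agents.cue_lag_sd)
        arrive = 1.0
        dep = dep0
        for i in range(n_sites - 1):
            role = "wintering" if i == 0 else "stopover"
            visits.append(_Visit(lats_up[i], lons_up[i], role, arrive, dep))
            arrive = dep + travel_days[i]
            dep = arrive + agents.stopover_stay
        visits.append(_Visit(lats_up[-1], lons_up[-1], "breeding", arrive, np.inf))
    else:
        onsets = np.array([_onset(world, season_cue, la, "spring") for la in lats_up])
        lags = rng.normal(agents.cue_lag_mean, agents.cue_lag_sd, n_sites)
        # scheduled presence date at each node: wave origin + slope * wave
        sched = onsets[0] + agents.surf_slope * (onsets - onsets[0]) + lags
        arrive = 1.0
        for i in range(n_sites - 1):
            role = "wintering" if i == 0 else "stopover"
            dep = max(sched[i + 1] - travel_days[i], arrive + agents.min_stay_days)
            visits.append(_Visit(lats_up[i], lons_up[i], role, arrive, dep))
            arrive = dep + travel_days[i]
        visits.append(_Visit(lats_up[-1], lons_up[-1], "breeding", arrive, np.inf))

    # ---- optional moult relocation ----
    breeding = visits[-1]
    moulted = rng.random() < agents.moult_fraction
    if moulted:
        m_lat = breeding.lat + agents.moult_distance_km / 111.19
        m_travel = agents.moult_distance_km / agents.flight_speed_kmh / 24.0
        move = breeding.arrive + 30.0
        breeding.depart = move
        visits.append(_Visit(m_lat, breeding.lon, "moulting",
                             move + m_travel, np.inf))
    origin = visits[-1]

    # ---- autumn (southward) ----
    lats_dn = np.linspace(origin.lat, agents.wintering_lat, n_sites)
    lats_dn[1:-1] += rng.normal(0.0, agents.site_lat_jitter, n_sites - 2)
    lons_dn = origin.lon + np.concatenate(
        [[0.0], rng.normal(0.0, agents.site_lon_jitter, n_sites - 2), [0.0]])
    travel_dn = np.array([
        haversine_km(lons_dn[i], lats_dn[i], lons_dn[i + 1], lats_dn[i + 1])
        / agents.flight_speed_kmh / 24.0 for i in range(n_sites - 1)])

    if agents.timing_mode == "hazard":
        arrive = origin.arrive
        for i in range(n_sites - 1):
            site = origin if i == 0 else _Visit(lats_dn[i], lons_dn[i], "stopover",
                                                arrive, np.inf)
            if i > 0:
                visits.append(site)
            start = max(arrive + agents.min_stay_days, 183.0)
            site.depart = _hazard_departure(world, agents.autumn_hazard, site.lat,
                                            "autumn", start, rng)
            arrive = site.depart + travel_dn[i]
        visits.append(_Visit(lats_dn[-1], lons_dn[-1], "wintering", arrive, np.inf))
    elif agents.autumn_cue == "none" or season_cue == "none":
        dep = agents.autumn_depart_doy + rng.normal(0.0, agents.autumn_lag_sd)
        arrive = origin.arrive
        for i in range(n_sites - 1):
            site = origin if i == 0 else _Visit(lats_dn[i], lons_dn[i], "stopover",
                                                arrive, np.inf)
            if i > 0:
                visits.append(site)
            site.depart = max(dep, arrive + agents.min_stay_days)
            arrive = site.depart + travel_dn[i]
            dep = arrive + agents.stopover_stay
        visits.append(_Visit(lats_dn[-1], lons_dn[-1], "wintering", arrive, np.inf))
    else:
        onsets = np.array([_onset(world, agents.autumn_cue, la, "autumn")
                           for la in lats_dn])
        lags = rng.normal(agents.autumn_lag_mean, agents.autumn_lag_sd, n_sites)
        sched = onsets[0] + agents.surf_slope * (onsets - onsets[0]) + lags
        arrive = origin.arrive
        for i in range(n_sites - 1):
            site = origin if i == 0 else _Visit(lats_dn[i], lons_dn[i], "stopover",
                                                arrive, np.inf)
            if i > 0:
                visits.append(site)
            site.depart = max(sched[i], arrive + agents.min_stay_days)
            arrive = site.depart + travel_dn[i]
        visits.append(_Visit(lats_dn[-1], lons_dn[-1], "wintering", arrive, np.inf))

    return visits, moulted


def _ground_truth_rows(ind_id, agents, visits, year, moulted):
    """One row per season x node.

    Spring nodes run wintering origin (departure date), stopovers and the
    breeding destination (arrival dates).  Autumn nodes run the origin
    (moult site for relocated birds, else the breeding site; departure
    date), southbound stopovers (departure dates) and the final wintering
    site (arrival date).
    """
    breeding_idx = next(i for i, v in enumerate(visits) if v.role == "breeding")
    rows = []
    for i, v in enumerate(visits):
        if i <= breeding_idx:
            seasons = ["spring"]
            if i == breeding_idx and not moulted:
                seasons.append("autumn")
        else:
            seasons = ["autumn"]
        for season in seasons:
            rows.append({
                "individual_id": ind_id, "species": agents.species,
                "group": agents.group, "year": year, "season": season,
                "node_index": i, "role": v.role, "lon": v.lon, "lat": v.lat,
                "arrive_doy": v.arrive if np.isfinite(v.arrive) else np.nan,
                "depart_doy": v.depart if np.isfinite(v.depart) else np.nan,
            })
    return rows


def simulate_tracks(world: WorldSpec, agents: AgentSpec,
                    grids: Optional[dict] = None, seed: int = 0,
                    track_end_pad_days: float = 20.0):
    """Simulate agent geese; returns (tracks, ground_truth DataFrame).

    If ``grids`` is given it is validated to contain the variables the
    agents' cues require (the timing itself uses the world's closed-form
    onsets, which the grids realize with noise).
    """
    if grids is not None:
        missing = agents.required_grid_vars() - set(grids)
        if missing:
            raise ValueError(f"agents' cues need missing grids: {sorted(missing)}")
    rng = np.random.default_rng([int(seed) % (2 ** 31), 101])
    year = int(world.years[0])
    year_start = pd.Timestamp(year=year, month=1, day=1)

    tracks, gt_rows = [], []
    for k in range(agents.n_individuals):
        ind_id = f"{agents.species}_{agents.group}_{k:03d}"
        visits, moulted = _schedule_individual(world, agents, k, rng)
        gt_rows.extend(_ground_truth_rows(ind_id, agents, visits, year, moulted))

        end_doy = min(visits[-1].arrive + track_end_pad_days, 364.5)
        step = 1.0 / agents.fix_rate
        fix_doys = np.arange(1.0, end_doy, step)
        lons = np.empty_like(fix_doys)
        lats = np.empty_like(fix_doys)
        vi = 0
        for fi, d in enumerate(fix_doys):
            while (vi < len(visits) - 1 and d >= visits[vi].depart
                   and d >= visits[vi + 1].arrive):
                vi += 1
            v = visits[vi]
            if d < v.depart or vi == len(visits) - 1:
                lons[fi], lats[fi] = v.lon, v.lat
            else:  # in flight toward the next visit
                nxt = visits[vi + 1]
                span = max(nxt.arrive - v.depart, 1e-9)
                frac = np.clip((d - v.depart) / span, 0.0, 1.0)
                lons[fi] = v.lon + (nxt.lon - v.lon) * frac
                lats[fi] = v.lat + (nxt.lat - v.lat) * frac
        if agents.position_jitter_sd > 0:
            jit = rng.normal(0.0, agents.position_jitter_sd, (len(fix_doys), 2))
            lats = lats + jit[:, 0] / 111.19
            lons = lons + jit[:, 1] / (111.19 * np.cos(np.radians(lats)))
        stamps = year_start + pd.to_timedelta(fix_doys - 1.0, unit="D")
        fixes = [Fix(ind_id, ts, float(lo), float(la))
                 for ts, lo, la in zip(stamps, lons, lats)]
        tracks.append(Track(ind_id, agents.species, agents.group, fixes))
    return tracks, pd.DataFrame(gt_rows)


def simulate_node_table(world: WorldSpec, agents: AgentSpec, seed: int = 0,
                        dpre_noise_sd: float = 1.0) -> pd.DataFrame:
    """Node-by-metric table straight from the scheduler (no fix emission).

    Gives the ``Dobs``/``Dpre`` long table the surfer analysis consumes,
    with ``Dpre`` equal to the closed-form onsets plus retrieval noise of
    ``dpre_noise_sd`` days.  Useful for statistical power checks where
    simulating and re-segmenting full GPS tracks would only add the error
    sources already tested elsewhere.
    """
    rng = np.random.default_rng([int(seed) % (2 ** 31), 101])
    noise_rng = np.random.default_rng([int(seed) % (2 ** 31), 202])
    year = int(world.years[0])
    rows = []
    for k in range(agents.n_individuals):
        ind_id = f"{agents.species}_{agents.group}_{k:03d}"
        visits, moulted = _schedule_individual(world, agents, k, rng)
        for r in _ground_truth_rows(ind_id, agents, visits, year, moulted):
            if r["season"] == "spring":
                if r["role"] == "wintering":
                    continue
                dobs, metrics = r["arrive_doy"], ("LSTa", "LSTn", "Ta", "Tcum",
                                                  "SOS", "Greenup", "Snow")
            else:
                if r["role"] == "wintering" or not np.isfinite(r["depart_doy"]):
                    continue
                dobs, metrics = r["depart_doy"], ("LSTa", "LSTn", "Ta", "Tcum",
                                                  "EOS", "Dormancy", "Snow")
            for m in metrics:
                true = world.true_onset(m, r["lat"], r["season"])
                dpre = (np.nan if true is None
                        else true + noise_rng.normal(0.0, dpre_noise_sd))
                rows.append({
                    "node_id": f"{ind_id}_{r['season']}_{r['node_index']}",
                    "individual_id": ind_id, "species": r["species"],
                    "group": r["group"], "season": r["season"], "year": year,
                    "lon": r["lon"], "lat": r["lat"], "dobs": dobs,
                    "metric": m, "dpre": dpre,
                })
    return pd.DataFrame(rows)


SCENARIOS = ("paper_like", "green_wave", "null")


def scenario_specs(name: str, seed: int = 0):
    """World and agent cohorts for a named scenario.

    * ``paper_like`` — temperature wave, near-synchronous vegetation, patchy
      snow; hazard-timed agents cue on temperature (spring LSTa; autumn
      nighttime frost, leaving before vegetation dormancy).
    * ``green_wave`` — latitudinally graded vegetation; agents surf SOS.
    * ``null`` — agents depart on a fixed calendar schedule.
    """
    if name == "paper_like":
        world = WorldSpec(ndvi_mode="synchronous", snow_mode="patchy")
        gg_spring = {"intercept": -3.0, "LSTa": 0.75}    # earlier departure
        gg_autumn = {"intercept": -6.5, "LSTn": 0.6, "EOS": -0.15}  # later
        cohorts = [
            AgentSpec(n_individuals=8, species="SG", group="E",
                      timing_mode="hazard", breeding_lat=48.0,
                      wintering_lat=31.0, corridor_lon=108.0),
            AgentSpec(n_individuals=8, species="SG", group="C",
                      timing_mode="hazard", breeding_lat=47.5,
                      wintering_lat=30.5, corridor_lon=104.0),
            AgentSpec(n_individuals=8, species="GG", group="E",
                      timing_mode="hazard", breeding_lat=47.0,
                      wintering_lat=31.0, corridor_lon=108.5,
                      spring_hazard=gg_spring, autumn_hazard=gg_autumn),
            AgentSpec(n_individuals=8, species="GG", group="C",
                      timing_mode="hazard", breeding_lat=47.0,
                      wintering_lat=30.5, corridor_lon=103.5,
                      spring_hazard=gg_spring, autumn_hazard=gg_autumn),
        ]
    elif name == "green_wave":
        world = WorldSpec(ndvi_mode="graded", snow_mode="patchy")
        cohorts = [
            AgentSpec(n_individuals=20, species="SG", group="E",
                      timing_mode="cue_lag", cue="SOS", autumn_cue="EOS",
                      surf_slope=1.0),
        ]
    elif name == "null":
        # calendar migrants flying directly to the breeding grounds: node
        # dates then carry no latitudinal gradient at all.  (A stopover
        # itinerary would mechanically track any northward wave at the rate
        # stay-length / onset-spacing, which is weak surfing, not a null.)
        world = WorldSpec(ndvi_mode="synchronous", snow_mode="patchy")
        cohorts = [
            AgentSpec(n_individuals=20, species="SG", group="E",
                      timing_mode="cue_lag", cue="none", autumn_cue="none",
                      n_stopovers=0, cue_lag_sd=6.0, autumn_lag_sd=6.0),
        ]
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return world, cohorts


def generate_scenario(name: str, seed: int, out_dir,
                      config: Optional[AnalysisConfig] = None):
    """Write a full synthetic dataset (tracks, grids, truth, config) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world, cohorts = scenario_specs(name, seed)
    grids = generate_grids(world, seed)
    all_tracks, gts = [], []
    for i, agents in enumerate(cohorts):
        tr, gt = simulate_tracks(world, agents, grids, seed=int(seed) + 1000 * i)
        all_tracks.extend(tr)
        gts.append(gt)
    write_tracks(all_tracks, out / "tracks.csv")
    for var, grid in grids.items():
        write_env_grid(grid, out / f"{var}.nc")
    gt = pd.concat(gts, ignore_index=True)
    gt.to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    cfg = config or AnalysisConfig(rng_seed=int(seed))
    cfg.to_yaml(out / "config.yaml")
    return out
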