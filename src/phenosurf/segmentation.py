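"""Track segmentation: residency runs, migration events and node tables.

A simple greedy spatial-run clusterer stands in for heavier published
segmentation schemes: a run of consecutive fixes that all stay within a
radius of the running centroid forms a stationary site.  Downstream
analyses only consume node dates and locations, so the clusterer's job is
to recover those; its radius and the strict >2-day stopover rule live in
:class:`~phenosurf.config.AnalysisConfig`.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from .config import AnalysisConfig
from .geo import haversine_km, spherical_polygon_area_km2
from .types import MigrationEvent, StationarySite, Track, doy

log = logging.getLogger("phenosurf")


def detect_stationary_sites(track: Track, radius_km: float = 30.0,
                            min_days: float = 2.0) -> list[StationarySite]:
    """Greedy sequential clustering of a time-sorted track into residency runs.

    Consecutive fixes within ``radius_km`` of the running centroid extend
    the current run; the first fix outside it closes the run and starts a
    new one.  Runs lasting strictly more than ``min_days`` are
    stopover-eligible (role left as ``brief_stop`` otherwise; roles are
    refined by :func:`derive_migration_events`).
    """
    ts = track.timestamps
    if (ts[-1] - ts[0]) < pd.Timedelta(days=1):
        return []
    lons, lats = track.lons, track.lats
    sites: list[StationarySite] = []
    start = 0
    c_lon, c_lat = lons[0], lats[0]
    for i in range(1, len(lons) + 1):
        inside = False
        if i < len(lons):
            inside = haversine_km(c_lon, c_lat, lons[i], lats[i]) <= radius_km
        if inside:
            n = i - start + 1
            c_lon += (lons[i] - c_lon) / n
            c_lat += (lats[i] - c_lat) / n
            continue
        dur = (ts[i - 1] - ts[start]) / pd.Timedelta(days=1)
        sites.append(StationarySite(
            site_id=f"{track.individual_id}_s{len(sites):03d}",
            lon=float(c_lon), lat=float(c_lat),
            first_date=ts[start], last_date=ts[i - 1],
            n_fixes=i - start,
            role="stopover" if dur > min_days else "brief_stop"))
        if i < len(lons):
            start = i
            c_lon, c_lat = lons[i], lats[i]
    return sites


def _mean_daily_fixes(track: Track) -> float:
    days = track.timestamps.normalize()
    return float(pd.Series(1, index=days).groupby(level=0).sum().mean())


def _summer_candidates(resident: list[StationarySite],
                       min_days: float = 20.0) -> list[StationarySite]:
    """Long residencies whose midpoint falls in the boreal summer window."""
    cands = []
    for s in resident:
        mid = s.first_date + (s.last_date - s.first_date) / 2
        if s.duration_days > min_days and 105 <= doy(mid) <= 280:
            cands.append(s)
    return cands


def derive_migration_events(track: Track, sites: list[StationarySite],
                            config: Optional[AnalysisConfig] = None
                            ) -> list[MigrationEvent]:
    """Turn residency runs into spring and autumn migration events.

    Spring runs from the first fix after the bird leaves its wintering
    residency to the first fix of the summering residency.  The autumn
    origin is the moult site when the bird made a post-arrival summer
    relocation longer than ``moult_min_km``, else the breeding site.
    Events cut short by transmitter loss carry ``complete=False``.
    """
    config = config or AnalysisConfig()
    resident = [s for s in sites if s.duration_days > config.stopover_min_days]
    if not resident:
        log.info("derive_migration_events: %s: no residency runs, skipped",
                 track.individual_id)
        return []
    summer_cands = _summer_candidates(resident)
    summer = summer_cands[0] if summer_cands else None
    wintering = None
    for s in resident:
        if summer is not None and s.first_date >= summer.first_date:
            break
        wintering = s if (wintering is None
                          or s.duration_days > wintering.duration_days) else wintering
    events: list[MigrationEvent] = []
    mdf = _mean_daily_fixes(track)
    year = int(track.timestamps[0].year)
    if wintering is None:
        log.info("derive_migration_events: %s: no wintering residency",
                 track.individual_id)
        return []
    wintering.role = "wintering"

    ts = track.timestamps
    after_w = ts[ts > wintering.last_date]
    departure = after_w[0] if len(after_w) else None

    def between(a, b):
        return [s for s in sites
                if s.first_date > a and (b is None or s.last_date < b)
                and s.duration_days > config.stopover_min_days]

    if summer is None:
        mids = between(wintering.last_date, None)
        for s in mids:
            s.role = "stopover"
        events.append(MigrationEvent(
            track.individual_id, track.species, track.group, "spring", year,
            departure_date=departure, arrival_date=None,
            complete=False, nodes=[wintering] + mids, mean_daily_fixes=mdf))
        return events

    summer.role = "breeding"
    mids = between(wintering.last_date, summer.first_date)
    for s in mids:
        s.role = "stopover"
    events.append(MigrationEvent(
        track.individual_id, track.species, track.group, "spring", year,
        departure_date=departure, arrival_date=summer.first_date,
        complete=True, nodes=[wintering] + mids + [summer],
        mean_daily_fixes=mdf))

    # ---- autumn ----
    # moult relocation: a second long summer residency far from the breeding
    # site, occupied before the autumn season opens
    origin = summer
    for s in summer_cands[1:]:
        if (haversine_km(summer.lon, summer.lat, s.lon, s.lat)
                > config.moult_min_km
                and doy(s.first_date) < config.autumn_start_doy):
            origin = s
            s.role = "moulting"
            break
    after_o = ts[ts > origin.last_date]
    if not len(after_o):
        return events
    aut_departure = after_o[0]
    # terminal wintering: a long residency reaching the end of the track
    terminal = None
    for s in resident:
        if (s.first_date > origin.last_date and s.duration_days > 10.0
                and s.last_date >= ts[-1] - pd.Timedelta(days=1)):
            terminal = s
    if terminal is not None:
        terminal.role = "wintering"
    aut_mids = [s for s in between(origin.last_date,
                                   terminal.first_date if terminal is not None
                                   else None)
                if s is not terminal]
    for s in aut_mids:
        s.role = "stopover"
    nodes = [origin] + aut_mids + ([terminal] if terminal is not None else [])
    events.append(MigrationEvent(
        track.individual_id, track.species, track.group, "autumn", year,
        departure_date=aut_departure,
        arrival_date=terminal.first_date if terminal is not None else None,
        complete=terminal is not None, nodes=nodes, mean_daily_fixes=mdf))
    return events


def filter_nodes(events: list[MigrationEvent],
                 config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Per-node table with observed dates (Dobs) and exclusion filters applied.

    Spring nodes carry arrival day-of-year, autumn nodes departure
    day-of-year.  Nodes south of the January 0 deg C isotherm boundary are
    removed, as are whole records whose mean daily fix count falls outside
    the configured range.
    """
    config = config or AnalysisConfig()
    rows = []
    n_south = n_fixrate = 0
    for ev in events:
        if config.fix_rate_policy == "record_mean" and not (
                config.min_fixes_per_day <= ev.mean_daily_fixes
                <= config.max_fixes_per_day):
            n_fixrate += 1
            continue
        if ev.season == "spring":
            nodes = [s for s in ev.nodes if s.role in ("stopover", "breeding")]
        else:
            nodes = [s for s in ev.nodes
                     if s.role in ("stopover", "breeding", "moulting")]
        for s in nodes:
            if s.lat < config.isotherm_boundary_lat:
                n_south += 1
                continue
            if ev.season == "spring":
                dobs = doy(s.first_date)
            else:
                if s is ev.nodes[-1] and not ev.complete and s.role == "stopover":
                    continue  # truncated final visit: departure unobserved
                dobs = doy(s.last_date)
            rows.append({
                "node_id": s.site_id + "_" + ev.season,
                "individual_id": ev.individual_id, "species": ev.species,
                "group": ev.group, "season": ev.season, "year": ev.year,
                "role": "breeding" if s.role in ("breeding", "moulting") else "stopover",
                "lon": s.lon, "lat": s.lat, "dobs": dobs,
                "first_doy": doy(s.first_date), "last_doy": doy(s.last_date),
                "complete": ev.complete,
            })
    if n_south or n_fixrate:
        log.info("filter_nodes: removed %d south-of-boundary nodes, "
                 "%d out-of-range fix-rate records", n_south, n_fixrate)
    return pd.DataFrame(rows)


def mcp_home_range(lons, lats) -> tuple[Polygon, float]:
    """Minimum convex polygon of fixes and its area in km^2."""
    pts = MultiPoint(list(zip(np.asarray(lons, float), np.asarray(lats, float))))
    hull = pts.convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("MCP needs at least 3 non-collinear fixes")
    x, y = hull.exterior.coords.xy
    area = spherical_polygon_area_km2(np.array(x)[:-1], np.array(y)[:-1])
    return hull, area


def summarize_migration(events: list[MigrationEvent]) -> pd.DataFrame:
    """Group-level summary: mean +- SD of dates, duration, stopovers, N/n."""
    rows = []
    for ev in events:
        rows.append({
            "species": ev.species, "group": ev.group, "season": ev.season,
            "individual_id": ev.individual_id,
            "departure_doy": doy(ev.departure_date) if ev.departure_date is not None
                             else np.nan,
            "arrival_doy": doy(ev.arrival_date) if ev.arrival_date is not None
                           else np.nan,
            "duration": ev.duration_days if ev.duration_days is not None else np.nan,
            "n_stopovers": ev.n_stopovers,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    out = (df.groupby(["species", "group", "season"])
             .agg(departure_mean=("departure_doy", "mean"),
                  departure_sd=("departure_doy", "std"),
                  arrival_mean=("arrival_doy", "mean"),
                  arrival_sd=("arrival_doy", "std"),
                  duration_mean=("duration", "mean"),
                  stopovers_total=("n_stopovers", "sum"),
                  n_records=("individual_id", "size"),
                  n_individuals=("individual_id", "nunique"))
             .reset_index())
    return out
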