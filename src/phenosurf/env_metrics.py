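"""Node-level environmental onset metrics (Dpre).

For every migration node a foraging buffer is cut from each gridded
variable (pixels within a radius of the node, minus unsuitable land-cover
classes and low-quality retrievals), composite series are interpolated to
daily resolution, and the season's crossing date is extracted:

* ``LSTa`` / ``LSTn`` / ``Ta`` — first day the daily series exceeds the
  0 deg C threshold in spring (strictly ``>``), or falls below it
  (strictly ``<``) in the second half-year in autumn;
* ``Tcum`` — the same crossings for the trailing 2-week cumulative air
  temperature (window includes the focal day);
* ``Snow`` — daily-interpolated snow-cover fraction crossing the 50 %
  level: melt below it in spring (after the annual cover maximum), rise to
  it in autumn;
* ``SOS``/``EOS``/``Greenup``/``Dormancy`` — delegated per-pixel to
  :mod:`phenosurf.ndvi` and aggregated over the buffer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geo import haversine_km
from .types import EnvGrid, doy

log = logging.getLogger("phenosurf")


@dataclass
class BufferSeries:
    """Buffer-mean time series of one variable around one node."""

    node_id: str
    variable: str
    dates: np.ndarray          # datetime64[D] composite/period starts
    values: np.ndarray         # buffer means, NaN where nothing usable
    n_pixels_used: int
    valid: bool = True
    reason: Optional[str] = None  # insufficient_data when invalid


@dataclass
class MetricDate:
    node_id: str
    metric: str
    season: str
    year: int
    dpre: Optional[float]
    missing_reason: Optional[str] = None   # no_crossing|qc_excluded|insufficient_data
    n_pixels_used: int = 0


def buffer_pixel_indices(grid: EnvGrid, lon: float, lat: float,
                         radius_km: float) -> list[tuple[int, int]]:
    """Pixels whose center lies within ``radius_km`` of the node.

    The cell containing the node (nearest center) is always included, so
    buffers remain usable on grids coarser than the buffer radius.
    """
    glat, glon = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    dist = haversine_km(lon, lat, glon, glat)
    sel = np.argwhere(dist <= radius_km)
    pixels = {tuple(p) for p in sel}
    pixels.add(grid.nearest_cell(lon, lat))
    return sorted(pixels)


def extract_buffer_series(grid: EnvGrid, lon: float, lat: float,
                          radius_km: float,
                          landcover: Optional[EnvGrid] = None,
                          lst_max_error: Optional[float] = None,
                          masked_classes=(0, 2, 13),
                          node_id: str = "") -> BufferSeries:
    """Buffer-mean series with land-cover and per-date quality exclusions."""
    pixels = buffer_pixel_indices(grid, lon, lat, radius_km)
    if landcover is not None:
        pixels = [(i, j) for (i, j) in pixels
                  if landcover.values[0,
                                      int(np.argmin(np.abs(landcover.lats - grid.lats[i]))),
                                      int(np.argmin(np.abs(landcover.lons - grid.lons[j])))]
                  not in masked_classes]
    if not pixels:
        return BufferSeries(node_id, grid.variable, grid.times,
                            np.full(len(grid.times), np.nan), 0,
                            valid=False, reason="insufficient_data")
    ii = np.array([p[0] for p in pixels])
    jj = np.array([p[1] for p in pixels])
    vals = grid.values[:, ii, jj]                      # (time, n_pixels)
    mask = np.isfinite(vals)
    if lst_max_error is not None and grid.quality is not None:
        mask &= grid.quality[:, ii, jj] < lst_max_error
    with np.errstate(invalid="ignore"):
        sums = np.where(mask, vals, 0.0).sum(axis=1)
        counts = mask.sum(axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not np.isfinite(means).any():
        return BufferSeries(node_id, grid.variable, grid.times, means, 0,
                            valid=False, reason="insufficient_data")
    return BufferSeries(node_id, grid.variable, grid.times, means, len(pixels))


def series_to_daily(series: BufferSeries, year: int):
    """Linear interpolation of a (possibly composite) series to daily DOY.

    Returns ``(doys, values)`` covering the calendar year; values outside
    the observed composite range are held at the nearest observation.
    """
    dates = series.dates
    years = dates.astype("datetime64[Y]").astype(int) + 1970
    sel = years == year
    d = dates[sel]
    v = series.values[sel]
    ok = np.isfinite(v)
    if ok.sum() < 2:
        return None
    start = np.datetime64(f"{year}-01-01")
    x = (d[ok] - start).astype("timedelta64[D]").astype(float) + 1.0
    n_days = int((np.datetime64(f"{year + 1}-01-01") - start)
                 .astype("timedelta64[D]").astype(int))
    doys = np.arange(1, n_days + 1, dtype=float)
    return doys, np.interp(doys, x, v[ok])


def _first_crossing_integer(doys, values, threshold, direction, start_doy):
    """First integer day with value strictly above/below the threshold."""
    if direction == "up":
        hit = (values > threshold) & (doys >= start_doy)
    else:
        hit = (values < threshold) & (doys >= start_doy)
    idx = np.nonzero(hit)[0]
    return float(doys[idx[0]]) if idx.size else None


def compute_onset_date(series: BufferSeries, mode: str, season: str,
                       year: int, threshold: float = 0.0,
                       cum_window: int = 14, autumn_start_doy: int = 183,
                       min_doy: Optional[int] = None) -> MetricDate:
    """Temperature onset date for one node-year.

    ``mode="daily"`` thresholds the daily series directly;
    ``mode="cumulative"`` thresholds the trailing ``cum_window``-day sum
    (window ``[d - cum_window + 1, d]``, undefined for the first
    ``cum_window - 1`` days).  Spring searches for the first strict
    upcrossing from day 1, autumn for the first strict downcrossing from
    ``autumn_start_doy``.  ``min_doy`` applies the early-spring exclusion
    (dates before it are set missing as ``qc_excluded``).
    """
    metric = series.variable
    if not series.valid:
        return MetricDate(series.node_id, metric, season, year, None,
                          "insufficient_data", 0)
    daily = series_to_daily(series, year)
    if daily is None:
        return MetricDate(series.node_id, metric, season, year, None,
                          "insufficient_data", series.n_pixels_used)
    doys, values = daily
    if mode == "cumulative":
        csum = np.cumsum(values)
        trailing = csum[cum_window - 1:] - np.concatenate([[0.0],
                                                           csum[:-cum_window]])
        doys, values = doys[cum_window - 1:], trailing
    elif mode != "daily":
        raise ValueError(f"unknown mode {mode!r}")
    if season == "spring":
        d = _first_crossing_integer(doys, values, threshold, "up", doys[0])
    elif season == "autumn":
        d = _first_crossing_integer(doys, values, threshold, "down",
                                    autumn_start_doy)
    else:
        raise ValueError(f"unknown season {season!r}")
    if d is None:
        return MetricDate(series.node_id, metric, season, year, None,
                          "no_crossing", series.n_pixels_used)
    if season == "spring" and min_doy is not None and d < min_doy:
        return MetricDate(series.node_id, metric, season, year, None,
                          "qc_excluded", series.n_pixels_used)
    return MetricDate(series.node_id, metric, season, year, float(d),
                      n_pixels_used=series.n_pixels_used)


def compute_snow_date(series: BufferSeries, season: str, year: int,
                      snow_threshold: float = 0.5,
                      autumn_start_doy: int = 183,
                      spring_rule: str = "after_max") -> MetricDate:
    """Snow melt (spring) / snow onset (autumn) date at the 50 % cover level.

    Composites are linearly interpolated to daily cover.  Spring looks for
    the interpolated downward crossing of the threshold after the annual
    cover maximum (``spring_rule="from_year_start"`` searches from day 1
    instead); autumn for the first upward crossing in the second half-year.
    Crossings are located by linear interpolation between adjacent days, so
    the returned day can be fractional.
    """
    if not series.valid:
        return MetricDate(series.node_id, "Snow", season, year, None,
                          "insufficient_data", 0)
    daily = series_to_daily(series, year)
    if daily is None:
        return MetricDate(series.node_id, "Snow", season, year, None,
                          "insufficient_data", series.n_pixels_used)
    doys, values = daily
    if season == "spring":
        # melt is a first-half-year phenomenon; the annual maximum is taken
        # before the autumn search window so late-year snowpack cannot mask it
        half = np.searchsorted(doys, autumn_start_doy)
        values, doys = values[:half], doys[:half]
        start = int(np.argmax(values)) if spring_rule == "after_max" else 0
        v = values[start:]
        dd = doys[start:]
        below = v < snow_threshold
        if not below.any() or below.all():
            return MetricDate(series.node_id, "Snow", season, year, None,
                              "no_crossing", series.n_pixels_used)
        k = int(np.nonzero(below)[0][0])
        if k == 0:
            d = float(dd[0])
        else:
            v0, v1 = v[k - 1], v[k]
            d = float(dd[k - 1] + (v0 - snow_threshold) / (v0 - v1))
        return MetricDate(series.node_id, "Snow", season, year, d,
                          n_pixels_used=series.n_pixels_used)
    # autumn: first rise to >= threshold in the second half-year
    sel = doys >= autumn_start_doy
    v = values[sel]
    dd = doys[sel]
    atol = v >= snow_threshold
    if not atol.any():
        return MetricDate(series.node_id, "Snow", season, year, None,
                          "no_crossing", series.n_pixels_used)
    k = int(np.nonzero(atol)[0][0])
    if k == 0:
        d = float(dd[0])
    else:
        v0, v1 = v[k - 1], v[k]
        d = float(dd[k - 1] + (snow_threshold - v0) / (v1 - v0))
    return MetricDate(series.node_id, "Snow", season, year, d,
                      n_pixels_used=series.n_pixels_used)


def compute_metrics_for_nodes(nodes: pd.DataFrame, grids: dict,
                              config: Optional[AnalysisConfig] = None
                              ) -> pd.DataFrame:
    """All nine onset metrics for every node row.

    ``nodes`` is the table from
    :func:`phenosurf.segmentation.filter_nodes`; ``grids`` maps variable
    names (``LST_avg``, ``LST_night``, ``T_air``, ``NDVI``,
    ``snow_fraction``, ``landcover``) to :class:`~phenosurf.types.EnvGrid`.
    Vegetation dates come from per-pixel season fits aggregated over the
    buffer (median by default).
    """
    from . import ndvi as ndvi_mod

    config = config or AnalysisConfig()
    lc = grids.get("landcover")
    out: list[MetricDate] = []
    pheno_cache: dict = {}
    for row in nodes.itertuples():
        year = int(row.year)
        season = row.season
        veg_metrics = ("SOS", "Greenup") if season == "spring" else ("EOS", "Dormancy")

        for metric, var, mode, min_doy in (
                ("LSTa", "LST_avg", "daily", None),
                ("LSTn", "LST_night", "daily", None),
                ("Ta", "T_air", "daily", config.doy_min),
                ("Tcum", "T_air", "cumulative", config.doy_min)):
            grid = grids.get(var)
            if grid is None:
                continue
            qc = config.lst_max_error if var.startswith("LST") else None
            bs = extract_buffer_series(grid, row.lon, row.lat,
                                       config.buffer_radius_km, landcover=lc,
                                       lst_max_error=qc,
                                       masked_classes=config.masked_landcover,
                                       node_id=row.node_id)
            md = compute_onset_date(bs, mode, season, year,
                                    threshold=config.zero_threshold,
                                    cum_window=config.cum_window,
                                    autumn_start_doy=config.autumn_start_doy,
                                    min_doy=min_doy if season == "spring" else None)
            md.metric = metric
            out.append(md)

        if "snow_fraction" in grids:
            bs = extract_buffer_series(grids["snow_fraction"], row.lon, row.lat,
                                       config.buffer_radius_km, landcover=lc,
                                       masked_classes=config.masked_landcover,
                                       node_id=row.node_id)
            out.append(compute_snow_date(bs, season, year,
                                         snow_threshold=config.snow_threshold,
                                         autumn_start_doy=config.autumn_start_doy,
                                         spring_rule=config.snow_spring_rule))

        if "NDVI" in grids:
            grid = grids["NDVI"]
            pixels = buffer_pixel_indices(grid, row.lon, row.lat,
                                          config.buffer_radius_km)
            if lc is not None:
                pixels = [(i, j) for (i, j) in pixels
                          if lc.values[0,
                                       int(np.argmin(np.abs(lc.lats - grid.lats[i]))),
                                       int(np.argmin(np.abs(lc.lons - grid.lons[j])))]
                          not in config.masked_landcover]
            per_pixel = {m: [] for m in veg_metrics}
            n_used = 0
            for (i, j) in pixels:
                key = (i, j, year)
                if key not in pheno_cache:
                    pheno_cache[key] = ndvi_mod.pixel_phenology(
                        grid.times, grid.values[:, i, j], year, config)
                dates = pheno_cache[key]
                if dates is None:
                    continue
                n_used += 1
                for m in veg_metrics:
                    v = getattr(dates, m)
                    if v is not None:
                        per_pixel[m].append(v)
            for m in veg_metrics:
                vals = per_pixel[m]
                if not pixels:
                    out.append(MetricDate(row.node_id, m, season, year, None,
                                          "insufficient_data", 0))
                elif not vals:
                    out.append(MetricDate(row.node_id, m, season, year, None,
                                          "qc_excluded", n_used))
                else:
                    agg = (np.median if config.buffer_pheno_agg == "median"
                           else np.mean)
                    out.append(MetricDate(row.node_id, m, season, year,
                                          float(agg(vals)),
                                          n_pixels_used=len(vals)))
    return pd.DataFrame([{
        "node_id": m.node_id, "metric": m.metric, "season": m.season,
        "year": m.year, "dpre": np.nan if m.dpre is None else m.dpre,
        "missing_reason": m.missing_reason or "",
        "n_pixels_used": m.n_pixels_used,
    } for m in out])


def assign_dpre_to_nodes(nodes: pd.DataFrame,
                         metric_dates: pd.DataFrame) -> pd.DataFrame:
    """Long node-by-metric table joining Dobs with each metric's Dpre.

    Rows with missing Dpre are retained with the missing reason flagged;
    model-level code drops them per analysis.
    """
    md = metric_dates[["node_id", "metric", "year", "dpre", "missing_reason",
                       "n_pixels_used"]]
    out = nodes.merge(md, on=["node_id", "year"], how="inner")
    return out.reset_index(drop=True)
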