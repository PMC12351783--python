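"""Readers and writers for tracks and environmental grids.

Tracks travel as delimited text with columns
``individual_id,species,group,timestamp,lon,lat`` (ISO-8601 UTC timestamps).
Grids travel either as NetCDF with dims (time, lat, lon) or as long-format
CSV ``date,lat,lon,value[,quality]``.  Kelvin-labelled temperature grids are
converted to deg C on read using the declared ``units`` attribute.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .types import EmptyInputError, EnvGrid, Fix, FormatError, SchemaError, Track

log = logging.getLogger("phenosurf")

TRACK_COLUMNS = ("individual_id", "species", "group", "timestamp", "lon", "lat")


def read_tracks(path, schema: Optional[dict] = None) -> list[Track]:
    """Read tracks from a delimited text file.

    ``schema`` optionally maps canonical column names to the file's column
    names.  Fixes are sorted by time per individual; exact-duplicate
    timestamps are collapsed to the first fix; rows with unparseable
    coordinates or timestamps are dropped (counts logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path} contains no rows")
    colmap = {k: (schema or {}).get(k, k) for k in TRACK_COLUMNS}
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[list(TRACK_COLUMNS)]

    n0 = len(df)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad = df[["lon", "lat", "timestamp"]].isna().any(axis=1)
    bad |= (df["lon"].abs() > 180) | (df["lat"].abs() > 90)
    if bad.any():
        log.warning("read_tracks: dropped %d unparseable rows", int(bad.sum()))
    df = df[~bad]
    if df.empty:
        raise EmptyInputError(f"{path}: no parseable rows")

    tracks = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.sort_values("timestamp")
        dup = sub["timestamp"].duplicated()
        if dup.any():
            log.warning("read_tracks: %s: collapsed %d duplicate timestamps",
                        ind, int(dup.sum()))
            sub = sub[~dup]
        if len(sub) < 2:
            log.warning("read_tracks: %s: fewer than 2 fixes, skipped", ind)
            continue
        fixes = [Fix(str(ind), r.timestamp, float(r.lon), float(r.lat))
                 for r in sub.itertuples()]
        tracks.append(Track(str(ind), str(sub["species"].iloc[0]),
                            str(sub["group"].iloc[0]), fixes))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    frames = [t.to_frame() for t in tracks]
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


_KELVIN_NAMES = {"k", "kelvin", "degk", "deg_k"}
_CELSIUS_NAMES = {"c", "celsius", "degc", "deg_c", "degree_celsius", "degrees_c"}
_TEMP_VARS = {"LST_avg", "LST_night", "T_air"}


def read_env_grid(path, variable: Optional[str] = None) -> EnvGrid:
    """Read an :class:`EnvGrid` from NetCDF or long-format CSV."""
    path = Path(path)
    if path.suffix in (".nc", ".nc3", ".cdf"):
        return _read_grid_netcdf(path, variable)
    return _read_grid_csv(path, variable)


def _read_grid_netcdf(path, variable):
    ds = xr.open_dataset(path, engine="scipy")
    try:
        data_vars = [v for v in ds.data_vars if v != "quality"]
        if variable is None:
            if len(data_vars) != 1:
                raise SchemaError(f"specify variable; file has {data_vars}")
            variable = data_vars[0]
        if variable not in ds:
            raise SchemaError(f"variable {variable!r} not in {path}")
        da = ds[variable]
        values = da.transpose("time", "lat", "lon").values.astype(float)
        units = str(da.attrs.get("units", "")).strip().lower()
        if variable in _TEMP_VARS:
            if units in _KELVIN_NAMES:
                values = values - 273.15
            elif units and units not in _CELSIUS_NAMES:
                raise FormatError(f"unrecognized temperature units {units!r}")
        quality = None
        if "quality" in ds:
            quality = ds["quality"].transpose("time", "lat", "lon").values.astype(float)
        return EnvGrid(variable=variable,
                       times=ds["time"].values.astype("datetime64[D]"),
                       lats=ds["lat"].values, lons=ds["lon"].values,
                       values=values, quality=quality)
    finally:
        ds.close()


def _read_grid_csv(path, variable):
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path} contains no rows")
    required = {"date", "lat", "lon", "value"}
    if not required.issubset(df.columns):
        raise SchemaError(f"long-format grid CSV needs columns {sorted(required)}")
    if variable is None:
        variable = str(df["variable"].iloc[0]) if "variable" in df.columns else "value"
    df["date"] = pd.to_datetime(df["date"]).values.astype("datetime64[D]")
    times = np.sort(df["date"].unique())
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    shape = (len(times), len(lats), len(lons))
    ti = pd.Index(times).get_indexer(df["date"])
    yi = pd.Index(lats).get_indexer(df["lat"])
    xi = pd.Index(lons).get_indexer(df["lon"])
    values = np.full(shape, np.nan)
    values[ti, yi, xi] = df["value"].astype(float).values
    quality = None
    if "quality" in df.columns and df["quality"].notna().any():
        quality = np.full(shape, np.nan)
        quality[ti, yi, xi] = df["quality"].astype(float).values
    return EnvGrid(variable=variable, times=times, lats=lats, lons=lons,
                   values=values, quality=quality)


def write_env_grid(grid: EnvGrid, path) -> None:
    """Write a grid; format chosen by extension (.nc => NetCDF, else CSV)."""
    path = Path(path)
    if path.suffix in (".nc", ".nc3", ".cdf"):
        data = {grid.variable: (("time", "lat", "lon"), grid.values)}
        if grid.quality is not None:
            data["quality"] = (("time", "lat", "lon"), grid.quality)
        ds = xr.Dataset(data, coords={"time": grid.times.astype("datetime64[ns]"),
                                      "lat": grid.lats, "lon": grid.lons})
        if grid.variable in _TEMP_VARS:
            ds[grid.variable].attrs["units"] = "degC"
        ds.to_netcdf(path, engine="scipy")
        return
    t, y, x = np.meshgrid(np.arange(len(grid.times)), np.arange(len(grid.lats)),
                          np.arange(len(grid.lons)), indexing="ij")
    df = pd.DataFrame({
        "date": grid.times[t.ravel()].astype(str),
        "lat": grid.lats[y.ravel()],
        "lon": grid.lons[x.ravel()],
        "value": grid.values.ravel(),
        "variable": grid.variable,
    })
    if grid.quality is not None:
        df["quality"] = grid.quality.ravel()
    df.to_csv(path, index=False, float_format="%.10g")
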