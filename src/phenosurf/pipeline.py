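"""End-to-end pipeline steps over a run directory.

Each step reads the files previous steps wrote (``tracks.csv``, grid
NetCDFs, ``events.csv``, ``nodes.csv``, ``metrics.csv``) and writes its own
outputs, so the command-line interface stays a thin shell around these
functions.  All floating-point CSV output uses a fixed format so that runs
with the same seed and configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import analysis, env_metrics, segmentation
from .config import AnalysisConfig
from .io import read_env_grid, read_tracks
from .types import ALL_METRICS, doy

log = logging.getLogger("phenosurf")

FLOAT_FMT = "%.6f"
GRID_VARS = ("LST_avg", "LST_night", "T_air", "NDVI", "snow_fraction", "landcover")


def _load_config(run_dir: Path) -> AnalysisConfig:
    cfg_path = run_dir / "config.yaml"
    return AnalysisConfig.from_yaml(cfg_path) if cfg_path.exists() else AnalysisConfig()


def _require(run_dir: Path, name: str) -> Path:
    p = run_dir / name
    if not p.exists():
        raise FileNotFoundError(
            f"{p} not found — run the earlier pipeline step that produces it")
    return p


def run_segment(run_dir) -> pd.DataFrame:
    """tracks.csv -> events.csv + nodes.csv"""
    run_dir = Path(run_dir)
    config = _load_config(run_dir)
    tracks = read_tracks(_require(run_dir, "tracks.csv"))
    all_events = []
    for tr in tracks:
        sites = segmentation.detect_stationary_sites(
            tr, radius_km=config.residency_radius_km,
            min_days=config.stopover_min_days)
        all_events.extend(segmentation.derive_migration_events(tr, sites, config))
    nodes = segmentation.filter_nodes(all_events, config)
    ev_rows = [{
        "individual_id": e.individual_id, "species": e.species,
        "group": e.group, "season": e.season, "year": e.year,
        "departure_doy": doy(e.departure_date) if e.departure_date is not None
                         else np.nan,
        "arrival_doy": doy(e.arrival_date) if e.arrival_date is not None
                       else np.nan,
        "complete": e.complete, "n_stopovers": e.n_stopovers,
        "mean_daily_fixes": e.mean_daily_fixes,
    } for e in all_events]
    pd.DataFrame(ev_rows).to_csv(run_dir / "events.csv", index=False,
                                 float_format=FLOAT_FMT)
    nodes.to_csv(run_dir / "nodes.csv", index=False, float_format=FLOAT_FMT)
    summary = segmentation.summarize_migration(all_events)
    summary.to_csv(run_dir / "migration_summary.csv", index=False,
                   float_format=FLOAT_FMT)
    log.info("segment: %d events, %d nodes", len(ev_rows), len(nodes))
    return nodes


def run_metrics(run_dir) -> pd.DataFrame:
    """nodes.csv + grids -> metrics.csv"""
    run_dir = Path(run_dir)
    config = _load_config(run_dir)
    nodes = pd.read_csv(_require(run_dir, "nodes.csv"))
    grids = {}
    for var in GRID_VARS:
        p = run_dir / f"{var}.nc"
        if not p.exists():
            p = run_dir / f"{var}.csv"
        if p.exists():
            grids[var] = read_env_grid(p, var)
    if not grids:
        raise FileNotFoundError(f"no environmental grids found in {run_dir}")
    metrics = env_metrics.compute_metrics_for_nodes(nodes, grids, config)
    metrics.to_csv(run_dir / "metrics.csv", index=False, float_format=FLOAT_FMT)
    log.info("metrics: %d node-metric rows", len(metrics))
    return metrics


def _node_metric_table(run_dir: Path) -> pd.DataFrame:
    nodes = pd.read_csv(_require(run_dir, "nodes.csv"))
    metrics = pd.read_csv(_require(run_dir, "metrics.csv"))
    return env_metrics.assign_dpre_to_nodes(nodes, metrics)


def run_surf(run_dir) -> pd.DataFrame:
    """nodes.csv + metrics.csv -> surfer_results.csv"""
    run_dir = Path(run_dir)
    table = _node_metric_table(run_dir)
    results = analysis.run_surfer_analysis(table)
    results.to_csv(run_dir / "surfer_results.csv", index=False,
                   float_format=FLOAT_FMT)
    log.info("surf: %d cells", len(results))
    return results


def run_probability(run_dir, seed: Optional[int] = None) -> dict:
    """nodes.csv + metrics.csv -> probability_records.csv, model_fits.json,
    effect_curves.csv"""
    run_dir = Path(run_dir)
    config = _load_config(run_dir)
    seed = config.rng_seed if seed is None else int(seed)
    nodes = pd.read_csv(_require(run_dir, "nodes.csv"))
    metrics = pd.read_csv(_require(run_dir, "metrics.csv"))

    fits = {}
    all_records = []
    all_curves = []
    for season, candidates in (("spring", ("LSTa", "LSTn", "Ta", "Tcum",
                                           "SOS", "Greenup", "Snow")),
                               ("autumn", ("LSTa", "LSTn", "Ta", "Tcum",
                                           "EOS", "Dormancy", "Snow"))):
        records = analysis.build_probability_records(nodes, metrics, season,
                                                     config)
        if records.empty:
            continue
        all_records.append(records)
        usable = [m for m in candidates
                  if m in records.columns and records[m].notna().mean() > 0.5]
        try:
            sel = analysis.select_best_model(records, usable, config)
        except (RuntimeError, ValueError) as exc:
            log.warning("probability: %s selection failed: %s", season, exc)
            continue
        _, summary = analysis.posterior_sim(
            sel.best, n_draws=config.n_posterior_draws, seed=seed)
        fits[season] = {
            "selected_metrics": list(sel.best_metrics),
            "aic": float(sel.best.aic),
            "loglik": float(sel.best.loglik),
            "sigma_u": float(sel.best.sigma_u),
            "r2_marginal": float(sel.best.r2_marginal),
            "r2_conditional": float(sel.best.r2_conditional),
            "n_obs": int(sel.best.n_obs),
            "n_groups": int(sel.best.n_groups),
            "vif_dropped": sel.vif_dropped,
            "coefficients": summary.to_dict(orient="records"),
            "selection_table": sel.table.head(10).to_dict(orient="records"),
        }
        for metric in sel.best_metrics:
            curve = analysis.effect_curve(sel, metric, seed=seed,
                                          n_draws=config.n_posterior_draws)
            curve.insert(0, "season", season)
            all_curves.append(curve)
    if all_records:
        pd.concat(all_records, ignore_index=True).to_csv(
            run_dir / "probability_records.csv", index=False,
            float_format=FLOAT_FMT)
    if all_curves:
        pd.concat(all_curves, ignore_index=True).to_csv(
            run_dir / "effect_curves.csv", index=False, float_format=FLOAT_FMT)
    (run_dir / "model_fits.json").write_text(
        json.dumps(fits, indent=2, sort_keys=True, default=float))
    return fits


def run_compare(run_dir) -> pd.DataFrame:
    """events.csv -> contrasts.csv"""
    run_dir = Path(run_dir)
    events = pd.read_csv(_require(run_dir, "events.csv"))
    out = analysis.compare_migration_dates(events)
    frames = []
    for (season, endpoint), entry in out.items():
        for key in ("species_contrasts", "group_contrasts"):
            if key in entry and not entry[key].empty:
                t = entry[key].copy()
                t.insert(0, "season", season)
                t.insert(1, "endpoint", endpoint)
                t.insert(2, "contrast", key.replace("_contrasts", ""))
                frames.append(t)
    contrasts = (pd.concat(frames, ignore_index=True)
                 if frames else pd.DataFrame())
    contrasts.to_csv(run_dir / "contrasts.csv", index=False,
                     float_format=FLOAT_FMT)
    return contrasts


def run_all(run_dir, scenario: str = "paper_like", seed: int = 0) -> None:
    """simulate -> segment -> metrics -> surf -> probability -> compare."""
    from .synthetic import generate_scenario

    run_dir = Path(run_dir)
    generate_scenario(scenario, seed, run_dir)
    run_segment(run_dir)
    run_metrics(run_dir)
    run_surf(run_dir)
    run_probability(run_dir, seed=seed)
    run_compare(run_dir)
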