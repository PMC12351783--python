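"""The three core analyses.

1. **Surfer classification** — per species x group x season x metric, a
   linear mixed model of observed node dates on the metric's predicted
   onset dates; slope/intercept inference decides whether the population
   *surfs* the metric's spatial wave (slope CI straddling 1, intercept
   indistinguishable from 0), *weakly surfs* (significant positive slope
   deviating in magnitude, or a shifted intercept), or does not respond.
2. **Arrival / departure probability** — daily presence records per node
   visit (y = 1 on the departure day in autumn, on the arrival day in
   spring) with days-since-onset covariates, VIF-screened, fitted as
   logistic mixed models over all metric subsets with species
   interactions, ranked by AIC; effect curves by posterior simulation.
3. **Migration-date comparison** — Gaussian mixed model of event dates on
   species x group with Tukey-adjusted marginal-mean contrasts.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .config import AnalysisConfig
from .mixed_models import (GlmmFit, RankDeficiencyError, SeparationError,
                           SmallSampleError, compute_vif, emm_tukey,
                           fit_glmm_logistic, fit_lmm, posterior_sim)
from .types import MigrationEvent, doy

log = logging.getLogger("phenosurf")


def classify_surfer(slope: float, slope_ci: Sequence[float], slope_p: float,
                    intercept_p: float) -> str:
    """Surfing class from slope/intercept inference.

    *surfer*: significant positive slope whose 95 % CI straddles 1 from a
    positive lower bound, with a nonsignificant intercept.  *weak_surfer*:
    significant positive slope whose CI sits inside (0, 1), or entirely
    above 1, or any significant positive slope with a significant
    intercept.  Everything else is *non_surfer*.  The surfer test takes
    precedence.  Any missing input yields *not_estimable*.
    """
    vals = [slope, slope_ci[0], slope_ci[1], slope_p, intercept_p]
    if any(v is None or not np.isfinite(v) for v in vals):
        return "not_estimable"
    lo, hi = float(slope_ci[0]), float(slope_ci[1])
    if lo > hi:
        raise ValueError("slope CI bounds out of order")
    sig_pos = slope_p < 0.05 and slope > 0
    if sig_pos and 0 < lo <= 1 and hi >= 1 and intercept_p > 0.05:
        return "surfer"
    if sig_pos and ((lo > 0 and hi < 1) or lo > 1 or intercept_p <= 0.05):
        return "weak_surfer"
    return "non_surfer"


def run_surfer_analysis(node_metric_table: pd.DataFrame,
                        min_n: int = 5,
                        include_pooled: bool = True) -> pd.DataFrame:
    """Fit Dobs ~ Dpre per species x group x season x metric cell.

    ``node_metric_table`` is the long table with columns
    ``species, group, season, metric, dobs, dpre, individual_id, year``.
    Pooled per-species rows (group ``ALL``) are appended when requested.
    """
    df = node_metric_table.copy()
    frames = [df]
    if include_pooled:
        pooled = df.copy()
        pooled["group"] = "ALL"
        frames.append(pooled)
    work = pd.concat(frames, ignore_index=True)

    rows = []
    for (species, group, season, metric), cell in work.groupby(
            ["species", "group", "season", "metric"], sort=True):
        cell = cell.dropna(subset=["dobs", "dpre"])
        row = {"species": species, "group": group, "season": season,
               "metric": metric, "n_nodes": len(cell)}
        try:
            fit = fit_lmm(cell, min_n=min_n)
            row.update({
                "slope": fit.slope, "slope_ci_low": float(fit.conf_int[1, 0]),
                "slope_ci_high": float(fit.conf_int[1, 1]),
                "slope_p": float(fit.pvalues[1]),
                "intercept": fit.intercept,
                "intercept_p": float(fit.pvalues[0]),
                "random_structure": fit.group_desc,
                "fallbacks": ";".join(fit.fallbacks),
            })
            row["classification"] = classify_surfer(
                row["slope"], (row["slope_ci_low"], row["slope_ci_high"]),
                row["slope_p"], row["intercept_p"])
        except (SmallSampleError, RankDeficiencyError, RuntimeError) as exc:
            row.update({"slope": np.nan, "slope_ci_low": np.nan,
                        "slope_ci_high": np.nan, "slope_p": np.nan,
                        "intercept": np.nan, "intercept_p": np.nan,
                        "random_structure": "", "fallbacks": type(exc).__name__,
                        "classification": "not_estimable"})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probability records
# ---------------------------------------------------------------------------

def build_probability_records(nodes: pd.DataFrame, metric_dates: pd.DataFrame,
                              season: str,
                              config: Optional[AnalysisConfig] = None,
                              standardize: bool = True) -> pd.DataFrame:
    """Daily presence records for the arrival/departure probability models.

    Autumn: one record per presence day at each departure node (from the
    later of arrival and the autumn season start), ``y = 1`` on the last
    presence day — only for visits whose departure was observed.  Spring:
    mirrored coding over an approach window — ``y = 0`` on the
    ``approach_window_days`` days before arrival at the node and ``y = 1``
    on the arrival day itself.  Covariates are days since each metric's
    onset (day - Dpre); ``*_z`` columns add the z-standardized versions.
    """
    config = config or AnalysisConfig()
    metrics = (("LSTa", "LSTn", "Ta", "Tcum", "SOS", "Greenup", "Snow")
               if season == "spring"
               else ("LSTa", "LSTn", "Ta", "Tcum", "EOS", "Dormancy", "Snow"))
    dpre = metric_dates.pivot_table(index="node_id", columns="metric",
                                    values="dpre", aggfunc="first")
    sub = nodes[nodes["season"] == season]
    rows = []
    for r in sub.itertuples():
        if r.node_id not in dpre.index:
            continue
        onsets = dpre.loc[r.node_id]
        if season == "autumn":
            first = float(r.first_doy)
            if r.role == "breeding":
                # summer-long residencies enter the risk set at the season start
                first = max(first, float(config.autumn_start_doy))
            last = float(r.last_doy)
            days = np.arange(np.floor(first), np.floor(last) + 1.0)
            if days.size == 0:
                continue
            ys = np.zeros(days.size)
            ys[-1] = 1.0
        else:
            arrive = np.floor(float(r.first_doy))
            days = np.arange(arrive - config.approach_window_days, arrive + 1.0)
            ys = np.zeros(days.size)
            ys[-1] = 1.0
        for d, yv in zip(days, ys):
            rec = {"individual_id": r.individual_id, "species": r.species,
                   "group": r.group, "year": int(r.year), "season": season,
                   "node_id": r.node_id, "doy": float(d), "y": float(yv)}
            for m in metrics:
                v = onsets.get(m, np.nan)
                rec[m] = float(d) - float(v) if np.isfinite(v) else np.nan
            rows.append(rec)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if standardize:
        for m in metrics:
            if m in out.columns:
                v = out[m]
                sd = v.std(ddof=0)
                out[m + "_z"] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


@dataclass
class ModelSelection:
    best: GlmmFit
    best_metrics: tuple
    table: pd.DataFrame           # all candidates ranked by AIC
    vif_table: pd.DataFrame
    vif_dropped: list
    records: pd.DataFrame         # rows actually fitted (complete cases)
    design_columns: list


def _design_matrix(records: pd.DataFrame, metrics: Sequence[str],
                   species_levels: Sequence[str]):
    """Intercept + species mains + per-metric z-covariate x species terms."""
    n = len(records)
    cols, names = [np.ones(n)], ["intercept"]
    ref = species_levels[0]
    for s in species_levels[1:]:
        cols.append((records["species"] == s).to_numpy(dtype=float))
        names.append(f"species[{s}]")
    for m in metrics:
        x = records[m + "_z"].to_numpy(dtype=float)
        cols.append(x)
        names.append(m)
        for s in species_levels[1:]:
            cols.append(x * (records["species"] == s).to_numpy(dtype=float))
            names.append(f"{m}:species[{s}]")
    return np.column_stack(cols), names, ref


def select_best_model(records: pd.DataFrame, candidate_metrics: Sequence[str],
                      config: Optional[AnalysisConfig] = None,
                      max_subset_size: Optional[int] = None) -> ModelSelection:
    """VIF screen, then exhaustive AIC search over metric subsets.

    Each candidate model contains the retained metrics' standardized
    days-since-onset covariates with species interactions, and a random
    intercept for individual nested within year.
    """
    config = config or AnalysisConfig()
    cand = [m for m in candidate_metrics if (m + "_z") in records.columns]
    work = records.dropna(subset=[m for m in cand]).copy()
    if work.empty:
        raise ValueError("no complete-case records for the candidate metrics")
    # re-standardize on the fitted subset so z-columns have mean 0, sd 1
    for m in cand:
        v = work[m]
        sd = v.std(ddof=0)
        work[m + "_z"] = (v - v.mean()) / sd if sd > 0 else 0.0

    if len(cand) >= 2:
        design = work[[m + "_z" for m in cand]]
        design.columns = cand
        vif_table, retained, dropped = compute_vif(design,
                                                   limit=config.vif_limit)
        if dropped:
            log.info("select_best_model: VIF dropped %s", dropped)
    else:
        vif_table = pd.DataFrame({"predictor": cand, "vif": [1.0] * len(cand)})
        retained, dropped = list(cand), []

    species_levels = sorted(work["species"].unique())
    groups = work["year"].astype(str) + ":" + work["individual_id"].astype(str)
    y = work["y"].to_numpy(dtype=float)

    results = []
    max_k = max_subset_size or len(retained)
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(retained, k):
            X, names, _ = _design_matrix(work, subset, species_levels)
            try:
                fit = fit_glmm_logistic(X, y, groups, names=names)
            except (SeparationError, np.linalg.LinAlgError) as exc:
                log.info("select_best_model: %s failed: %s", subset, exc)
                continue
            results.append({"metrics": subset, "aic": fit.aic,
                            "loglik": fit.loglik, "k": len(names) + 1,
                            "fit": fit})
    if not results:
        raise RuntimeError("no candidate probability model converged")
    table = pd.DataFrame(results).sort_values("aic").reset_index(drop=True)
    best_row = table.iloc[0]
    best: GlmmFit = best_row["fit"]
    best.x_means = work[list(best_row["metrics"])].mean()
    best.x_sds = work[list(best_row["metrics"])].std(ddof=0)
    return ModelSelection(best, tuple(best_row["metrics"]),
                          table.drop(columns="fit").assign(
                              metrics=table["metrics"].map(lambda t: "+".join(t))),
                          vif_table, dropped, work,
                          list(best_row["metrics"]))


def effect_curve(selection: ModelSelection, focal: str,
                 value_range: Optional[tuple] = None, n_points: int = 101,
                 n_draws: int = 2000, seed: int = 0,
                 species: Optional[str] = None) -> pd.DataFrame:
    """Predicted probability vs one covariate, others held at their means.

    The focal axis is in original units (days since onset); predictions are
    population-level (random effects at zero) with a posterior-simulation
    CI band.  Values outside the observed range are annotated.
    """
    fit = selection.best
    metrics = list(selection.best_metrics)
    if focal not in metrics:
        raise ValueError(f"{focal!r} not in the selected model {metrics}")
    work = selection.records
    obs = work[focal]
    if value_range is None:
        value_range = (float(obs.min()), float(obs.max()))
    xs = np.linspace(value_range[0], value_range[1], n_points)
    extrapolated = (xs < obs.min()) | (xs > obs.max())
    if extrapolated.any():
        log.warning("effect_curve: %d points outside the observed range",
                    int(extrapolated.sum()))

    species_levels = sorted(work["species"].unique())
    if species is None:
        species = species_levels[0]
    grid = pd.DataFrame({m + "_z": np.zeros(n_points) for m in metrics})
    mu = float(fit.x_means[focal])
    sd = float(fit.x_sds[focal]) or 1.0
    grid[focal + "_z"] = (xs - mu) / sd
    grid["species"] = species
    X, _, _ = _design_matrix(grid, metrics, species_levels)

    draws, _ = posterior_sim(fit, n_draws=n_draws, seed=seed)
    eta_draws = X @ draws.T
    prob = fit.predict_prob(X)
    from scipy.special import expit as _expit
    band = _expit(eta_draws)
    return pd.DataFrame({
        "focal": focal, "species": species, "x": xs, "probability": prob,
        "ci_low": np.percentile(band, 2.5, axis=1),
        "ci_high": np.percentile(band, 97.5, axis=1),
        "extrapolated": extrapolated,
    })


# ---------------------------------------------------------------------------
# migration-date comparison
# ---------------------------------------------------------------------------

def compare_migration_dates(events: list[MigrationEvent],
                            alpha: float = 0.05) -> dict:
    """Date ~ species x group mixed models with Tukey contrasts.

    One Gaussian mixed model per endpoint (spring/autumn x
    departure/arrival) with random intercepts for year (group factor) and
    individual (variance component), then pairwise marginal-mean contrasts
    across species within group and across groups within species.
    """
    rows = []
    if isinstance(events, pd.DataFrame):
        for r in events.itertuples():
            for endpoint, d in (("departure", r.departure_doy),
                                ("arrival", r.arrival_doy)):
                if d is None or not np.isfinite(d):
                    continue
                rows.append({"species": r.species, "group": r.group,
                             "season": r.season, "endpoint": endpoint,
                             "individual_id": r.individual_id,
                             "year": str(r.year), "date": float(d)})
    else:
        for ev in events:
            for endpoint, date in (("departure", ev.departure_date),
                                   ("arrival", ev.arrival_date)):
                if date is None:
                    continue
                rows.append({"species": ev.species, "group": ev.group,
                             "season": ev.season, "endpoint": endpoint,
                             "individual_id": ev.individual_id,
                             "year": str(ev.year), "date": doy(date)})
    df = pd.DataFrame(rows)
    out = {}
    for (season, endpoint), sub in df.groupby(["season", "endpoint"]):
        n_species = sub["species"].nunique()
        n_groups = sub["group"].nunique()
        if n_species < 2 and n_groups < 2:
            continue
        cells = sub.groupby(["species", "group"]).size()
        aliased = len(cells) <= max(n_species, n_groups)
        terms = []
        if n_species > 1 and not (aliased and n_groups >= n_species):
            terms.append("C(species)")
        if n_groups > 1 and not (aliased and n_species > n_groups):
            terms.append("C(group)")
        if len(terms) == 2 and (len(cells) < n_species * n_groups
                                or (cells < 2).any()):
            formula = "date ~ " + " + ".join(terms)
            log.warning("compare_migration_dates: %s %s: unreplicated cells, "
                        "interaction dropped", season, endpoint)
        else:
            formula = "date ~ " + " * ".join(terms)
        use_year = sub["year"].nunique() > 1
        groups = sub["year"] if use_year else sub["individual_id"]
        vc = {"individual": "0 + C(individual_id)"} if use_year else None
        res = None
        try:
            if groups.value_counts().max() == 1:
                # singleton groups: the random intercept is confounded with
                # the residual and mixed-model SEs are unreliable
                raise ValueError("singleton random-effect groups")
            model = MixedLM.from_formula(formula, groups=groups,
                                         vc_formula=vc, data=sub)
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=False, method="lbfgs", maxiter=500,
                                disp=False)
                if not np.all(np.isfinite(np.asarray(res.bse_fe))):
                    res = None
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is None:
            # single observation per random-effect group: the mixed model is
            # unidentifiable, plain least squares is the correct reduction
            import statsmodels.formula.api as smf
            res = smf.ols(formula, data=sub).fit()
            log.info("compare_migration_dates: %s %s: random intercepts "
                     "unidentifiable, OLS fallback", season, endpoint)
        entry = {"model": res, "formula": formula, "n": len(sub)}
        has_sp = "C(species)" in formula
        has_gr = "C(group)" in formula
        if has_sp:
            entry["species_contrasts"] = emm_tukey(
                res, sub, "species", within="group" if has_gr else None)
        if has_gr:
            entry["group_contrasts"] = emm_tukey(
                res, sub, "group", within="species" if has_sp else None)
        out[(season, endpoint)] = entry
    return out
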