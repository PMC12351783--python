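"""Mixed-model machinery.

* :func:`fit_lmm` — Gaussian linear mixed model of observed node dates on
  predicted onset dates (random intercept + slope for individuals nested
  within year), maximum likelihood via :mod:`statsmodels`, with a
  documented fallback chain for singular fits.
* :func:`fit_glmm_logistic` — logistic mixed model with a random intercept
  per group, marginal likelihood integrated by adaptive Gauss-Hermite
  quadrature (the Laplace mode plus curvature-scaled quadrature nodes) and
  maximized directly; yields ML coefficients, observed-information
  covariance, AIC and Nakagawa R-squared.
* :func:`posterior_sim` — draws from the multivariate-normal approximation
  to the joint posterior of the coefficients (the standard `arm::sim`
  device) for percentile CIs and significance flags.
* :func:`compute_vif` — iterative variance-inflation-factor screening.
* :func:`emm_tukey` — estimated marginal means with studentized-range
  (Tukey) adjusted pairwise contrasts.

Fixed-effect p-values use the normal (Wald) approximation throughout; all
Gaussian fits use ML rather than REML so AIC comparisons are valid.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.stats.outliers_influence import variance_inflation_factor

log = logging.getLogger("phenosurf")


class SmallSampleError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    pass


class SeparationError(ValueError):
    pass


@dataclass
class LmmFit:
    """Fixed effects with Wald inference plus variance components."""

    names: list
    params: np.ndarray
    bse: np.ndarray
    vcov: np.ndarray
    conf_int: np.ndarray          # (p, 2)
    pvalues: np.ndarray
    cov_re: np.ndarray
    resid_var: float
    group_desc: str
    fallbacks: list = field(default_factory=list)
    n_obs: int = 0
    n_groups: int = 0
    converged: bool = True
    singular: bool = False
    loglik: float = np.nan

    @property
    def slope(self) -> float:
        return float(self.params[1])

    @property
    def intercept(self) -> float:
        return float(self.params[0])


def _wald(params, bse, alpha=0.05):
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ci = np.column_stack([params - z * bse, params + z * bse])
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(params / bse))
    return ci, p


def _is_singular(res, tol=1e-4) -> bool:
    cov = np.atleast_2d(np.asarray(res.cov_re))
    if cov.size == 0:
        return False
    scale = max(float(res.scale), 1e-12)
    eig = np.linalg.eigvalsh(cov / scale)
    return bool(eig.min() < tol)


def fit_lmm(data: pd.DataFrame, response: str = "dobs", predictor: str = "dpre",
            individual: str = "individual_id", year: str = "year",
            alpha: float = 0.05, min_n: int = 5) -> LmmFit:
    """ML linear mixed model ``response ~ predictor`` with random slopes.

    Individuals are nested within migration year (each individual-year is a
    random-effect group carrying its own intercept and slope); when every
    individual has single-year data the nesting collapses to individual
    alone.  On a singular fit the random structure is simplified stepwise —
    drop the slope-intercept correlation, then the random slope, then the
    nesting — recording each fallback taken.
    """
    df = data[[response, predictor, individual, year]].dropna()
    n = len(df)
    if n < min_n:
        raise SmallSampleError(f"only {n} usable rows (need >= {min_n})")
    x = df[predictor].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    if np.ptp(x) < 1e-12:
        raise RankDeficiencyError("predictor is constant")
    X = np.column_stack([np.ones(n), x])

    # perfect linear fit: variance components are all zero, return OLS
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if np.var(resid) < 1e-18:
        vcov = np.zeros((2, 2))
        ci = np.column_stack([beta, beta])
        return LmmFit(["intercept", predictor], beta, np.zeros(2), vcov, ci,
                      np.zeros(2), np.zeros((2, 2)), 0.0, "degenerate:ols",
                      ["perfect_fit_ols"], n, df[individual].nunique(),
                      True, False, np.inf)

    multi_year = df.groupby(individual)[year].nunique().max() > 1
    if multi_year:
        groups = (df[year].astype(str) + ":" + df[individual].astype(str)).to_numpy()
        gdesc = "individual_in_year"
    else:
        groups = df[individual].astype(str).to_numpy()
        gdesc = "individual"

    fallbacks: list[str] = []
    attempts = [("full", groups, gdesc, X, None),
                ("diag", groups, gdesc, X,
                 MixedLMParams.from_components(fe_params=np.ones(2),
                                               cov_re=np.eye(2))),
                ("intercept_only", groups, gdesc, None, None)]
    if multi_year:
        attempts.append(("no_nesting", df[individual].astype(str).to_numpy(),
                         "individual", None, None))

    chosen = usable = None
    for tag, grp, desc, exog_re, free in attempts:
        try:
            model = MixedLM(y, X, groups=grp,
                            exog_re=exog_re if exog_re is not None
                            else np.ones((n, 1)))
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=False, free=free, method="lbfgs",
                                maxiter=500, disp=False)
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                finite = np.all(np.isfinite(np.asarray(res.bse_fe)))
            if finite and res.converged and not _is_singular(res):
                chosen = (res, desc)
                break
            if finite and usable is None:
                usable = (res, desc)
            fallbacks.append(tag)
        except Exception as exc:  # singular Hessian etc.
            fallbacks.append(f"{tag}:{type(exc).__name__}")
            continue
    if chosen is None and usable is not None:
        chosen = usable
    if chosen is not None:
        res, gdesc = chosen
        params = np.asarray(res.fe_params)
        bse = np.asarray(res.bse_fe)
        ci, p = _wald(params, bse, alpha)
        return LmmFit(["intercept", predictor], params, bse,
                      np.asarray(res.cov_params())[:2, :2], ci, p,
                      np.atleast_2d(np.asarray(res.cov_re)), float(res.scale),
                      gdesc, fallbacks, n, len(np.unique(groups)),
                      bool(res.converged), _is_singular(res), float(res.llf))
    # terminal fallback: zero random variance, plain least squares
    fallbacks.append("ols")
    ols = sm.OLS(y, X).fit()
    params = np.asarray(ols.params)
    bse = np.asarray(ols.bse)
    ci, p = _wald(params, bse, alpha)
    return LmmFit(["intercept", predictor], params, bse,
                  np.asarray(ols.cov_params()), ci, p, np.zeros((1, 1)),
                  float(ols.scale), "ols", fallbacks, n,
                  int(df[individual].nunique()), True, False, float(ols.llf))


# ---------------------------------------------------------------------------
# logistic GLMM with scalar random intercept
# ---------------------------------------------------------------------------

@dataclass
class GlmmFit:
    names: list
    params: np.ndarray            # fixed effects
    bse: np.ndarray
    vcov: np.ndarray              # fixed-effect block of inverse information
    sigma_u: float                # random-intercept SD
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan
    var_fixed: float = np.nan
    x_means: Optional[pd.Series] = None   # standardization info, set by callers
    x_sds: Optional[pd.Series] = None

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        """Population-level probabilities (random effects at zero)."""
        return expit(np.asarray(X, dtype=float) @ self.params)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(15)


def _glmm_loglik(theta, X, y, gidx, n_groups):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature."""
    beta = theta[:-1]
    sigma = np.exp(theta[-1])
    eta0 = X @ beta
    u = np.zeros(n_groups)
    # Newton for the per-group posterior mode of the random intercept
    for _ in range(30):
        p = expit(eta0 + u[gidx])
        g = np.bincount(gidx, weights=y - p, minlength=n_groups) - u / sigma ** 2
        h = -np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) \
            - 1.0 / sigma ** 2
        step = g / h
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(eta0 + u[gidx])
    h = np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma ** 2
    tau = 1.0 / np.sqrt(h)
    # adaptive GH: nodes centred on the mode, scaled by the curvature
    nodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * _GH_NODES[None, :]
    # log integrand at each node
    ll = np.zeros((n_groups, _GH_NODES.size))
    for k in range(_GH_NODES.size):
        eta = eta0 + nodes[gidx, k]
        contrib = y * eta - np.logaddexp(0.0, eta)
        ll[:, k] = np.bincount(gidx, weights=contrib, minlength=n_groups)
    ll += stats.norm.logpdf(nodes, scale=sigma)
    ll += _GH_NODES[None, :] ** 2 + np.log(_GH_WEIGHTS)[None, :]
    ll += 0.5 * np.log(2.0) + np.log(tau)[:, None]
    m = ll.max(axis=1)
    return float(np.sum(m + np.log(np.sum(np.exp(ll - m[:, None]), axis=1))))


def _numeric_hessian(f, x, eps=1e-4):
    n = x.size
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            h[i, j] = h[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps ** 2)
    return h


def fit_glmm_logistic(X, y, groups, names: Optional[Sequence[str]] = None,
                      maxiter: int = 300) -> GlmmFit:
    """ML logistic mixed model with a random intercept per group.

    ``groups`` identifies the random-effect clusters (individuals nested
    within year are encoded as their interaction).  Raises
    :class:`SeparationError` when the outcome is degenerate or the
    fixed-effect fit diverges (complete separation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.min() == y.max():
        raise SeparationError("outcome has a single class")
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]

    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    with np.errstate(all="ignore"), _warnings.catch_warnings(record=True) as wrec:
        _warnings.simplefilter("always")
        try:
            start = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            beta0 = np.asarray(start.params)
        except Exception:
            beta0 = np.zeros(X.shape[1])
    if any(issubclass(w.category, PerfectSeparationWarning) for w in wrec):
        raise SeparationError("complete or quasi-complete separation")
    if np.max(np.abs(beta0)) > 50.0:
        raise SeparationError("complete or quasi-complete separation")
    theta0 = np.append(beta0, np.log(0.5))

    def nll(theta):
        return -_glmm_loglik(theta, X, y, codes, n_groups)

    res = minimize(nll, theta0, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-8})
    theta = res.x
    if np.max(np.abs(theta[:-1])) > 50.0:
        raise SeparationError("diverging coefficients (separation)")
    hess = _numeric_hessian(nll, theta)
    try:
        vcov_full = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov_full = np.linalg.pinv(hess)
    p = X.shape[1]
    vcov = vcov_full[:p, :p]
    bse = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    ll = -res.fun
    k = p + 1
    sigma_u = float(np.exp(theta[-1]))
    fit = GlmmFit(names, theta[:p], bse, vcov, sigma_u, ll,
                  2.0 * k - 2.0 * ll, len(y), n_groups, bool(res.success))
    fit.var_fixed = float(np.var(X @ fit.params))
    fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit)
    return fit


def nakagawa_r2(fit: GlmmFit) -> tuple[float, float]:
    """Marginal / conditional R-squared for a logistic mixed model.

    Latent-scale decomposition: fixed-effect variance over fixed + random +
    distribution variance, with the logistic distribution variance
    ``pi^2 / 3``; the conditional version adds the random variance to the
    numerator.
    """
    var_f = fit.var_fixed
    var_r = fit.sigma_u ** 2
    var_d = np.pi ** 2 / 3.0
    total = var_f + var_r + var_d
    if total <= 0:
        return np.nan, np.nan
    return var_f / total, (var_f + var_r) / total


def posterior_sim(fit, n_draws: int = 2000, seed: int = 0):
    """Simulate coefficient draws from the normal posterior approximation.

    Returns ``(draws, summary)`` where summary is a DataFrame of posterior
    means, percentile 95 % CIs and a significance flag (CI excluding zero).
    """
    params = np.asarray(fit.params, dtype=float)
    vcov = np.asarray(fit.vcov, dtype=float)
    # repair non-positive-definite covariances by eigenvalue clipping
    w, v = np.linalg.eigh((vcov + vcov.T) / 2.0)
    if w.min() < 0:
        log.warning("posterior_sim: clipping %d negative eigenvalues",
                    int((w < 0).sum()))
        w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    rng = np.random.default_rng(seed)
    draws = params + rng.standard_normal((n_draws, params.size)) @ root.T
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    summary = pd.DataFrame({
        "name": list(fit.names), "estimate": params,
        "mean": draws.mean(axis=0), "ci_low": lo, "ci_high": hi,
        "significant": (lo > 0) | (hi < 0),
    })
    return draws, summary


def compute_vif(design: pd.DataFrame, limit: float = 10.0):
    """Iterative VIF screening.

    Regress each predictor on the others; drop the worst offender until
    every VIF is below ``limit``.  Perfectly collinear pairs produce
    infinite VIFs; the later column is dropped first (deterministic
    tie-break).  Returns ``(vif_table, retained_columns, drop_order)``.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors")
    work = design.dropna().astype(float)
    if len(work) <= len(cols):
        raise ValueError("need more rows than predictors")
    drop_order = []
    while True:
        X = np.column_stack([np.ones(len(work))] +
                            [work[c].to_numpy() for c in cols])
        with np.errstate(all="ignore"):
            vifs = np.array([variance_inflation_factor(X, i + 1)
                             for i in range(len(cols))])
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        if len(cols) <= 1 or np.nanmax(vifs) < limit:
            break
        worst = np.max(vifs)
        # later column wins the tie-break
        idx = max(i for i, v in enumerate(vifs) if v == worst)
        drop_order.append(cols[idx])
        cols = [c for i, c in enumerate(cols) if i != idx]
    table = pd.DataFrame({"predictor": cols, "vif": vifs[:len(cols)]}) \
        if len(cols) > 1 else pd.DataFrame({"predictor": cols,
                                            "vif": [1.0] * len(cols)})
    return table, cols, drop_order


# ---------------------------------------------------------------------------
# estimated marginal means with Tukey adjustment
# ---------------------------------------------------------------------------

def emm_tukey(result, data: pd.DataFrame, factor: str,
              within: Optional[str] = None, df_resid: Optional[float] = None
              ) -> pd.DataFrame:
    """Pairwise Tukey-adjusted contrasts of estimated marginal means.

    ``result`` is a formula-fitted statsmodels result (MixedLM or OLS)
    whose design contains categorical ``factor`` (and possibly other
    factors, averaged over with balanced weights).  When ``within`` is
    given, contrasts of ``factor`` are computed separately inside each
    level of ``within``, each family Tukey-adjusted on its own.
    """
    from patsy import build_design_matrices

    design_info = result.model.data.design_info
    factors = [factor] + ([within] if within else [])
    other = [c for c in _categorical_terms(design_info) if c not in factors]

    levels = {c: sorted(pd.unique(data[c].astype(str))) for c in factors + other}
    for c, lv in levels.items():
        if len(lv) < 1:
            raise ValueError(f"factor {c} has no levels")

    params = np.asarray(result.fe_params if hasattr(result, "fe_params")
                        else result.params)
    vcov = np.asarray(result.cov_params())[:params.size, :params.size]
    if df_resid is None:
        df_resid = max(float(result.nobs) - params.size, 2.0)

    def emm_row(assign: dict) -> np.ndarray:
        """Design row for one cell, averaged over unassigned factors."""
        free = [c for c in levels if c not in assign]
        rows = []
        for combo in itertools.product(*[levels[c] for c in free]):
            d = dict(assign, **dict(zip(free, combo)))
            frame = pd.DataFrame({c: [v] for c, v in d.items()})
            (m,) = build_design_matrices([design_info], frame)
            rows.append(np.asarray(m)[0][:params.size])
        return np.mean(rows, axis=0)

    families = [None] if within is None else levels[within]
    out = []
    for fam in families:
        base = {} if fam is None else {within: fam}
        sub = data if fam is None else data[data[within].astype(str) == fam]
        fam_levels = sorted(pd.unique(sub[factor].astype(str)))
        if len(fam_levels) < 2:
            log.warning("emm_tukey: family %s has < 2 levels, skipped", fam)
            continue
        k = len(fam_levels)
        rows = {lv: emm_row(dict(base, **{factor: lv})) for lv in fam_levels}
        for a, b in itertools.combinations(fam_levels, 2):
            l = rows[a] - rows[b]
            est = float(l @ params)
            se = float(np.sqrt(l @ vcov @ l))
            if se <= 0:
                pval, q = (0.0, np.inf) if abs(est) > 0 else (1.0, 0.0)
            else:
                q = abs(est) / se * np.sqrt(2.0)
                pval = float(stats.studentized_range.sf(q, k, df_resid))
            out.append({"family": fam if fam is not None else "all",
                        "level_1": a, "level_2": b, "estimate": est,
                        "se": se, "p_adjusted": min(max(pval, 0.0), 1.0)})
    return pd.DataFrame(out)


def _categorical_terms(design_info) -> list:
    names = []
    for f in design_info.factor_infos.values():
        if f.type == "categorical":
            # factor code looks like C(species) or species
            code = f.factor.name()
            inner = code[2:-1] if code.startswith("C(") else code
            names.append(inner.split(",")[0].strip())
    return names
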