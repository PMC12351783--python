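"""NDVI land-surface phenology: smoothing, season fitting, date extraction.

The per-pixel pipeline is two-stage, the standard remote-sensing recipe:

1. **Weighted Whittaker smoothing** of the 16-day composites — penalized
   least squares minimizing ``sum w_i (y_i - z_i)^2 + lambda * sum
   (D^order z)^2``, robust to dropouts via zero weights.
2. An **asymmetric Gaussian season model** fitted to the smoothed curve,

   ``f(t) = v0 + A * exp(-|(t - t_p)/sigma_L|^{k_L})`` for ``t < t_p``,
   mirrored with ``(sigma_R, k_R)`` on the right — a flexible local model
   for a single growing season whose width and flatness differ between
   green-up and senescence.

Dates are read off the fitted curve:

* ``SOS``/``EOS`` — the days the curve reaches 50 % of the annual
  amplitude on the rising / falling limb (threshold method);
* ``Greenup``/``Dormancy`` — the first local maximum / last local minimum
  of the rate of change (inflection method), computed analytically from
  the season parameters where the exponent allows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares
from scipy.sparse.linalg import spsolve

from .config import AnalysisConfig


def whittaker_smooth(y, lam: float = 100.0, order: int = 2,
                     weights=None) -> np.ndarray:
    """Weighted Whittaker smoother on an evenly spaced series.

    Missing points should carry zero weight.  ``lam -> 0`` returns the data;
    for very large ``lam`` with ``order=2`` the result tends to the weighted
    least-squares straight line.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    if np.all(w == 0):
        raise ValueError("all weights are zero")
    if n < order + 2:
        raise ValueError(f"need at least order + 2 = {order + 2} points")
    d = sp.eye(n, format="csc")
    for _ in range(order):
        d = d[1:] - d[:-1]
    a = sp.diags(w) + lam * (d.T @ d)
    z = spsolve(a.tocsc(), w * np.nan_to_num(y))
    return np.asarray(z)


@dataclass
class SeasonFit:
    """Fitted asymmetric Gaussian season for one pixel-year."""

    v0: float
    amplitude: float
    peak_day: float
    sigma_left: float
    k_left: float
    sigma_right: float
    k_right: float
    rmse: float
    success: bool

    @property
    def params(self) -> np.ndarray:
        return np.array([self.v0, self.amplitude, self.peak_day,
                         self.sigma_left, self.k_left,
                         self.sigma_right, self.k_right])

    def predict(self, t) -> np.ndarray:
        return _ag_curve(self.params, np.asarray(t, dtype=float))

    def derivative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        h = 0.05
        return (self.predict(t + h) - self.predict(t - h)) / (2.0 * h)


def _ag_curve(p, t):
    v0, a, tp, sl, kl, sr, kr = p
    u = np.where(t < tp, np.abs((t - tp) / sl), np.abs((t - tp) / sr))
    k = np.where(t < tp, kl, kr)
    return v0 + a * np.exp(-np.power(u, k))


def fit_asymmetric_gaussian(t, y, max_starts: int = 4) -> SeasonFit:
    """Nonlinear least-squares fit of the asymmetric Gaussian season model.

    Initialization is taken from the curve itself (peak position, half-max
    crossing distances) with a small grid of starting exponents; the best
    converged start by RMSE wins.  A fit that never converges is returned
    with ``success=False``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 7:
        return SeasonFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, np.inf, False)
    v0 = float(np.min(y))
    a0 = float(np.max(y) - v0)
    tp0 = float(t[np.argmax(y)])
    if a0 <= 0:
        return SeasonFit(v0, 0.0, tp0, np.nan, np.nan, np.nan, np.nan,
                         0.0, False)
    half = v0 + 0.5 * a0
    left = t[(t < tp0) & (y < half)]
    right = t[(t > tp0) & (y < half)]
    # half-max offset -> sigma for k=2: sigma = offset / sqrt(ln 2)
    sl0 = (tp0 - left[-1]) / np.sqrt(np.log(2.0)) if left.size else 30.0
    sr0 = (right[0] - tp0) / np.sqrt(np.log(2.0)) if right.size else 30.0
    sl0 = float(np.clip(sl0, 5.0, 150.0))
    sr0 = float(np.clip(sr0, 5.0, 150.0))

    lower = [v0 - abs(a0), 1e-6, t[0] - 30.0, 2.0, 1.2, 2.0, 1.2]
    upper = [v0 + abs(a0), 3.0 * a0 + 1.0, t[-1] + 30.0, 250.0, 8.0, 250.0, 8.0]

    def resid(p):
        return _ag_curve(p, t) - y

    best = None
    for k_start in (2.0, 3.0, 1.5, 4.0)[:max_starts]:
        p0 = np.array([v0, a0, tp0, sl0, k_start, sr0, k_start])
        p0 = np.clip(p0, lower, upper)
        try:
            res = least_squares(resid, p0, bounds=(lower, upper),
                                method="trf", xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, max_nfev=2000)
        except Exception:
            continue
        rmse = float(np.sqrt(np.mean(res.fun ** 2)))
        if res.success and (best is None or rmse < best[1]):
            best = (res.x, rmse)
    if best is None:
        return SeasonFit(v0, a0, tp0, sl0, 2.0, sr0, 2.0, np.inf, False)
    p, rmse = best
    return SeasonFit(*[float(v) for v in p], rmse=rmse, success=True)


@dataclass
class PhenoDates:
    """The four season dates of one pixel-year (None where missing)."""

    SOS: Optional[float] = None
    EOS: Optional[float] = None
    Greenup: Optional[float] = None
    Dormancy: Optional[float] = None
    qc_flag: Optional[str] = None


def extract_threshold_dates(fit: SeasonFit,
                            level: float = 0.5) -> tuple[Optional[float],
                                                         Optional[float]]:
    """SOS / EOS: days the curve reaches ``level`` of the amplitude.

    For the asymmetric Gaussian the crossing is closed-form:
    ``t_p -+ sigma * (ln(1/level))^(1/k)`` on each limb.
    """
    if not fit.success or not np.isfinite(fit.amplitude) or fit.amplitude <= 0:
        return None, None
    g = np.log(1.0 / level)
    sos = fit.peak_day - fit.sigma_left * g ** (1.0 / fit.k_left)
    eos = fit.peak_day + fit.sigma_right * g ** (1.0 / fit.k_right)
    return float(sos), float(eos)


def _inflection_offset(sigma: float, k: float) -> Optional[float]:
    """Offset from the peak of the extremum of df/dt on one limb.

    Setting the second derivative of ``exp(-u^k)`` to zero gives
    ``u* = ((k - 1)/k)^(1/k)`` for ``k > 1``; below that the rate of change
    has no interior extremum on the limb.
    """
    if k <= 1.0:
        return None
    return float(sigma * ((k - 1.0) / k) ** (1.0 / k))


def extract_inflection_dates(fit: SeasonFit,
                             grid_step: float = 0.1
                             ) -> tuple[Optional[float], Optional[float]]:
    """Greenup / Dormancy: extrema of the fitted curve's rate of change.

    Analytic where the limb exponent exceeds 1; otherwise located
    numerically on a fine daily grid.  Returns ``(None, None)`` when the
    derivative is numerically flat everywhere.
    """
    if not fit.success or not np.isfinite(fit.amplitude) or fit.amplitude <= 0:
        return None, None
    off_l = _inflection_offset(fit.sigma_left, fit.k_left)
    off_r = _inflection_offset(fit.sigma_right, fit.k_right)
    greenup = None if off_l is None else fit.peak_day - off_l
    dormancy = None if off_r is None else fit.peak_day + off_r
    if greenup is None or dormancy is None:
        t = np.arange(fit.peak_day - 6.0 * fit.sigma_left,
                      fit.peak_day + 6.0 * fit.sigma_right, grid_step)
        d = fit.derivative(t)
        if np.max(np.abs(d)) < 1e-12:
            return None, None
        if greenup is None:
            left = t < fit.peak_day
            greenup = float(t[left][np.argmax(d[left])])
        if dormancy is None:
            right = t >= fit.peak_day
            dormancy = float(t[right][np.argmin(d[right])])
    return float(greenup), float(dormancy)


def qc_filter_pheno(dates: PhenoDates, annual_mean_ndvi: float,
                    config: Optional[AnalysisConfig] = None) -> PhenoDates:
    """Spring-anomaly and low-NDVI exclusions.

    A pixel-year is blanked (all four dates set missing) when spring
    phenology is anomalous — SOS or Greenup before ``doy_min``, after
    ``doy_max``, or later than the corresponding autumn date — or when the
    annual mean NDVI falls below the low-vegetation cutoff.
    """
    config = config or AnalysisConfig()
    flag = None
    if annual_mean_ndvi < config.ndvi_min_annual_mean:
        flag = "low_ndvi"
    for spring, autumn in ((dates.SOS, dates.EOS), (dates.Greenup, dates.Dormancy)):
        if flag:
            break
        if spring is None:
            continue
        if spring < config.doy_min:
            flag = "spring_before_doy_min"
        elif spring > config.doy_max:
            flag = "spring_after_doy_max"
        elif autumn is not None and spring > autumn:
            flag = "spring_after_autumn"
    if flag:
        return PhenoDates(None, None, None, None, qc_flag=flag)
    return dates


def pixel_phenology(dates, values, year: int,
                    config: Optional[AnalysisConfig] = None
                    ) -> Optional[PhenoDates]:
    """Full per-pixel pipeline for one year; None when the fit fails."""
    config = config or AnalysisConfig()
    dates = np.asarray(dates, dtype="datetime64[D]")
    years = dates.astype("datetime64[Y]").astype(int) + 1970
    sel = years == year
    if sel.sum() < 12:
        return None
    start = np.datetime64(f"{year}-01-01")
    t = (dates[sel] - start).astype("timedelta64[D]").astype(float) + 1.0
    y = np.asarray(values, dtype=float)[sel]
    w = np.isfinite(y).astype(float)
    if w.sum() < 12:
        return None
    smoothed = whittaker_smooth(y, lam=config.whittaker_lambda,
                                order=config.whittaker_order, weights=w)
    fit = fit_asymmetric_gaussian(t, smoothed)
    if not fit.success:
        return None
    sos, eos = extract_threshold_dates(fit, config.ndvi_amplitude_threshold)
    greenup, dormancy = extract_inflection_dates(fit)
    out = PhenoDates(sos, eos, greenup, dormancy)
    annual_mean = float(np.nanmean(y))
    return qc_filter_pheno(out, annual_mean, config)
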