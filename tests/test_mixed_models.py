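"""Statistical engine: LMM, logistic GLMM, posterior sim, VIF, R2, EMMs."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from phenosurf.mixed_models import (GlmmFit, RankDeficiencyError,
                                    SeparationError, SmallSampleError,
                                    compute_vif, emm_tukey, fit_glmm_logistic,
                                    fit_lmm, nakagawa_r2, posterior_sim)


def _lmm_frame(y, x, ind, year=2021):
    return pd.DataFrame({"dobs": y, "dpre": x, "individual_id": ind,
                         "year": year})


class TestFitLmm:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(60, 120, 12)
        df = _lmm_frame(3.0 + x, x, [f"i{k}" for k in range(12)])
        fit = fit_lmm(df)
        assert fit.intercept == pytest.approx(3.0, abs=1e-9)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-12)

    def test_zero_random_variance_matches_ols(self, rng):
        # group effects exactly zero: residuals are projected out of each
        # group's {1, x} span, so the ML variance components sit on the
        # boundary and the GLS fit collapses to OLS
        n = 60
        x = rng.uniform(0, 10, n)
        e = rng.normal(0, 1.0, n)
        ind = np.repeat([f"i{k}" for k in range(20)], 3)
        for g in np.unique(ind):
            m = ind == g
            Zg = np.column_stack([np.ones(m.sum()), x[m]])
            e[m] -= Zg @ np.linalg.lstsq(Zg, e[m], rcond=None)[0]
        y = 2.0 + 0.8 * x + e
        fit = fit_lmm(_lmm_frame(y, x, ind))
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.params, beta, atol=1e-6)

    def test_single_year_uses_individual_grouping(self, rng):
        n = 40
        x = rng.uniform(0, 10, n)
        ind = np.repeat([f"i{k}" for k in range(20)], 2)
        u = dict(zip([f"i{k}" for k in range(20)], rng.normal(0, 2, 20)))
        y = 1 + x + np.array([u[i] for i in ind]) + rng.normal(0, 1, n)
        fit = fit_lmm(_lmm_frame(y, x, ind))
        assert fit.group_desc == "individual"

    def test_multi_year_nests_individuals_in_year(self, rng):
        n_ind, n_per = 12, 3
        rows = []
        for year in (2020, 2021):
            for k in range(n_ind):
                x = rng.uniform(0, 10, n_per)
                rows.append(pd.DataFrame({
                    "dobs": 1 + x + rng.normal(0, 2) + rng.normal(0, 1, n_per),
                    "dpre": x, "individual_id": f"i{k}", "year": year}))
        fit = fit_lmm(pd.concat(rows))
        assert fit.group_desc in ("individual_in_year", "individual", "ols")

    def test_constant_predictor_rejected(self):
        df = _lmm_frame(np.arange(10.0), np.full(10, 5.0),
                        [f"i{k}" for k in range(10)])
        with pytest.raises(RankDeficiencyError):
            fit_lmm(df)

    def test_small_sample_refused(self):
        df = _lmm_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.1], ["a", "b", "c"])
        with pytest.raises(SmallSampleError):
            fit_lmm(df)


class TestFitGlmm:
    def test_single_class_outcome_rejected(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        with pytest.raises(SeparationError):
            fit_glmm_logistic(X, np.zeros(50), np.repeat(np.arange(10), 5))

    def test_separation_detected(self):
        x = np.concatenate([-np.ones(20), np.ones(20)])
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        with pytest.raises(SeparationError):
            fit_glmm_logistic(X, y, np.repeat(np.arange(8), 5))

    def test_moderate_recovery(self, rng):
        n_g, n_i = 150, 12
        g = np.repeat(np.arange(n_g), n_i)
        x = rng.normal(0, 1, n_g * n_i)
        eta = -1.0 + 1.0 * x + rng.normal(0, 0.5, n_g)[g]
        y = (rng.random(n_g * n_i) < expit(eta)).astype(float)
        fit = fit_glmm_logistic(np.column_stack([np.ones_like(x), x]), y, g)
        assert fit.params[0] == pytest.approx(-1.0, abs=0.25)
        assert fit.params[1] == pytest.approx(1.0, abs=0.2)
        assert fit.converged


class TestLme4CrossCheck:
    """Independent oracle: identical fits from R lme4 on the same data."""

    def test_lmm_matches_lmer_ml(self, tmp_path):
        rng = np.random.default_rng(11)
        n_g, n_i = 30, 4
        g = np.repeat(np.arange(n_g), n_i)
        x = rng.uniform(0, 10, n_g * n_i)
        u0 = rng.normal(0, 3, n_g)
        u1 = rng.normal(0, 0.3, n_g)
        y = 2 + x + u0[g] + u1[g] * x + rng.normal(0, 1, n_g * n_i)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        csv = tmp_path / "lmm.csv"
        df.to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(lme4));'
             f'd<-read.csv("{csv}");'
             f'm<-lmer(y~x+(1+x|g),data=d,REML=FALSE);'
             f'cat(fixef(m),logLik(m))'],
            capture_output=True, text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        b0, b1, ll = map(float, r.stdout.split())
        fit = fit_lmm(df.rename(columns={"y": "dobs", "x": "dpre",
                                         "g": "individual_id"})
                      .assign(year=2021))
        assert fit.intercept == pytest.approx(b0, rel=1e-3)
        assert fit.slope == pytest.approx(b1, rel=1e-3)
        assert fit.loglik == pytest.approx(ll, abs=0.01)

    def test_glmm_matches_glmer_agq(self, tmp_path):
        rng = np.random.default_rng(43)
        n_g, n_i = 80, 10
        g = np.repeat(np.arange(n_g), n_i)
        x = rng.normal(0, 1, n_g * n_i)
        eta = -1.0 + 1.2 * x + rng.normal(0, 0.8, n_g)[g]
        y = (rng.random(n_g * n_i) < expit(eta)).astype(int)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(lme4));'
             f'd<-read.csv("{csv}");'
             f'm<-glmer(y~x+(1|g),data=d,family=binomial,nAGQ=15);'
             f'cat(fixef(m),sqrt(unlist(VarCorr(m))),logLik(m))'],
            capture_output=True, text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        b0, b1, sd_u, ll = map(float, r.stdout.split())
        X = np.column_stack([np.ones(len(x)), x])
        fit = fit_glmm_logistic(X, y, g)
        assert fit.params[0] == pytest.approx(b0, rel=1e-3, abs=1e-3)
        assert fit.params[1] == pytest.approx(b1, rel=1e-3)
        assert fit.sigma_u == pytest.approx(sd_u, rel=1e-2)
        assert fit.loglik == pytest.approx(ll, abs=0.01)


class TestPosteriorSim:
    def _fit(self, params, vcov):
        params = np.asarray(params, dtype=float)
        f = GlmmFit([f"b{i}" for i in range(len(params))], params,
                    np.sqrt(np.diag(vcov)), np.asarray(vcov, float), 0.5,
                    -10.0, 26.0, 100, 10, True)
        return f

    def test_vcov_zero_limit_degenerate(self):
        fit = self._fit([1.5, -0.3], np.zeros((2, 2)))
        draws, summary = posterior_sim(fit, n_draws=500, seed=1)
        np.testing.assert_allclose(draws,
                                   np.broadcast_to([1.5, -0.3], (500, 2)))
        assert summary["significant"].tolist() == [True, True]

    def test_n_draws_honored(self):
        fit = self._fit([1.0], [[0.04]])
        draws, _ = posterior_sim(fit, n_draws=2000, seed=2)
        assert draws.shape == (2000, 1)

    def test_percentile_ci_matches_wald_large_draws(self):
        fit = self._fit([2.0], [[0.25]])
        _, summary = posterior_sim(fit, n_draws=100000, seed=3)
        lo, hi = 2.0 - 1.96 * 0.5, 2.0 + 1.96 * 0.5
        assert summary.ci_low[0] == pytest.approx(lo, abs=0.02)
        assert summary.ci_high[0] == pytest.approx(hi, abs=0.02)

    def test_non_pd_vcov_repaired(self):
        fit = self._fit([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])  # indefinite
        draws, _ = posterior_sim(fit, n_draws=100, seed=4)
        assert np.all(np.isfinite(draws))


class TestVif:
    def test_orthogonal_predictors_unit_vif(self, rng):
        n = 400
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        b -= a * (a @ b) / (a @ a)     # exactly orthogonal
        table, cols, dropped = compute_vif(pd.DataFrame({"a": a, "b": b}))
        assert dropped == []
        assert np.allclose(table.vif, 1.0, atol=0.02)

    def test_exact_duplicate_later_column_dropped(self, rng):
        a = rng.normal(size=100)
        table, cols, dropped = compute_vif(pd.DataFrame({"x1": a, "x2": a}))
        assert dropped == ["x2"] and cols == ["x1"]

    def test_closed_form_correlated_pair(self, rng):
        # VIF = 1/(1-r^2); construct exact sample correlation r = 0.9
        n = 1000
        a = rng.normal(size=n)
        e = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        e -= a * (a @ e) / (a @ a)
        e = (e - e.mean()) / e.std()
        r = 0.9
        b = r * a + np.sqrt(1 - r ** 2) * e
        table, cols, dropped = compute_vif(pd.DataFrame({"a": a, "b": b}),
                                           limit=100.0)
        expected = 1.0 / (1.0 - r ** 2)
        assert np.allclose(table.vif, expected, atol=1e-6)
        assert expected == pytest.approx(5.263, abs=1e-3)

    def test_iterative_retention_terminates_below_limit(self, rng):
        n = 300
        base = rng.normal(size=(n, 2))
        df = pd.DataFrame({
            "a": base[:, 0], "b": base[:, 0] * 0.99 + 0.01 * rng.normal(size=n),
            "c": base[:, 1], "d": base[:, 1] * 0.995 + 0.01 * rng.normal(size=n),
            "e": rng.normal(size=n)})
        table, cols, dropped = compute_vif(df, limit=10.0)
        assert len(cols) >= 1
        assert np.all(table.vif < 10.0)


class TestNakagawa:
    def _fit(self, var_fixed, sigma_u):
        f = GlmmFit(["b"], np.array([1.0]), np.array([0.1]),
                    np.array([[0.01]]), sigma_u, -1.0, 4.0, 100, 10, True)
        f.var_fixed = var_fixed
        return f

    def test_zero_random_variance_conditional_equals_marginal(self):
        m, c = nakagawa_r2(self._fit(2.0, 0.0))
        assert m == pytest.approx(c)

    def test_null_model_marginal_zero(self):
        m, c = nakagawa_r2(self._fit(0.0, 1.0))
        assert m == 0.0 and c > 0.0

    def test_formula_oracle(self):
        var_f, var_u = 2.0, 1.0
        m, c = nakagawa_r2(self._fit(var_f, np.sqrt(var_u)))
        denom = var_f + var_u + np.pi ** 2 / 3.0
        assert m == pytest.approx(var_f / denom, abs=1e-6)
        assert c == pytest.approx((var_f + var_u) / denom, abs=1e-6)

    def test_conditional_never_below_marginal(self, rng):
        for _ in range(20):
            m, c = nakagawa_r2(self._fit(rng.uniform(0, 5), rng.uniform(0, 2)))
            assert c >= m


class TestEmmTukey:
    @staticmethod
    def _ols(df):
        import statsmodels.formula.api as smf
        return smf.ols("date ~ C(species)", data=df).fit()

    def test_two_level_tukey_equals_wald(self, rng):
        n = 200
        df = pd.DataFrame({
            "species": np.repeat(["GG", "SG"], n // 2),
            "date": np.concatenate([rng.normal(80, 3, n // 2),
                                    rng.normal(84, 3, n // 2)])})
        res = self._ols(df)
        out = emm_tukey(res, df, "species", df_resid=1e6)
        z = abs(out.estimate[0]) / out.se[0]
        assert out.p_adjusted[0] == pytest.approx(2 * norm.sf(z), rel=1e-3)

    def test_identical_groups_zero_contrast(self):
        df = pd.DataFrame({"species": ["GG"] * 4 + ["SG"] * 4,
                           "date": [80.0] * 8})
        res = self._ols(df)
        out = emm_tukey(res, df, "species")
        assert out.estimate[0] == pytest.approx(0.0, abs=1e-10)

    def test_shift_recovered_and_significant(self, rng):
        n = 30
        df = pd.DataFrame({
            "species": np.repeat(["GG", "SG"], n),
            "date": np.concatenate([rng.normal(70, 3, n),
                                    rng.normal(80, 3, n)])})
        res = self._ols(df)
        out = emm_tukey(res, df, "species")
        assert abs(out.estimate[0]) == pytest.approx(10.0, abs=1.5)
        assert out.p_adjusted[0] < 0.05

    def test_balanced_emm_with_two_factors(self, rng):
        df = pd.DataFrame({
            "species": np.tile(np.repeat(["GG", "SG"], 10), 2),
            "group": np.repeat(["C", "E"], 20),
            "date": rng.normal(80, 2, 40)})
        df.loc[df.species == "SG", "date"] += 5.0
        import statsmodels.formula.api as smf
        res = smf.ols("date ~ C(species) * C(group)", data=df).fit()
        out = emm_tukey(res, df, "species", within="group")
        assert set(out.family) == {"C", "E"}
        for est in out.estimate:
            assert abs(est) == pytest.approx(5.0, abs=2.5)
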