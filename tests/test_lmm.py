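"""Mixed-model engine: GLS limits, AR(1) structure, AICc, predictions."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from fluxtrend.lmm import (
    LMMSpec,
    aicc,
    build_design,
    fit_lmm,
    predict_lmm,
    profile_loglik,
)
from fluxtrend.lmm import _ar1_corr


def dense_ar1_gls_ml(years, y):
    """Independent oracle: single-series AR(1)-GLS maximum likelihood.

    Profiles beta (intercept + centered-year slope) and sigma2 by GLS at
    each phi, optimizing phi by dense-matrix computation.
    """
    years = np.asarray(years, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), years - years.mean()])
    dy = np.abs(years[:, None] - years[None, :])

    def neg2ll(phi):
        R = np.power(abs(phi), dy) * np.where(dy.astype(int) % 2 == 0, 1.0, np.sign(phi))
        np.fill_diagonal(R, 1.0)
        Ri = np.linalg.inv(R)
        beta = np.linalg.solve(X.T @ Ri @ X, X.T @ Ri @ y)
        r = y - X @ beta
        sigma2 = float(r @ Ri @ r) / n
        _, logdet = np.linalg.slogdet(R)
        return n * (np.log(2 * np.pi * sigma2)) + logdet + n

    res = minimize_scalar(neg2ll, bounds=(-0.95, 0.95), method="bounded",
                          options={"xatol": 1e-10})
    return -0.5 * res.fun


class TestFitLMM:
    def test_degenerate_limit_equals_ols(self, synth):
        panel = synth.panel
        spec = LMMSpec(
            response="NEP", fixed_terms=("year", "CO2"),
            random_intercept=False, random_slope=False, ar1=False, reml=False,
        )
        fit = fit_lmm(panel, spec)
        X = np.column_stack(
            [panel["year"] - panel["year"].mean(), panel["CO2"]]
        )
        ols = sm.OLS(panel["NEP"], sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-6)

    def test_single_site_ar1_gls_oracle(self):
        rng = np.random.default_rng(21)
        years = np.arange(1995, 2012, dtype=float)
        e = np.zeros(len(years))
        e[0] = rng.normal()
        for t in range(1, len(e)):
            e[t] = 0.5 * e[t - 1] + rng.normal() * 0.8
        y = 3.0 + 1.2 * (years - years.mean()) + e
        panel = pd.DataFrame({"site": "only", "year": years, "y": y})
        spec = LMMSpec(
            response="y", fixed_terms=("year",),
            random_intercept=False, random_slope=False, ar1=True, reml=False,
        )
        fit = fit_lmm(panel, spec)
        assert fit.loglik == pytest.approx(dense_ar1_gls_ml(years, y), abs=1e-6)

    def test_gapped_years_use_year_distance(self):
        # AR(1) correlation across a gap must be phi^gap, not phi^1
        dy = np.abs(
            np.array([1995.0, 1996.0, 1999.0])[:, None]
            - np.array([1995.0, 1996.0, 1999.0])[None, :]
        )
        R = _ar1_corr(0.6, dy)
        expected = np.array(
            [[1.0, 0.6, 0.6**4], [0.6, 1.0, 0.6**3], [0.6**4, 0.6**3, 1.0]]
        )
        np.testing.assert_allclose(R, expected)
        R_neg = _ar1_corr(-0.6, dy)
        np.testing.assert_allclose(
            R_neg,
            np.array(
                [[1.0, -0.6, (-0.6) ** 4], [-0.6, 1.0, (-0.6) ** 3],
                 [(-0.6) ** 4, (-0.6) ** 3, 1.0]]
            ),
        )

    def test_optimum_dominates_true_parameters(self, synth):
        spec = LMMSpec(response="NEP", fixed_terms=("year",), reml=False)
        fit = fit_lmm(synth.panel, spec)
        cfg = synth.config
        true_g0 = (cfg.random_intercept_sd / cfg.resid_sd["NEP"]) ** 2
        true_g1 = (cfg.random_slope_sd["NEP"] / cfg.resid_sd["NEP"]) ** 2
        at_truth = profile_loglik(
            synth.panel, spec, true_g0, true_g1, cfg.resid_ar1
        )
        assert fit.loglik >= at_truth - 1e-8

    def test_fixed_term_order_invariance(self, anomaly_panel):
        s1 = LMMSpec(response="NEP_an", fixed_terms=("CO2_an", "Sdep_an"), reml=False)
        s2 = LMMSpec(response="NEP_an", fixed_terms=("Sdep_an", "CO2_an"), reml=False)
        f1, f2 = fit_lmm(anomaly_panel, s1), fit_lmm(anomaly_panel, s2)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        b1 = dict(zip(f1.term_names, f1.beta))
        b2 = dict(zip(f2.term_names, f2.beta))
        for k in b1:
            assert b1[k] == pytest.approx(b2[k], abs=1e-8)

    def test_reml_ml_agree_on_beta_single_balanced_group(self):
        rng = np.random.default_rng(3)
        years = np.arange(2000, 2012, dtype=float)
        y = 5.0 + 0.4 * (years - years.mean()) + rng.normal(size=len(years))
        panel = pd.DataFrame({"site": "g", "year": years, "y": y})
        kw = dict(response="y", fixed_terms=("year",),
                  random_intercept=False, random_slope=False, ar1=False)
        f_ml = fit_lmm(panel, LMMSpec(reml=False, **kw))
        f_reml = fit_lmm(panel, LMMSpec(reml=True, **kw))
        np.testing.assert_allclose(f_ml.beta, f_reml.beta, atol=1e-8)

    def test_requires_two_sites_for_random_effects(self, toy_panel):
        single = toy_panel[toy_panel["site"] == "A"]
        with pytest.raises(ValueError):
            fit_lmm(single, LMMSpec(response="NEP", fixed_terms=("year",)))

    def test_variance_recovery_on_synthetic_panel(self):
        # pooled check across independent panels: estimates of the random
        # slope SD and phi should land near the generating values
        import fluxtrend as ft

        slopes_sd, phis = [], []
        for seed in range(4):
            cfg = ft.SimulationConfig(seed=seed, site_span=(18, 20))
            sp = ft.generate_panel(cfg)
            fit = fit_lmm(sp.panel, LMMSpec(response="NEP", fixed_terms=("year",)))
            slopes_sd.append(np.sqrt(fit.var_slope))
            phis.append(fit.phi)
        assert abs(np.mean(slopes_sd) - 5.0) < 2.5
        assert abs(np.mean(phis) - 0.3) < 0.25


class TestAgainstRNlme:
    def test_matches_nlme_lme_with_corar1(self, synth, tmp_path):
        """Independent oracle: R nlme::lme with pdDiag random effects and
        corAR1 on the same panel."""
        panel = synth.panel.copy()
        panel["yearc"] = panel["year"] - panel["year"].mean()
        csv = tmp_path / "panel.csv"
        panel[["site", "year", "yearc", "NEP"]].to_csv(csv, index=False)
        rcode = f"""
suppressMessages(library(nlme))
d <- read.csv("{csv}")
m <- lme(NEP ~ yearc, random = list(site = pdDiag(~ yearc)), data = d,
         correlation = corAR1(form = ~ year | site), method = "ML",
         control = lmeControl(maxIter = 200, msMaxIter = 200, opt = "optim"))
cat(fixef(m)["yearc"], coef(m$modelStruct$corStruct, unconstrained = FALSE),
    as.numeric(logLik(m)), sep = "\\n")
"""
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        r_slope, r_phi, r_ll = (float(v) for v in out.stdout.split())
        fit = fit_lmm(panel, LMMSpec(response="NEP", fixed_terms=("year",), reml=False))
        slope, _ = fit.fixed_effect("year")
        assert slope == pytest.approx(r_slope, rel=1e-3)
        assert fit.phi == pytest.approx(r_phi, abs=5e-3)
        assert fit.loglik == pytest.approx(r_ll, abs=0.01)


class TestPredict:
    def test_training_data_noise_free(self, linear_panel):
        spec = LMMSpec(
            response="NEP_an", fixed_terms=("CO2_an",),
            random_intercept=False, random_slope=False, ar1=False, reml=False,
        )
        fit = fit_lmm(linear_panel, spec)
        pred = predict_lmm(fit, linear_panel)
        np.testing.assert_allclose(
            pred["prediction"], linear_panel["NEP_an"], atol=1e-8
        )

    def test_intercept_only_predicts_grand_mean(self, toy_panel):
        spec = LMMSpec(
            response="NEP", fixed_terms=(),
            random_intercept=False, random_slope=False, ar1=False, reml=False,
        )
        fit = fit_lmm(toy_panel, spec)
        pred = predict_lmm(fit, toy_panel)
        assert pred["prediction"].iloc[0] == pytest.approx(toy_panel["NEP"].mean())

    def test_linearity_in_covariate(self, anomaly_panel):
        spec = LMMSpec(response="NEP_an", fixed_terms=("CO2_an", "Sdep_an"), reml=False)
        fit = fit_lmm(anomaly_panel, spec)
        beta = dict(zip(fit.term_names, fit.beta))["CO2_an"]
        a = anomaly_panel.head(10).copy()
        b = a.copy()
        b["CO2_an"] = b["CO2_an"] + 2.5
        pa = predict_lmm(fit, a)["prediction"]
        pb = predict_lmm(fit, b)["prediction"]
        np.testing.assert_allclose(pb - pa, 2.5 * beta, atol=1e-10)

    def test_unseen_site_flagged_with_zero_random_part(self, synth):
        spec = LMMSpec(response="NEP", fixed_terms=("year",), reml=False)
        fit = fit_lmm(synth.panel, spec)
        new = synth.panel.head(3).copy()
        new["site"] = "never-seen"
        pred = predict_lmm(fit, new, include_random=True)
        assert pred["unseen_site"].all()
        fixed_only = predict_lmm(fit, new, include_random=False)
        np.testing.assert_allclose(pred["prediction"], fixed_only["prediction"])


class TestAICc:
    def test_formula_arithmetic(self, toy_panel):
        # AIC = 100, k = 3, n = 20 -> 100 + 2*3*4/16 = 101.5
        spec = LMMSpec(
            response="NEP", fixed_terms=("year",),
            random_intercept=False, random_slope=False, ar1=False, reml=False,
        )
        fit = fit_lmm(toy_panel, spec)
        fit.loglik = -47.0  # AIC = 94 + 6 = 100 with k=3
        fit.n_obs = 20
        assert fit.k_params == 3  # intercept + slope + sigma2
        assert aicc(fit) == pytest.approx(101.5)

    def test_undefined_when_n_too_small(self, toy_panel):
        spec = LMMSpec(
            response="NEP", fixed_terms=("year",),
            random_intercept=False, random_slope=False, ar1=False, reml=False,
        )
        fit = fit_lmm(toy_panel, spec)
        fit.n_obs = 4
        with pytest.raises(ValueError):
            aicc(fit)

    def test_bic_formula(self, toy_panel):
        spec = LMMSpec(
            response="NEP", fixed_terms=("year",),
            random_intercept=False, random_slope=False, ar1=False, reml=False,
        )
        fit = fit_lmm(toy_panel, spec)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.k_params * np.log(fit.n_obs)
        )

    def test_penalty_grows_with_k(self):
        def penalty(k, n=30):
            return 2 * k + 2 * k * (k + 1) / (n - k - 1)

        assert all(penalty(k + 1) > penalty(k) for k in range(1, 10))
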