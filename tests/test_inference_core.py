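"""Estimation-machinery tests: standardization, VIF, and the four fitters.

The Gaussian random-intercept LMM and the Laplace binomial GLMM are
implemented in-package; statsmodels MixedLM and R lme4 (glmer/lmer) serve as
independent cross-checks on small simulated datasets.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from flamingotrack.inference_core import (
    Cat,
    Cont,
    Interaction,
    ModelSpec,
    SeparationError,
    build_design,
    diagnostics,
    fit_glm,
    fit_glmm_binomial,
    fit_lm,
    fit_lmm,
    marginal_r2,
    standardize,
    vif_screen,
    vif_table,
)


class TestStandardize:
    def test_hand_arithmetic(self):
        out, rec = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["x"], [-1.0, 0.0, 1.0])
        assert rec["x"] == (2.0, 1.0)  # sample SD of (1,2,3) is 1

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1)
        out, _ = standardize(pd.DataFrame({"x": x}))
        assert np.allclose(out["x"], x, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out, rec = standardize(pd.DataFrame({"x": [5.0] * 10, "y": [1.0, 2.0] * 5}))
        assert "x" not in out.columns and rec["x"][1] == 0.0


class TestVif:
    def test_orthogonal_predictors_all_one(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(100, 3))
        q, _ = np.linalg.qr(z - z.mean(axis=0))  # centred => orthogonal to intercept
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        vifs = vif_table(X)
        assert np.allclose(vifs.values, 1.0, atol=1e-8)
        kept, _ = vif_screen(X)
        assert set(kept) == {"a", "b", "c"}

    def test_duplicated_predictor_removed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        kept, hist = vif_screen(X)
        assert len(kept) == 2 and "c" in kept
        assert np.isinf(hist["vif"].max())

    def test_vif_matches_one_over_one_minus_r2(self):
        # r^2 = 0.96 between x1 and x2 -> VIF = 1/(1-0.96) = 25
        rng = np.random.default_rng(3)
        n = 4000
        x1 = rng.normal(size=n)
        x2 = np.sqrt(0.96) * x1 + np.sqrt(0.04) * rng.normal(size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        vifs = vif_table(X)
        assert vifs["x1"] == pytest.approx(25.0, rel=0.15)
        kept, _ = vif_screen(X, threshold=3.0)
        assert len(kept) == 1


class TestDesign:
    def test_quadratic_accompanies_linear(self):
        df = pd.DataFrame({"y": np.arange(6.0), "x": [0.0, 1, 2, 3, 4, 5]})
        d = build_design(df, ModelSpec("y", [Cont("x", quadratic=True)]))
        assert "x" in d.columns and "x^2" in d.columns
        assert d.term_blocks["x"] != d.term_blocks["x^2"]

    def test_single_level_factor_reported_aliased(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "g": ["a"] * 4, "x": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning):
            fit = fit_lm(ModelSpec("y", [Cat("g"), Cont("x")]), df)
        assert any(f.startswith("aliased:g") for f in fit.flags)

    def test_reference_level_excluded(self):
        df = pd.DataFrame(
            {"y": np.arange(6.0), "colony": ["Comacchio", "Molentargius", "Margherita"] * 2}
        )
        d = build_design(df, ModelSpec("y", [Cat("colony", ref="Comacchio")]))
        assert "colony[Comacchio]" not in d.columns
        assert {"colony[Margherita]", "colony[Molentargius]"} <= set(d.columns)


class TestLm:
    def test_exact_ols_recovery_vs_normal_equations(self):
        rng = np.random.default_rng(4)
        n = 300
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 1.5 + 2.0 * x1 - 0.7 * x2 + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = fit_lm(ModelSpec("y", [Cont("x1"), Cont("x2")]), df, standardize_continuous=False)
        X = np.column_stack([np.ones(n), x1, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # normal-equations oracle
        assert np.allclose(fit.params.values, beta, atol=1e-8)

    def test_identical_response_gives_zero_slopes(self):
        df = pd.DataFrame({"y": [3.0] * 12, "g": ["a", "b", "c"] * 4})
        fit = fit_lm(ModelSpec("y", [Cat("g")]), df)
        assert np.allclose(fit.params.values[1:], 0.0, atol=1e-12)


class TestGlm:
    def test_poisson_recovery_and_dispersion(self):
        rng = np.random.default_rng(5)
        covered = 0
        disp = []
        for _ in range(50):
            n = 500
            x = rng.normal(size=n)
            y = rng.poisson(np.exp(1.0 + 0.5 * x))
            df = pd.DataFrame({"y": y, "x": x})
            fit = fit_glm(
                ModelSpec("y", [Cont("x")], family="poisson"), df, standardize_continuous=False
            )
            if fit.ci_low["x"] <= 0.5 <= fit.ci_high["x"]:
                covered += 1
            disp.append(fit.dispersion)
        assert covered >= 45
        assert 0.8 <= np.mean(disp) <= 1.2

    def test_single_class_response_raises(self):
        df = pd.DataFrame({"y": [0.0] * 20, "x": np.arange(20.0)})
        with pytest.raises(SeparationError):
            fit_glm(ModelSpec("y", [Cont("x")], family="binomial"), df)


def _sim_lmm(rng, n_groups=30, per=20, tau=5.0, sigma=10.0, beta=(10.0, 2.0)):
    g = np.repeat(np.arange(n_groups), per)
    x = rng.normal(size=n_groups * per)
    u = rng.normal(0, tau, n_groups)
    y = beta[0] + beta[1] * x + u[g] + rng.normal(0, sigma, n_groups * per)
    return pd.DataFrame({"y": y, "x": x, "bird": g})


class TestLmm:
    def test_zero_between_group_variance_matches_ols(self):
        rng = np.random.default_rng(6)
        df = _sim_lmm(rng, tau=0.0)
        lmm = fit_lmm(ModelSpec("y", [Cont("x")], group="bird"), df, standardize_continuous=False)
        ols = fit_lm(ModelSpec("y", [Cont("x")]), df, standardize_continuous=False)
        assert np.allclose(lmm.params.values, ols.params.values, atol=1e-4)
        assert lmm.group_var < 1.0

    def test_matches_statsmodels_mixedlm(self):
        rng = np.random.default_rng(7)
        df = _sim_lmm(rng)
        mine = fit_lmm(ModelSpec("y", [Cont("x")], group="bird"), df, standardize_continuous=False)
        ref = sm.MixedLM(df["y"], sm.add_constant(df["x"]), groups=df["bird"]).fit(reml=True)
        assert mine.params["Intercept"] == pytest.approx(ref.params["const"], abs=1e-4)
        assert mine.params["x"] == pytest.approx(ref.params["x"], abs=1e-4)
        assert mine.resid_var == pytest.approx(ref.scale, rel=1e-3)
        assert mine.group_var == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-2)

    def test_balanced_anova_method_of_moments(self):
        # balanced one-way design: REML intercept variance equals the ANOVA
        # method-of-moments estimate (MSB - MSW) / m
        rng = np.random.default_rng(8)
        G, m = 25, 12
        g = np.repeat(np.arange(G), m)
        u = rng.normal(0, 4.0, G)
        y = 3.0 + u[g] + rng.normal(0, 6.0, G * m)
        df = pd.DataFrame({"y": y, "bird": g})
        df["x"] = 0.0  # no fixed effects beyond intercept
        fit = fit_lmm(ModelSpec("y", [], group="bird"), df)
        ybar_g = df.groupby("bird")["y"].mean()
        msb = m * np.sum((ybar_g - df["y"].mean()) ** 2) / (G - 1)
        msw = np.sum((df["y"] - ybar_g[g].values) ** 2) / (G * (m - 1))
        mom = (msb - msw) / m
        assert fit.group_var == pytest.approx(mom, rel=1e-3)

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(9)
        df = _sim_lmm(rng, n_groups=30, per=20, tau=5.0, sigma=10.0)
        fit = fit_lmm(ModelSpec("y", [Cont("x")], group="bird"), df)
        assert np.sqrt(fit.group_var) == pytest.approx(5.0, rel=0.4)
        assert np.sqrt(fit.resid_var) == pytest.approx(10.0, rel=0.15)

    def test_satterthwaite_df_within_range(self):
        rng = np.random.default_rng(10)
        df = _sim_lmm(rng)
        fit = fit_lmm(ModelSpec("y", [Cont("x")], group="bird"), df)
        den = fit.term_table.set_index("term")["den_df"]["x"]
        assert 2.0 < den <= len(df) - 2


def _sim_glmm(rng, n_groups=150, per=15, sigma_u=1.0, beta=(-1.0, 0.8)):
    g = np.repeat(np.arange(n_groups), per)
    x = rng.normal(size=n_groups * per)
    u = rng.normal(0, sigma_u, n_groups)
    y = (rng.random(n_groups * per) < expit(beta[0] + beta[1] * x + u[g])).astype(float)
    return pd.DataFrame({"y": y, "x": x, "bird": g})


class TestGlmmBinomial:
    def test_fixed_zero_variance_matches_plain_logistic(self):
        rng = np.random.default_rng(11)
        df = _sim_glmm(rng, sigma_u=0.0)
        spec = ModelSpec("y", [Cont("x")], "binomial", group="bird")
        glmm = fit_glmm_binomial(spec, df, fix_sigma_zero=True)
        glm = fit_glm(ModelSpec("y", [Cont("x")], "binomial"), df)
        assert np.allclose(glmm.params.values, glm.params.values, atol=1e-4)
        assert glmm.group_var == 0.0

    def test_matches_lme4_glmer(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(12)
        df = _sim_glmm(rng)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        spec = ModelSpec("y", [Cont("x")], "binomial", group="bird")
        mine = fit_glmm_binomial(spec, df, standardize_continuous=False)
        rcode = (
            f"suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            f"m <- glmer(y ~ x + (1|bird), data=d, family=binomial);"
            f"cat(fixef(m), sqrt(unlist(VarCorr(m))), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        ).stdout.split()
        b0, b1, sd_u = map(float, out)
        assert mine.params["Intercept"] == pytest.approx(b0, abs=0.02)
        assert mine.params["x"] == pytest.approx(b1, abs=0.02)
        assert np.sqrt(mine.group_var) == pytest.approx(sd_u, abs=0.05)

    def test_all_zero_response_raises_separation(self):
        df = pd.DataFrame({"y": [0.0] * 40, "x": np.arange(40.0), "bird": [0, 1] * 20})
        with pytest.raises(SeparationError):
            fit_glmm_binomial(ModelSpec("y", [Cont("x")], "binomial", group="bird"), df)

    def test_loglik_of_nested_models_ordered(self):
        rng = np.random.default_rng(13)
        df = _sim_glmm(rng, n_groups=60, per=10)
        full = fit_glmm_binomial(ModelSpec("y", [Cont("x")], "binomial", group="bird"), df)
        assert full.loglik >= full.loglik_null - 1e-6


class TestDiagnostics:
    def test_single_df_wald_equals_squared_z(self):
        rng = np.random.default_rng(14)
        df = _sim_lmm(rng)
        fit = fit_lmm(ModelSpec("y", [Cont("x")], group="bird"), df)
        z2 = (fit.params["x"] / fit.se["x"]) ** 2
        wald = fit.term_table.set_index("term")["statistic"]["x"]
        assert wald == pytest.approx(z2, abs=1e-10)

    def test_type3_invariant_to_term_order(self):
        rng = np.random.default_rng(15)
        n = 400
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "g": rng.choice(["a", "b", "c"], n),
            }
        )
        df["y"] = 1 + 0.5 * df.x1 - 0.3 * df.x2 + (df.g == "b") * 0.7 + rng.normal(0, 1, n)
        f1 = fit_lm(ModelSpec("y", [Cont("x1"), Cont("x2"), Cat("g")]), df)
        f2 = fit_lm(ModelSpec("y", [Cat("g"), Cont("x2"), Cont("x1")]), df)
        t1 = f1.term_table.set_index("term")["statistic"]
        t2 = f2.term_table.set_index("term")["statistic"]
        for term in ("x1", "x2", "g"):
            assert t1[term] == pytest.approx(t2[term], rel=1e-9)

    def test_mcfadden_zero_for_null_model(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame({"y": rng.integers(0, 2, 200).astype(float)})
        fit = fit_glm(ModelSpec("y", [], family="binomial"), df)
        assert fit.mcfadden_r2() == pytest.approx(0.0, abs=1e-9)

    def test_semi_partial_near_zero_for_absent_predictor(self):
        rng = np.random.default_rng(17)
        n = 800
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["y"] = 2.0 * df.x1 + rng.normal(0, 1, n)  # x2 absent from truth
        spec = ModelSpec("y", [Cont("x1"), Cont("x2")])
        fit = fit_lm(spec, df)
        diag = diagnostics(fit, spec, df, fitter=fit_lm)
        assert abs(diag["semi_partial_r2"]["x2"]) < 0.02
        assert diag["semi_partial_r2"]["x1"] > 0.5

    def test_marginal_r2_partitions_variance(self):
        rng = np.random.default_rng(18)
        df = _sim_lmm(rng, tau=3.0, sigma=4.0, beta=(0.0, 5.0))
        spec = ModelSpec("y", [Cont("x")], group="bird")
        fit = fit_lmm(spec, df)
        r2 = marginal_r2(fit, spec, df)
        expected = 25.0 / (25.0 + 9.0 + 16.0)
        assert r2 == pytest.approx(expected, rel=0.2)


class TestInteraction:
    def test_continuous_interaction_recovered(self):
        rng = np.random.default_rng(19)
        n = 600
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 1 + x1 + x2 + 0.8 * x1 * x2 + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        spec = ModelSpec(
            "y", [Cont("x1"), Cont("x2"), Interaction(Cont("x1"), Cont("x2"))]
        )
        fit = fit_lm(spec, df, standardize_continuous=False)
        assert fit.params["x1:x2"] == pytest.approx(0.8, abs=0.15)

    def test_constant_interaction_component_aliased(self):
        df = pd.DataFrame(
            {"y": np.arange(8.0), "x": np.arange(8.0), "d": [1.0] * 8}
        )
        with pytest.warns(UserWarning):
            fit = fit_lm(
                ModelSpec("y", [Cont("x"), Cont("d"), Interaction(Cont("x"), Cont("d"))]),
                df,
            )
        assert any(f.startswith("aliased") for f in fit.flags)
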