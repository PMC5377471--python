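"""varIdent GLS: estimation, likelihood ratios, backward selection."""

import numpy as np
import pandas as pd
import pytest

from bioturbaton.gls import ModelSpec, backward_select, build_design, fit, lrt
from bioturbaton.synthetic import ExperimentDesign, make_experiment

TREATMENTS = ("HD", "HU", "CV", "Mix")
EQUAL_SIGMA = {t: 120.0 for t in TREATMENTS}


def two_group_data(seed, n_per_group=200, sd_ratio=3.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(["a", "b"], n_per_group)
    y = np.where(g == "a", rng.normal(0, 1, 2 * n_per_group), rng.normal(2, sd_ratio, 2 * n_per_group))
    return pd.DataFrame({"response": y, "grp": g})


class TestFit:
    def test_homoscedastic_equals_ols(self):
        import statsmodels.api as sm

        d = make_experiment(ExperimentDesign(seed=7), sigma_by_group=EQUAL_SIGMA)
        spec = ModelSpec("response", ("treatment", "core_shape"), None, "ML")
        f = fit(spec, d)
        X, _ = build_design(d, spec)
        ols = sm.OLS(d.response.to_numpy(), X).fit()
        assert np.allclose(f.beta, ols.params, atol=1e-8)
        assert f.logLik == pytest.approx(ols.llf, abs=1e-8)

    def test_reml_homoscedastic_matches_closed_form(self):
        d = make_experiment(ExperimentDesign(seed=3), sigma_by_group=EQUAL_SIGMA)
        spec = ModelSpec("response", ("treatment",), None, "REML")
        f = fit(spec, d)
        X, _ = build_design(d, spec)
        y = d.response.to_numpy()
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        ll = -0.5 * (n - p) * (np.log(2 * np.pi) + 1 - np.log(n - p) + np.log(rss))
        ll -= 0.5 * np.linalg.slogdet(X.T @ X)[1]
        assert f.logLik == pytest.approx(ll, abs=1e-8)

    def test_wls_identity_at_fixed_ratios(self):
        # at the optimum, fixed effects equal WLS with weights 1/ratio^2
        import statsmodels.api as sm

        d = two_group_data(0)
        spec = ModelSpec("response", ("grp",), "grp", "ML")
        f = fit(spec, d)
        X, _ = build_design(d, spec)
        w = np.where(d.grp == "a", 1.0, 1.0 / f.variance_ratios["b"] ** 2)
        wls = sm.WLS(d.response.to_numpy(), X, weights=w).fit()
        assert np.allclose(f.beta, wls.params, atol=1e-8)

    def test_sd_ratio_recovery(self):
        f = fit(ModelSpec("response", ("grp",), "grp", "REML"), two_group_data(12))
        assert 2.7 <= f.variance_ratios["b"] <= 3.3
        assert f.converged

    def test_small_design_mean_recovery_and_reference_invariance(self):
        means = {"HD": -486.79, "CV": -383.0, "Mix": -360.0, "HU": -347.0}
        sds = {"HD": 160.0, "CV": 90.0, "Mix": 70.0, "HU": 110.0}
        d = make_experiment(
            ExperimentDesign(core_shapes=("square",), replicates=100, seed=21),
            sigma_by_group=sds, mean_by_group=means,
        )
        spec = ModelSpec("response", ("treatment",), "treatment", "REML",
                         (("treatment", "HD"),))
        f = fit(spec, d)
        mu_hd = f.coefficients["(Intercept)"].estimate
        se_pool = max(sds.values()) / np.sqrt(100)
        assert abs(mu_hd - means["HD"]) < 2 * se_pool
        for t in ("CV", "Mix", "HU"):
            est = mu_hd + f.coefficients[f"treatment[{t}]"].estimate
            assert abs(est - means[t]) < 2 * 2 * se_pool
        # swapping the reference level changes coefficients, not the fit
        spec2 = ModelSpec("response", ("treatment",), "treatment", "REML",
                          (("treatment", "HU"),))
        f2 = fit(spec2, d)
        assert f2.coefficients["(Intercept)"].estimate != pytest.approx(mu_hd)
        assert f2.logLik == pytest.approx(f.logLik, abs=1e-6)
        assert np.allclose(np.sort(f2.fitted), np.sort(f.fitted), atol=1e-6)

    def test_aic_parameter_count(self):
        d = make_experiment(ExperimentDesign(seed=1), sigma_by_group=EQUAL_SIGMA)
        f = fit(ModelSpec("response", ("treatment",), "treatment", "ML"), d)
        # 4 fixed + 3 free ratios + sigma_ref
        assert f.AIC == pytest.approx(-2 * f.logLik + 2 * 8)
        assert all(0 <= c.p <= 1 for c in f.coefficients.values())

    def test_rank_deficient_design_named(self):
        d = make_experiment(ExperimentDesign(seed=1), sigma_by_group=EQUAL_SIGMA)
        d["dup"] = d["treatment"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit(ModelSpec("response", ("treatment", "dup"), None, "ML"), d)

    def test_variance_group_minimum_size(self):
        d = make_experiment(ExperimentDesign(seed=1), sigma_by_group=EQUAL_SIGMA)
        d = d[~((d.treatment == "HD") & (d.aquarium_id != "HD-square-01"))]
        with pytest.raises(ValueError, match="< 2 observations"):
            fit(ModelSpec("response", ("treatment",), "treatment", "ML"), d)


class TestLRT:
    def test_identical_models(self):
        d = make_experiment(ExperimentDesign(seed=2), sigma_by_group=EQUAL_SIGMA)
        f = fit(ModelSpec("response", ("treatment",), None, "ML"), d)
        res = lrt(f, f)
        assert res.L_ratio == 0.0 and res.p == 1.0

    def test_reml_with_different_fixed_effects_refused(self):
        d = make_experiment(ExperimentDesign(seed=2), sigma_by_group=EQUAL_SIGMA)
        full = fit(ModelSpec("response", ("treatment",), None, "REML"), d)
        red = fit(ModelSpec("response", (), None, "REML"), d)
        with pytest.raises(ValueError, match="REML"):
            lrt(full, red)

    def test_ml_fixed_effect_lrt_reported_with_df(self):
        # a 3-df species-identity deletion test, reported as L-ratio/df/p
        means = {"HD": -486.79, "CV": -383.0, "Mix": -360.0, "HU": -347.0}
        d = make_experiment(
            ExperimentDesign(core_shapes=("square",), replicates=5, seed=4),
            sigma_by_group=EQUAL_SIGMA, mean_by_group=means,
        )
        full = fit(ModelSpec("response", ("treatment",), None, "ML"), d)
        red = fit(ModelSpec("response", (), None, "ML"), d)
        res = lrt(full, red)
        assert res.df == 3
        assert res.L_ratio >= 0
        assert "d.f. = 3" in str(res)

    def test_variance_lrt_null_calibration(self, null_experiment):
        # equal sds: the varIdent-vs-homoscedastic REML LRT should rarely
        # clear the chi-square critical value (<= 10% over 200 seeds)
        from scipy import stats

        crit = stats.chi2.ppf(0.95, 3)
        n_reject = 0
        for seed in range(200):
            d = null_experiment(30_000 + seed)
            het = fit(ModelSpec("response", ("treatment",), "treatment", "REML"), d)
            hom = fit(ModelSpec("response", ("treatment",), None, "REML"), d)
            if 2 * (het.logLik - hom.logLik) > crit:
                n_reject += 1
        assert n_reject <= 20


class TestBackwardSelect:
    def test_intercept_only_start_unchanged(self, null_experiment):
        d = null_experiment(1)
        final, trace = backward_select(ModelSpec("response", (), None), d)
        assert final.spec.fixed_factors == ()
        assert len(trace) == 1

    def test_strong_factor_retained(self):
        means = {"HD": -486.79, "CV": -100.0, "Mix": -90.0, "HU": -80.0}
        kept = 0
        for seed in range(20):
            d = make_experiment(
                ExperimentDesign(core_shapes=("square",), replicates=5, seed=500 + seed),
                sigma_by_group={t: 60.0 for t in TREATMENTS}, mean_by_group=means,
            )
            final, _ = backward_select(
                ModelSpec("response", ("treatment",), "treatment"), d
            )
            kept += "treatment" in final.spec.fixed_factors
        assert kept >= 19

    def test_null_data_reaches_intercept_only(self, null_experiment):
        n_intercept = 0
        for seed in range(40):
            final, _ = backward_select(
                ModelSpec("response", ("treatment",), "treatment"),
                null_experiment(40_000 + seed),
            )
            n_intercept += final.spec.fixed_factors == ()
        assert n_intercept >= 32  # ~90% expected

    def test_trace_records_candidate_aics(self, null_experiment):
        final, trace = backward_select(
            ModelSpec("response", ("treatment",), "treatment"), null_experiment(3)
        )
        steps = {t["step"] for t in trace}
        assert "variance" in steps and "final" in steps
        assert any("AIC" in t for t in trace)

    def test_final_model_is_reml(self, null_experiment):
        final, _ = backward_select(
            ModelSpec("response", ("treatment",), "treatment"), null_experiment(5)
        )
        assert final.spec.estimation == "REML"


class TestRatioConsistency:
    def test_bias_shrinks_with_replication(self):
        # mean absolute log-ratio error must fall as group size grows
        errors = {}
        for n in (5, 50, 500):
            errs = []
            for seed in range(10):
                f = fit(
                    ModelSpec("response", ("grp",), "grp", "REML"),
                    two_group_data(1000 * n + seed, n_per_group=n),
                )
                errs.append(abs(np.log(f.variance_ratios["b"] / 3.0)))
            errors[n] = np.mean(errs)
        assert errors[500] < errors[50] < errors[5]
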