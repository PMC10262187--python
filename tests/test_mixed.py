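import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from chronopanel.mixed import (
    LmmSpec,
    fit_random_intercept,
    lr_chisq_test,
    run_biomarker_suite,
)


def _clustered_data(rng, n_groups=120, mean_size=2, beta=0.5, sigma_u=0.4, sigma_e=1.0):
    sizes = rng.integers(1, 2 * mean_size + 1, n_groups)
    g = np.repeat(np.arange(n_groups), sizes)
    n = len(g)
    x = rng.normal(size=n)
    w = rng.normal(size=n)
    u = rng.normal(0, sigma_u, n_groups)[g]
    y = 1.0 + beta * x + 0.3 * w + u + rng.normal(0, sigma_e, n)
    return pd.DataFrame({"y": y, "x": x, "w": w, "household_id": g})


class TestFitRandomIntercept:
    def test_matches_ols_when_no_cluster_variance(self):
        rng = np.random.default_rng(0)
        df = _clustered_data(rng, sigma_u=0.0, n_groups=300)
        spec = LmmSpec(outcome="y", exposures=["x"], covariates=["w"])
        fit = fit_random_intercept(spec, df)
        X = sm.add_constant(df[["x", "w"]])
        ols = sm.OLS(df["y"], X).fit()
        assert fit.coef("x") == pytest.approx(ols.params["x"], abs=1e-6)
        assert fit.coef("w") == pytest.approx(ols.params["w"], abs=1e-6)

    def test_balanced_anova_variance_components(self):
        """Balanced one-way layout: variance components match the classical
        method-of-moments ANOVA estimators."""
        rng = np.random.default_rng(1)
        n_groups, m = 200, 4
        g = np.repeat(np.arange(n_groups), m)
        u = rng.normal(0, 0.7, n_groups)[g]
        y = 2.0 + u + rng.normal(0, 1.0, len(g))
        df = pd.DataFrame({"y": y, "household_id": g})
        spec = LmmSpec(outcome="y", exposures=[], covariates=[])
        fit = fit_random_intercept(spec, df)  # REML
        ybar_g = df.groupby("household_id")["y"].mean().to_numpy()
        msb = m * np.sum((ybar_g - y.mean()) ** 2) / (n_groups - 1)
        msw = np.sum((y - ybar_g[g]) ** 2) / (n_groups * (m - 1))
        mom_u = (msb - msw) / m
        assert fit.sigma2_e == pytest.approx(msw, rel=0.02)
        assert fit.sigma2_u == pytest.approx(mom_u, rel=0.05)

    def test_planted_effect_recovered_within_2se(self):
        rng = np.random.default_rng(2)
        df = _clustered_data(rng, n_groups=600, beta=0.13)
        spec = LmmSpec(outcome="y", exposures=["x"], covariates=["w"])
        fit = fit_random_intercept(spec, df)
        assert abs(fit.coef("x") - 0.13) < 2 * fit.se("x")
        assert fit.converged

    def test_intercept_shift_only_changes_intercept(self):
        rng = np.random.default_rng(3)
        df = _clustered_data(rng)
        spec = LmmSpec(outcome="y", exposures=["x"], covariates=["w"])
        base = fit_random_intercept(spec, df)
        df2 = df.assign(y=df["y"] + 5.0)
        shifted = fit_random_intercept(spec, df2)
        assert shifted.coef("x") == pytest.approx(base.coef("x"), abs=1e-6)
        assert shifted.coef("intercept") == pytest.approx(base.coef("intercept") + 5.0, abs=1e-5)

    def test_collinear_terms_reported(self):
        rng = np.random.default_rng(4)
        df = _clustered_data(rng)
        df["x2"] = 2.0 * df["x"]
        spec = LmmSpec(outcome="y", exposures=["x"], covariates=["x2"])
        with pytest.raises(ValueError, match="x2"):
            fit_random_intercept(spec, df)

    def test_exposure_covariate_overlap_rejected(self):
        with pytest.raises(ValueError, match="both exposure and covariate"):
            LmmSpec(outcome="y", exposures=["x"], covariates=["x"])


class TestLrChisqTest:
    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(5)
        df = _clustered_data(rng)
        spec = LmmSpec(outcome="y", exposures=["x"], covariates=["w"], reml=False)
        fit = fit_random_intercept(spec, df)
        lr = lr_chisq_test(fit, fit)
        assert lr.statistic == pytest.approx(0.0, abs=1e-9)
        assert lr.p_value == 1.0

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(6)
        df = _clustered_data(rng, n_groups=400, beta=0.5)
        full = fit_random_intercept(
            LmmSpec(outcome="y", exposures=["x"], covariates=["w"], reml=False), df
        )
        null = fit_random_intercept(
            LmmSpec(outcome="y", exposures=[], covariates=["w"], reml=False), df
        )
        lr = lr_chisq_test(full, null)
        assert lr.df == 1
        assert lr.p_value < 1e-6

    def test_reml_fits_rejected(self):
        rng = np.random.default_rng(7)
        df = _clustered_data(rng)
        fit = fit_random_intercept(LmmSpec(outcome="y", exposures=["x"]), df)
        with pytest.raises(ValueError, match="ML"):
            lr_chisq_test(fit, fit)

    def test_row_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        df = _clustered_data(rng)
        spec = LmmSpec(outcome="y", exposures=["x"], reml=False)
        f1 = fit_random_intercept(spec, df)
        f2 = fit_random_intercept(spec, df.iloc[:-5])
        with pytest.raises(ValueError, match="different rows"):
            lr_chisq_test(f1, f2)


class TestSuite:
    def test_config_validated_before_fitting(self):
        df = pd.DataFrame({"CHL": [1.0], "household_id": [0]})
        with pytest.raises(KeyError, match="absent columns"):
            run_biomarker_suite(df, config={"CHL": {"exposures": ["SJL"], "covariates": []}})

    def test_suite_on_synthetic_cohort(self, default_dataset):
        from chronopanel.recovery import _derive_analysis_table

        table = _derive_analysis_table(default_dataset.cohort)
        suite, fits, lr = run_biomarker_suite(table)
        assert set(fits) == {"CHL", "LDL", "HDL", "TAG", "AIP"}
        chl = fits["CHL"]
        planted = default_dataset.config.biomarkers["CHL"].effects["SJL"]
        assert abs(chl.coef("SJL") - planted) < 2.5 * chl.se("SJL")
        assert chl.n_groups > 500
        assert all(v.df == 1 for v in lr.values())
        # exposures carry the planted signal: CHL LR test should be strong
        assert lr["CHL"].p_value < 0.01
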