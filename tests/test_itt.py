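"""ITT estimation: imputation, robust OLS, effect sizes, balance table."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import eegrct
from eegrct.itt import (
    balance_table,
    design_matrix,
    effect_size,
    fit_itt,
    impute_covariates,
    treatment_stats,
    two_proportion_z,
)


class TestImputation:
    def test_no_missing_is_identity(self, band_power_table):
        again = impute_covariates(band_power_table, band_power_table["id"])
        pd.testing.assert_frame_equal(again, band_power_table)

    def test_mean_imputation_arithmetic(self):
        co = pd.DataFrame(
            {
                "id": [0, 1, 2, 3],
                "hh_income": [10.0, 20.0, 30.0, np.nan],
                "arm": ["low"] * 4,
                "site": [1] * 4,
            }
        )
        out = impute_covariates(co, co["id"])
        assert out.loc[3, "hh_income"] == 20.0

    def test_analytic_mean_not_full_cohort_mean(self):
        """Attrition correlated with the covariate: the analytic-sample mean
        differs from the cohort mean and must be the one imputed."""
        co = pd.DataFrame(
            {
                "id": range(6),
                "hh_income": [10.0, 20.0, 30.0, 100.0, 200.0, np.nan],
                "arm": ["low"] * 6,
                "site": [1] * 6,
            }
        )
        out = impute_covariates(co, np.array([0, 1, 2, 5]))  # low-income analytic
        assert out.loc[5, "hh_income"] == 20.0  # not (10+20+30+100+200)/5 = 72

    def test_entirely_missing_covariate_errors(self):
        co = pd.DataFrame(
            {"id": [0, 1], "hh_income": [np.nan, np.nan], "arm": ["low", "high"], "site": [1, 1]}
        )
        with pytest.raises(ValueError, match="hh_income"):
            impute_covariates(co, co["id"])

    def test_categorical_missing_level(self):
        co = pd.DataFrame(
            {"id": [0, 1], "race_ethnicity": ["hispanic", None], "arm": ["low", "high"], "site": [1, 1]}
        )
        out = impute_covariates(co, co["id"])
        assert out.loc[1, "race_ethnicity"] == "missing"


class TestFit:
    def test_treatment_indicator_outcome_degenerate(self, band_power_table):
        """Regressing the treatment dummy on itself: coefficient exactly 1,
        robust SE collapses to ~0, standardized effect undefined (NaN)."""
        y = (band_power_table["arm"] == "high").astype(float)
        est = fit_itt(y, band_power_table, covariates=False, outcome_name="treat")
        assert est.coef_adjusted == pytest.approx(1.0, abs=1e-10)
        assert est.se_adjusted < 1e-8
        assert np.isnan(est.effect_size)

    def test_fast_path_matches_statsmodels(self, band_power_table):
        X0, treat = design_matrix(band_power_table, True)
        y = band_power_table["beta"].to_numpy(float)
        X = np.column_stack([treat, X0.to_numpy(float)])
        ref = sm.OLS(y, X).fit(cov_type="HC1", use_t=False)
        coef, se, t = treatment_stats(y, treat, X0.to_numpy(float))
        assert coef == pytest.approx(ref.params[0], abs=1e-8)
        assert se == pytest.approx(ref.bse[0], abs=1e-8)

    def test_null_pvalues_uniform(self):
        """Under no effect the robust-t p-values are uniform: rejection rate
        at 5% within its binomial interval over 500 replicates."""
        rng = np.random.default_rng(12)
        n = 300
        site = rng.integers(1, 5, n)
        X0 = np.column_stack([np.ones(n)] + [(site == s).astype(float) for s in (2, 3, 4)])
        from scipy import stats

        rejections = 0
        pvals = []
        for _ in range(500):
            treat = (rng.random(n) < 0.4).astype(float)
            y = rng.standard_normal(n)
            _, _, t = treatment_stats(y, treat, X0)
            p = 2 * stats.norm.sf(abs(t))
            pvals.append(p)
            rejections += p <= 0.05
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert 0.05 - 0.02 < rejections / 500 < 0.05 + 0.02

    def test_robust_close_to_classical_under_homoskedasticity(self):
        rng = np.random.default_rng(3)
        n = 435
        site = rng.integers(1, 5, n)
        treat = (rng.random(n) < 0.4).astype(float)
        y = 0.2 * treat + rng.standard_normal(n)
        X = np.column_stack(
            [treat, np.ones(n)] + [(site == s).astype(float) for s in (2, 3, 4)]
        )
        robust = sm.OLS(y, X).fit(cov_type="HC1", use_t=False).bse[0]
        classical = sm.OLS(y, X).fit().bse[0]
        assert abs(robust - classical) / classical < 0.10

    def test_site_fixed_effects_absorb_site_shifts(self, band_power_table):
        df = band_power_table.copy()
        base = fit_itt(df["beta"], df, covariates=True)
        df2 = df.copy()
        shift = (df2["site"] == 2).astype(float) * 50.0
        est2 = fit_itt(df2["beta"] + shift, df2, covariates=True, outcome_name="beta")
        assert est2.coef_adjusted == pytest.approx(base.coef_adjusted, abs=1e-8)

    def test_collinear_design_errors_with_columns(self, band_power_table):
        df = band_power_table.copy()
        df["net_worth"] = df["mother_age"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            fit_itt(df["beta"], df, covariates=True)

    def test_missing_outcome_rejected(self, band_power_table):
        y = band_power_table["beta"].copy()
        y.iloc[0] = np.nan
        with pytest.raises(ValueError, match="never imputed"):
            fit_itt(y, band_power_table)


class TestEffectSize:
    @pytest.mark.parametrize(
        "coef, sd, expected",
        [(0.414, 1.592, 0.26), (0.221, 0.947, 0.23), (0.720, 4.213, 0.17), (0.0, 2.0, 0.0)],
    )
    def test_standardization_arithmetic(self, coef, sd, expected):
        assert round(effect_size(coef, sd), 2) == expected

    def test_nonpositive_sd_error(self):
        with pytest.raises(ValueError):
            effect_size(1.0, 0.0)


class TestBalance:
    def test_identical_arms_give_null_pvalues(self):
        rng = np.random.default_rng(0)
        n = 400
        co = pd.DataFrame(
            {
                "id": range(n),
                "arm": ["low", "high"] * (n // 2),
                "site": rng.integers(1, 5, n),
                # period-4 patterns give both arms identical value multisets
                "child_female": np.tile([0, 0, 1, 1], n // 4),
                "child_age_months": np.tile([12.0, 12.0, 13.0, 13.0], n // 4),
                "mother_educ": np.tile([10.0, 10.0, 14.0, 14.0], n // 4),
                "hh_income": np.tile([1e4, 1e4, 3e4, 3e4], n // 4),
                "n_usable_epochs": np.tile([100, 100, 300, 300], n // 4),
                "in_eeg_sample": 1,
            }
        )
        bal = balance_table(co, co["id"], include_race=False)
        # arms are constructed identical: every difference is exactly zero
        assert np.allclose(bal["low_mean"], bal["high_mean"])
        assert (bal["p_value"] > 0.99).all()

    def test_two_proportion_oracle(self):
        """Hand-computed pooled z-test: x1=30/100 vs x2=10/50 → p = 0.1917."""
        assert two_proportion_z(30, 100, 10, 50) == pytest.approx(0.1917, abs=1e-3)

    def test_identical_proportions_p_one(self):
        assert two_proportion_z(20, 100, 10, 50) == pytest.approx(1.0)

    def test_balance_on_simulated_cohort(self, cohort):
        bal = balance_table(cohort, cohort.loc[cohort["in_eeg_sample"] == 1, "id"])
        assert {"variable", "low_mean", "high_mean", "p_value"} <= set(bal.columns)
        assert (bal["p_value"].dropna() >= 0).all() and (bal["p_value"].dropna() <= 1).all()


class TestRecovery:
    def test_effect_size_recovery_and_partial_power(self):
        """Replicated cohorts at the analytic sample sizes recover the
        injected standardized effects; power at 5% stays clearly below 1."""
        from eegrct.pipeline import recovery_study

        res = recovery_study(n_reps=60, seed=21)
        for band in eegrct.BAND_NAMES:
            row = res.loc[band]
            assert abs(row["mean_effect"] - row["injected"]) < 3 * row["mc_se"]
        assert 0.05 < res.loc["beta", "power"] < 0.95

    def test_covariate_adjustment_changes_but_does_not_bias(self, band_power_table):
        with_cov = fit_itt(band_power_table["beta"], band_power_table, covariates=True)
        without = fit_itt(band_power_table["beta"], band_power_table, covariates=False)
        # same estimand; finite-sample estimates differ but not wildly
        assert with_cov.coef_adjusted != without.coef_adjusted
        assert abs(with_cov.coef_adjusted - without.coef_adjusted) < 3 * without.se_adjusted
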