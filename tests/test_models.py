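import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import panelgxe as p
from panelgxe.errors import DataError
from panelgxe.models import ModelSpec, build_design
from panelgxe.synthetic import (EffectSpec, SnpSpec, make_visit_schedule,
                                simulate_exposure_series, simulate_genotypes,
                                simulate_panel_outcomes)


class TestMainModel:
    def test_recovers_planted_main_effect(self, analysis_panel):
        # dbp carries a pure main effect (0.62 per IQR, no interaction);
        # sbp's marginal slope includes the planted interaction times the
        # mean risk-allele count, so it is not 0.93
        fit = p.fit_main_model(analysis_panel,
                               ModelSpec(outcome="dbp", pollutant="pm10", lag=0))
        lo, hi = fit.conf_int(fit.pollutant_term)
        assert lo <= 0.62 <= hi
        assert fit.n_subjects == 400 and fit.n_obs == 2000

    def test_zero_variance_random_intercept_matches_ols(self):
        effect = EffectSpec(outcome="sbp", pollutant="pm10", main_effect=1.5,
                            random_intercept_sd=0.0, residual_sd=5.0)
        table = simulate_genotypes(300, [SnpSpec("s", "G", 0.3)], seed=21)
        series = simulate_exposure_series(760, seed=21)
        sched = make_visit_schedule(table.genotypes.index, seed=21)
        panel = simulate_panel_outcomes(table, series, sched, [effect], seed=21)
        panel = p.attach_lagged_exposures(p.prepare_outcomes(panel), series)
        spec = ModelSpec(outcome="sbp", pollutant="pm10", lag=0)
        fit = p.fit_main_model(panel, spec)
        y, X, _, _, _ = build_design(panel, spec)
        ols = sm.OLS(y, X).fit()
        assert fit.random_intercept_var == pytest.approx(0.0, abs=0.5)
        assert np.allclose(fit.params.to_numpy(), ols.params.to_numpy(),
                           rtol=1e-4, atol=1e-3)

    def test_per_iqr_equals_per_unit_times_iqr(self, analysis_panel):
        spec = ModelSpec(outcome="sbp", pollutant="pm10", lag=0)
        per_iqr = p.fit_main_model(analysis_panel, spec)
        per_unit = p.fit_main_model(
            analysis_panel, dataclasses.replace(spec, fixed_iqr=1.0))
        assert per_iqr.pollutant_estimate == pytest.approx(
            per_unit.pollutant_estimate * per_iqr.iqr, rel=1e-4)

    def test_aic_identity(self, analysis_panel):
        fit = p.fit_main_model(analysis_panel,
                               ModelSpec(outcome="sbp", pollutant="pm10", lag=1))
        k = len(fit.params) + 2
        assert fit.aic == pytest.approx(2 * k - 2 * fit.llf)

    def test_missing_columns_rejected(self, analysis_panel):
        with pytest.raises(DataError, match="missing columns"):
            p.fit_main_model(analysis_panel.drop(columns=["pm10_lag2"]),
                             ModelSpec(outcome="sbp", pollutant="pm10", lag=2))


class TestLagSelection:
    def test_recovers_strong_true_lag(self):
        from panelgxe.validation import lag_recovery
        out = lag_recovery(n_reps=25, seed=3, true_lag=2, beta_main=8.0)
        assert out["lag_recovery_rate"] >= 0.8

    def test_tie_breaks_to_smallest_lag(self):
        # series constant within 10-day plateaus; visits mid-plateau so
        # lags 0-3 carry identical values but the series is not degenerate
        n_days = 400
        values = np.repeat(np.linspace(20, 80, n_days // 10), 10)
        dates = pd.date_range("2008-07-01", periods=n_days, freq="D")
        series = pd.DataFrame({"date": dates, "pm10": values, "no2": values,
                               "so2": values, "mean_temp": 10.0, "dew_point": 5.0})
        table = simulate_genotypes(150, [SnpSpec("s", "G", 0.3)], seed=22)
        visit_dates = dates[np.arange(6, n_days, 80)][:5]
        sched = pd.DataFrame(
            [(s, v + 1, visit_dates[v]) for s in table.genotypes.index
             for v in range(5)], columns=["subject_id", "visit", "date"])
        effect = EffectSpec(outcome="sbp", pollutant="pm10", main_effect=2.0)
        panel = simulate_panel_outcomes(table, series, sched, [effect], seed=22)
        panel = p.attach_lagged_exposures(p.prepare_outcomes(panel), series)
        lag, table_aic = p.select_lag(panel, ModelSpec(outcome="sbp",
                                                       pollutant="pm10"))
        assert lag == 0
        assert table_aic["aic"].round(4).nunique() == 1

    def test_identical_observation_set_across_lags(self, analysis_panel):
        spec = ModelSpec(outcome="sbp", pollutant="pm10")
        _, table = p.select_lag(analysis_panel, spec)
        assert table["converged"].all()
        assert len(table) == 4


class TestSnpInteraction:
    def test_recovers_planted_interaction(self, analysis_panel, gxe_cohort):
        genotypes, _, _ = gxe_cohort
        spec = ModelSpec(outcome="sbp", pollutant="pm10", lag=0, snp_id="snp_b")
        res = p.test_snp_interaction(analysis_panel, genotypes, spec)
        lo, hi = res.fit.conf_int("snp_x_pollutant")
        assert lo <= 2.0 <= hi
        assert res.risk_allele_orientation == "minor_is_risk"
        assert res.p_interaction < 0.01

    def test_monomorphic_snp_skipped(self, analysis_panel, gxe_cohort):
        genotypes, _, _ = gxe_cohort
        mono = genotypes.genotypes.copy()
        mono["snp_d"] = 0.0
        table = type(genotypes)(mono, genotypes.snp_info.copy())
        spec = ModelSpec(outcome="sbp", pollutant="pm10", lag=0, snp_id="snp_d")
        assert p.test_snp_interaction(analysis_panel, table, spec) is None

    def test_orientation_flips_for_hrv(self, analysis_panel, gxe_cohort):
        """Adverse for log-HRV means negative; positive betas orient major."""
        from panelgxe.models import _orientation
        assert _orientation(1.0, "sbp") == "minor_is_risk"
        assert _orientation(-1.0, "sbp") == "major_is_risk"
        assert _orientation(-0.1, "log_sdnn") == "minor_is_risk"
        assert _orientation(0.1, "log_sdnn") == "major_is_risk"

    def test_wald_and_lrt_asymptotically_agree(self, analysis_panel, gxe_cohort):
        genotypes, _, _ = gxe_cohort
        spec = ModelSpec(outcome="sbp", pollutant="pm10", lag=0, snp_id="snp_b")
        wald = p.test_snp_interaction(analysis_panel, genotypes, spec)
        lrt = p.test_snp_interaction(
            analysis_panel, genotypes,
            dataclasses.replace(spec, interaction_test="lrt"))
        z2 = (wald.beta_interaction / wald.se) ** 2
        lrt_stat = stats.chi2.isf(lrt.p_interaction, 1)
        assert lrt_stat == pytest.approx(z2, rel=0.15)


class TestJoint2df:
    def test_planted_effects_detected(self, analysis_panel, gxe_cohort):
        genotypes, _, _ = gxe_cohort
        spec = ModelSpec(outcome="sbp", pollutant="pm10", lag=0, snp_id="snp_b")
        lrt, df, pval = p.joint_2df_test(analysis_panel, genotypes, spec)
        assert df == 2 and lrt > 0 and pval < 0.001

    def test_null_snp_not_flagged(self, analysis_panel, gxe_cohort):
        genotypes, _, _ = gxe_cohort
        spec = ModelSpec(outcome="dbp", pollutant="pm10", lag=0, snp_id="snp_c")
        lrt, _, pval = p.joint_2df_test(analysis_panel, genotypes, spec)
        assert lrt >= 0 and pval > 0.01

    def test_orthogonalized_snp_gives_null_lrt(self, analysis_panel, gxe_cohort):
        """A SNP column of pure noise orthogonal to the outcome leaves the
        2-df statistic near its null expectation."""
        genotypes, _, _ = gxe_cohort
        rng = np.random.default_rng(0)
        noise = genotypes.genotypes.copy()
        noise["snp_d"] = rng.binomial(2, 0.5, len(noise))
        table = type(genotypes)(noise, genotypes.snp_info.copy())
        spec = ModelSpec(outcome="sbp", pollutant="pm10", lag=0, snp_id="snp_d")
        lrt, _, _ = p.joint_2df_test(analysis_panel, table, spec)
        assert 0 <= lrt < stats.chi2.isf(0.01, 2)


class TestScreenAll:
    def test_alpha_one_flags_everything(self, analysis_panel, gxe_cohort):
        genotypes, _, _ = gxe_cohort
        screen = p.screen_all(analysis_panel, genotypes, pollutants=("pm10",),
                              outcomes=("sbp",), alpha=1.0)
        assert set(screen.bp_positive) == set(genotypes.snp_ids)
        assert screen.hrv_positive == []

    def test_planted_snp_flagged_for_bp(self, analysis_panel, gxe_cohort):
        genotypes, _, _ = gxe_cohort
        screen = p.screen_all(analysis_panel, genotypes, pollutants=("pm10",),
                              outcomes=("sbp", "log_sdnn"), alpha=0.05)
        assert "snp_b" in screen.bp_positive
        results = screen.results
        assert len(results) == 2 * len(genotypes.snp_ids)
        assert set(results["family"]) == {"blood_pressure",
                                          "heart_rate_variability"}
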