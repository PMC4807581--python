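import numpy as np
import pandas as pd
import pytest

import panelgxe as p
from panelgxe.errors import ConfigurationError, DataError
from panelgxe.synthetic import (DEFAULT_POLLUTANT_PARAMS, DropoutSpec, EffectSpec,
                                LdBlockSpec, SnpSpec, apply_dropout,
                                make_visit_schedule, simulate_covariates,
                                simulate_exposure_series, simulate_genotypes,
                                simulate_panel_outcomes, two_snp_haplotypes)


class TestGenotypeGeneration:
    def test_hardy_weinberg_at_half(self):
        table = simulate_genotypes(100_000, [SnpSpec("s", "G", 0.5)], seed=1)
        freqs = table.genotypes["s"].value_counts(normalize=True)
        assert freqs[0.0] == pytest.approx(0.25, abs=0.01)
        assert freqs[1.0] == pytest.approx(0.50, abs=0.01)
        assert freqs[2.0] == pytest.approx(0.25, abs=0.01)

    def test_sample_maf_close_to_spec(self):
        table = simulate_genotypes(50_000, [SnpSpec("s", "G", 0.2)], seed=2)
        assert table.genotypes["s"].mean() / 2 == pytest.approx(0.2, abs=0.005)

    def test_complete_ld_block_recovered(self):
        freqs = two_snp_haplotypes(0.3, 0.3, 1.0)
        block = LdBlockSpec("G", ("a", "b"), freqs)
        table = simulate_genotypes(5000, [SnpSpec("a", "G", 0.3),
                                          SnpSpec("b", "G", 0.3)],
                                   [block], seed=3)
        em = p.em_haplotype_freqs(table.genotypes["a"], table.genotypes["b"])
        assert p.d_prime(em.freqs).value == pytest.approx(1.0, abs=0.02)

    def test_block_referencing_unknown_snp_rejected(self):
        block = LdBlockSpec("G", ("a", "zz"), two_snp_haplotypes(0.3, 0.3, 0.9))
        with pytest.raises(ConfigurationError, match="zz"):
            simulate_genotypes(10, [SnpSpec("a", "G", 0.3)], [block])

    def test_inconsistent_haplotype_marginals_rejected(self):
        freqs = two_snp_haplotypes(0.4, 0.3, 0.9)  # implies maf_a = 0.4
        block = LdBlockSpec("G", ("a", "b"), freqs)
        snps = [SnpSpec("a", "G", 0.3), SnpSpec("b", "G", 0.3)]
        with pytest.raises(ConfigurationError, match="maf"):
            simulate_genotypes(10, snps, [block])

    def test_hwe_conforming_snps_pass_hwe_test(self):
        """At n=1000, conforming SNPs pass the chi-square at alpha=0.001
        in at least 99 % of replicates."""
        passes = 0
        reps = 200
        for r in range(reps):
            table = simulate_genotypes(1000, [SnpSpec("s", "G", 0.3)], seed=r)
            counts = table.genotypes["s"].value_counts().reindex(
                [0.0, 1.0, 2.0], fill_value=0)
            passes += p.hwe_test(*counts.astype(int)).p >= 0.001
        assert passes / reps >= 0.99

    def test_planted_violation_detectable(self):
        spec = SnpSpec("s", "G", 0.3, hwe_violation=True, inbreeding_f=0.35)
        table = simulate_genotypes(547, [spec], seed=4)
        counts = table.genotypes["s"].value_counts().reindex(
            [0.0, 1.0, 2.0], fill_value=0)
        assert p.hwe_test(*counts.astype(int)).p < 1e-3


class TestExposureGeneration:
    def test_default_pm10_matches_survey_marginals(self):
        series = simulate_exposure_series(2000, seed=5)
        assert series["pm10"].mean() == pytest.approx(42.6, abs=2.0)
        assert series["pm10"].std() == pytest.approx(24.7, abs=2.0)

    def test_zero_sd_zero_autocorr_is_constant(self):
        series = simulate_exposure_series(
            100, seed=6, pollutant_params={"pm10": (42.6, 0.0, 0.0)})
        assert (series["pm10"] == 42.6).all()

    def test_ar1_autocorrelation_recovered(self):
        series = simulate_exposure_series(
            2000, seed=7, pollutant_params={"no2": (36.5, 12.6, 0.7)})
        assert series["no2"].autocorr(1) == pytest.approx(0.7, abs=0.05)

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_exposure_series(100, pollutant_params={"so2": (4.0, -1.0, 0.5)})

    def test_pollutants_floored_positive(self):
        series = simulate_exposure_series(3000, seed=8)
        for name in DEFAULT_POLLUTANT_PARAMS:
            assert (series[name] >= 0.1).all()


class TestCovariatesAndOutcomes:
    def test_covariate_marginals(self):
        cov = simulate_covariates([f"S{i}" for i in range(547)], seed=9)
        assert cov["sex"].mean() == pytest.approx(0.739, abs=0.05)
        assert (cov["smoking"] == "current").mean() == pytest.approx(0.055, abs=0.03)
        assert cov["age"].mean() == pytest.approx(70.7, abs=0.7)
        assert (cov["age"] >= 60).all()

    def test_pure_noise_outcome_variance(self):
        effect = EffectSpec(outcome="sbp", pollutant="pm10", main_effect=0.0,
                            random_intercept_sd=0.0, residual_sd=8.0)
        table = simulate_genotypes(800, [SnpSpec("s", "G", 0.3)], seed=10)
        series = simulate_exposure_series(760, seed=10)
        sched = make_visit_schedule(table.genotypes.index, seed=10)
        panel = simulate_panel_outcomes(table, series, sched, [effect], seed=10)
        assert panel["sbp"].var() == pytest.approx(64.0, rel=0.1)

    def test_hrv_stored_positive_log_scale(self):
        effect = EffectSpec(outcome="sdnn", pollutant="pm10",
                            random_intercept_sd=0.35, residual_sd=0.4)
        table = simulate_genotypes(200, [SnpSpec("s", "G", 0.3)], seed=11)
        series = simulate_exposure_series(760, seed=11)
        sched = make_visit_schedule(table.genotypes.index, seed=11)
        panel = simulate_panel_outcomes(table, series, sched, [effect], seed=11)
        assert (panel["sdnn"] > 0).all()
        assert np.log(panel["sdnn"]).mean() == pytest.approx(np.log(26.9), abs=0.1)

    def test_visit_outside_coverage_names_date(self):
        effect = EffectSpec(outcome="sbp", pollutant="pm10", true_lag=3)
        table = simulate_genotypes(5, [SnpSpec("s", "G", 0.3)], seed=12)
        series = simulate_exposure_series(30, start="2008-08-14", seed=12)
        sched = pd.DataFrame({"subject_id": table.genotypes.index, "visit": 1,
                              "date": pd.Timestamp("2008-08-15")})
        with pytest.raises(DataError, match="2008-08-13"):
            simulate_panel_outcomes(table, series, sched, [effect], seed=12)

    def test_duplicate_outcome_specs_rejected(self):
        e1 = EffectSpec(outcome="sbp", pollutant="pm10")
        with pytest.raises(ConfigurationError):
            simulate_panel_outcomes(None, None, None, [e1, e1], seed=0)

    def test_identical_seeds_bit_identical(self):
        args = dict(n_subjects=50, effects=[EffectSpec(outcome="sbp",
                                                       pollutant="pm10")],
                    snps=[SnpSpec("s", "G", 0.3)], blocks=[])
        _, _, p1 = p.simulate_cohort(seed=42, **args)
        _, _, p2 = p.simulate_cohort(seed=42, **args)
        pd.testing.assert_frame_equal(p1, p2)


class TestDropout:
    def _panel(self, n=2000, seed=13):
        effect = EffectSpec(outcome="sbp", pollutant="pm10")
        table = simulate_genotypes(n, [SnpSpec("s", "G", 0.3)], seed=seed)
        series = simulate_exposure_series(760, seed=seed)
        sched = make_visit_schedule(table.genotypes.index, seed=seed)
        return simulate_panel_outcomes(table, series, sched, [effect], seed=seed)

    def test_none_mechanism_is_identity(self):
        panel = self._panel(n=100)
        out = apply_dropout(panel, DropoutSpec("none"), seed=1)
        pd.testing.assert_frame_equal(out, panel)

    def test_intercept_zero_retains_half_of_second_visits(self):
        panel = self._panel()
        out = apply_dropout(panel, DropoutSpec("MCAR", {"intercept": 0.0}), seed=2)
        retained = (out["visit"] == 2).sum() / (panel["visit"] == 2).sum()
        assert retained == pytest.approx(0.5, abs=0.03)

    def test_first_visit_always_kept_and_monotone(self):
        panel = self._panel(n=500)
        out = apply_dropout(panel, DropoutSpec("MCAR", {"intercept": -0.5}), seed=3)
        visits = out.groupby("subject_id")["visit"].agg(["min", "max", "count"])
        assert (visits["min"] == 1).all()
        assert (visits["max"] == visits["count"]).all()  # no gaps: monotone

    def test_mar_on_bmi_selects_heavier_subjects(self):
        panel = self._panel()
        spec = DropoutSpec("MAR-on-covariates", {"intercept": -7.0, "bmi": 0.28})
        out = apply_dropout(panel, spec, seed=4)
        kept2 = set(out.loc[out["visit"] == 2, "subject_id"])
        base = panel[panel["visit"] == 1].set_index("subject_id")["bmi"]
        dropped = base.index.difference(kept2)
        assert base[list(kept2)].mean() > base[dropped].mean()

    def test_mar_without_covariates_rejected(self):
        with pytest.raises(ConfigurationError):
            DropoutSpec("MAR-on-covariates", {"intercept": 1.0})
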