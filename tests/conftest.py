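"""Shared fixtures: one mid-sized synthetic cohort with a planted
SNP x PM10 interaction on SBP, reused by the model-layer tests."""

import warnings

import pytest

import panelgxe as p
from panelgxe.synthetic import EffectSpec, SnpSpec, simulate_cohort

warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def gxe_cohort():
    """(genotypes, exposures, panel) with beta_main=0.93, beta_int=2.0
    per IQR per minor allele of snp_b on SBP; 400 subjects x 5 visits."""
    snps = [SnpSpec("snp_a", "GENE01", 0.45), SnpSpec("snp_b", "GENE01", 0.30),
            SnpSpec("snp_c", "GENE02", 0.20), SnpSpec("snp_d", "GENE03", 0.35)]
    effects = [
        EffectSpec(outcome="sbp", pollutant="pm10", main_effect=0.93,
                   interaction_per_risk_allele=2.0,
                   interacting_snps=(("snp_b", "minor_is_risk"),),
                   covariate_effects={"age": 0.3, "bmi": 0.5}),
        EffectSpec(outcome="dbp", pollutant="pm10", main_effect=0.62,
                   random_intercept_sd=6.0, residual_sd=6.0),
        EffectSpec(outcome="sdnn", pollutant="pm10", main_effect=0.0,
                   random_intercept_sd=0.35, residual_sd=0.4),
    ]
    genotypes, exposures, panel = simulate_cohort(
        n_subjects=400, effects=effects, snps=snps, blocks=[], seed=2024)
    return genotypes, exposures, panel


@pytest.fixture(scope="session")
def analysis_panel(gxe_cohort):
    """The cohort panel with derived outcomes and lagged exposures."""
    _, exposures, panel = gxe_cohort
    return p.attach_lagged_exposures(p.prepare_outcomes(panel), exposures)
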