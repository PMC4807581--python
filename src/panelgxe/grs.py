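"""Genetic risk scores, tertile stratification and heterogeneity tests.

The genetic risk score (GRS) for an outcome family is the unweighted
count of risk alleles over the pruned interaction-positive SNP panel:
score = sum over SNPs of (genotype if the minor allele is the risk
allele, else 2 - genotype), so with K SNPs the score lies in [0, 2K].
Scores are cut into tertiles; the pollutant effect is re-estimated
within each tertile (with the whole-cohort IQR so strata are
comparable) and heterogeneity is tested by the product of the ordinal
tertile score with the pollutant in the pooled model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DataError
from .genetics import GenotypeTable, LdBlock, prune_blocks
from .models import (FitResult, ModelSpec, ScreenResult, build_design,
                     _fit_mixedlm, fit_main_model)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cohort exclusion bookkeeping


@dataclass
class CohortFilterReport:
    n_enrolled: int
    exclusions: list          # (reason, count)
    n_analyzed: int


def apply_exclusions(roster: pd.DataFrame) -> tuple[CohortFilterReport, pd.DataFrame]:
    """Apply the cohort exclusion filter.

    ``roster`` has one row per enrolled subject with boolean
    ``has_bp`` and ``has_hrv`` availability flags.  Subjects with no
    blood-pressure measurement are removed first, then (among the
    remainder) subjects with no heart-rate-variability information.
    """
    for col in ("has_bp", "has_hrv"):
        if col not in roster.columns:
            raise DataError(f"roster needs a boolean {col!r} column")
    n0 = len(roster)
    step1 = roster[roster["has_bp"].astype(bool)]
    n_no_bp = n0 - len(step1)
    step2 = step1[step1["has_hrv"].astype(bool)]
    n_no_hrv = len(step1) - len(step2)
    report = CohortFilterReport(
        n_enrolled=n0,
        exclusions=[("no blood pressure measurement", n_no_bp),
                    ("no heart rate variability information", n_no_hrv)],
        n_analyzed=len(step2))
    if report.n_analyzed == 0:
        logger.warning("cohort filter removed every subject")
    return report, step2.copy()


# ---------------------------------------------------------------------------
# Risk panels and scores


def panel_from_screen(screen: ScreenResult, family: str,
                      blocks: list[LdBlock], rule: str = "min_p") -> list[tuple]:
    """Pruned risk panel with orientations from screening results.

    Candidates are the family's interaction-positive SNPs; one SNP per
    LD block is retained (default: the one with the smallest
    interaction p-value in the family).  Each retained SNP's risk
    orientation is taken from its single smallest-p interaction.
    """
    candidates = (screen.bp_positive if family == "blood_pressure"
                  else screen.hrv_positive)
    if not candidates:
        raise DataError(f"no interaction-positive SNPs for {family}")
    sub = screen.results[screen.results["family"] == family]
    best = sub.loc[sub.groupby("snp_id")["p_interaction"].idxmin()]
    pvalues = dict(zip(best["snp_id"], best["p_interaction"]))
    orientations = dict(zip(best["snp_id"], best["orientation"]))
    retained = prune_blocks(candidates, blocks, rule=rule, pvalues=pvalues)
    return [(snp, orientations.get(snp) or "minor_is_risk") for snp in retained]


def alternative_panel(screen: ScreenResult, family: str,
                      blocks: list[LdBlock]) -> list[tuple]:
    """Sensitivity panel choosing the *other* member of each LD pair."""
    return panel_from_screen(screen, family, blocks, rule="other_member")


def compute_grs(genotypes: GenotypeTable, risk_panel,
                missing: str = "complete_case") -> pd.Series:
    """Per-subject unweighted risk-allele count over the panel.

    ``missing='complete_case'`` leaves the score NaN for subjects
    missing any panel genotype; ``'mean_impute'`` substitutes the
    per-SNP mean risk-allele dose.
    """
    if not risk_panel:
        raise DataError("risk panel is empty")
    doses = []
    for snp_id, orientation in risk_panel:
        if snp_id not in genotypes.genotypes.columns:
            raise DataError(f"panel SNP {snp_id} not in genotype table")
        g = genotypes.genotypes[snp_id].astype(float)
        dose = g if orientation == "minor_is_risk" else 2.0 - g
        if missing == "mean_impute":
            dose = dose.fillna(dose.mean())
        doses.append(dose)
    score = pd.concat(doses, axis=1).sum(axis=1, skipna=False)
    score.name = "grs"
    return score


@dataclass
class Tertiles:
    cutpoints: tuple            # (q1, q2) empirical 1/3 and 2/3 quantiles
    groups: pd.Series           # low / moderate / high per subject
    bands: dict                 # group -> (min score, max score)


def assign_tertiles(scores: pd.Series) -> Tertiles:
    """Cut integer scores into tertiles at the 1/3 and 2/3 quantiles.

    Ties at a cutpoint go to the lower group, which yields contiguous
    integer score bands per group.
    """
    s = scores.dropna()
    if s.nunique() < 3:
        raise DataError("need at least 3 distinct scores for tertiles")
    q1, q2 = np.quantile(s.to_numpy(), [1 / 3, 2 / 3])
    def classify(v):
        if v <= q1:
            return "low"
        return "moderate" if v <= q2 else "high"
    groups = s.map(classify).astype("category").cat.set_categories(
        ["low", "moderate", "high"])
    groups = groups.reindex(scores.index)
    groups.name = "tertile"
    if groups.dropna().nunique() < 2:
        raise DataError("score distribution too skewed for tertiles: "
                        f"all subjects fall at or below cutpoint {q1:g}")
    bands = {g: (float(s[groups.loc[s.index] == g].min()),
                 float(s[groups.loc[s.index] == g].max()))
             for g in ("low", "moderate", "high") if (groups == g).any()}
    return Tertiles(cutpoints=(float(q1), float(q2)), groups=groups, bands=bands)


# ---------------------------------------------------------------------------
# Stratified effects and heterogeneity


def stratified_association(panel: pd.DataFrame, groups: pd.Series,
                           spec: ModelSpec) -> pd.DataFrame:
    """Pollutant effect per IQR within each GRS tertile.

    The IQR is computed once on the full (unstratified) analysis set so
    per-IQR estimates are comparable across strata.  Non-convergence in
    a stratum yields a flagged row rather than an error.
    """
    full = fit_main_model(panel, spec)
    work = replace(spec, fixed_iqr=full.iqr)
    rows = []
    for tertile in ("low", "moderate", "high"):
        subjects = groups.index[groups == tertile]
        sub = panel[panel["subject_id"].isin(subjects)]
        try:
            fit = fit_main_model(sub, work)
            lo, hi = fit.conf_int(fit.pollutant_term)
            rows.append({"tertile": tertile, "pollutant": spec.pollutant,
                         "outcome": spec.outcome, "beta": fit.pollutant_estimate,
                         "se": float(fit.bse[fit.pollutant_term]),
                         "ci_low": lo, "ci_high": hi,
                         "n_obs": fit.n_obs, "converged": True})
        except (ConvergenceError, DataError) as exc:
            logger.warning("stratum %s did not fit: %s", tertile, exc)
            rows.append({"tertile": tertile, "pollutant": spec.pollutant,
                         "outcome": spec.outcome, "beta": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "n_obs": 0, "converged": False})
    return pd.DataFrame(rows)


@dataclass
class HeterogeneityResult:
    pollutant: str
    outcome: str
    p_heterogeneity: float
    beta_product: float
    se_product: float
    fit: FitResult


def heterogeneity_test(panel: pd.DataFrame, groups: pd.Series,
                       spec: ModelSpec, categorical: bool = False
                       ) -> HeterogeneityResult:
    """Test effect modification by the tertile score.

    Adds the ordinal tertile score (0/1/2) and its product with the
    IQR-scaled pollutant to the main model; the Wald p-value of the
    product term is the heterogeneity p.  ``categorical=True`` instead
    uses two indicator products and a 2-df Wald test.
    """
    ordinal = groups.map({"low": 0.0, "moderate": 1.0, "high": 2.0})
    work = panel.copy()
    work["_tertile_score"] = ordinal.reindex(work["subject_id"]).to_numpy()
    y, X, g, iqr, _ = build_design(
        work.dropna(subset=["_tertile_score"]), spec)
    pol = f"{spec.pollutant}_lag{spec.lag}"
    score = work.loc[X.index, "_tertile_score"].to_numpy()
    if categorical:
        for level, name in ((1.0, "moderate"), (2.0, "high")):
            X[f"tertile[{name}]"] = (score == level).astype(float)
            X[f"tertile[{name}]_x_pollutant"] = X[f"tertile[{name}]"] * X[pol]
        fit = _fit_mixedlm(y, X, g, pol, iqr)
        terms = ["tertile[moderate]_x_pollutant", "tertile[high]_x_pollutant"]
        beta = fit.params[terms].to_numpy()
        cov = fit.fe_cov.loc[terms, terms].to_numpy()
        w = float(beta @ np.linalg.solve(cov, beta))
        p = float(stats.chi2.sf(w, df=2))
        return HeterogeneityResult(spec.pollutant, spec.outcome, p,
                                   float(beta[1]), float(fit.bse[terms[1]]), fit)
    X["tertile_score"] = score
    X["tertile_x_pollutant"] = score * X[pol]
    fit = _fit_mixedlm(y, X, g, pol, iqr)
    beta = float(fit.params["tertile_x_pollutant"])
    se = float(fit.bse["tertile_x_pollutant"])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return HeterogeneityResult(spec.pollutant, spec.outcome, p, beta, se, fit)
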