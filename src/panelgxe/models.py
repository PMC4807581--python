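"""Linear mixed models for the panel analysis.

Every model is a subject-level random-intercept linear mixed model with
the a-priori covariate set (age, sex, smoking status, alcohol drinking,
BMI, hypertension medication, and apparent temperature at the same lag
as the pollutant under test) plus the IQR-scaled lagged pollutant.
Models are fitted by maximum likelihood (not REML) throughout so that
AIC comparisons across fixed-effect structures and likelihood-ratio
tests are valid.

Provided operations: the pollutant main-effect model, AIC selection of
the distributed lag (0-3 days), the per-SNP interaction model with
additive (0/1/2) coding and a Wald (optionally LRT) test of the product
term, the 2-df joint likelihood-ratio test of SNP main effect and
interaction, and the full screen over SNP x pollutant x outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConvergenceError, DataError
from .exposure import BP_OUTCOMES, HRV_OUTCOMES, POLLUTANTS, iqr_scale
from .genetics import GenotypeTable

logger = logging.getLogger(__name__)

#: A-priori adjustment set.  Smoking and alcohol enter as indicator
#: contrasts against the most frequent level ("non"); apparent
#: temperature is added automatically at the pollutant's lag.
DEFAULT_COVARIATES = ("age", "sex", "smoking", "alcohol", "bmi", "htn_med")

CATEGORICAL_LEVELS = {
    "smoking": ("non", "current", "ex", "no_answer"),   # first = reference
    "alcohol": ("non", "current", "no_answer"),
}

OUTCOME_FAMILIES = {
    "blood_pressure": tuple(BP_OUTCOMES),
    "heart_rate_variability": tuple(HRV_OUTCOMES),
}


def outcome_family(outcome: str) -> str:
    for family, members in OUTCOME_FAMILIES.items():
        if outcome in members:
            return family
    raise DataError(f"unknown outcome {outcome!r}")


@dataclass
class ModelSpec:
    """What to fit: outcome, pollutant, lag, covariates, optional SNP term."""

    outcome: str
    pollutant: str
    lag: int | None = None
    covariates: tuple = DEFAULT_COVARIATES
    snp_id: str | None = None
    include_interaction: bool = False
    fixed_iqr: float | None = None       # reuse a whole-cohort IQR in strata
    interaction_test: str = "wald"       # or "lrt"

    def __post_init__(self):
        if self.include_interaction and self.snp_id is None:
            raise DataError("include_interaction requires snp_id")
        if self.lag is not None and self.lag not in (0, 1, 2, 3):
            raise DataError("lag must be in {0,1,2,3}")


@dataclass
class FitResult:
    """One mixed-model fit, pollutant coefficient on the per-IQR scale."""

    params: pd.Series
    bse: pd.Series
    llf: float
    aic: float
    n_obs: int
    n_subjects: int
    converged: bool
    pollutant_term: str
    iqr: float
    random_intercept_var: float
    residual_var: float
    row_index: pd.Index = field(repr=False, default=None)
    fe_cov: pd.DataFrame = field(repr=False, default=None)

    def conf_int(self, term: str | None = None, level: float = 0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        lo, hi = self.params - z * self.bse, self.params + z * self.bse
        if term is None:
            return pd.DataFrame({"low": lo, "high": hi})
        return float(lo[term]), float(hi[term])

    @property
    def pollutant_estimate(self) -> float:
        return float(self.params[self.pollutant_term])


@dataclass
class InteractionResult:
    """One SNP x pollutant x outcome interaction fit."""

    snp_id: str
    pollutant: str
    outcome: str
    lag: int
    beta_interaction: float     # per IQR per minor allele
    se: float
    p_interaction: float
    risk_allele_orientation: str | None
    n_obs: int
    p_joint_2df: float | None = None
    lrt_joint: float | None = None
    fit: FitResult | None = field(repr=False, default=None)


def _orientation(beta: float, outcome: str) -> str | None:
    """Minor allele is "risk" when the interaction points adverse:
    positive for BP outcomes, negative for log-HRV outcomes."""
    if beta == 0:
        return None
    adverse_positive = outcome_family(outcome) == "blood_pressure"
    minor_adverse = (beta > 0) == adverse_positive
    return "minor_is_risk" if minor_adverse else "major_is_risk"


def build_design(panel: pd.DataFrame, spec: ModelSpec,
                 genotypes: GenotypeTable | None = None,
                 rows: pd.Index | None = None):
    """Complete-case design for a model spec.

    Returns ``(y, X, groups, iqr, row_index)``.  The pollutant enters
    scaled by its IQR over the analysis rows (or ``spec.fixed_iqr``);
    apparent temperature enters at the same lag as the pollutant.
    """
    if spec.lag is None:
        raise DataError("lag must be chosen before building a design")
    pol_col = f"{spec.pollutant}_lag{spec.lag}"
    at_col = f"at_lag{spec.lag}"
    needed = [spec.outcome, pol_col, at_col, "subject_id", *spec.covariates]
    missing_cols = [c for c in needed if c not in panel.columns]
    if missing_cols:
        raise DataError(f"panel is missing columns {missing_cols}; "
                        "attach lagged exposures first")
    df = panel[needed].copy()
    if spec.snp_id is not None:
        if genotypes is None:
            raise DataError("genotypes required when spec.snp_id is set")
        df["snp"] = genotypes.genotypes[spec.snp_id].reindex(
            df["subject_id"]).to_numpy()
    if rows is not None:
        df = df.loc[rows.intersection(df.index)]
    df = df.dropna()
    if df.empty:
        raise DataError("no complete cases for this model")

    if spec.fixed_iqr is not None:
        iqr = float(spec.fixed_iqr)
        if iqr <= 0:
            raise DataError("fixed_iqr must be positive")
        x = df[pol_col].to_numpy() / iqr
    else:
        x, iqr = iqr_scale(df[pol_col].to_numpy())

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X[pol_col] = x
    for cov in spec.covariates:
        if cov in CATEGORICAL_LEVELS:
            # contrasts only for levels present in the analysis subset:
            # rare levels ("did not answer") can vanish within a stratum
            # and an all-zero indicator makes the design singular
            present = set(df[cov].unique())
            for level in CATEGORICAL_LEVELS[cov][1:]:
                if level in present:
                    X[f"{cov}[{level}]"] = (df[cov] == level).astype(float)
        else:
            X[cov] = pd.to_numeric(df[cov]).astype(float)
    X[at_col] = df[at_col].astype(float)
    if spec.snp_id is not None:
        X["snp"] = df["snp"].astype(float)
        if spec.include_interaction:
            X["snp_x_pollutant"] = X["snp"] * X[pol_col]
    return df[spec.outcome].astype(float), X, df["subject_id"], iqr, df.index


def _fit_mixedlm(y, X, groups, pollutant_term, iqr) -> FitResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y.to_numpy(), X.to_numpy(), groups=groups.to_numpy())
        res = None
        last = None
        # powell handles the sigma_b ~ 0 boundary that stalls bfgs
        for method in ("bfgs", "powell"):
            try:
                candidate = model.fit(reml=False, method=method)
            except np.linalg.LinAlgError as exc:
                last = exc
                continue
            last = candidate
            if candidate.converged:
                res = candidate
                break
    if res is None:
        raise ConvergenceError(f"mixed model did not converge ({last})",
                               last_state=last)
    k = X.shape[1] + 2  # fixed effects + random-intercept var + residual var
    params = pd.Series(res.fe_params, index=X.columns)
    bse = pd.Series(res.bse_fe, index=X.columns)
    return FitResult(
        params=params, bse=bse, llf=float(res.llf),
        aic=float(2 * k - 2 * res.llf), n_obs=int(len(y)),
        n_subjects=int(groups.nunique()), converged=bool(res.converged),
        pollutant_term=pollutant_term, iqr=iqr,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale), row_index=X.index,
        fe_cov=pd.DataFrame(np.asarray(res.cov_params())[:len(X.columns),
                                                         :len(X.columns)],
                            index=X.columns, columns=X.columns))


def fit_main_model(panel: pd.DataFrame, spec: ModelSpec,
                   rows: pd.Index | None = None) -> FitResult:
    """Pollutant main-effect mixed model (no SNP terms)."""
    if spec.snp_id is not None:
        raise DataError("fit_main_model takes a spec without a SNP term")
    y, X, groups, iqr, _ = build_design(panel, spec, rows=rows)
    return _fit_mixedlm(y, X, groups, f"{spec.pollutant}_lag{spec.lag}", iqr)


def select_lag(panel: pd.DataFrame, spec: ModelSpec,
               max_lag: int = 3) -> tuple[int, pd.DataFrame]:
    """Choose the distributed lag (0..max_lag) by minimum AIC.

    All lag variants are fitted on the identical observation set
    (complete cases across every lag's columns); AIC ties break to the
    smallest lag.  Non-convergent lags are dropped with a warning.
    """
    cols = [f"{spec.pollutant}_lag{k}" for k in range(max_lag + 1)]
    cols += [f"at_lag{k}" for k in range(max_lag + 1)]
    cols += [spec.outcome, "subject_id", *spec.covariates]
    missing_cols = [c for c in cols if c not in panel.columns]
    if missing_cols:
        raise DataError(f"panel is missing columns {missing_cols}")
    shared_rows = panel[cols].dropna().index
    records = []
    fits = {}
    for lag in range(max_lag + 1):
        try:
            fit = fit_main_model(panel, replace(spec, lag=lag), rows=shared_rows)
        except ConvergenceError:
            logger.warning("lag %d model did not converge; excluded", lag)
            records.append((lag, np.nan, np.nan, False))
            continue
        fits[lag] = fit
        records.append((lag, fit.aic, fit.pollutant_estimate, True))
    table = pd.DataFrame(records, columns=["lag", "aic", "estimate", "converged"])
    if not fits:
        raise ConvergenceError("no lag model converged")
    n_obs = {f.n_obs for f in fits.values()}
    assert len(n_obs) == 1, "lag comparison must use identical observations"
    best = min(fits, key=lambda lag: (round(fits[lag].aic, 6), lag))
    return best, table


def test_snp_interaction(panel: pd.DataFrame, genotypes: GenotypeTable,
                         spec: ModelSpec, joint: bool = False
                         ) -> InteractionResult | None:
    """Fit main model + SNP + SNP x pollutant; test the product term.

    The SNP enters additively (minor-allele count).  Returns None (with
    a log entry) when the SNP is monomorphic in the analysis sample.
    The interaction p-value is Wald by default, LRT on request.
    """
    work = replace(spec, include_interaction=True)
    y, X, groups, iqr, rows = build_design(panel, work, genotypes)
    if X["snp"].nunique() < 2:
        logger.info("SNP %s monomorphic in analysis sample; skipped", spec.snp_id)
        return None
    fit = _fit_mixedlm(y, X, groups, f"{spec.pollutant}_lag{spec.lag}", iqr)
    beta = float(fit.params["snp_x_pollutant"])
    se = float(fit.bse["snp_x_pollutant"])
    if work.interaction_test == "lrt":
        y0, X0, g0, _, _ = build_design(panel, replace(work, include_interaction=False),
                                        genotypes, rows=rows)
        fit0 = _fit_mixedlm(y0, X0, g0, fit.pollutant_term, iqr)
        lrt = max(2 * (fit.llf - fit0.llf), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
    else:
        z = beta / se
        p = float(2 * stats.norm.sf(abs(z)))
    result = InteractionResult(
        snp_id=spec.snp_id, pollutant=spec.pollutant, outcome=spec.outcome,
        lag=spec.lag, beta_interaction=beta, se=se, p_interaction=p,
        risk_allele_orientation=_orientation(beta, spec.outcome),
        n_obs=fit.n_obs, fit=fit)
    if joint:
        lrt, _, p_joint = joint_2df_test(panel, genotypes, spec,
                                         full_fit=fit, full_rows=rows, iqr=iqr)
        result.p_joint_2df = p_joint
        result.lrt_joint = lrt
    return result


def joint_2df_test(panel: pd.DataFrame, genotypes: GenotypeTable,
                   spec: ModelSpec, full_fit: FitResult | None = None,
                   full_rows: pd.Index | None = None,
                   iqr: float | None = None) -> tuple[float, int, float]:
    """2-df joint LRT of the SNP main effect and SNP x pollutant term.

    Full model: covariates + pollutant + SNP + SNP x pollutant; nested
    model drops both SNP terms.  Both are ML fits on the identical
    observation set; fitting on different rows is refused.
    """
    work = replace(spec, include_interaction=True)
    if full_fit is None:
        y, X, groups, iqr, full_rows = build_design(panel, work, genotypes)
        full_fit = _fit_mixedlm(y, X, groups, f"{spec.pollutant}_lag{spec.lag}", iqr)
    nested_spec = replace(spec, snp_id=None, include_interaction=False,
                          fixed_iqr=iqr)
    y0, X0, g0, _, rows0 = build_design(panel, nested_spec, rows=full_rows)
    if not rows0.equals(full_rows):
        raise DataError("full and nested models cover different observations")
    fit0 = _fit_mixedlm(y0, X0, g0, full_fit.pollutant_term, iqr)
    lrt = 2 * (full_fit.llf - fit0.llf)
    if lrt < -1e-6:
        raise ConvergenceError(f"negative LRT statistic ({lrt:.3g}): "
                               "full-model fit is suspect")
    lrt = max(lrt, 0.0)
    return float(lrt), 2, float(stats.chi2.sf(lrt, df=2))


@dataclass
class ScreenResult:
    """Full interaction screen over SNP x pollutant x outcome."""

    results: pd.DataFrame
    lag_choices: dict            # (outcome, pollutant) -> lag
    bp_positive: list            # SNPs with any BP interaction p < alpha
    hrv_positive: list
    skipped: list


def screen_all(panel: pd.DataFrame, genotypes: GenotypeTable,
               pollutants=POLLUTANTS,
               outcomes=tuple(BP_OUTCOMES) + tuple(HRV_OUTCOMES),
               alpha: float = 0.05, joint: bool = False,
               covariates: tuple = DEFAULT_COVARIATES) -> ScreenResult:
    """Run the single-SNP interaction screen for every combination.

    Lag selection happens once per (outcome, pollutant) on the main
    model and is reused for all that pair's SNP models.  A SNP is
    interaction-positive for an outcome family when any pollutant x
    outcome combination in the family has p < alpha; no multiplicity
    correction is applied (each SNP is screened at the nominal level).
    """
    rows = []
    lag_choices = {}
    skipped = []
    for outcome in outcomes:
        for pollutant in pollutants:
            base = ModelSpec(outcome=outcome, pollutant=pollutant,
                             covariates=covariates)
            lag, _ = select_lag(panel, base)
            lag_choices[(outcome, pollutant)] = lag
            for snp_id in genotypes.snp_ids:
                spec = replace(base, lag=lag, snp_id=snp_id)
                res = test_snp_interaction(panel, genotypes, spec, joint=joint)
                if res is None:
                    skipped.append((snp_id, outcome, pollutant))
                    continue
                lo, hi = res.fit.conf_int("snp_x_pollutant")
                rows.append({
                    "snp_id": snp_id, "pollutant": pollutant, "outcome": outcome,
                    "family": outcome_family(outcome), "lag": lag,
                    "beta_interaction": res.beta_interaction, "se": res.se,
                    "ci_low": lo, "ci_high": hi,
                    "p_interaction": res.p_interaction,
                    "p_joint_2df": res.p_joint_2df,
                    "orientation": res.risk_allele_orientation,
                    "n_obs": res.n_obs,
                })
    results = pd.DataFrame(rows)
    positive = {}
    for family in OUTCOME_FAMILIES:
        sub = results[(results["family"] == family)
                      & (results["p_interaction"] < alpha)]
        order = {s: i for i, s in enumerate(genotypes.snp_ids)}
        positive[family] = sorted(sub["snp_id"].unique(), key=order.get)
    return ScreenResult(results=results, lag_choices=lag_choices,
                        bp_positive=positive["blood_pressure"],
                        hrv_positive=positive["heart_rate_variability"],
                        skipped=skipped)
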