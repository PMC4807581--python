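"""Inverse-probability-of-follow-up weighting for non-random dropout.

A logistic model predicts, for every subject at risk of visit v >= 2
(i.e. observed at v-1 under monotone dropout), the probability of
actually attending visit v from the *prior* visit's covariates: age,
sex, BMI, years of schooling, blood pressure, season, and outdoor
temperature.  Observed follow-ups are then re-weighted by the inverse
of that probability (the first observation always carries weight 1),
and the exposure models are refitted with the weights.

The weighted refit uses weighted estimating equations (a Gaussian GEE
with independence working correlation and cluster-robust standard
errors), the standard IPW vehicle for longitudinal dropout: an
unweighted estimating-equation fit is biased when dropout depends on
observed outcome history, and the weights restore consistency.  A
correctly specified likelihood-based mixed model would already be
MAR-consistent, which is why the weights are not pushed through the
mixed-model likelihood here.  Unweighted comparisons use the same GEE
path with unit weights, so "all weights one" is exactly the unweighted
fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConvergenceError, DataError
from .models import FitResult, ModelSpec, build_design

logger = logging.getLogger(__name__)

#: Prior-visit predictors of follow-up.  ``season`` is the calendar
#: quarter of the prior visit date; ``mean_temp`` the same-day outdoor
#: temperature at the prior visit (the ``mean_temp_lag0`` column).
DEFAULT_FOLLOWUP_COVARIATES = ("age", "sex", "bmi", "schooling", "sbp",
                               "season", "mean_temp")


@dataclass
class FollowupModel:
    result: object                 # statsmodels Logit results
    design_columns: list
    predictions: pd.DataFrame      # subject_id, visit, observed, p_hat
    n_at_risk: int
    n_observed: int


def _at_risk_table(panel: pd.DataFrame, covariates) -> pd.DataFrame:
    """One row per at-risk follow-up slot with prior-visit covariates.

    Under monotone dropout a subject is at risk of visit v when visit
    v-1 was observed and v does not exceed the panel's planned maximum.
    """
    needed = {"subject_id", "visit", "date"}
    if not needed.issubset(panel.columns):
        raise DataError("panel needs subject_id, visit and date columns")
    n_planned = int(panel["visit"].max())
    if n_planned < 2:
        raise DataError("need at least 2 planned visits")
    df = panel.sort_values(["subject_id", "visit"])
    rows = []
    for subject, sub in df.groupby("subject_id", sort=False):
        observed = set(sub["visit"])
        by_visit = sub.set_index("visit")
        for v in range(2, n_planned + 1):
            if v - 1 not in observed:
                break
            prior = by_visit.loc[v - 1]
            row = {"subject_id": subject, "visit": v,
                   "observed": float(v in observed)}
            for cov in covariates:
                if cov == "season":
                    row["season"] = f"Q{pd.Timestamp(prior['date']).quarter}"
                elif cov == "mean_temp":
                    src = "mean_temp_lag0" if "mean_temp_lag0" in prior.index else "mean_temp"
                    row["mean_temp"] = prior.get(src, np.nan)
                else:
                    if cov not in prior.index:
                        raise DataError(f"prior-visit covariate {cov!r} not in panel")
                    row[cov] = prior[cov]
            rows.append(row)
    return pd.DataFrame(rows)


def fit_followup_model(panel: pd.DataFrame,
                       covariates=DEFAULT_FOLLOWUP_COVARIATES) -> FollowupModel:
    """Logistic regression of follow-up attendance on prior-visit covariates."""
    table = _at_risk_table(panel, covariates)
    n_before = len(table)
    table = table.dropna()
    if n_before - len(table):
        logger.info("follow-up model: %d at-risk rows dropped for missing "
                    "prior covariates", n_before - len(table))
    if table.empty:
        raise DataError("no usable at-risk observations")
    if table["observed"].nunique() < 2:
        raise DataError("degenerate follow-up outcome: every at-risk visit "
                        f"has observed={table['observed'].iloc[0]:g}")
    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    for cov in covariates:
        if cov == "season":
            # contrasts only for quarters actually visited, else singular
            levels = sorted(table["season"].unique())
            for q in levels[1:]:
                X[f"season[{q}]"] = (table["season"] == q).astype(float)
        else:
            X[cov] = pd.to_numeric(table[cov]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(table["observed"], X).fit(disp=False)
        except Exception as exc:
            raise ConvergenceError(
                "follow-up logistic regression failed (possible separation); "
                f"consider penalized estimation: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError(
            "follow-up logistic regression did not converge (possible "
            "separation); consider penalized estimation", last_state=res)
    preds = table[["subject_id", "visit", "observed"]].copy()
    preds["p_hat"] = res.predict(X)
    return FollowupModel(result=res, design_columns=list(X.columns),
                         predictions=preds, n_at_risk=len(table),
                         n_observed=int(table["observed"].sum()))


def compute_ipw_weights(panel: pd.DataFrame, model: FollowupModel,
                        clip_floor: float = 0.01,
                        cumulative: bool = False,
                        stabilized: bool = False) -> pd.DataFrame:
    """Per-observation weights: 1 for first visits, 1/p_hat for follow-ups.

    Probabilities are clipped below at ``clip_floor`` (clip events are
    flagged and logged) so weights stay bounded; ``cumulative=True``
    multiplies the inverse probabilities along each subject's visit
    history (the full correction for monotone dropout) instead of using
    the per-visit inverse alone; ``stabilized=True`` multiplies each
    follow-up's weight by the marginal retention fraction at its visit,
    which tempers weight variability without affecting consistency
    (stabilized weights are centred near 1 and may fall below it).
    """
    df = panel.sort_values(["subject_id", "visit"])
    first_visit = df.groupby("subject_id", sort=False)["visit"].transform("min")
    out = df[["subject_id", "visit"]].copy()
    out["first_visit"] = (df["visit"] == first_visit).to_numpy()
    preds = model.predictions.set_index(["subject_id", "visit"])["p_hat"]
    p_hat = pd.MultiIndex.from_frame(out[["subject_id", "visit"]]).map(preds)
    out["p_hat"] = np.where(out["first_visit"], np.nan, p_hat)
    if out.loc[~out["first_visit"], "p_hat"].isna().any():
        raise DataError("no predicted follow-up probability for some "
                        "observed follow-up rows")
    clipped = (~out["first_visit"]) & (out["p_hat"] < clip_floor)
    if clipped.any():
        logger.warning("clipped %d follow-up probabilities below %g",
                       int(clipped.sum()), clip_floor)
    out["clipped"] = clipped
    p = out["p_hat"].clip(lower=clip_floor)
    if stabilized:
        marginal = model.predictions.groupby("visit")["observed"].mean()
        num = out["visit"].map(marginal).fillna(1.0)
        out["weight"] = np.where(out["first_visit"], 1.0, num / p)
    else:
        out["weight"] = np.where(out["first_visit"], 1.0, 1.0 / p)
    if cumulative:
        out["weight"] = out.groupby(out["subject_id"].to_numpy())["weight"].cumprod()
    return out.loc[panel.index.intersection(out.index)].sort_index()


def weighted_refit(panel: pd.DataFrame, weights: pd.DataFrame | None,
                   spec: ModelSpec, genotypes=None) -> FitResult:
    """Refit a pollutant model with observation weights.

    Weighted estimating equations: Gaussian GEE with independence
    working correlation and robust (cluster) standard errors.  Passing
    ``weights=None`` fits the same estimator with unit weights, so the
    unweighted comparison shares every numerical detail.
    """
    y, X, groups, iqr, rows = build_design(panel, spec, genotypes)
    if weights is None:
        w = np.ones(len(y))
    else:
        keyed = weights.set_index(["subject_id", "visit"])["weight"]
        key = pd.MultiIndex.from_frame(
            panel.loc[rows, ["subject_id", "visit"]])
        w = np.asarray(key.map(keyed), dtype=float)
        if np.isnan(w).any():
            raise DataError("weights missing for some analysis rows")
        if np.any(w <= 0):
            raise DataError("IPW weights must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(y.to_numpy(), X.to_numpy(), groups=groups.to_numpy(),
                       family=sm.families.Gaussian(),
                       cov_struct=sm.cov_struct.Independence(), weights=w)
        res = model.fit()
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    return FitResult(
        params=params, bse=bse, llf=float("nan"), aic=float("nan"),
        n_obs=int(len(y)), n_subjects=int(groups.nunique()),
        converged=bool(getattr(res, "converged", True)),
        pollutant_term=f"{spec.pollutant}_lag{spec.lag}", iqr=iqr,
        random_intercept_var=float("nan"), residual_var=float(res.scale),
        row_index=X.index,
        fe_cov=pd.DataFrame(np.asarray(res.cov_params()),
                            index=X.columns, columns=X.columns))
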