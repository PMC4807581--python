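"""Configuration, orchestration and table-shell reporting.

``run_pipeline`` sequences the full analysis on either a synthetic
scenario or user-supplied CSV inputs: cohort exclusions, outcome
preparation, lagged exposures, genotype QC, lag selection and main
models, the single-SNP interaction screen, LD blocks and pruning,
genetic risk scores with tertile-stratified estimates and heterogeneity
tests, and the sensitivity analyses (2-df joint test columns,
alternative LD-pruned panel, IPW-weighted refits).  Every tabular
artifact is a plain CSV; a structured run log records seeds, selected
lags and fit diagnostics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grs as grs_mod
from . import ipw as ipw_mod
from . import synthetic
from .errors import ConfigurationError, PanelGxeError
from .exposure import (BP_OUTCOMES, HRV_OUTCOMES, HRV_RAW, POLLUTANTS,
                       attach_lagged_exposures, prepare_outcomes)
from .genetics import apply_hwe_exclusion, find_ld_blocks, ld_report
from .models import DEFAULT_COVARIATES, ModelSpec, fit_main_model, screen_all, select_lag

logger = logging.getLogger(__name__)

VALID_OUTCOMES = tuple(BP_OUTCOMES) + tuple(HRV_OUTCOMES)


@dataclass
class RunConfig:
    """Validated pipeline configuration with documented defaults."""

    seed: int = 0
    n_subjects: int = 200
    n_visits: int = 5
    n_snps: int = 10
    n_genes: int = 5
    outcomes: tuple = ("sbp", "log_sdnn")
    pollutants: tuple = ("pm10",)
    alpha: float = 0.05
    hwe_alpha: float = 1e-3
    ld_threshold: float = 0.8
    max_lag: int = 3
    do_joint_test: bool = False
    do_ipw: bool = False
    do_alternative_panel: bool = False
    effects: tuple = ()              # EffectSpec list for synthetic scenarios
    dropout: synthetic.DropoutSpec | None = None
    panel_csv: str | None = None     # supply all three to skip simulation
    genotype_csv: str | None = None
    snp_csv: str | None = None
    exposure_csv: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        for out in self.outcomes:
            if out not in VALID_OUTCOMES:
                raise ConfigurationError(
                    f"outcomes: unknown outcome {out!r}; valid: {VALID_OUTCOMES}")
        for pol in self.pollutants:
            if pol not in POLLUTANTS:
                raise ConfigurationError(
                    f"pollutants: unknown pollutant {pol!r}; valid: {POLLUTANTS}")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha: must be in (0, 1]")
        if self.max_lag not in (0, 1, 2, 3):
            raise ConfigurationError("max_lag: must be in {0,1,2,3}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        effects = tuple(synthetic.EffectSpec(**e) for e in raw.pop("effects", []))
        dropout = raw.pop("dropout", None)
        if dropout is not None:
            raw["dropout"] = synthetic.DropoutSpec(**dropout)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        for key in ("outcomes", "pollutants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(effects=effects, **raw)


def summarize_exposures(series: pd.DataFrame, dates) -> pd.DataFrame:
    """Survey-day exposure summary: mean, SD, median, range, IQR."""
    s = series.copy()
    s["date"] = pd.to_datetime(s["date"])
    dates = pd.to_datetime(pd.Series(list(dates))).drop_duplicates()
    sub = s[s["date"].isin(dates)]
    if len(sub) < 4:
        raise ConfigurationError("need at least 4 survey-day values")
    rows = []
    for var in [c for c in sub.columns if c != "date"]:
        v = sub[var].dropna().to_numpy()
        q1, q3 = np.quantile(v, [0.25, 0.75])
        rows.append({"variable": var, "mean": v.mean(), "sd": v.std(ddof=1),
                     "median": float(np.median(v)), "min": v.min(),
                     "max": v.max(), "iqr": q3 - q1})
    return pd.DataFrame(rows)


def cohort_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics shell (first visit per subject)."""
    base = panel.sort_values("visit").groupby("subject_id", as_index=False).first()
    rows = [("n", len(base)), ("female_pct", 100 * base["sex"].mean()),
            ("age_mean", base["age"].mean()), ("age_sd", base["age"].std(ddof=1)),
            ("bmi_mean", base["bmi"].mean())]
    for level in ("current", "ex", "non", "no_answer"):
        if "smoking" in base:
            rows.append((f"smoking_{level}_pct",
                         100 * (base["smoking"] == level).mean()))
    for var in ("sbp", "dbp", "map"):
        if var in base:
            rows.append((f"{var}_mean", base[var].mean()))
            rows.append((f"{var}_sd", base[var].std(ddof=1)))
    for var in HRV_RAW:
        if var in base:
            logs = np.log(base[var].dropna())
            rows.append((f"{var}_geo_mean", float(np.exp(logs.mean()))))
            rows.append((f"{var}_geo_sd", float(np.exp(logs.std(ddof=1)))))
    return pd.DataFrame(rows, columns=["statistic", "value"])


@dataclass
class ReportBundle:
    """Every table the pipeline emits, plus the run log."""

    cohort: pd.DataFrame
    exposure_summary: pd.DataFrame
    main_effects: pd.DataFrame
    qc_report: pd.DataFrame
    ld: pd.DataFrame
    screen: pd.DataFrame
    grs_tables: dict = field(default_factory=dict)        # family -> scores df
    stratified: pd.DataFrame | None = None
    heterogeneity: pd.DataFrame | None = None
    ipw_comparison: pd.DataFrame | None = None
    run_log: list = field(default_factory=list)

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        named = {"cohort_table.csv": self.cohort,
                 "exposure_summary.csv": self.exposure_summary,
                 "main_effects.csv": self.main_effects,
                 "qc_report.csv": self.qc_report,
                 "ld_report.csv": self.ld,
                 "screen_results.csv": self.screen,
                 "stratified_estimates.csv": self.stratified,
                 "heterogeneity.csv": self.heterogeneity,
                 "ipw_comparison.csv": self.ipw_comparison}
        for family, table in self.grs_tables.items():
            named[f"grs_{family}.csv"] = table
        for name, table in named.items():
            if table is not None:
                table.to_csv(out / name, index=False)
        (out / "run_log.json").write_text(json.dumps(self.run_log, indent=2,
                                                     default=str))
        return out


def _load_or_simulate(config: RunConfig):
    if config.panel_csv:
        from .genetics import GenotypeTable
        panel = pd.read_csv(config.panel_csv, parse_dates=["date"])
        genotypes = GenotypeTable.from_csv(config.genotype_csv, config.snp_csv)
        exposures = pd.read_csv(config.exposure_csv, parse_dates=["date"])
        return genotypes, exposures, panel
    snps, blocks = synthetic.default_snp_panel(
        n_snps=config.n_snps, n_genes=config.n_genes,
        hwe_violation_snps=("snp_03",) if config.n_snps >= 3 else ())
    effects = list(config.effects)
    have = {e.outcome for e in effects}
    for out in config.outcomes:
        raws = ("sbp", "dbp") if out == "map" else (out.removeprefix("log_"),)
        for raw in raws:
            if raw in have:
                continue
            hrv = raw in HRV_RAW
            effects.append(synthetic.EffectSpec(
                outcome=raw, pollutant=config.pollutants[0],
                main_effect=-0.02 if hrv else 0.9,
                random_intercept_sd=0.35 if hrv else 8.0,
                residual_sd=0.4 if hrv else 8.0))
            have.add(raw)
    return synthetic.simulate_cohort(
        n_subjects=config.n_subjects, n_visits=config.n_visits,
        effects=effects, snps=snps, blocks=blocks, seed=config.seed,
        dropout=config.dropout)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis; idempotent for a given config + seed."""
    log = [{"stage": "config", **{k: str(v) for k, v in
                                  dataclasses.asdict(config).items()}}]
    genotypes, exposures, panel = _load_or_simulate(config)

    roster = panel.groupby("subject_id").agg(
        has_bp=("sbp", lambda s: s.notna().any()),
        has_hrv=("sdnn", lambda s: s.notna().any())
        if "sdnn" in panel.columns else ("sbp", lambda s: True)).reset_index()
    filter_report, kept = grs_mod.apply_exclusions(roster)
    panel = panel[panel["subject_id"].isin(kept["subject_id"])]
    log.append({"stage": "exclusions",
                "n_enrolled": filter_report.n_enrolled,
                "exclusions": filter_report.exclusions,
                "n_analyzed": filter_report.n_analyzed})

    panel = prepare_outcomes(panel)
    panel = attach_lagged_exposures(panel, exposures, max_lag=config.max_lag)

    qc_table, hwe_log = apply_hwe_exclusion(genotypes, alpha=config.hwe_alpha)
    log.append({"stage": "hwe", "n_before": len(genotypes.snp_ids),
                "n_after": len(qc_table.snp_ids),
                "excluded": hwe_log["snp_id"].tolist()})
    qc_report = qc_table.snp_info.reset_index()
    pairs = ld_report(qc_table)
    blocks = find_ld_blocks(qc_table, threshold=config.ld_threshold, pairs=pairs)

    main_rows = []
    for outcome in config.outcomes:
        for pollutant in config.pollutants:
            spec = ModelSpec(outcome=outcome, pollutant=pollutant,
                             covariates=DEFAULT_COVARIATES)
            lag, aic_table = select_lag(panel, spec, max_lag=config.max_lag)
            fit = fit_main_model(panel, dataclasses.replace(spec, lag=lag))
            lo, hi = fit.conf_int(fit.pollutant_term)
            main_rows.append({"outcome": outcome, "pollutant": pollutant,
                              "lag": lag, "n_obs": fit.n_obs,
                              "estimate": fit.pollutant_estimate,
                              "ci_low": lo, "ci_high": hi, "iqr": fit.iqr})
            log.append({"stage": "main_model", "outcome": outcome,
                        "pollutant": pollutant, "lag": lag,
                        "aic_by_lag": aic_table["aic"].tolist(),
                        "n_obs": fit.n_obs, "converged": fit.converged})
    main_effects = pd.DataFrame(main_rows)

    screen = screen_all(panel, qc_table, pollutants=config.pollutants,
                        outcomes=config.outcomes, alpha=config.alpha,
                        joint=config.do_joint_test)
    log.append({"stage": "screen", "bp_positive": screen.bp_positive,
                "hrv_positive": screen.hrv_positive,
                "n_skipped": len(screen.skipped)})

    grs_tables = {}
    strat_rows, het_rows = [], []
    family_outcomes = {"blood_pressure": [o for o in config.outcomes
                                          if o in BP_OUTCOMES],
                       "heart_rate_variability": [o for o in config.outcomes
                                                  if o in HRV_OUTCOMES]}
    for family, fam_outs in family_outcomes.items():
        positive = (screen.bp_positive if family == "blood_pressure"
                    else screen.hrv_positive)
        if not fam_outs or not positive:
            continue
        risk_panel = grs_mod.panel_from_screen(screen, family, blocks)
        panels = {"primary": risk_panel}
        if config.do_alternative_panel:
            panels["alternative"] = grs_mod.alternative_panel(screen, family, blocks)
        for panel_name, rp in panels.items():
            scores = grs_mod.compute_grs(qc_table, rp)
            try:
                tertiles = grs_mod.assign_tertiles(scores)
            except PanelGxeError as exc:
                log.append({"stage": "grs", "family": family,
                            "panel": panel_name, "error": str(exc)})
                continue
            if panel_name == "primary":
                grs_tables[family] = pd.DataFrame(
                    {"subject_id": scores.index, "score": scores.to_numpy(),
                     "tertile": tertiles.groups.to_numpy()})
            for outcome in fam_outs:
                for pollutant in config.pollutants:
                    lag = screen.lag_choices[(outcome, pollutant)]
                    spec = ModelSpec(outcome=outcome, pollutant=pollutant, lag=lag)
                    if panel_name == "primary":
                        strat = grs_mod.stratified_association(
                            panel, tertiles.groups, spec)
                        strat.insert(0, "family", family)
                        strat_rows.append(strat)
                    try:
                        het = grs_mod.heterogeneity_test(panel, tertiles.groups, spec)
                    except PanelGxeError as exc:
                        log.append({"stage": "heterogeneity", "family": family,
                                    "panel": panel_name, "outcome": outcome,
                                    "error": str(exc)})
                        continue
                    het_rows.append({"family": family, "panel": panel_name,
                                     "outcome": outcome, "pollutant": pollutant,
                                     "p_heterogeneity": het.p_heterogeneity,
                                     "beta_product": het.beta_product})

    ipw_comparison = None
    if config.do_ipw:
        try:
            followup = ipw_mod.fit_followup_model(panel)
        except PanelGxeError as exc:
            followup = None
            log.append({"stage": "ipw", "skipped": str(exc)})
    if config.do_ipw and followup is not None:
        weights = ipw_mod.compute_ipw_weights(panel, followup)
        rows = []
        for _, row in main_effects.iterrows():
            spec = ModelSpec(outcome=row["outcome"], pollutant=row["pollutant"],
                             lag=int(row["lag"]))
            unweighted = ipw_mod.weighted_refit(panel, None, spec)
            weighted = ipw_mod.weighted_refit(panel, weights, spec)
            rows.append({"outcome": row["outcome"], "pollutant": row["pollutant"],
                         "mixed_estimate": row["estimate"],
                         "unweighted_estimate": unweighted.pollutant_estimate,
                         "weighted_estimate": weighted.pollutant_estimate})
        ipw_comparison = pd.DataFrame(rows)
        log.append({"stage": "ipw", "n_at_risk": followup.n_at_risk,
                    "n_observed": followup.n_observed})

    visit_dates = panel["date"].unique()
    bundle = ReportBundle(
        cohort=cohort_table(panel),
        exposure_summary=summarize_exposures(exposures, visit_dates),
        main_effects=main_effects,
        qc_report=qc_report,
        ld=pairs,
        screen=screen.results,
        grs_tables=grs_tables,
        stratified=pd.concat(strat_rows, ignore_index=True) if strat_rows else None,
        heterogeneity=pd.DataFrame(het_rows) if het_rows else None,
        ipw_comparison=ipw_comparison,
        run_log=log)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
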