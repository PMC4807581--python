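"""Synthetic elderly-panel cohort generator.

Emulates the statistical structure the analysis assumes, so the whole
pipeline is testable without access to any cohort data: biallelic SNP
genotypes with configurable within-gene LD and optional Hardy-Weinberg
violations, daily pollutant and weather series, repeated-measures
outcomes from a random-intercept linear model with planted SNP x
pollutant interaction effects, and (optionally non-random) loss to
follow-up.

Default parameter values reproduce the marginal summaries of a
~547-subject urban elderly panel followed for up to five visits over
two years: PM10 42.6 (24.7) ug/m3, NO2 36.5 (12.6) ppb, SO2 4.0 (2.1)
ppb on survey days; 73.9 % women, age 70.7 (5.2) years, BMI ~24.7
kg/m2, 5.5 % current smokers; SBP 131.8 (16.7) / DBP 74.5 (9.9) mmHg
and log-normal HRV outcomes (geometric mean SDNN ~26.9 ms).

Reproducibility: every operation derives an independent random stream
from (seed, operation-name), so modules can be regenerated separately
and identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, DataError
from .exposure import HRV_RAW
from .genetics import GenotypeTable

#: Default pollutant marginals on survey days: mean, SD, lag-1 autocorrelation.
DEFAULT_POLLUTANT_PARAMS = {
    "pm10": (42.6, 24.7, 0.5),
    "no2": (36.5, 12.6, 0.6),
    "so2": (4.0, 2.1, 0.6),
}

#: Temperate-climate annual cycle: mean (degC), amplitude, daily noise SD,
#: plus mean/SD of the dew-point depression (temp minus dew point).
DEFAULT_MET_PARAMS = {
    "temp_mean": 12.5,
    "temp_amplitude": 14.0,
    "temp_noise_sd": 3.0,
    "dew_depression_mean": 8.0,
    "dew_depression_sd": 4.0,
}

#: Baseline covariate marginals of the emulated cohort.
DEFAULT_COVARIATE_MARGINALS = {
    "female": 0.739,
    "age_mean": 70.7,
    "age_sd": 5.2,
    "age_min": 60.0,
    "bmi_mean": 24.7,
    "bmi_sd": 3.0,
    "smoking": {"current": 30 / 547, "ex": 36 / 547, "non": 467 / 547,
                "no_answer": 14 / 547},
    "alcohol": {"current": 118 / 547, "non": 412 / 547, "no_answer": 17 / 547},
    "htn_med": 0.30,
    "schooling_mean": 6.0,
    "schooling_sd": 4.0,
}

#: Generating-model intercepts (BP in mmHg; HRV on the natural-log scale).
DEFAULT_INTERCEPTS = {
    "sbp": 131.8, "dbp": 74.5,
    "sdnn": log(26.9), "rmssd": log(20.5), "lf": log(90.8), "hf": log(66.9),
}

POLLUTANT_FLOOR = 0.1  # keeps concentrations positive and IQRs well defined


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one named operation under a master seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Scenario specification types


@dataclass(frozen=True)
class SnpSpec:
    """One biallelic SNP: id, gene, minor-allele frequency.

    ``hwe_violation`` switches genotype draws to an inbreeding-style
    departure from Hardy-Weinberg proportions with heterozygote
    probability 2pq(1-F); F = ``inbreeding_f``.
    """

    snp_id: str
    gene: str
    maf: float
    hwe_violation: bool = False
    inbreeding_f: float = 0.35

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ConfigurationError(f"{self.snp_id}: maf must be in (0, 0.5]")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ConfigurationError(f"{self.snp_id}: inbreeding_f in [0, 1]")


@dataclass(frozen=True)
class LdBlockSpec:
    """A set of SNPs inheriting jointly from block haplotypes.

    ``haplotype_freqs`` has length 2**k for k member SNPs; haplotype i
    carries the minor allele at member j iff bit j of i is set (member 0
    is the least significant bit).
    """

    gene: str
    snp_ids: tuple
    haplotype_freqs: tuple

    def __post_init__(self):
        k = len(self.snp_ids)
        if k < 2:
            raise ConfigurationError("an LD block needs at least 2 SNPs")
        f = np.asarray(self.haplotype_freqs, dtype=float)
        if f.shape != (2 ** k,) or np.any(f < 0):
            raise ConfigurationError("haplotype_freqs must be 2**k non-negative values")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ConfigurationError("haplotype_freqs must sum to 1 (tol 1e-12)")

    def marginal_maf(self, j: int) -> float:
        f = np.asarray(self.haplotype_freqs, dtype=float)
        idx = np.arange(len(f))
        return float(f[(idx >> j) & 1 == 1].sum())


def two_snp_haplotypes(maf_a: float, maf_b: float, target_d_prime: float) -> tuple:
    """Four haplotype frequencies for a 2-SNP block with a given |D'| > 0.

    D is set to ``target_d_prime * Dmax`` with positive sign (minor
    alleles co-occur).  Returned in LdBlockSpec order (ab, Ab, aB, AB
    with member 0 = the first SNP as the low bit).
    """
    pa, pb = maf_a, maf_b
    if not (0 < pa <= 0.5 and 0 < pb <= 0.5):
        raise ConfigurationError("mafs must be in (0, 0.5]")
    if not 0 <= target_d_prime <= 1:
        raise ConfigurationError("|D'| must be in [0, 1]")
    dmax = min(pa * (1 - pb), (1 - pa) * pb)
    d = target_d_prime * dmax
    f_ab = (1 - pa) * (1 - pb) + d
    f_Ab = pa * (1 - pb) - d
    f_aB = (1 - pa) * pb - d
    f_AB = pa * pb + d
    return (f_ab, f_Ab, f_aB, f_AB)


@dataclass
class EffectSpec:
    """Generating model for one outcome.

    outcome_ij = intercept + covariate effects + beta_main * x_ij
                 + sum_k beta_int * g_ik * x_ij + b_i + e_ij

    where x_ij is the pollutant at ``true_lag`` days before visit j,
    scaled to its IQR over visit days, and g_ik is subject i's
    risk-allele count at interacting SNP k.  HRV outcomes are generated
    on the log scale and stored as positive raw values.
    """

    outcome: str
    pollutant: str
    main_effect: float = 0.0                       # outcome units per IQR
    interaction_per_risk_allele: float = 0.0       # per IQR per risk allele
    interacting_snps: tuple = ()                   # (snp_id, orientation)
    covariate_effects: dict = field(default_factory=dict)
    random_intercept_sd: float = 8.0
    residual_sd: float = 8.0
    true_lag: int = 0
    intercept: float | None = None
    #: SD of a subject-specific per-visit drift (outcome units/visit);
    #: nonzero values give subjects their own outcome trajectories
    random_slope_sd: float = 0.0

    def __post_init__(self):
        if self.true_lag not in (0, 1, 2, 3):
            raise ConfigurationError("true_lag must be in {0,1,2,3}")
        if (self.random_intercept_sd < 0 or self.residual_sd < 0
                or self.random_slope_sd < 0):
            raise ConfigurationError("standard deviations must be >= 0")
        for _, orientation in self.interacting_snps:
            if orientation not in ("minor_is_risk", "major_is_risk"):
                raise ConfigurationError(f"unknown orientation {orientation!r}")


@dataclass
class DropoutSpec:
    """Loss-to-follow-up mechanism.

    ``none`` keeps every planned visit; ``MCAR`` retains each follow-up
    with a constant probability expit(intercept); ``MAR-on-covariates``
    evaluates the logit linear predictor at the prior visit's row
    (keys of ``logit_coefficients`` are panel columns, plus
    ``intercept``).  Dropout is monotone: once lost, lost.
    """

    mechanism: str = "none"
    logit_coefficients: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mechanism not in ("none", "MCAR", "MAR-on-covariates"):
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "MAR-on-covariates":
            if not any(k != "intercept" for k in self.logit_coefficients):
                raise ConfigurationError(
                    "MAR-on-covariates requires at least one covariate coefficient")


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(n_subjects: int, snps, blocks=(), seed: int = 0,
                       missing_rate: float = 0.0) -> GenotypeTable:
    """Draw an additive-coded genotype table.

    SNPs outside any block are two independent allele draws at their
    MAF (Hardy-Weinberg in expectation) unless flagged with
    ``hwe_violation``; block members are built from two haplotypes per
    subject drawn from the block's haplotype distribution.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    spec_by_id = {s.snp_id: s for s in snps}
    if len(spec_by_id) != len(snps):
        raise ConfigurationError("snp_id values must be unique")
    in_block = set()
    for block in blocks:
        for j, snp_id in enumerate(block.snp_ids):
            if snp_id not in spec_by_id:
                raise ConfigurationError(f"block references unknown SNP {snp_id}")
            if snp_id in in_block:
                raise ConfigurationError(f"SNP {snp_id} is in two blocks")
            in_block.add(snp_id)
            implied = block.marginal_maf(j)
            if abs(implied - spec_by_id[snp_id].maf) > 1e-9:
                raise ConfigurationError(
                    f"haplotype_freqs imply maf {implied:.6g} for {snp_id}, "
                    f"spec says {spec_by_id[snp_id].maf:.6g}")

    rng = substream(seed, "genotypes")
    geno = {}
    for spec in snps:
        if spec.snp_id in in_block:
            continue
        if spec.hwe_violation:
            p, q = spec.maf, 1 - spec.maf
            f = spec.inbreeding_f
            probs = [q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q]
            geno[spec.snp_id] = rng.choice(3, size=n_subjects, p=probs)
        else:
            geno[spec.snp_id] = rng.binomial(2, spec.maf, size=n_subjects)
    for block in blocks:
        f = np.asarray(block.haplotype_freqs, dtype=float)
        haps = rng.choice(len(f), size=(n_subjects, 2), p=f / f.sum())
        for j, snp_id in enumerate(block.snp_ids):
            geno[snp_id] = ((haps >> j) & 1).sum(axis=1)

    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    frame = pd.DataFrame({s.snp_id: geno[s.snp_id] for s in snps},
                         index=pd.Index(subjects, name="subject_id"), dtype=float)
    if missing_rate > 0:
        mask = rng.random(frame.shape) < missing_rate
        frame = frame.mask(mask)
    info = pd.DataFrame({"gene": [s.gene for s in snps],
                         "spec_maf": [s.maf for s in snps]},
                        index=pd.Index([s.snp_id for s in snps], name="snp_id"))
    return GenotypeTable(frame, info)


def default_snp_panel(n_snps: int = 47, n_genes: int = 18, seed: int = 7,
                      hwe_violation_snps=("snp_13",)):
    """A deterministic SNP panel resembling an oxidative-stress candidate set.

    ~47 SNPs over ~18 genes, MAF spread over [0.05, 0.5], a handful of
    high-|D'| two-SNP blocks within genes, and (by default) one SNP
    planted out of Hardy-Weinberg equilibrium.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{g + 1:02d}" for g in range(n_genes)]
    gene_of = [genes[i % n_genes] for i in range(n_snps)]
    gene_of.sort()
    mafs = np.round(np.linspace(0.05, 0.5, n_snps), 3)
    rng.shuffle(mafs)
    snps = []
    for i in range(n_snps):
        snp_id = f"snp_{i + 1:02d}"
        snps.append(SnpSpec(snp_id=snp_id, gene=gene_of[i], maf=float(mafs[i]),
                            hwe_violation=snp_id in set(hwe_violation_snps)))
    # pair consecutive same-gene SNPs into a few strong blocks
    blocks = []
    used = set()
    targets = [0.98, 0.93, 1.0, 0.94]
    for a, b in zip(snps, snps[1:]):
        if len(blocks) == len(targets):
            break
        if (a.gene == b.gene and a.snp_id not in used and b.snp_id not in used
                and not a.hwe_violation and not b.hwe_violation):
            freqs = two_snp_haplotypes(a.maf, b.maf, targets[len(blocks)])
            blocks.append(LdBlockSpec(gene=a.gene, snp_ids=(a.snp_id, b.snp_id),
                                      haplotype_freqs=freqs))
            used.update((a.snp_id, b.snp_id))
    return snps, blocks


# ---------------------------------------------------------------------------
# Exposures and visit schedule


def simulate_exposure_series(n_days: int, start: str = "2008-07-01",
                             pollutant_params: dict | None = None,
                             met_params: dict | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Daily exposure series: AR(1) pollutants, sinusoidal temperature.

    Pollutants follow stationary AR(1) processes at the requested
    mean/SD/lag-1 autocorrelation, floored at 0.1 units.  Mean
    temperature is an annual sinusoid (coldest mid-January) plus noise;
    dew point is temperature minus a positive random depression.
    """
    if n_days < 4:
        raise ConfigurationError("n_days must be >= 4 (lags up to 3)")
    pparams = dict(DEFAULT_POLLUTANT_PARAMS, **(pollutant_params or {}))
    met = dict(DEFAULT_MET_PARAMS, **(met_params or {}))
    rng = substream(seed, "exposures")
    dates = pd.date_range(start, periods=n_days, freq="D")
    out = {"date": dates}
    for name, params in pparams.items():
        # (mean, sd, autocorr) with an optional 4th element: a secular
        # linear trend in units/year (urban pollutant levels drift)
        mean, sd, phi = params[:3]
        trend = params[3] if len(params) > 3 else 0.0
        if sd < 0:
            raise ConfigurationError(f"{name}: sd must be >= 0")
        if not -1 < phi < 1:
            raise ConfigurationError(f"{name}: autocorrelation must be in (-1, 1)")
        x = np.empty(n_days)
        x[0] = sd * rng.standard_normal()
        innov = sd * np.sqrt(1 - phi ** 2) * rng.standard_normal(n_days - 1)
        for t in range(1, n_days):
            x[t] = phi * x[t - 1] + innov[t - 1]
        level = mean + trend * (np.arange(n_days) - (n_days - 1) / 2) / 365.25
        out[name] = np.maximum(x + level, POLLUTANT_FLOOR)
    doy = dates.dayofyear.to_numpy()
    seasonal = met["temp_mean"] - met["temp_amplitude"] * np.cos(
        2 * np.pi * (doy - 15) / 365.25)
    temp = seasonal + met["temp_noise_sd"] * rng.standard_normal(n_days)
    depression = np.maximum(
        rng.normal(met["dew_depression_mean"], met["dew_depression_sd"], n_days), 0.5)
    out["mean_temp"] = temp
    out["dew_point"] = temp - depression
    return pd.DataFrame(out)


def make_visit_schedule(subject_ids, n_visits: int = 5,
                        start: str = "2008-08-15", period_days: int = 700,
                        jitter_days: int = 14, seed: int = 0) -> pd.DataFrame:
    """Planned visit dates: evenly spaced waves with uniform jitter.

    ``n_visits`` waves are centred evenly over ``period_days`` starting
    at ``start``; each subject's visit is jittered by up to
    +/- ``jitter_days`` days around its wave centre.
    """
    rng = substream(seed, "schedule")
    start_ts = pd.Timestamp(start)
    step = period_days / max(n_visits - 1, 1)
    rows = []
    for i, subject in enumerate(subject_ids):
        for v in range(n_visits):
            jitter = int(rng.integers(-jitter_days, jitter_days + 1))
            rows.append((subject, v + 1,
                         start_ts + pd.Timedelta(days=round(v * step) + jitter)))
    return pd.DataFrame(rows, columns=["subject_id", "visit", "date"])


# ---------------------------------------------------------------------------
# Covariates and outcomes


def simulate_covariates(subject_ids, seed: int = 0,
                        marginals: dict | None = None) -> pd.DataFrame:
    """Baseline covariates drawn independently at the cohort marginals."""
    m = dict(DEFAULT_COVARIATE_MARGINALS, **(marginals or {}))
    rng = substream(seed, "covariates")
    n = len(subject_ids)
    age = rng.normal(m["age_mean"], m["age_sd"], n)
    age = np.where(age < m["age_min"], m["age_min"] + np.abs(age - m["age_min"]) % 10, age)
    smoking_levels = list(m["smoking"])
    smoking_p = np.array([m["smoking"][k] for k in smoking_levels], dtype=float)
    alcohol_levels = list(m["alcohol"])
    alcohol_p = np.array([m["alcohol"][k] for k in alcohol_levels], dtype=float)
    frame = pd.DataFrame({
        "subject_id": list(subject_ids),
        "age": np.round(age, 1),
        "sex": (rng.random(n) < m["female"]).astype(int),  # 1 = female
        "smoking": rng.choice(smoking_levels, size=n, p=smoking_p / smoking_p.sum()),
        "alcohol": rng.choice(alcohol_levels, size=n, p=alcohol_p / alcohol_p.sum()),
        "bmi_baseline": np.round(rng.normal(m["bmi_mean"], m["bmi_sd"], n), 1),
        "htn_med": (rng.random(n) < m["htn_med"]).astype(int),
        "schooling": np.clip(np.round(rng.normal(m["schooling_mean"],
                                                 m["schooling_sd"], n)), 0, 18).astype(int),
    })
    return frame


def risk_allele_count(genotypes: pd.DataFrame, interacting_snps) -> pd.Series:
    """Per-subject risk-allele count over (snp_id, orientation) pairs."""
    total = pd.Series(0.0, index=genotypes.index)
    for snp_id, orientation in interacting_snps:
        g = genotypes[snp_id]
        total = total + (g if orientation == "minor_is_risk" else 2.0 - g)
    return total


def simulate_panel_outcomes(genotypes: GenotypeTable, exposures: pd.DataFrame,
                            schedule: pd.DataFrame, effects,
                            seed: int = 0,
                            covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format panel with outcomes from the random-intercept model.

    Every outcome needs exactly one :class:`EffectSpec`.  Visit dates
    must lie inside the exposure series minus the largest true lag.
    """
    effects = list(effects)
    outcomes = [e.outcome for e in effects]
    if len(set(outcomes)) != len(outcomes):
        raise ConfigurationError("each outcome needs exactly one EffectSpec")
    exp = exposures.copy()
    exp["date"] = pd.to_datetime(exp["date"])
    exp = exp.set_index("date")
    panel = schedule.copy()
    panel["date"] = pd.to_datetime(panel["date"])
    max_lag = max((e.true_lag for e in effects), default=0)
    needed = pd.concat([panel["date"] - pd.Timedelta(days=k)
                        for k in range(max_lag + 1)])
    missing = needed[~needed.isin(exp.index)]
    if len(missing):
        raise DataError(f"visit requires exposure on {missing.iloc[0].date()}, "
                        "outside the series")

    if covariates is None:
        covariates = simulate_covariates(genotypes.genotypes.index, seed=seed)
    panel = panel.merge(covariates, on="subject_id", how="left")
    rng = substream(seed, "outcomes")
    panel["bmi"] = panel["bmi_baseline"] + rng.normal(0, 0.5, len(panel))
    panel = panel.drop(columns="bmi_baseline")

    # apparent temperature same-day, available as a generating covariate
    from .exposure import apparent_temperature
    at0 = apparent_temperature(exp.loc[panel["date"], "mean_temp"].to_numpy(),
                               exp.loc[panel["date"], "dew_point"].to_numpy())
    # covariate effects apply to centred covariates so the intercept stays
    # at the cohort-typical outcome level whatever effects are planted
    centres = {"age": DEFAULT_COVARIATE_MARGINALS["age_mean"],
               "sex": DEFAULT_COVARIATE_MARGINALS["female"],
               "bmi": DEFAULT_COVARIATE_MARGINALS["bmi_mean"],
               "htn_med": DEFAULT_COVARIATE_MARGINALS["htn_med"],
               "schooling": DEFAULT_COVARIATE_MARGINALS["schooling_mean"],
               "at": 12.0}
    gen_covs = {"age": panel["age"].to_numpy() - centres["age"],
                "sex": panel["sex"].to_numpy() - centres["sex"],
                "bmi": panel["bmi"].to_numpy() - centres["bmi"],
                "htn_med": panel["htn_med"].to_numpy() - centres["htn_med"],
                "schooling": panel["schooling"].to_numpy() - centres["schooling"],
                "at": at0 - centres["at"]}

    subj_index = pd.Index(panel["subject_id"])
    for effect in effects:
        e_rng = substream(seed, f"outcome:{effect.outcome}")
        lag_dates = panel["date"] - pd.Timedelta(days=effect.true_lag)
        x_raw = exp.loc[lag_dates, effect.pollutant].to_numpy()
        q1, q3 = np.quantile(x_raw, [0.25, 0.75])
        iqr = q3 - q1
        if iqr <= 0:
            raise ConfigurationError(f"degenerate exposure for {effect.outcome}")
        x = x_raw / iqr
        lin = np.full(len(panel), DEFAULT_INTERCEPTS.get(effect.outcome, 0.0)
                      if effect.intercept is None else effect.intercept)
        for name, beta in effect.covariate_effects.items():
            if name not in gen_covs:
                raise ConfigurationError(f"unknown generating covariate {name!r}")
            lin = lin + beta * gen_covs[name]
        lin = lin + effect.main_effect * x
        if effect.interacting_snps:
            g = risk_allele_count(genotypes.genotypes, effect.interacting_snps)
            lin = lin + (effect.interaction_per_risk_allele
                         * g.reindex(subj_index).to_numpy() * x)
        b = e_rng.normal(0, effect.random_intercept_sd,
                         genotypes.genotypes.shape[0])
        b_by_subject = pd.Series(b, index=genotypes.genotypes.index)
        value = (lin + b_by_subject.reindex(subj_index).to_numpy()
                 + e_rng.normal(0, effect.residual_sd, len(panel)))
        if effect.random_slope_sd > 0:
            s = e_rng.normal(0, effect.random_slope_sd,
                             genotypes.genotypes.shape[0])
            s_by_subject = pd.Series(s, index=genotypes.genotypes.index)
            value = value + (s_by_subject.reindex(subj_index).to_numpy()
                             * (panel["visit"].to_numpy() - 1))
        panel[effect.outcome] = np.exp(value) if effect.outcome in HRV_RAW else value
    return panel.sort_values(["subject_id", "visit"]).reset_index(drop=True)


def apply_dropout(panel: pd.DataFrame, spec: DropoutSpec, seed: int = 0) -> pd.DataFrame:
    """Thin a panel by (possibly covariate-dependent) monotone dropout.

    The first visit is always retained; visit v is retained with
    probability expit(linear predictor at the visit v-1 row).  Once a
    visit is missed all later visits are missed.
    """
    if spec.mechanism == "none":
        return panel.copy()
    if panel.groupby("subject_id")["visit"].count().max() < 2:
        raise DataError("apply_dropout needs subjects with >= 2 visits")
    rng = substream(seed, "dropout")
    coeffs = dict(spec.logit_coefficients)
    df = panel.sort_values(["subject_id", "visit"])
    lp = np.full(len(df), coeffs.get("intercept", 0.0))
    for name, beta in coeffs.items():
        if name == "intercept":
            continue
        if name not in df.columns:
            raise ConfigurationError(f"dropout covariate {name!r} not in panel")
        lp = lp + beta * df[name].to_numpy(dtype=float)
    # retention probability of each row = expit(lp of the *prior* row
    # within the same subject); the first row of a subject is always kept
    grp = df.groupby("subject_id", sort=False)
    prob_prev = pd.Series(expit(lp), index=df.index).groupby(
        df["subject_id"], sort=False).shift(1)
    first = grp.cumcount() == 0
    missed = (~first).to_numpy() & (rng.random(len(df))
                                    >= prob_prev.fillna(1.0).to_numpy())
    lost = pd.Series(missed, index=df.index).groupby(
        df["subject_id"].to_numpy()).cummax()  # monotone
    return df.loc[~lost.to_numpy()].sort_index().copy()


# ---------------------------------------------------------------------------
# Convenience scenario


def simulate_cohort(n_subjects: int = 547, n_visits: int = 5, effects=(),
                    snps=None, blocks=None, seed: int = 0,
                    dropout: DropoutSpec | None = None):
    """End-to-end scenario: genotypes, exposures, schedule, panel.

    Returns ``(genotypes, exposures, panel)``.  The exposure series
    covers the visit window plus a 10-day lag buffer.
    """
    if snps is None:
        panel_snps, panel_blocks = default_snp_panel()
        snps = panel_snps
        blocks = panel_blocks if blocks is None else blocks
    blocks = blocks or ()
    genotypes = simulate_genotypes(n_subjects, snps, blocks, seed=seed)
    exposures = simulate_exposure_series(n_days=760, start="2008-07-01", seed=seed)
    schedule = make_visit_schedule(genotypes.genotypes.index, n_visits=n_visits,
                                   start="2008-08-15", period_days=700, seed=seed)
    panel = simulate_panel_outcomes(genotypes, exposures, schedule, effects, seed=seed)
    if dropout is not None:
        panel = apply_dropout(panel, dropout, seed=seed)
    return genotypes, exposures, panel
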