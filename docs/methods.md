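# Methods

`panelgxe` implements a gene–environment interaction analysis for
repeated-measures (panel) studies of short-term air-pollution exposure:
single-SNP interaction screening in linear mixed models, genetic risk
score (GRS) construction over the interaction-positive SNPs, tertile-
stratified effect estimation with a heterogeneity test, and an
inverse-probability-of-follow-up-weighting (IPW) sensitivity analysis.
A synthetic-cohort generator reproduces the statistical structure such
an analysis assumes, so every stage is testable end to end without any
cohort data.

## The analysis model

All inference is built on subject-level random-intercept linear mixed
models fitted by maximum likelihood (statsmodels `MixedLM`):

    y_ij = β₀ + β_x·x_ij + γ'z_ij + b_i + e_ij,
    b_i ~ N(0, σ_b²),  e_ij ~ N(0, σ_e²)

where `y_ij` is subject i's outcome at visit j — systolic or diastolic
blood pressure (SBP/DBP, mmHg), mean arterial pressure
(MAP = SBP/3 + 2·DBP/3), or a log-transformed heart-rate-variability
(HRV) measure (ln SDNN, ln RMSSD, ln LF, ln HF; these are approximately
log-normal) — and `x_ij` is the daily pollutant concentration (PM₁₀,
NO₂ or SO₂) at a lag of 0–3 days before the visit, divided by its
interquartile range so β_x reads "outcome change per IQR increase".
`z_ij` is the a-priori adjustment set: age, sex, smoking status
(4 levels), alcohol drinking (3 levels), BMI, hypertension medication,
and apparent temperature, AT = −2.653 + 0.994·T + 0.0153·D² (T = daily
mean temperature °C, D = dew point °C), entered at the same lag as the
pollutant. Age, sex, smoking, alcohol and medication are
time-independent; BMI and apparent temperature are time-varying.

Design choices worth knowing:

- **ML, not REML.** Lags are chosen by AIC across fixed-effect variants
  and the 2-df joint test is a likelihood-ratio test; both require ML.
  AIC is computed as 2k − 2ℓ with k = fixed effects + 2 variance
  parameters.
- **Lag selection** fits lags 0–3 on the *identical* complete-case
  observation set and takes the minimum-AIC lag (ties, compared after
  rounding AIC to 6 decimals, break to the smallest lag). It is done
  once per (outcome, pollutant) pair on the main model and reused for
  all SNP models of that pair.
- **Interaction test.** The SNP enters additively (minor-allele count
  0/1/2) together with SNP × pollutant; the default "p for interaction"
  is the Wald test on the product term (an LRT variant is available).
  The 2-df joint test compares the full model against the nested model
  without both SNP terms, on the same rows, with χ²₂ reference.
- **Risk-allele orientation** is a definition, not an estimate: the
  minor allele is "risk" when the interaction points adverse — positive
  for BP outcomes, negative for log-HRV outcomes.
- **Categorical covariates** enter as indicator contrasts against the
  most frequent level; contrasts are built only from levels present in
  the analysis subset, so rare levels ("did not answer") cannot leave
  an all-zero, singular column inside a small stratum.
- **IQR convention**: linear-interpolation quantiles (numpy default,
  R type 7), computed over the analysis rows (survey days) at the
  model's lag. Stratified fits reuse the whole-cohort IQR so per-IQR
  estimates are comparable across strata.
- The optimizer is BFGS with a Powell fallback, which handles the
  σ_b → 0 boundary; boundary fits (random-intercept variance ≈ 0)
  reproduce OLS.

## Genotype QC and LD structure

Minor-allele frequency is computed after orienting each SNP to its
minor allele. Hardy–Weinberg equilibrium is tested per SNP with the
1-df Pearson chi-square against n·(p², 2pq, q²) at the sample allele
frequency; SNPs with p below the threshold (default 10⁻³) are excluded
before any modelling.

Pairwise linkage disequilibrium within genes uses the classic two-locus
EM for haplotype frequencies from unphased genotypes: only double
heterozygotes are phase-ambiguous and are split between the cis (AB/ab)
and trans (Ab/aB) resolutions in proportion to the current frequency
products. The EM starts at linkage-equilibrium products, stops when the
largest frequency change is < 10⁻⁸ (max 1000 iterations), and its
log-likelihood trace is retained so monotonicity can be asserted.
|D'| = D/D_max with D = f_AB − p_A·p_B and
D_max = min(p_A·q_B, q_A·p_B) for D > 0, min(p_A·p_B, q_A·q_B)
otherwise. Blocks are connected components of the within-gene
|D'| > 0.8 graph (the threshold is configurable; the pruned pairs in
the motivating study all had |D'| ≥ 0.93, and the study never states
its cutoff). One SNP per block is retained — by default the member with
the smallest single-SNP interaction p-value, with an "other member"
rule for the alternative-panel sensitivity analysis.

The EM is validated against an independent brute-force grid
maximization of the 3×3 genotype-table multinomial likelihood over the
haplotype-frequency simplex (coarse 0.01 grid, then local refinements
to a 10⁻⁵ step; the refinement is needed because |D'| amplifies
frequency quantization by ~1/D_max).

## Genetic risk scores and stratification

The GRS is the unweighted risk-allele count over the pruned panel
(weighted scores are deliberately not offered: there is no principled
single weight per SNP when each SNP's relevance is an interaction, not
a main effect). With K SNPs the score lies in [0, 2K]; subjects missing
any panel genotype get a missing score by default (per-SNP mean-dose
imputation is available). Orientation per SNP is inherited from its
smallest-p interaction within the outcome family.

Tertiles cut the integer scores at the empirical 1/3 and 2/3 quantiles;
ties at a cutpoint go to the lower group, yielding contiguous integer
bands. A distribution so skewed that fewer than two groups are nonempty
is an error. The pollutant effect is then re-estimated within each
tertile, and heterogeneity is tested by adding the ordinal tertile
score (0/1/2) and its product with the pollutant to the pooled model
(Wald p on the product; a 2-df categorical version is available).

## The IPW sensitivity analysis

A logistic model estimates each subject's probability of attending
visit v ≥ 2 given attendance at v − 1, from the prior visit's age, sex,
BMI, years of schooling, SBP, season (calendar quarter) and outdoor
temperature. Weights are 1 for first observations and 1/p̂ for observed
follow-ups (p̂ clipped below at 0.01), per-visit by default; cumulative
products along the visit history — the full correction under monotone
dropout — and stabilized variants (numerator = marginal retention at
that visit) are options.

The weighted refit solves weighted estimating equations: a Gaussian GEE
with independence working correlation and cluster-robust standard
errors, the standard IPW vehicle for longitudinal dropout. The weights
are *not* pushed through the mixed-model likelihood, for a substantive
reason: a correctly specified random-intercept likelihood is already
consistent under dropout that depends on the observed outcome history
(MAR), so weighting it demonstrates nothing; it is the
estimating-equation analysis that dropout biases and IPW repairs.
Unweighted comparisons run the same GEE with unit weights, so the two
fits differ only in the weights.

The bias-reduction demonstration uses a scenario where unweighted
estimation genuinely fails: subjects' BP trajectories drift
(random slope, SD 5 mmHg/visit), PM₁₀ declines secularly
(−6 µg/m³/year, mimicking policy-era improvements in urban particulate
levels), and retention at each visit depends on the prior visit's SBP
(log-odds −0.08 per mmHg around a 75 % mean retention). Selection on
trajectories gives the retained sample an emergent downward time trend
that the fitted model does not carry; because exposure also trends, the
unweighted pollutant coefficient is biased upward (~+0.8 per IQR
against a planted 1.0 at n = 1200 × 5), and cumulative stabilized
weights remove most of it.

## The synthetic cohort

The generator emulates an urban elderly panel, ~547 subjects with up to
5 visits over ~2 years:

- **Genotypes**: independent binomial allele draws at each SNP's MAF
  (so HWE holds in expectation); optional HWE violation via an
  inbreeding coefficient (P(het) = 2pq(1−F), default F = 0.35, chosen
  so a violation at n ≈ 550 is detected at α = 10⁻³ with near-certain
  power); LD blocks simulated by drawing two block haplotypes per
  subject from a specified haplotype distribution. A default 47-SNP /
  18-gene panel includes four two-SNP blocks at |D'| 0.98/0.93/1.0/0.94
  and one planted HWE violator.
- **Exposures**: stationary AR(1) daily series per pollutant at the
  survey-day marginals PM₁₀ 42.6 (24.7) µg/m³, NO₂ 36.5 (12.6) ppb,
  SO₂ 4.0 (2.1) ppb, lag-1 autocorrelation 0.5–0.6, floored at 0.1
  units; an optional linear trend (units/year, default 0). Temperature
  is an annual sinusoid (mean 12.5 °C, amplitude 14 °C, coldest
  mid-January, noise SD 3 °C); dew point subtracts a positive random
  depression (mean 8, SD 4 °C).
- **Covariates** are drawn independently at the cohort marginals
  (73.9 % female; age 70.7 (5.2), floor 60; BMI 24.7 (3.0) with
  ±0.5 visit-level jitter; smoking 5.5/6.6/85.4/2.6 %; alcohol
  21.6/75.3/3.1 %; hypertension medication 30 %; schooling ~N(6, 4)
  years rounded). The joint distribution is independent because no
  joint information exists to emulate. Covariate effects apply to
  centred covariates so planted intercepts stay at the cohort-typical
  outcome levels (SBP 131.8, DBP 74.5 mmHg; geometric means SDNN 26.9,
  RMSSD 20.5, LF ~90.8, HF 66.9).
- **Outcomes** follow exactly the analysis model above, with the
  true-lag pollutant scaled to its visit-day IQR, optional per-risk-
  allele interaction over a specified SNP set, and optional random
  visit-slope. HRV outcomes are generated on the log scale and stored
  as positive raw values.
- **Visit schedule**: 5 waves evenly spaced over 700 days starting
  mid-August, ±14-day uniform jitter per subject-visit (spacing and
  jitter are parameters — real survey timing is unknown).
- **Dropout** is monotone: the first visit is always kept and each
  later visit is retained with probability expit of a linear predictor
  in the *prior* visit's row (prior outcomes allowed — that is still
  MAR).

Every operation draws from an independent stream derived from
(master seed, operation name), so identical seeds give bit-identical
outputs and modules can be regenerated separately.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: spatial exposure misclassification
(one shared series stands in for nearest-monitor assignment),
covariate–covariate and gene–covariate dependence, genotyping error,
measurement error in BP/HRV, non-monotone (intermittent) missingness,
and any true biological interaction architecture. The simulations show
the *procedure* is calibrated and recovers what was planted, not that
the substantive findings generalize.

## Simulation studies (validation module)

Problem sizes were chosen to give informative Monte-Carlo precision at
desk scale: type-I calibration of the Wald interaction test and 2-df
joint LRT on 500 × 5 panels (band 0.035–0.065 at nominal 0.05);
95 % CI coverage of a planted interaction of 2.0 mmHg per IQR per risk
allele with σ_b = σ_e = 8 (band 93–97 %); the tertile signature run
with an 11-SNP GRS and a −0.03 per-IQR-per-allele interaction on
ln SDNN whose main effect is set to −β_int·E[G] so the whole-cohort
association is null — the published pattern of opposite low/high-
tertile directions with a null marginal association is reproducible
only under this marginal-null reading; and the IPW scenario described
above. Replicate counts differ between the test suite and the
acceptance script (each reports its own n); they trade Monte-Carlo
precision against run length, not correctness.

## Known limitations

- Two-locus EM only; no multi-SNP phasing, r², or confidence-interval
  block definitions.
- Weighted estimation is GEE-based; weighted estimates carry no
  log-likelihood or AIC.
- The heterogeneity test treats tertiles as ordinal by default; with
  strongly non-monotone modification the 2-df categorical variant is
  more appropriate.
- Single-pollutant models only; multi-pollutant co-adjustment is out of
  scope.
- The pipeline's GRS step degrades gracefully but uninformatively when
  the screen yields one or two SNPs: a near-degenerate integer score
  may not support tertiles (it is logged and skipped rather than
  forced).
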