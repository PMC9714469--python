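# Methods

This document describes the statistical methodology implemented in `curvemr`,
the model notation, parameter defaults, and the main design decisions. The
running application is an LDL-cholesterol (exposure, mmol/L) analysis of
diabetes (binary) and fasting blood glucose (FBG, continuous, mmol/L), but
every routine is generic in the exposure/outcome columns.

## 1. Cohort processing

**Input.** Tab- or comma-separated tables with one row per individual.
Required columns: `individual_id`, `sex` (1 = male), `age`, `ldl_c`, `fbg`;
all other columns are optional. A `schema` mapping renames arbitrary source
headers. Unparseable numeric cells and missing required columns raise a
`SchemaError` naming the offending column.

**Outlier handling.** For each screened continuous column, Tukey fences
Q1 − 1.5·IQR and Q3 + 1.5·IQR (type-7 quantiles) flag cells; flagged cells
are set to missing and the rows are kept. Columns with more than 10% missing
values are dropped before model fitting.

**Derived outcomes.** Diabetes is the inclusive disjunction of self-reported
diabetes, hypoglycemic drug use, FBG ≥ 7.0 mmol/L, or 2-h OGTT ≥ 11.1 mmol/L.
Hypertension is self-report, antihypertensive use, SBP ≥ 140 mmHg, or
DBP ≥ 90 mmHg. A disjunction with at least one positive criterion is positive
regardless of missingness elsewhere; a disjunction that is negative on the
observed criteria but has any criterion missing is itself missing
(negative-but-incomplete propagates).

**Summary table.** `summarize_by_outcome` produces the overall/control/case
long-format baseline table: `n (%)` per level for categorical variables
(percentages among the group's non-missing rows) and `median [Q1, Q3]` for
continuous ones.

## 2. Instruments and the genetic risk score

**QC.** A variant is dropped when its call rate is below 0.999 or its
Hardy–Weinberg equilibrium p-value is below 10⁻⁴. HWE uses the 1-df
chi-square test, switching to an exact mid-p computation when any expected
genotype count is below 5.

**Selection.** Candidate variants must reach genome-wide significance
(p < 5×10⁻⁸, strict inequality). Clumping is greedy over variants sorted by
ascending p (ties broken by chromosome, then position) in two tiers:
tier 1 removes a candidate whose LD r² with any retained variant on the same
chromosome within ±500 kb is ≥ 0.001; tier 2 then removes candidates with
r² ≥ 0.1 to any retained variant anywhere on the same chromosome. r² is the
squared Pearson correlation of dosages over pairwise-complete observations.

**Harmonization.** GWAS effect alleles are matched to the counted allele of
the genotype matrix; swapped alleles flip the weight's sign; strand-ambiguous
(A/T, C/G) and unmatchable variants are dropped.

**Score.** GRS_i = Σ_j w_j g_ij with missing dosages mean-imputed per
variant. Instrument strength is the partial F-statistic of the score in the
first-stage regression (exposure on score + sex + age + age²), with
incremental R²; F ≤ 10 flags a weak instrument.

## 3. Observational models

The adjusted GLM is `outcome ~ exposure + C` on complete cases, logistic for
binary and linear for continuous outcomes, with C = {age, sex, BMI, diabetes
family history, dyslipidemia, CHD, SBP, DBP} and additionally hypoglycemic
drug use for FBG.

**Restricted cubic splines.** With knots t₁ < … < t_k, the basis is the
linear term plus k − 2 terms

    [(x−t_j)₊³ − (x−t_{k−1})₊³ (t_k−t_j)/(t_k−t_{k−1})
               + (x−t_k)₊³ (t_{k−1}−t_j)/(t_k−t_{k−1})] / (t_k−t₁)²

which is linear beyond the boundary knots. Knots sit at Harrell's recommended
quantiles (k = 3: 10/50/90%, up to k = 7). The knot count is chosen by
minimum AIC = 2p − 2ℓ over candidates {3, 4, 5} on a fixed complete-case
sample; ties go to the smaller k. Nonlinearity is the likelihood-ratio test
of the k − 2 nonlinear terms (df = k − 2). Effect curves are link-scale
contrasts against a reference exposure with delta-method pointwise 95% bands.

## 4. Linear Mendelian randomization

Two-stage predictor substitution. Stage 1: exposure on GRS + sex + age + age²
by least squares. Stage 2: outcome on the stage-1 fitted exposure plus the
observational adjustment set (logistic or linear). The reported estimate is
the stage-2 coefficient of the fitted exposure (log-OR per mmol/L for
binary outcomes). Model-based SEs are the default; an individual-level
bootstrap (seeded; accepted when at least max(50, B/2) replicates converge)
is available. Covariates without variation in a subgroup (e.g. sex in a
sex-stratified analysis) are dropped from both stages. The single-instrument
Wald ratio β_yg/β_xg with delta-method SE is provided for cross-checks; with
no covariates it coincides with the two-stage estimate exactly.

## 5. Nonlinear Mendelian randomization

**Stratification.** The instrument-free exposure is the residual of exposure
on the GRS (simple regression). Individuals are ranked on this residual and
split into `n_strata` (default 10) near-equal groups; stratifying on the
residual rather than the exposure avoids collider bias.

**LACE.** Within each stratum, the two-stage linear MR estimate is the
localized average causal effect with its SE and the stratum's mean exposure.
Degenerate strata are dropped with a warning; more than 20% degenerate
aborts.

**Fractional-polynomial meta-regression.** The effect-curve *derivative* is
modelled as h′(x) = Σ_m β_m d/dx x^{p_m} with powers from
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 ≡ ln x; a repeated power contributes
x^p ln x). The LACE values are regressed on this derivative basis at the
stratum mean exposures by weighted least squares (weights 1/SE², no
intercept, Gaussian likelihood with known variances). All 8 degree-1 and 36
degree-2 combinations are scanned; degree 2 is adopted only when it beats the
best degree-1 model in a 1-df chi-square comparison at 0.05.

**Tests.**
* *Trend test*: inverse-variance-weighted regression of LACE on mean exposure
  with an intercept; two-sided normal p for the slope.
* *FP test*: chi-square of 2(ℓ_best − ℓ_linear) against the linear
  (constant-slope) model, df = 1 for a degree-1 non-unit power and 2 for
  degree 2; p = 1 when the best model *is* linear.

Note an intentional equivalence: in derivative space the design of the
degree-2 powers-(1, 2) model is [1, 2x], which spans the same space as the
trend regression's [1, x]; the slope z-statistic and p-value agree to machine
precision (property-tested). The degree-1 power-1 model itself is the IVW
*mean* of the LACEs, not the trend regression.

**Curve and significance.** The effect curve is the antiderivative of the
fitted slope model anchored at the median stratum-mean exposure, with
delta-method bands. A grid point is flagged significant only when the
numerical slopes of *both* confidence-band bounds share the sign of the
estimated slope there (slope-sign rule); grids beyond ±10% of the
stratum-mean range trigger an extrapolation warning.

## 6. Analytic power

For a binary outcome with causal odds ratio OR per SD of exposure, case
fraction K and instrument R², NCP = n·R²·ln(OR)²·K(1−K); for a continuous
outcome with standardized effect β, NCP = n·R²·β². Two-sided power at level α
is Φ(−z_{1−α/2} + √NCP) + Φ(−z_{1−α/2} − √NCP). OR and 1/OR give identical
power. The closed forms are validated against 2000-replicate brute-force
two-stage MR simulations (agreement within 0.03).

## 7. Synthetic cohort generator

The generator emulates an epidemiological cohort with a known causal curve:

* **Genotypes**: 30 biallelic variants, MAF ~ U(0.10, 0.45), dosages
  Binomial(2, MAF), positions ≥ 2.5 Mb apart round-robin over chromosomes
  1–22 (so no LD, and clumping retains all).
* **Exposure**: X = μ + Σ w_j (g_j − 2·MAF_j) + γU + ε, with raw weights
  |N(1, 0.3)| + 0.05 rescaled so the genetic component explains exactly the
  target variance share (default 4.9%); U ~ N(0,1) latent; X clipped at 0.1.
* **Outcome**: logit P(D=1) = c₀ + c₁(X−μ) + c₂(X−μ)² + δ·f(U), with
  f(U) = U (linear coupling) or (U²−1)/√2 (nonmonotone coupling; mean 0,
  variance 1). FBG is the analogous linear model.
* **Covariates**: sex, age, BMI (loads 0.3 on U), SBP/DBP, smoking, CHD,
  family history, drug-use flags; the latent `confounder` column is kept for
  diagnostics.

Preset scenarios: `NULL` (c₁ = c₂ = 0, linear confounding), `LINEAR_PROTECTIVE`
(c₁ = ln 0.44), `CAUSAL_U` (c₂ = 0.8), `SPURIOUS_U` (c₁ = c₂ = 0, γ = 0.6,
δ = 1.2, nonmonotone coupling).

**Why SPURIOUS_U works.** With X | U linear in U, E[U² | X] is a quadratic
function of X, so the observational log-odds inherit curvature of magnitude
≈ δ·γ²/(√2·σ_X⁴) ≈ 0.75 per (mmol/L)² — comparable to CAUSAL_U's genuine
c₂ = 0.8 — while G ⊥ U keeps every MR estimate unbiased at zero. The
coefficients (γ = 0.6, δ = 1.2) were fixed from this calculation *before* any
acceptance simulation was run.

**Scope and limits.** The generator reproduces the marginal structure needed
by the analyses (prevalence, exposure moments, instrument strength, the
confounding mechanism); it does not attempt LD structure, population
stratification, age-cohort effects, or selection bias.

## 8. Numerical choices

* GLMs are fitted with statsmodels (`OLS`/`Logit`) on explicit numpy design
  matrices; rank deficiency is detected up front and reported with the
  offending column's name.
* Quantiles are type-7 (numpy default) throughout.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  simulation is bit-for-bit reproducible.
* The default problem size (n = 4876, 30 variants, 10 strata, k ∈ {3,4,5})
  is the package's own choice of a realistic mid-size cohort; all routines
  accept other sizes.

## 9. Limitations

* Stage-2 model-based SEs ignore first-stage estimation noise; the bootstrap
  option addresses this at computational cost.
* The FP meta-regression treats stratum SEs as known variances (standard in
  this literature) and ignores between-stratum correlation of the LACE
  estimates.
* The slope-sign significance rule is a heuristic band-based screen, not a
  formal multiple-testing procedure.
* Analytic power assumes a normally distributed composite instrument and a
  rare-ish outcome approximation on the log-odds scale; the validation
  simulations quantify the (small) resulting gap.
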