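# Methods

This note documents the generative model, the estimators, the inference
rules, the numerical choices, and what the synthetic-data design does and
does not establish about real cohort data.

## The generative model

The synthetic cohort encodes the causal diagram the analysis assumes.  For
individual *i* and variant *j* (J independent biallelic loci, the
post-clumping world):

- dosages `d_ij ~ Binomial(2, p_j)` with `p_j ~ Uniform(0.05, 0.5)`;
  linkage disequilibrium is introduced only by explicit correlation
  matrices in clumping tests, never by the cohort generator, because every
  downstream stage operates on a clumped instrument.
- exposure (age at menarche, years):
  `X_i = μ_X + Σ_j γ_j (d_ij − 2p_j) + b_U U_i + ε_i`, with the `γ_j`
  rescaled so the score explains exactly `target_r2` of `Var(X)` in the
  population, and `ε` absorbing the remaining variance.  Defaults:
  `μ_X = 12.69`, `SD = 1.18` years, `target_r2 = 0.069`, J = 235,
  n = 13,398.
- confounder `U` (childhood body size proxy, standard normal), optionally
  loaded on the variants through `φ` (`corr(T, U) = φ/√(1+φ²)` where `T` is
  the standardised allele count) to simulate an independence-assumption
  violation.  Defaults: `U` lowers AAM by 0.25 years/SD and raises the
  latent symptom score by 0.15 SD.
- right-censoring: `X` is unobserved when `X > 14.41` years (the
  questionnaire age); at the default exposure distribution this is 7.25% of
  girls, matching `Φ((14.41−12.69)/1.18)`.
- continuous outcomes: a latent standard-normal score
  `L = θ(X−μ_X) + c_U U + Σ_j α_j (d_ij−2p_j) + covariate effects + noise`,
  mapped to raw scores by `exp(μ_L + σ_L L)` with `(μ_L, σ_L)` solved so the
  marginal mean/SD are 9.20/6.56 (symptoms) or 5.71/4.93 (pre-pubertal
  negative controls).  The log-normal map makes scores non-negative and
  right-skewed, so the transformation-selection step has real work to do.
- binary outcomes: `logit P(Y=1) = b_0 + θ_OR(X−μ_X) + c U + pleiotropy`,
  with `b_0` solved by root-finding on the realised linear predictor so the
  marginal prevalence is exact in expectation (default depression
  prevalence 5.2%; per-year log-OR defaults to `log(0.74)/1.18`).
- pleiotropy: a fraction `invalid_fraction` of variants receive a direct
  outcome effect `α_j = alpha_pleio` (directional) or `±alpha_pleio` with
  random signs (balanced).
- attrition: participation is Bernoulli with logit linear in baseline
  covariates (default: intercept 1.4, −0.3·U, +0.25·education ≈ 78%
  participation), i.e. missing-at-random given observed baselines — the
  identifying assumption of the inverse-probability weights.

Everything is drawn from one `numpy` Generator seeded by `SimParams.seed`;
the exposure-side effects are re-derived from the same seed when summary
statistics are generated, so individual-level and summary-level analyses of
one parameter set estimate the same causal quantity.

What the generator does **not** emulate: linkage disequilibrium and
imputation dosage uncertainty, pedigree/family structure, population
stratification beyond the `φ` mechanism, item-level measurement models for
the questionnaires, informative (not-at-random) missingness, and
registry-code extraction.  Tests passing against this generator therefore
establish that the estimators and decision rules behave as specified under
the assumed causal structure — not that the substantive conclusions would
survive violations the generator cannot produce.

## Instrument construction

Clumping is greedy by ascending p-value (ties broken by chromosome and
position for determinism): a SNP is kept if its LD r² with every
already-kept SNP within the window (default 10,000 kb, threshold 0.001) is
below threshold; SNPs absent from the LD panel count as independent and are
logged.  The allele score is `Σ_j d_ij w_j / J`; missing dosages error
unless mean-imputation by `2·eaf` is requested.  Batch and 20 principal
components are removed by least-squares residualisation (constant columns
absorbed by the intercept, collinear columns dropped with a warning).
Relevance is summarised by R² and `F = R²/((1−R²)/(n−2))`.  Steiger
filtering computes per-SNP variance explained as `z²/(z²+n)` on each side —
chosen over allele-frequency formulas because it needs no frequencies and
is standard practice — and removes SNPs with strictly greater outcome r²
(ties retained); an optional mode additionally requires Steiger's z-test on
the Fisher-transformed correlations to reject.

## Missing data

Only the censored exposure is imputed.  The imputation model is a linear
regression of observed AAM on covariates, log-transformed continuous
outcomes, negative controls and binary diagnoses; each of the m (default
20) imputations draws `σ²` from its scaled inverse-chi-square posterior and
coefficients from their conditional normal before sampling each censored
value from the implied normal truncated to [15, ∞) years.  The proper
posterior draws make Rubin's between-imputation variance genuinely
positive.  Binary diagnoses are never imputed.  Estimates are pooled with
`T = W̄ + (1+1/m)B` and the classic `(m−1)(1 + W̄/((1+1/m)B))²` degrees of
freedom.  Participation weights are stabilised (`marginal rate / fitted
probability` from a logistic model), truncated at the 1st/99th percentiles
by default, and audited by standardised mean differences of participants
against the full sample — the population the weights reconstruct.

## Models and estimators

- Transformation: the candidate in {identity, log(y+1), √y} minimising
  |skewness| wins; |kurtosis−3| breaks ties; the label is recorded.
  Scores are then z-standardised (sample SD), so betas are in SD units.
- Observational fits use statsmodels OLS/WLS and Logit/GLM; with weights
  the covariance is HC1.  Continuous covariate values beyond 3 SD are set
  missing before fitting.  One-tailed p-values follow each hypothesis's
  registered direction (negative for depression).
- 2SLS regresses the outcome on first-stage fitted exposure; the
  covariance uses the residual `y − [1,x]·β̂` (the original exposure, not
  the fitted values) inside an HC1 sandwich.  The logistic second stage
  uses two-stage predictor substitution by default — the registered
  description specifies only "a logistic model in the second stage" — with
  residual inclusion available behind a flag.  MR models carry no
  covariates (covariate adjustment inside MR can reintroduce bias).
- IVW is the fixed-effect weighted mean of Wald ratios (weights `1/se²`)
  with multiplicative random-effects SE inflation `√(Q/df)` when `Q/df>1`
  (never deflated).  MR-Egger orients exposure betas positive, fits a
  weighted regression with intercept, floors the dispersion at 1 and uses a
  t reference on J−2 df.  The weighted median interpolates the ratio at the
  50% cumulative-weight point and takes its SE from a seeded parametric
  bootstrap (1,000 draws).  The contamination mixture maximises
  `Σ_j max{log N(r_j; θ, se_j²), log N(r_j; 0, ψ²)}` over a θ grid
  (default 2,001 points spanning the 2nd–98th percentile of the ratios
  padded by three median SEs — the bulk of the distribution, so the peak is
  resolved even when a few ratios are wildly imprecise); ψ defaults to 1.5
  × the SD of the ratios; the 95% CI is the set with likelihood-ratio drop
  ≤ 3.84, reported verbatim (it can be asymmetric).  The PRESSO-style test
  computes the weighted sum of squared leave-one-out residuals, builds its
  null by parametric resampling of outcome betas around leave-one-out
  predictions (default 1,000 draws), flags per-SNP outliers at
  Bonferroni-corrected exceedance p-values, and reports the
  outlier-removed IVW.  MVMR is the weighted no-intercept regression of
  outcome betas on the exposure-beta matrix; conditional F for exposure k
  is the heterogeneity of regressing its betas on the other exposures'
  (weighted by that exposure's inverse variances) divided by J−K; the
  modified Q on J−K df measures residual heterogeneity.  Conditional F
  assumes non-overlapping exposure GWAS samples (zero covariance between
  their estimates) — a documented limitation.

## Registered inference

SESOIs arrive as Cohen's D and are converted with `d/√(d²+4)` on the
standardised-beta scale and `d·π/√3` on the log-OR scale — standard
effect-size conversions, isolated in one function so alternates can be
swapped.  Bounds apply on the per-SD-of-exposure scale, matching the
standardised axes on which the estimates are reported.  One-sided
hypotheses get an inferiority test of H0 "the effect is at least as extreme
as the SESOI"; two-sided hypotheses get the TOST (p = the larger of the two
one-sided tails).  The negative-control criterion takes the control's CI
bound farthest from 0 in the registered direction and asks whether the main
estimate is consistent with an effect at least that extreme
(`p = 1−Φ(z) ≥ α` passes); an alternative always-upper-bound reading is
selectable.  Verdicts: equivalence rejection dominates
(*practically equivalent to 0* regardless of the NHST); otherwise NHST
rejection in the registered direction plus a passing negative control
(where required) gives *supported*; anything else is *undecided*.  Under a
complete null, hypotheses whose SE is large relative to the bound retain
the irreducible NHST false-positive rate (their equivalence test has no
power), while precisely estimated hypotheses are essentially never
"supported" — the decision log of null pipeline runs shows exactly this
pattern.

## Power

Power is the rejection fraction across seeded Monte-Carlo replicates
(default 1,000).  D maps to a correlation `D/√(D²+4)` for continuous
outcomes and to a per-SD log-OR `D·π/√3` for binary ones — the same
conversions as the equivalence bounds, so power and inference speak one
language.  The logistic intercept for a target prevalence is solved by
Gauss–Hermite quadrature over the standard-normal predictor.  For
instrumented power, the mapping of D to the causal slope is ambiguous
between per-SD-of-exposure and per-year readings; both conventions are
implemented and labelled, defaulting to per-SD.

## Problem sizes and numerical choices

The registered power scenarios run at their full sizes (N = 12,000, 1,000
replicates).  Calibration checks that need thousands of replicates (type-I
error over 2,000 null replicates per family, CI coverage over 500) use
n = 1,500–4,000 per replicate — large enough for the asymptotics the tests
probe, chosen so the whole suite gives quick feedback.  The pipeline's
default run reproduces all tables bit-for-bit from the config hash and
seed; all tables are tab-delimited with `#`-prefixed metadata lines.
Degenerate inputs are handled explicitly: zero-variance instruments,
single-class outcomes, perfect separation, collinear covariates
(dropped with a warning), all-zero MVMR exposure columns (dropped;
informative collinearity errors), constant outcomes (identity transform
with a warning), and p-values are clamped away from exact 0.

## Known limitations

Estimator internals follow the canonical second-stage, meta-analytic and
profile-likelihood formulations; no LD-aware or overlap-aware MR variants
are included.  The equivalence-bound conversions are one defensible choice
among several.  The attrition model is a stand-in: the real study's
participation process is unknown.  The single-variable truncated
imputation is deliberately narrower than full chained-equations MI; it
captures the one constraint that is testable (the 15-year floor and
recovery of latent values in simulation) and nothing more.
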