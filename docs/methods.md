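# Methods

## The model

`mvpgs` fits a multivariate multivariable regression: three standardized
childhood outcomes — ADHD symptoms, internalizing problems, social problems
— regressed jointly on seven standardized adult-trait polygenic scores
(major depression, bipolar disorder, subjective well-being, neuroticism,
insomnia, educational attainment, BMI) plus covariates, across several
cohorts at once.

Within cohort *c*, child *i* has outcome vector

    y_i = B x_i + b_sex sex_i + b_age age_i + Γ_c z_i + μ_c + e_i

where `x_i` are the seven PGS, `z_i` the per-cohort nuisance covariates
(genetic PCs, genotyping chip/batch dummies) and `e_i ~ N(0, Σ_W^c)`.  The
PGS, sex and age coefficients (`B`, `b_sex`, `b_age`) are constrained equal
across cohorts; intercepts `μ_c`, nuisance coefficients `Γ_c` and the
residual covariance `Σ_W^c` are free per cohort.  In twin cohorts the two
children of a family are modelled jointly with residual covariance

    [[Σ_W, Σ_X],
     [Σ_X, Σ_W]]

where the symmetric `Σ_X` holds cross-twin same-trait and cross-trait
covariances — familial clustering is absorbed without decomposing it into
genetic/environmental components (no ACE model is attempted).

Estimation is full-information maximum likelihood (FIML): each family
contributes the multivariate-normal log-density of its *observed* outcome
sub-vector, so missing outcome cells (including whole outcomes a cohort
never measured) are marginalized out, never imputed.  The total
log-likelihood is the sum over cohorts of sums over families (a multi-group
model).  The likelihood conditions on the PGS and covariates (fixed-X); PGS
correlations are reported descriptively per cohort and averaged with equal
weights, not estimated as model parameters.  An equivalent treatment in SEM
software would model the predictors' covariance explicitly; for the
regression block the point estimates coincide, and conditioning keeps the
parameter space small.

A cohort that never measured an outcome is modelled in the reduced
dimension: its `Σ_W`/`Σ_X` are 2×2 and it has no intercept or nuisance
coefficients for the absent trait.  Shared coefficient slots are created
only when at least one cohort observes the (outcome, predictor) pair, so
the parameter vector never contains data-free directions.

### Why intercepts

Outcomes are z-scored within cohort, but sex is coded 0/1 (male = 1,
consistent with the positive sex→ADHD and negative sex→internalizing
effects) and left unstandardized, so the conditional outcome mean at
`sex = 0` is not zero.  Per-cohort intercepts absorb this; without them the
shared coefficients would be biased.  Intercepts are nuisance parameters
and do not appear in results tables.

## Parameterization and optimization

- `Σ_W` uses a log-Cholesky parameterization (`Σ_W = LLᵀ`, diagonal of `L`
  stored on the log scale): any real parameter vector maps to an SPD
  matrix.
- `Σ_X` is an unconstrained symmetric matrix (twin exchangeability imposes
  the symmetry).  The joint twin block must be PD; optimizer trial steps
  that leave the PD region are treated as infinitely bad and the line
  search backtracks.  A user-facing likelihood evaluation at an infeasible
  or near-singular point (sub-block condition number > 1e12) raises an
  error rather than silently regularizing.
- Families are grouped by (family size, missingness pattern); each pattern
  is one vectorized MVN evaluation (one Cholesky per pattern, one matrix
  solve for all its families).  The grouped evaluator is contractually
  identical to a naive per-family implementation (`loglik_naive`, routed
  through `scipy.stats.multivariate_normal`), and the test suite asserts
  agreement to 1e-8 on 50 random studies.
- The analytic gradient propagates through the mean (scatter into shared
  and per-cohort slots), the log-Cholesky map and the symmetric `Σ_X`
  parameterization; it is checked against finite differences.
- Optimizer: L-BFGS-B with the analytic gradient (numeric-gradient mode is
  available), started from per-outcome complete-case OLS, OLS residual
  moments for `Σ_W`, and cross-twin residual products (shrunk by 0.5 to
  stay inside the PD region) for `Σ_X`.  Target gradient max-norm 1e-5 on
  the flat scale; the relative-improvement stop effectively fires at
  machine precision.  With complete singleton data the start is already the
  MLE (the MVN regression MLE is per-outcome OLS), which the OLS-limit test
  checks at 1e-5.
- Degenerate design columns (absent factor levels, constant covariates)
  are dropped before fitting.

## Inference

Standard errors are square roots of the diagonal of the inverse observed
information, computed by central finite differences of the analytic
gradient at the optimum (steps shrink automatically near the covariance
boundary).  Wald `z = β/SE`, two-sided normal p-values, symmetric 95% CIs
(`β ± 1.96 SE`), and a Bonferroni threshold `α = 0.05/(3 × 7) ≈ 0.00238`
flag significance.  Whether the original analysis used Hessian- or
profile-based SEs is unknown; observed-information SEs are the conventional
choice and reproduce the published SE magnitudes (≈0.008–0.010) at the
published sample sizes.

Fit indices use the standard chi-square constructions: the comparison
("saturated") model releases every cross-cohort equality constraint; the
baseline model drops the PGS block and forces a diagonal `Σ_W` with no
cross-twin covariance.  `χ² = 2(llₛₐₜ − llₓ)`, `df = Δparams`,
`RMSEA = sqrt(max(χ²−df,0)/(df·N))`, with the usual CFI/TLI formulas.  CFI
can fall below zero when the baseline fits better per degree of freedom.
The baseline a given software package uses is a convention; published CFI
values are therefore not comparable across baselines.

## Univariate comparison and attenuation

`fit_univariate` refits the identical model with the PGS block restricted
to one score (covariates retained).  With standardized predictors and
outcomes, a score's univariate slope converges to `(R_pgs Bᵀ)` — the
correlation-weighted sum of all true joint slopes — so correlated scores
show spurious single-score associations that vanish in the joint model.
The pipeline's comparison table makes this visible per (outcome, score)
pair, and the test suite verifies the closed form quantitatively (e.g. a
true MDD→ADHD effect of 0.2 with corr(MDD, INS) = 0.191 induces a
univariate insomnia slope of ≈0.038 while the joint insomnia estimate is
≈0).

## Synthetic data generator

The generator emulates the four-cohort study layout: ALSPAC-shaped
singleton birth cohort (n = 5,025; 10 PCs, age, sex), CATSS-shaped twin
cohort (n = 7,284; no social-problems measure, no age covariate),
NTR-shaped twin cohort (n = 3,652; chip factor) and TEDS-shaped twin
cohort (n = 4,578; chip and batch factors) — 20,539 children in total.

Defaults are the study conditions:

- `R_pgs`: the published cross-cohort average PGS correlation matrix
  (verified SPD; smallest eigenvalue 0.61).
- `B`, `b_sex`, `b_age`: the published multivariate estimates.
- Ages uniform on [8.5, 10.5] years (shared within a twin pair); sex
  Bernoulli(0.5); PCs standard normal with zero true effect; chip/batch
  uniform over 2–3 family-level levels with zero true effect.
- Residual covariances are *not* published; the defaults are a
  convention: `Σ_W` with unit variances and 0.3 trait intercorrelation,
  `Σ_X = 0.3 Σ_W` (cross-twin correlation 0.3, between the classical MZ/DZ
  shared-environment plus half-heritability magnitudes for behavioural
  traits).  They live in `GeneratorTruth`, never in the likelihood.
- Outcome missingness: structural (whole outcomes a cohort lacks) plus
  MCAR masking at 10% per cell — FIML was the published study's answer to
  outcome missingness, so the generator produces some.
- Twins draw PGS independently by default (`twin_pgs_corr = 0`); residual
  clustering alone carries the family structure.  Setting
  `twin_pgs_corr = 0.5` mimics DZ genetic relatedness.
- Seeding: one study seed; per-cohort generators spawned from a single
  `numpy` `SeedSequence`, so studies are bit-reproducible.

What the generator does **not** emulate: genotype-level data and LDpred
score construction (scores are drawn directly as correlated standard
normals), MZ/DZ zygosity differences (one pooled cross-twin covariance),
same-sex twin pairs, instrument/scale differences between cohorts
(outcomes are exchangeable Gaussian traits), non-normal and skewed symptom
distributions, and informative (non-MCAR) missingness.  Passing recovery
tests therefore demonstrate correctness of the estimator under the model's
own assumptions, not robustness to real-data violations of them.

## Recovery studies and problem sizes

The acceptance-grade checks refit the model on studies generated at the
full published cohort sizes, with the published coefficient matrix and PGS
correlations as truth, averaged over 5 seeds.  These runs use 2 PCs per
cohort and no chip/batch factors: the nuisance covariates have zero
generating effect, so they contribute only parameter-space dimension, and
two per cohort are enough to exercise the per-cohort covariate machinery
(the full 10-PC + factor layout is exercised in the pipeline and CLI
tests).  The null-calibration study uses 20 replicates at 5% of the
published sizes, where binomial error on the 5% Wald rejection rate is the
operative tolerance.  Mean recovery errors observed: ≤ 0.004 on all
checked coefficients (targets 0.035 … 0.210), PGS correlation entry
recovered to ±0.005.

## Known limitations

- Fixed-X likelihood: SEs do not propagate uncertainty in the PGS
  correlation structure (matches the descriptive role the correlation
  table plays).
- `Σ_X` near the PD boundary (extreme twin correlation, tiny cohorts) can
  make the observed information singular; the package raises with the
  offending directions named rather than regularizing.
- No survey weights, no MZ/DZ distinction, no random-effects decomposition
  of the twin covariance.
- p-values are normal-approximation Wald; very small cohorts would warrant
  likelihood-ratio intervals instead.
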