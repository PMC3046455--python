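# Methods

## The problem

Common breast-cancer susceptibility SNPs act approximately multiplicatively
per risk allele, and established reproductive and anthropometric risk
factors (age at menarche, parity, age at first birth, BMI) act roughly
log-linearly. Risk-prediction models that combine the two families usually
assume their joint effect is the product of the marginal effects. `gxescan`
implements the machinery needed to test that assumption in pooled
multi-study case-control data: per-allele and trend main-effect models,
category-stratified per-allele odds ratios, a grid of 1-df product-term
interaction tests, and a single-step min-p family-wise adjustment of the
whole grid, together with a synthetic cohort generator and a Monte-Carlo
power module so every stage is testable without access to individual-level
consortium data (which are not public).

## Models

### Main effects

All fitting is unconditional logistic regression, estimated by
Newton/IRLS. For a SNP with dosage d ∈ {0,1,2} (count of the designated
risk allele), the per-allele model is

    logit P(case) = α_s + β_g d

with one intercept per study s (dummy coding, first sorted label as
reference). exp(β_g) is the per-allele OR; the log-additive form means the
homozygote OR is the heterozygote OR squared. Risk-factor trend models
replace β_g d by β_e x, where x is the factor on its natural continuous
scale (years, live births, kg/m²), and additionally adjust for age
(categorical bins ≤34, 35–39, …, ≥75 plus a linear term that absorbs
residual case-control age differences inside the extreme bins).

Stratified per-allele ORs come from a *single* joint model per (SNP,
factor) pair: study dummies + factor-category main-effect dummies + one
dosage slope per category. Each slope's exponential is the per-allele OR
within that category; because they share one likelihood, the category
estimates are mutually consistent and a homogeneity LRT is well defined.
Categories containing a single outcome class are flagged and excluded from
the fit (their dummy would diverge); the remaining categories are still
reported.

### Interaction tests

For each (SNP, factor) pair the full model is

    logit P(case) = α_s + β_g d + β_e x + β_ge d·x

and the null model drops only the product term. The test is the
likelihood-ratio statistic 2(ℓ_full − ℓ_null) on 1 df. exp(β_ge) is the
interaction OR: the multiplicative change in the per-allele OR per unit of
the factor. Interaction models adjust for study only (an `adjust_age` flag
enables sensitivity runs). Parity-dependent factors (number of births, age
at first birth) restrict to parous women; BMI is tested separately in the
<55 and ≥55 age strata (age as a surrogate for menopausal status, boundary
assigned to the older stratum). The default family is 12 SNPs × 6 factor
tests = 72.

Analysis subsets are complete-case per (SNP, factor) pair; no imputation.
This mirrors the per-analysis Ns of pooled consortium tables, where
different studies collected different factors.

### Min-p multiplicity adjustment

The family-wise adjustment is single-step min-p. For each test, the
main-effects-only model (study + dosage + factor) is fitted to the observed
data and each subject's fitted case probability retained. One replicate
then consists of, for each test: draw a uniform number per subject, assign
"case" where it falls below the fitted probability, refit full and null
interaction models on this dummy outcome against the real covariates, and
record the LRT p. The minimum p across tests is stored per replicate
(default B = 10,000), and

    p_adj(t) = #{replicates with min-p < p_unadj(t)} / B.

The strict `<` counting rule is the default for fidelity to the procedure
it implements; it can return exactly 0, so an `add_one` rule
((count+1)/(B+1)) is offered. A permutation variant replaces the redraw
with a within-study permutation of the observed labels inside each test's
subset; on null data the two agree closely.

Because each test's dummy outcome is redrawn independently, replicate
minima are minima of independent uniforms, and for any family the adjusted
p converges to the Šidák form 1 − (1 − p)^m as B → ∞ — a closed-form
oracle used in the tests. Correlation between observed tests (shared
subjects and outcome) makes the observed minimum stochastically larger
than the independence reference, so the procedure errs on the conservative
side; simulation confirms family-wise error at or just below the nominal
level. Replicate fits that fail to converge or separate are dropped from
that replicate's minimum (counted and logged); the run errors if more than
1% of fits fail. Replicate streams are keyed by (seed, test index), so
results are independent of worker count.

### Power

Power is estimated by direct Monte-Carlo: simulate a single-study
case-control dataset from an explicit design (arm sizes, risk-allele
frequency, factor distribution, main-effect ORs), run the interaction
test, and count rejections at the chosen level. The minimum detectable
interaction OR at a target power is the first value on an ascending OR
grid whose estimated power reaches the target; the whole curve is
returned. Designs must state the factor distribution explicitly, because
interaction power scales with the exposure variance and a hidden default
would silently condition the answer.

## The synthetic cohort generator

The generator emulates the *structure* of a multi-study consortium
dataset, not any particular study's data. Per study, population records
are drawn, disease status is sampled from a multiplicative logistic model
used generatively, and cases/controls are accumulated by rejection until
the per-study targets are met — i.e. retrospective ascertainment with
fixed margins. Study intercepts are auto-calibrated (root-finding on a
fixed calibration sample) so expected prevalence sits at a configurable
target (default 12.5%, band 5–20%), keeping rejection cheap and mimicking
the elevated apparent prevalence of case-enriched sampling frames.

Defaults (all config-exposed):

| quantity | default | note |
| --- | --- | --- |
| genotypes | Hardy-Weinberg at catalog frequency | SNPs independent (no LD): each SNP is analysed marginally |
| age | round N(56, 11²), clipped 25–90 | per-study override possible via config |
| menarche | 9 + Binomial(9, 4/9) | support 9–18, mean 13 |
| parous | Bernoulli(0.85) | |
| age at first birth | round N(25, 4.5²), clipped [14, 45] and < age | parous only |
| births | 1 + Poisson(λ by AFB band), λ = 1.6/1.3/0.9/0.6, capped 12 | earlier first birth → more births |
| BMI | logN(log 25.2, 0.15²), 1 decimal | |
| ER/PR | cases only: 75% ER+, 70% PR+ | optional dosage-dependent ER model |

The packaged demo configuration (`data/demo_consortium_config.json`) has 21
studies at realistic consortium sizes, the 12-SNP catalog with its
published per-allele ORs as main effects, trend main effects of 0.96/year
(menarche), 0.84 (parous), 0.89/birth, 1.0136/year of age at first birth
(1.07 per 5 years), 0.97/BMI unit under age 55, and one non-null
interaction: 1.05 per allele per live birth for the LSP1 SNP — the
weak-interaction regime the scanner is designed to interrogate.

Modelling choices worth knowing:

* **Centering.** Main effects of parous-only factors enter the generative
  logit centered at a typical parous woman (2 births, first birth at 25),
  so the `ever_birth` coefficient keeps its marginal parous-vs-nulliparous
  interpretation. Interaction products use raw factor values, exactly as
  the fitted models do; centering shifts only intercepts, never the
  recoverable trend or interaction coefficients.
* **Correlated exposures.** Birth count depends on age-at-first-birth band
  structurally rather than through a copula. A consequence visible in any
  single-factor trend model (generated or real): the age-at-first-birth
  trend absorbs part of the parity effect (the demo configuration yields
  ≈1.12–1.13 per 5 years against a conditional 1.07), because the trend
  model does not adjust for the correlated factor. This mirrors how such
  models behave on real data and is left as is.
* **Missingness** is missing-completely-at-random per field per study. A
  missing parous flag hides the dependent parity fields. Real consortium
  missingness is study-structured rather than random; complete-case
  subsets remain valid under MCAR, which is what the generator provides.
* **Randomness.** A master seed spawns per-study, per-field substreams
  (CRC-32 keyed), so adding a study or field never perturbs existing
  draws and a fixed seed fixes the cohort byte-for-byte.

What passing tests on these cohorts shows: the pipeline's estimators are
consistent, its tests calibrated, and its multiplicity adjustment
family-wise valid *under the stated generative model*. What it cannot
show: robustness to population stratification, genotyping error,
differential (study- or outcome-correlated) missingness, or
between-study effect heterogeneity — none of which the generator emulates.

## Numerical choices

* IRLS: convergence when the largest score component < 1e-8, max 100
  iterations, step-halving (up to 30 halvings) on likelihood decrease.
  Separation is reported as an error — not a huge OR — when a coefficient
  passes |β| > 15 with non-vanishing score. Rank deficiency is detected
  via the QR diagonal and names the offending column.
* The batched fitter used inside the bootstrap runs plain Newton across
  replicate columns (tolerance 1e-6, warm-started at the observed null
  fit, ~4–6 iterations in practice) with a tiny ridge (1e-10·n) on the
  Hessian for safety; diverged or non-converged columns are flagged and
  discarded by the caller.
* LRT statistics are clipped at zero within 1e-6 tolerance; a more
  negative value raises a nesting error.
* Reference categories: first sorted study label, lowest observed
  age/category bin. Dummies are built from observed levels only, so empty
  bins cannot create rank-deficient designs.
* Category bins are left-closed at their lower edge (BMI 25.0 falls in
  25.00–29.99, 30.0 in ≥30.00).

## Validation problem sizes

The test-suite validation runs use sizes chosen to give each check real
statistical teeth on a single CPU: null-calibration KS over 2,000
simulated cohorts of 3 × 2,000/2,000; family-wise error over 200
repetitions of a 6-test grid at B = 500; interaction-OR recovery over 100
cohorts of 25,000/25,000; Šidák convergence at B = 10,000 on a 4,000-row
cohort; bootstrap-vs-permutation agreement at B = 2,000; power checks at
200–400 simulations per grid point. The acceptance script scans the full
72-test family on a 3-study, 15,000-row cohort with B = 1,000.

## Known limitations

* Wald intervals and chi-square LRT reference distributions are
  asymptotic; very sparse strata should rely on the flagging behaviour
  rather than the estimates.
* The min-p adjustment treats tests as independent in the replicate draw
  (each test redraws its own outcome); with positively correlated tests
  this is mildly conservative, never anti-conservative.
* The generator's exposure distributions are conventional defaults, not
  estimates of any real population; power results are conditional on the
  stated design and should be read as orderings and magnitudes, not
  universal thresholds.
* No LD between SNPs, no population structure, no genotype error model —
  out of scope by design.
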