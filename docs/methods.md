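# Methods

`bmimr` implements a stratified Mendelian-randomization (MR) analysis of the
effect of body mass index (BMI) on type 2 diabetes odds, together with a
synthetic biobank-scale cohort generator that gives every stage a testable
substrate. This note records the models, the calibrations, the numerical
conventions, and what the synthetic world does and does not establish.

## The estimators

**Per-variant scans.** The exposure scan is ordinary least squares of BMI on
`[intercept, dosage, covariates]`, per variant, over complete cases for that
variant; the dosage coefficient's two-sided p comes from the t distribution.
The outcome scan is a per-variant maximum-likelihood logistic regression fit
by Newton/IRLS (convergence `max |score| < 1e-8`, at most 50 iterations,
step-halving on score growth) with Wald standard errors; perfect separation
is detected by a diverging coefficient (|beta| > 20) and reported as a
per-variant failure flag. When driven by the pipeline the exposure scan runs
on the stratum's diabetes *controls* only, mitigating bias from sample
overlap between the exposure and outcome associations. Default covariates:
age, sex, genotyping array, assessment center (dummy-coded) and the leading
principal components.

**Instrument QC.** Variants must be missing in fewer than 10% of individuals
(strict) and have an exact-conditional Hardy–Weinberg mid-p above 1e-20
(strict). The mid-p enumerates every heterozygote count compatible with the
observed allele counts, sums the probabilities of configurations strictly
less probable than the observed one, and adds half the observed
configuration's probability; equally-probable non-observed configurations
are excluded (this differs from the common `<=` convention only on exact
ties). Monomorphic variants return 1.

**MR estimators.** Effect alleles are re-oriented so every exposure beta is
positive (IVW is invariant to this; the Egger intercept is not, so a
deterministic convention is required). The IVW estimate is the fixed-effect
inverse-variance-weighted combination
`sum(w * bx * by) / sum(w * bx^2)` with `w = 1/se_y^2` (exposure standard
errors ignored — first-order weights), standard error
`1/sqrt(sum(w * bx^2))`, and Cochran's Q against chi-square(k−1). MR–Egger
is weighted least squares of `by` on `[1, bx]` with the same weights;
standard errors use the multiplicative random-effects convention (normal-
equation SEs scaled by `max(1, sqrt(residual mean square))`) and the
intercept test uses the t distribution with k−2 df. Between-stratum
comparisons use the difference-of-odds-ratios z test
`(log OR1 − log OR2)/sqrt(se1^2 + se2^2)` with a normal reference; printed
confidence intervals are converted back to standard errors via
`(ln hi − ln lo)/(2·1.96)`. No multiple-testing adjustment anywhere.

**Collider guards.** Stratifying on a variable the instruments influence
would induce collider bias, so before stratification: continuous stratifiers
(BMI, polygenic score) have the instruments regressed out (multilinear fit
on mean-imputed dosages, predictions mean-centered and subtracted — the
output keeps the input mean and is orthogonal to every instrument in
sample); the binary family-history stratifier is handled by matched
subsampling: a logistic regression predicts family history from the
instruments, individuals are binned into deciles of the prediction, and
within each decile the no-family-history group is randomly subsampled to
`round(4.5 × n_with_history)` without replacement, rounding half away from
zero. Deciles with too few candidates keep everyone and record the
shortfall. The subsample uses a dedicated named random stream.

**Nonlinear MR.** A weighted allele score (dosages harmonized to the weight
file's effect alleles, missing dosages mean-imputed; weight rows absent from
the genotypes dropped with a warning) serves as a single instrument. The
"IV-free exposure" is the residual of BMI on the score and covariates;
individuals are ranked into 50 equal-size strata of it. Within each stratum
the localized average causal effect (LACE) is the score→disease logistic
coefficient over the score→BMI linear coefficient, with first-order standard
error. Cochran's Q against the precision-weighted mean tests homogeneity; an
inverse-variance-weighted linear regression of LACE on stratum mean BMI
tests for a dose–response trend; the same machinery applied to the
score→BMI coefficients checks the method's constant-instrument-strength
assumption. Design choices fixed here (the method family leaves them open):
residual-based (not doubly-ranked) stratification, first-order LACE SEs,
fixed-effect Q, and an IVW linear trend on stratum mean BMI.

**Risk translation.** With odds ratio β per 1 kg/m² and baseline prevalence
P, under the rare-disease OR≈RR approximation: relative risk reduction for a
BMI decrease Δ is `1 − β^−Δ`; prevalence after the change is `P/β^Δ`;
absolute reduction is `P − P/β^Δ`; and the inverse problems solve for Δ
(hence weight, via Δ·height²) in closed form. Confidence intervals are
propagated by evaluating at the OR's CI bounds (every map is monotone in β;
bounds invert for the weight-needed direction). Rendering conventions:
percentages round half away from zero (1 decimal for prevalence-style
tables, integers for the weight-loss tables); weights render pounds rounded
to integer first and derive the displayed kilograms from the *rounded*
pounds (0.45359237 kg/lb exactly), which reproduces printed pairings such as
"14 lbs/6 kg" that direct kg rounding would not. A strict odds-scale variant
of the translation is deliberately not offered by default; the published
arithmetic is the OR≈RR form.

Known irreproducibilities in the published calculator tables: the absolute
columns of the weight-loss table and the overweight absolute rows of the
weight-needed table are mutually inconsistent with the printed inputs (they
trace to unrounded odds ratios ≈1.365/≈1.254 and to cohort rather than
reference prevalences); the package computes the formulas as defined and the
tests assert only cells that reproduce from printed inputs.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, at a
desk scale of n = 50,000 by default (the real cohort is ~287,000):

* **Genotypes:** 57 independent biallelic instruments, allele frequencies
  drawn U(0.05, 0.5), dosages binomial(2, f) — exact Hardy–Weinberg, no LD
  (instruments are assumed independent by MR). Missing dosages injected at
  0.5% per variant, with one designated bad variant at 15% so the QC filter
  has something to catch; the instrument panel carries the 57 rsIDs used in
  the analysis, and the emulated external score-weight file omits rs9581854,
  so allele scores are built from 56 instruments.
* **BMI** = 27.4 + instrument component + confounder + shared household
  environment + noise, total SD 4.8 kg/m² (the defaults are configurable and
  deliberately not asserted; a symmetric normal under-represents the
  non-overweight and over-represents the obese relative to the real
  right-skewed distribution). Per-allele instrument effects are proportional
  to 1/sqrt(2f(1−f)) with random sign and a single scalar rescales the
  component so its in-sample variance share is r² = 0.013.
* **Disease:** conditional logistic model
  `logit P(case) = α0 + c·(BMI − 27.4) + 0.9·Z + 0.2·U`, where Z is the
  standardized polygenic liability and U the BMI confounder; α0 is bisected
  so the expected prevalence is 4.9%. Because the outcome GWAS marginalizes
  over Z, U and the non-genetic part of BMI, summary MR estimates the
  *marginal* (population-averaged) OR, which non-collapsibility attenuates
  relative to the conditional coefficient c. The generator therefore treats
  the configured θ (default ln 1.3) as the causal marginal estimand and
  calibrates c by bisection on a held-out draw until the asymptotic per-SNP
  IVW estimand — computed deterministically as the information-weighted
  combination of fractional-logistic slopes of the expected case probability
  on dosage over control-weighted linear BMI slopes — equals θ.
* **Polygenic score:** PRS = Z + noise, the noise SD bisected on the same
  held-out draw until the score's AUC for case status is 0.66 ± 0.01; the
  instruments are independent of Z, so their r² with the PRS is pure sampling
  noise (~0.001 at n = 50,000, emulating the real 0.003).
* **Family history:** two parents and one sibling each carry a liability
  `sqrt(h)·Z_relative + sqrt(s)·H + residual` with h = 0.4 heritable share
  and s = 0.1 a shared household component H that also feeds the proband's
  BMI; relatives' genetic liabilities share half the proband's genetic
  component through mid-parent transmission. The affection threshold is the
  empirical quantile that makes "any affected first-degree relative" hit
  16.8%. This makes family history correlate positively with both PRS and
  BMI, which the stratified prevalence tables assume.
* **Labels, HbA1c, medication:** cases split 85/15 probable/possible type 2;
  1% of controls get type 1/gestational labels; control HbA1c ~ N(34, 3)
  mmol/mol so a few percent exceed the 39 mmol/mol undiagnosed-diabetes
  threshold (cases ~ N(50, 8)); metformin/insulin flags among cases at the
  published 56.7%/15.0% rates; 0.5% random sample-QC failures. Covariates
  (age U(40,70), sex, 3 centers, 2 arrays, 10 iid normal PCs) exist for the
  regressions but are immaterial by construction.

All draws are deterministic given the seed, via named substreams (setup,
calibration, cohort, missingness, matching), so re-running any stage is
bit-reproducible and the matching subsample does not perturb other draws.
Calibration failures (an unreachable target, bisection not converging in 100
steps) raise an error naming the target.

**What a green test establishes.** The synthetic world has independent
instruments with no horizontal pleiotropy, no population structure, no LD,
no measurement error in BMI, and exchangeable individuals; covariates are
noise. Green parameter-recovery tests therefore establish correctness of the
estimators and plumbing under the model's own assumptions — not robustness
to the violations (pleiotropy, stratification, dynastic effects) that real
cohorts exhibit. Real-data effect sizes are not reproduction targets;
reproduction of the published per-stratum odds ratios would require the
restricted individual-level data.

## Known finite-sample behavior

* At the stated world (r² = 0.013 jointly across 57 instruments,
  n = 50,000) the mean per-instrument F statistic is ≈ 11, so fixed-effect
  IVW with first-order weights carries the textbook weak-instrument
  attenuation of roughly F/(F+1) ≈ 0.92: across seeds the mean estimate sits
  ≈ 0.02 below θ = ln 1.3 while the 95% CI still covers θ in ≥ 90% of runs.
  At the real cohort's scale (F ≈ 65) the same bias is negligible. This is a
  property of the estimator the analysis prescribes, not of the generator,
  and is deliberately not calibrated away (doing so would make θ's meaning
  depend on n).
* In the 50-quantile MR at n = 50,000 the extreme low-BMI strata contain
  only a handful of cases (~1000 individuals, prevalence < 1%), so roughly
  a fifth of strata have no stable covariate-adjusted logistic fit; they are
  flagged, logged and dropped from the Q and trend tests, which remain
  calibrated on the valid strata. At the real scale every stratum is dense.
* Monte Carlo scale: the acceptance suite runs the full 100-seed × n=50,000
  recovery experiment. Module-level calibration checks (trend-test
  uniformity, null-effect coverage) use fewer, smaller replicates with
  binomial bounds chosen in advance to give equivalent per-seed strictness,
  keeping the default test run inside a desktop time budget.

## Numerical conventions

* All equal-size rank binning (match deciles, PRS tertiles, BMI bins of the
  prevalence curves, the 50 MR quantiles) uses one rule: stable ties, sizes
  differing by at most one, remainder assigned to the highest bins.
* Rounding of rendered quantities is half away from zero everywhere.
* Matching targets round half away from zero; 4.5 × an even count is exact,
  which is the only way the published 48,238 / 217,071 / 22,085 bookkeeping
  can arise exactly under the stated rule.
* Strict inequalities at QC boundaries: missingness exactly 10% and HWE
  mid-p exactly 1e-20 are rejected.
* BMI is clipped to (10.5, 79.5) in the generator to respect the cohort
  table's validity range; the clip is essentially never active at the
  default parameters.
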