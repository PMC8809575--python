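# Methods

`mrmediate` implements a complete two-sample Mendelian randomization (MR)
workflow for studies that ask whether an intermediate trait (for example a
circulating hormone) confounds or mediates the effect of an exposure (an
ordinal chronotype-like score) on a binary disease outcome, together with a
synthetic GWAS summary-statistics generator that gives every stage of the
workflow a known ground truth.

## The model

Two-sample MR works on per-SNP association summary statistics. For SNP *j*,
let β̂Xj (σXj) be its estimated effect on the exposure from one GWAS and
β̂Yj (σYj) its effect on the outcome from an independent GWAS. Under the
instrumental-variable assumptions (relevance, independence from confounders,
exclusion restriction), each SNP yields a Wald ratio β̂Yj/β̂Xj estimating
the causal effect θ, and the inverse-variance-weighted (IVW) estimator pools
them as the zero-intercept weighted regression

    θ̂ = Σ wj β̂Xj β̂Yj / Σ wj β̂Xj²,   wj = 1/σYj²,

with exposure betas oriented positive (the estimate is invariant to this).
Heterogeneity between per-SNP estimates is measured by Cochran's
Q = Σ wj (β̂Yj − θ̂ β̂Xj)² on L−1 degrees of freedom, summarised as
I² = 100·max(0, (Q−df)/Q). Binary outcomes are analysed on the log-odds
scale and results also reported as odds ratios.

### Sensitivity estimators

* **MR-Egger** frees the intercept; the intercept estimates average
  directional pleiotropy, the slope remains consistent under InSIDE
  (instrument strength independent of direct effects) *and* NOME (exposure
  betas measured without error). SEs carry a multiplicative overdispersion
  factor bounded below at 1; p-values use t on L−2 df.
* **Weighted median**: the interpolated 50% point of the inverse-variance-
  weighted empirical CDF of Wald ratios (weights β̂Xj²/σYj²); consistent if
  ≥50% of the weight is valid. SE by seeded parametric bootstrap.
* **Weighted mode**: the maximiser of a weighted Gaussian kernel density of
  the ratios; bandwidth is a modified Silverman rule, phi × 0.9·s·n^(−1/5)
  with s the smallest positive of {sd, scaled MAD, IQR/1.349} (robust
  spread measures keep the bandwidth tight when a minority of ratios are
  outlying; default phi = 1).
* **Radial MR** regresses β̂Yj/σYj on β̂Xj/σYj through the origin; each
  SNP's squared residual Qj ~ χ²₁ under homogeneity, and SNPs with
  Qj p-value below 0.05/L (Bonferroni default) are flagged as outliers.
  First-order weights only.
* **Leave-one-out** refits IVW omitting each SNP in turn.
* **Steiger filtering** removes SNPs explaining more variance in the
  outcome than the exposure. Per-SNP r² is 2f(1−f)β² for SD-scale traits
  and z²/(z²+n) otherwise (see *Numerical conventions*); the Steiger z-test
  compares atanh-transformed correlations. Ties count as wrong direction.
  The sensitivity ratio R is evaluated on a 20×20 grid of measurement-
  reliability pairs in [0.1, 1]²: R = (#cells with direction unchanged) /
  (#cells reversed), infinite when no cell reverses.
* **I²GX / SIMEX**: I²GX quantifies NOME violation from the heterogeneity
  of oriented exposure betas about their (weighted or unweighted) mean;
  SIMEX adds Normal(0, λσXj²) noise to exposure betas over a λ grid
  (default 0 … 2 in steps of 0.25, 200 replicates per λ) and extrapolates
  the Egger fit quadratically to λ = −1. Quadratic extrapolation is the
  simplest defensible default and is flagged in the result metadata.
* **Split-sample MR** pools, by fixed-effects meta-analysis, the two IVW
  estimates obtained by crossing exposure betas from one half-sample with
  outcome betas from the other. Halves are disjoint by construction in the
  simulator; splitting real data is the caller's responsibility.

### Multivariable MR

With K exposures, direct effects come from the no-intercept weighted
regression of β̂Yj on (β̂X1j … β̂XKj), weights 1/σYj²; Q_A is the weighted
residual sum of squares on L−K df, and SEs carry the same bounded
overdispersion factor. Conditional instrument strength for exposure *k* is
the residual heterogeneity of its betas regressed on the other exposures'
betas (weights re-estimated over two passes, cross-trait covariance
configurable, default 0) divided by L−K+1. The Q-minimisation estimator
re-estimates the direct effects by minimising

    Q_A(θ) = Σj (β̂Yj − Σk θk β̂Xkj)² / (σYj² + Σk θk² σXkj²),

whose denominator propagates exposure-beta uncertainty (robust to weak
instruments); it is optimised by L-BFGS-B from five jittered starts
(tolerance 1e-8, seeded) with bootstrap CIs, and flagged experimental.

### Harmonization and instruments

Records are matched on variant id. If the outcome's effect allele equals the
exposure's other allele, the outcome beta is negated and its frequency
complemented; palindromic SNPs (A/T, C/G) are kept only when both sides'
minor-allele frequency is below 0.3 (both studies, conservatively) and the
minor-allele assignment agrees between studies, otherwise they are excluded;
other allele mismatches are dropped as incompatible. Instruments are either
an external SNP list re-extracted from the analysis GWAS regardless of
significance, or de novo genome-wide-significant SNPs (p < 5×10⁻⁸), then
greedily LD-clumped at r² = 0.001 (smallest p first, ties broken by variant
id; the LD matrix is supplied explicitly — no distance windows, no
reference-panel lookup).

### Mediation screen

A candidate mediator is screened on four criteria: (i) exposure→outcome
effect, (ii) exposure→mediator effect, (iii) mediator→outcome effect, and
(iv) no strong reverse mediator→exposure effect. The default evidence rule
is "95% CI excludes the null" (configurable to a p-value threshold);
criterion (iv) holds when the reverse estimate shows no evidence of effect
*or* its magnitude is below half the forward magnitude (both components are
logged — "strong" has no canonical definition). Verdicts: all four →
candidate mediator; (i–iii) with a strong reverse effect → candidate that
can both confound and mediate; anything else (or an indeterminate
criterion) → excluded. The verdict map is total and mutually exclusive over
the 16 criterion combinations.

## The synthetic-data generator

The generator draws an individual-level cohort from a structural model that
mirrors the exposure → mediator → binary-outcome design:

* genotypes Gj ~ Binomial(2, fj), fj ~ U(0.05, 0.5), optionally with
  block LD via a Gaussian copula on latent liabilities;
* a standard-normal confounder U feeding all three traits
  (default paths 0.3/0.3/0.3);
* a latent exposure liability X* = Σ aj Gj + θMX·M₀ + bU·U + ε, unit
  variance, discretised at fixed normal quantiles into K = 5 near-equal
  categories (the ordinal score is analysed as a numeric score by linear
  regression, as large-biobank chronotype GWAS do);
* a mediator M = M₀ + θXM·(category − 3), where M₀ carries the mediator's
  own SNPs (the *reverse* class), its confounding and noise (unit variance);
* a binary outcome Y ~ Bernoulli(logit⁻¹(α + θXY·(category − 3) + θMY·M +
  dU·U + pleiotropic direct effects)), with α solved by bisection to hit
  the target case fraction (default 0.5, matching the roughly balanced
  case/control totals of large cancer consortium GWAS).

SNP classes: *valid* (exposure only), *pleiotropic* (additional direct
effect on the mediator or outcome; balanced, directional, or
strength-proportional to violate InSIDE — directional effects are defined
relative to the exposure-increasing allele, because estimators re-orient
instruments that way and unsigned draws would average out as balanced), and
*reverse* (mediator-first; they associate with the exposure only through
the mediator→exposure path). Effect magnitudes are drawn N(0,1) and rescaled
so Σ 2f(1−f)a² equals the target variance explained exactly; an optional
truncation draws magnitudes from a floored |N(0,1)|, emulating the
effect-size floor that significance-based instrument selection induces
without its winner's-curse noise.

Summary statistics come from within-sample per-SNP univariable regressions —
linear for the ordinal score and the mediator, logistic (log-odds) for the
outcome. Both scans are vectorised across SNPs (the logistic one runs
per-SNP Newton iterations simultaneously for all SNPs) and are verified
against statsmodels in the test suite; this is what makes multi-hundred-
replicate studies run in minutes. Two-sample structure: exposure/mediator
GWAS on sample 1, outcome GWAS on sample 2, with a configurable overlap
fraction; disjoint half-samples of sample 1 support split-sample MR. Every
output is a pure function of the config (seed mandatory; reruns are
byte-identical).

**Default effect sizes** follow the female chronotype/testosterone pattern
of the emulated study design: θXY = log(0.93) per category, θXM = −0.08 SD
per category, θMY = log(1.10) per SD, with the reverse path off by default.
Heritabilities (exposure 0.2, mediator 0.15 over 100 SNPs) are set so
desk-scale samples (n = 20,000) give instruments in the same mean-F regime
(≈ 20–80) as the full-scale study; the per-SNP r² convention z²/(z²+n)
reproduces a combined r² of ≈1.8% for 190 instruments with mean F 22.75 at
n ≈ 244,000, the published-scale figures for the chronotype instrument.

### What the generator does and does not emulate

It reproduces the *statistical* structure MR methods care about: effect
scales (category / SD / log-odds), instrument strength regimes, balanced
and directional pleiotropy, InSIDE violation, reverse causation,
confounding, sample overlap, and LD blocks. It does not emulate genome
coordinates, imputation noise, relatedness or population structure, allele
frequency spectra beyond U(0.05, 0.5), palindromic strand ambiguity
(alleles are drawn from non-palindromic pairs; palindrome handling is
exercised by hand-built fixtures), or selection effects such as winner's
curse. Passing tests therefore demonstrate correctness of the estimators
and pipeline logic under the stated generative model, not robustness to
every artefact of real GWAS data.

## Validation studies (`mrmediate.validation`)

The repeated-simulation studies behind `scripts/acceptance.py` and
`tests/test_acceptance.py`, with the problem sizes chosen for this package:
100 SNPs and samples of 20,000 (the desk-scale default), a few hundred
replicates per study, all replicate seeds derived from one base seed.

* **Parameter recovery** (θXM = −0.2, exposure h² = 0.3, no pleiotropy,
  confounding on): mean IVW bias and type-I error at θ = 0. Both arms use
  the fixed-effects IVW: the scenario generates no heterogeneity, and the
  multiplicative-random-effects SE (overdispersion bounded below at 1) is
  conservative by construction. The h² = 0.3 choice comes from the
  two-sample regression-dilution identity — attenuation ≈
  Σβ²/(Σβ² + Σσx²) ≈ 0.983 at these sizes — keeping dilution bias below 2%
  of θ. Measured: relative bias ≈ 1.8%, type-I ≈ 0.04.
* **Pleiotropy robustness**: 30% of SNPs carry directional direct effects.
  The Egger arm uses a 100,000-person exposure GWAS and truncated effect
  draws so that its own assumptions (InSIDE *and* NOME) actually hold in
  the scenario — at equal desk sample sizes Egger dilution is exactly the
  phenomenon I²GX/SIMEX exist to flag, and near-null instruments whose
  estimated orientation flips would mechanically violate InSIDE. "Recovers
  within Monte-Carlo error" is operationalised as within 3.5 MC standard
  errors (or 10% of θ if larger), accommodating Egger's heavy-tailed seed
  distribution. The InSIDE-violation arm checks the robustness ordering
  |bias(mode)| ≤ |bias(median)| ≤ |bias(IVW)| at 2 MC-se tolerance.
* **Mediation recovery**: full mediation (θXY = 0, θXM = −0.4, θMY = 0.5)
  must show a univariable total effect with CI excluding zero and a
  multivariable direct effect with CI including zero; no mediation
  (θXM = 0, θXY = −0.2) must show univariable and multivariable estimates
  agreeing within 2 SE — each in ≥80% of replicates.
* **Directionality**: Steiger-filtered bidirectional MR must classify
  one-way (θMX = 0) vs two-way (θMX = −0.3) structures (≥90% / ≥80% of
  replicates), and on the contaminated instrument (reverse path strong
  enough for mediator-first SNPs to reach genome-wide significance in the
  exposure GWAS) remove ≥90% of reverse SNPs while keeping ≥95% of valid
  ones.
* **Split-sample overlap control**: null effect, weak instruments
  (h² = 0.05, mean F ≈ 10), full exposure/outcome sample overlap, strong
  confounding: the pooled cross-half estimate must be no more biased than
  the naive full-overlap estimate.
* **Cross-cohort correlation**: one 341-SNP instrument re-estimated in two
  cohorts whose true effects correlate at 0.60 (partially shared
  male/female architecture) yields an estimate correlation of ≈0.58 —
  mildly attenuated below the generative 0.60 by GWAS sampling noise.

The test suite runs these studies at 40–60 replicates; the acceptance
script at 200.

## Numerical conventions and edge cases

* Per-SNP r² for non-SD trait scales uses z²/(z²+n): the 2f(1−f)β² formula
  presumes unit phenotypic variance, which neither the ordinal score
  (variance ≈ 2) nor the log-odds scale satisfies; z²/(z²+n) is scale-free
  and matches the published-scale instrument-strength bookkeeping (see
  above). Documented as an approximation for binary traits.
* SNPs missing eaf are kept for MR but excluded (with a warning) from
  combined-r² and Steiger computations.
* IVW weighting default: multiplicative random effects when L > 3 and
  Q/df > 1, else fixed ("auto", configurable).
* A single-SNP instrument automatically falls back to the Wald ratio, and
  the sensitivity block is reported as not computed.
* Zero kept SNPs raise an explicit error at harmonization; in multi-pair
  pipeline runs the pair is recorded as skipped and the run continues.
* Clumping ties on p-value break by lexicographic variant id; clumping a
  clumped table is a no-op.
* Bootstrap SEs (median, mode, qhet) require an explicit seed; n_boot = 0
  skips the bootstrap and reports NaN SEs.
* The qhet optimiser raises with diagnostics if no start converges.
* CI level is fixed at 95% throughout.

## Known limitations

* Logistic-scale effects are non-collapsible: marginal per-SNP log-odds
  betas are mildly attenuated relative to the conditional parameters, so
  recovery of θ on the binary outcome is approximate by construction; the
  mediation studies therefore test attenuation *patterns* (CI coverage and
  uv/mv agreement), not exact binary-scale point recovery, and exact-bias
  studies use the continuous mediator as the outcome.
* Two-sample regression dilution (weak-instrument attenuation toward the
  null) is inherent to IVW; at the desk scale it is ≈1.7% of θ with the
  recovery settings and grows as instruments weaken.
* MR-Egger at desk-scale exposure GWAS sizes violates NOME noticeably
  (I²GX well below 100%); users should read I²GX and the SIMEX correction
  alongside any Egger estimate.
* No MR-PRESSO, contamination-mixture, or CAUSE estimators; no MVMR-Egger
  or MVMR-median; no multi-allelic variants, indels, liftover, or remote
  LD-reference lookup.
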