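# Methods

## Generative model

The simulator (`twostage.simmodel`) draws two biallelic SNPs independently
under Hardy–Weinberg equilibrium — genotype `g ~ Binomial(2, q)` with `q`
the minor allele frequency — and a binary disease from the log-linear
relative-risk penetrance

```
P[D = 1 | g1, g2] = min(1, exp(λ + β₁ g1 + β₂ g2 + β₃ g1 g2))
```

so `exp(λ)` is the baseline risk of a doubly-homozygous-major individual,
`exp(β₁)`, `exp(β₂)` are per-allele relative risks, and `exp(β₃)` is the
departure from multiplicativity on the relative-risk scale. Case-control
samples are simple random samples without replacement within each disease
stratum; requesting more cases or controls than the population holds is an
error, never a silent resample.

Parameters and defaults: `baseline_log_risk` (natural-log scale; the
package's study configuration uses `log 0.05`), `beta1 = beta2 = beta3 =
0`, `maf1 = maf2 = 0.2` (minor-allele convention, so MAFs must lie in
(0, 0.5]). One master seed is split into separate genotype and disease
streams, so sweeping the β grid under a fixed seed reuses the same
genotype draws — this couples power-curve cells across the grid and
removes spurious Monte-Carlo non-monotonicity.

**Risk clamping.** The log-linear model implies risks above 1 for large
relative risks; per-individual risk is clamped at 1 and a warning reports
the clamped fraction. In the moderately-rare regime the package targets
(see the RR grid below) at most 0.16% of the genotype probability mass is
affected.

**What the generator does not emulate:** linkage-disequilibrium blocks,
covariates, population stratification, genotyping error or missingness,
more than two interacting loci. Passing tests therefore demonstrate the
statistical properties of the procedure under its own assumptions, not
robustness to the confounding structure of real cohorts.

## Screening statistic

Composite LD between two features is operationalized as the Pearson
product-moment correlation of the additive codings, with significance from
the exact transform `t = r sqrt((n−2)/(1−r²))` referred to `t_{n−2}`,
two-sided. Two-sidedness is a deliberate choice: dependence in either
direction flags a disease-related pair, and the nominal level carries no
stated direction. Continuous exposures pass through the same statistic
unchanged, which is what makes the GxE and GxG scans formally identical.

Numerical conventions: `|r| = 1` maps to `p = 0` (not a failed t
computation); a constant vector within the selected stratum makes the pair
*unscreenable* — it is flagged and excluded from selection and from the
multiplicity denominator rather than being assigned `p = 1`; missing
values are dropped pairwise with the effective `n` recorded per pair.

The validity-critical property, enforced by test: given the pooled sample,
the screen is strictly a function of the feature matrix. Permuting disease
labels within a fixed pooled sample leaves every screening record exactly
unchanged.

## Testing stage

Selected pairs are fit by maximum likelihood in the four-parameter
logistic model (binary disease) or by OLS in the analogous linear model
(continuous trait, for the within-diseased design). Three null patterns
are supported: interaction only (1 df), one main effect plus interaction
(2 df, the active main effect configurable), and all three coefficients
(3 df). The canonical statistic is the likelihood ratio — better behaved
than Wald in sparse genotype cells — with Wald available as a cross-check;
the linear model uses the partial F test.

Convergence: Newton iterations with relative tolerance 1e−8, at most 100
iterations; non-convergence, complete or quasi-complete separation
(detected via statsmodels' separation check, a singular Hessian, or a
diverging coefficient `|β| > 30`), one-class outcomes, and rank-deficient
designs are explicit errors, never silent NAs. A perfect linear fit
returns the coefficients with `F = ∞, p = 0` (or `F = 0, p = 1` when the
restricted model also fits exactly), mirroring the screening `|r| = 1`
convention; only a constant trait is an error.

Note the intentional scale mismatch: data are generated on the
relative-risk scale but the case-control analysis is logistic
(odds scale). No correction is attempted — the interaction coefficients
coincide across scales only for rare disease, and the fitted β̂₃ under
ascertainment is expected to differ from the generating β₃.

## Two-stage orchestration and multiplicity

Selection is either `p ≤ alpha_screen` or the `m` smallest screening
p-values (boundary ties broken by pair index, deterministically).
Bonferroni over `n_tested` — the tests actually conducted — is the only
built-in correction; screening level and testing family level are
independent knobs, and no alpha is split between stages. An empty
selection is a valid empty result. Monotonicity holds by construction:
shrinking `alpha_screen` never increases `n_tested`.

## Permutation FDR

For scans whose screening and testing statistics are *not* independent
(e.g. screening on the interaction but jointly testing main effects plus
interaction), validity is recovered under exchangeability of observations:
disease labels are permuted uniformly, and the plug-in estimate at a
p-value threshold `t` is `mean over permutations of #{null p ≤ t}` divided
by `#{observed p ≤ t}`, capped at 1. No π₀ correction is applied, making
the estimator conservative in expectation. Labels are permuted rather than
genotype rows (equivalent under row exchangeability and cheaper). The
default of 10 permutations reflects the estimator's intended use at very
small permutation counts; a Monte-Carlo standard error over permutations
is reported alongside. When no observed p-value clears a threshold the
estimate is reported as 0 with an `undefined` flag.

For the pooled screening scheme the screen ignores labels given the
sample, so the selected pair set is permutation-invariant and only the
testing stage is recomputed per permutation — an exact optimization,
verified bit-identical to naive full recomputation. For cases-only or
controls-only screens the stratum itself changes with the labels and the
full scan is recomputed each time.

The plug-in estimate is not mathematically monotone in `t` (numerator and
denominator both grow with `t`); in signal-bearing scans it typically is,
and the test suite checks this on a fixed seeded scan rather than
asserting it as a theorem.

## Power and calibration studies

The headline power study simulates, per replicate: a 40,000-person
population (baseline risk 5%, MAFs 0.2, `exp(β₃) = 1.1`,
`β₁ = β₂ = log RR`), a sample of 1000 cases and 1000 controls, and the
composite-LD screen at α = 0.05 in each of three sampling schemes —
cases only, controls only, pooled. Power is the rejection fraction with
binomial Monte-Carlo standard errors.

**RR grid.** The default grid is 1.0 to 2.0 in steps of 0.25. The upper
end is a considered choice: by exact enumeration of the nine genotype
cells, prevalence reaches 0.11 at RR = 2 (the edge of "moderately rare"),
and past RR ≈ 2.5 risk clamping drives the within-stratum genotype
correlations negative enough that the pooled-sample correlation — and
hence screening power — *decreases* while the controls-only scheme
overtakes it. On 1.0–2.0 the clamped mass stays ≤ 0.16%, pooled power is
monotone in RR, and the main-effects-boost phenomenon is cleanly visible.
The grid and replicate count are configurable.

The calibration study draws global-null data (disease independent of all
SNPs; optionally with each screened SNP pair made dependent by copying
half the draws between columns) and reports the empirical family-wise
error rate of the full pipeline with binomial standard errors. Study sizes
used by the shipped tests — 10,000 screen replicates at n = 2,000; 2,000
calibration replicates of a 5-SNP, 600-person sample; 1,000 power
replicates per grid cell — were chosen as the package's own desk-scale
defaults giving Monte-Carlo standard errors a few permille to a percent.

## Known limitations

- The screen is correlation-based and additive-coded; allele-level
  (haplotype) composite-LD decompositions and dominance codings are out of
  scope.
- Bonferroni is the only frequentist family-wise correction; weighted or
  modular alpha-allocation hybrids are not implemented.
- The permutation FDR ships point estimates with Monte-Carlo standard
  errors, not confidence intervals.
- No covariate adjustment, retrospective-likelihood corrections, dosage
  uncertainty, or genome-scale chunked pair enumeration.
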