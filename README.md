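# twostage

Two-stage **screening–testing** scans for gene–gene (GxG) and
gene–environment (GxE) interactions in case-control studies.

## The problem and the idea

Genome-wide interaction scans face a brutal multiple-testing burden: with
*p* features there are *p(p−1)/2* candidate pairs, and correcting across
all of them drowns faint signals. The two-stage remedy implemented here is:

1. **Screening stage.** Rank every feature pair with a statistic that is a
   function of the features alone — *composite LD*, the Pearson
   product-moment correlation of the additive genotype codings (0/1/2
   minor-allele counts), referred to a t distribution with *n − 2* df.
   Given the ascertained sample, this statistic never looks at disease
   status.
2. **Testing stage.** Only pairs that survive screening are formally
   tested in a logistic interaction model,
   `logit P[D] = α + β₁·SNP1 + β₂·SNP2 + β₃·SNP1·SNP2`,
   with a likelihood-ratio test of β₃ alone (1 df), a main effect together
   with β₃ (2 df), or all three coefficients jointly (3 df). Bonferroni
   correction counts **only the tests actually conducted**.

Because any function of the features is independent of disease under the
global null, the reduced family is all that needs correction — the
procedure controls family-wise error even when the screening assumption of
pairwise independence in the population fails.

The package also demonstrates, by simulation from the relative-risk model
`log P[D] = λ + β₁·SNP1 + β₂·SNP2 + β₃·SNP1·SNP2`, that pooling cases and
controls lets **main effects** — not just interactions — power the screen:
conditioning on ascertainment induces genotype dependencies in the pooled
sample that neither stratum shows on its own.

Beyond case-control disease scans it supports the within-diseased design
(screen for unexpected dependencies among affected individuals, then test
joint effects on a continuous trait with a linear model) and a plug-in
permutation FDR estimator for scans whose screening and testing statistics
are not independent, usable with as few as 10 permutations.

## Worked example

```python
import numpy as np
from twostage import (PopulationModel, simulate_population,
                      sample_case_control, TwoStageScan)

model = PopulationModel(
    baseline_log_risk=np.log(0.05),          # 5% baseline risk
    beta1=np.log(2.0), beta2=np.log(2.0),    # main-effect RR 2 per allele
    beta3=np.log(1.1),                       # weak interaction
    maf1=0.2, maf2=0.2,
)
pop = simulate_population(model, n_pop=40_000, seed=1)
sample = sample_case_control(pop, n_cases=1000, n_controls=1000, seed=101)

scan = TwoStageScan(screen_scheme="pooled", alpha_screen=0.05,
                    test_kind="interaction_1df", family_alpha=0.05)
scan.fit(sample.genotypes, sample.disease)
```

prints (via the obvious formatting of the fitted attributes):

```
population prevalence: 0.105
screen: r=0.1012, t=4.55, df=1998, p=5.79e-06
test:   beta3=0.331, LR=5.52, df=1, p=0.0188, adjusted p=0.0188
discoveries (family alpha 0.05, 1 test): [(0, 1)]
```

Reading it: the two SNPs are independent in the population, yet in the
pooled 1000 + 1000 sample their genotypes correlate at r ≈ 0.10 — the
ascertainment-induced dependence the screen exploits — so the pair is
passed to the testing stage. There the interaction coefficient on the
odds scale is β̂₃ ≈ 0.33 with a 1-df likelihood-ratio p of 0.019, and
since exactly one test was conducted, the Bonferroni-adjusted p equals the
raw p and the pair is a discovery at family α = 0.05. (β̂₃ exceeds
log 1.1 ≈ 0.095 because the data are generated on the relative-risk scale
but analyzed on the odds scale under case-control sampling — a deliberate,
documented mismatch.)

The same scan is available from the shell:

```bash
twostage simulate --rr1 2 --rr2 2 --rr-interaction 1.1 --seed 1 --out sim/
twostage run --features sim/features.tsv --phenotypes sim/phenotypes.tsv \
             --scheme pooled --alpha-screen 0.05 --test interaction1 \
             --family-alpha 0.05 --out results/
twostage fdr --features sim/features.tsv --phenotypes sim/phenotypes.tsv \
             --n-perm 10 --thresholds 0.05,0.01,0.001 --seed 2 --out fdr/
twostage experiment power --n-reps 1000 --seed 3 --out power/
```

Every run writes a JSON manifest (config, seed, versions) next to its
outputs, sufficient to regenerate them bit-identically.

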