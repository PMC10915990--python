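# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument construction, five causal estimators, a full sensitivity suite,
and two-step MR mediation — plus a seeded synthetic summary-statistics
generator so every stage can be exercised and verified without any external
data.

`mrkit` is for epidemiologists and statistical geneticists who estimate
causal effects of one trait on another (e.g. a behavioural exposure on a
psychiatric outcome) using only published per-variant association tables
from two non-overlapping GWAS samples.

## The method

A genetic variant *j* with exposure association β̂<sub>Xj</sub> (SE
σ<sub>Xj</sub>) and outcome association β̂<sub>Yj</sub> (SE σ<sub>Yj</sub>)
yields a Wald ratio β̂<sub>Yj</sub>/β̂<sub>Xj</sub>, an estimate of the causal
effect if the variant is a valid instrument. The package implements:

- **Instrument construction** — significance filtering (p < 5×10⁻⁸),
  greedy LD clumping (r² > 0.001 within 10,000 kb), proxy substitution
  (r² > 0.8, sign-aligned), effect-allele harmonization with strand
  handling, removal of palindromic variants at intermediate allele
  frequency, iterative radial-Q outlier removal, and Steiger filtering
  (drop variants explaining more outcome than exposure variance, with
  R² = β²/(β² + N·se²) and instrument strength F = R²(N−2)/(1−R²)).
- **Estimators** — inverse-variance-weighted average
  β̂ = Σw<sub>j</sub>r<sub>j</sub>/Σw<sub>j</sub> with w<sub>j</sub> =
  β̂²<sub>Xj</sub>/σ²<sub>Yj</sub> (multiplicative random effects by
  default); MR-Egger (WLS with a pleiotropy intercept); the weighted
  median; the mode-based estimate (weighted KDE argmax); and the robust
  adjusted profile score (MR-RAPS) with Huber/Tukey loss and
  overdispersion.
- **Sensitivity** — Cochran's and Rücker's Q, the Egger intercept test,
  the simulation-based residual-sum-of-squares global/outlier/distortion
  (MR-PRESSO) tests, leave-one-out influence, and Bonferroni-corrected
  exclusion of instruments associated with known confounders.
- **Mediation** — two-step MR: indirect effect a·b by the product of
  coefficients, delta-method SE √(a²se²<sub>b</sub> + b²se²<sub>a</sub>),
  and the mediated proportion (indirect/total).
- **Standardization** — Z-score-only tables are converted with
  β = z/√(2f(1−f)(N+z²)), se = 1/√(2f(1−f)(N+z²)).

## Worked example

```bash
python examples/01_simulate_and_estimate.py
```

```
true slope: 0.300  (OR 1.350)
method               beta       se     OR           95% CI          p
IVW                0.2937   0.0141  1.341   (1.305, 1.379)   1.16e-96
MR-RAPS            0.2926   0.0125  1.340   (1.308, 1.373)  1.75e-121
MR-Egger           0.3149   0.0206  1.370   (1.316, 1.427)   1.54e-52
weighted-median    0.3154   0.0215  1.371   (1.314, 1.430)   6.64e-49
weighted-mode      0.3195   0.0222  1.376   (1.318, 1.438)   7.09e-47
```

One hundred simulated instruments carry a true causal log-odds slope of
0.3 (odds ratio 1.35 per SD of exposure); all five estimators recover it
within sampling error, and the 95% CIs cover the truth. The other example
scripts walk through instrument construction (`02`), the sensitivity suite
on a planted outlier (`03`), two-step mediation (`04`), and the full
bidirectional pipeline with on-disk reports (`05`).

A thin CLI wraps the same functions:

```bash
mrkit simulate --seed 3 --n-snps 100 --true-slope 0.3 --out sim/
mrkit mr sim/exposure.tsv sim/outcome.tsv --out report/
```

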