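# Methods

## Model and assumptions

`mrkit` implements two-sample summary-data Mendelian randomization. The
data for one analysis are per-variant association estimates
(β̂_Xj, σ_Xj) with an exposure from one GWAS sample and (β̂_Yj, σ_Yj)
with an outcome from a second, non-overlapping sample. Under the
instrumental-variable assumptions — each variant is (1) associated with
the exposure, (2) independent of exposure–outcome confounders, and
(3) affects the outcome only through the exposure — each Wald ratio
r_j = β̂_Yj/β̂_Xj estimates the same causal slope β, and the package's
estimators combine the ratios under progressively weaker versions of
assumption (3). Binary traits are handled on the log-odds scale
throughout; the causal slope for a binary outcome is a log odds ratio and
is reported alongside exp(β) with a normal-theory CI.

Sample overlap between the two GWAS is assumed absent (two-sample
design); correlated instruments are assumed removed by clumping. Neither
assumption is checked internally — both are properties of the inputs.

## Instrument construction

The stage chain mirrors standard practice, and every discarded variant is
recorded in a dropped ledger so `selected = retained + dropped` is an
enforced invariant:

1. **Selection**: p < 5×10⁻⁸ (strict) in the exposure GWAS.
2. **Clumping**: greedy by ascending p; a candidate is discarded if
   r² > 0.001 with an already-kept variant within 10,000 kb (inclusive,
   same chromosome). Ties break by position then identifier, making the
   result independent of input order. Variants absent from the
   user-supplied LD matrix are treated as unlinked; cross-chromosome
   pairs are always unlinked.
3. **Confounder exclusion** (optional): any instrument with a
   confounder-association p below 0.05/(n_instruments × n_risk_factors)
   is removed.
4. **Proxies**: an instrument missing from the outcome table is replaced
   by the highest-r² variant present with r² > 0.8, re-oriented with the
   LD sign matrix. Without a sign the proxy's phase is unknowable from
   summary data, so the instrument is dropped rather than guessed.
5. **Harmonization**: outcome effects are aligned to the exposure effect
   allele; swapped allele order flips the sign and mirrors the
   frequency, strand-complement pairs are complemented first, and
   incompatible pairs are dropped. Harmonizing already-aligned data is a
   no-op.
6. **Palindromic filter**: A/T and C/G variants with exposure EAF inside
   (0.42, 0.58) (configurable) are removed; extreme-frequency
   palindromic variants are retained, with the outcome sign flipped when
   the two frequencies sit on opposite sides of 0.5.
7. **Radial filter**: first-order radial regression; each variant's
   heterogeneity contribution Q_j = w_j(r_j − β̂)² is referred to χ²(1)
   and the single worst variant with p < 0.05 is removed per iteration
   until convergence. One-at-a-time removal is deliberate: a gross
   outlier inflates every other variant's Q_j, so batch removal can
   discard the whole panel in one step.
8. **Steiger filter**: a variant is removed when
   R²_out = β̂²_Y/(β̂²_Y + N_Y σ²_Y) exceeds R²_exp computed analogously.
   The default is this plain comparison; a z-tested variant (Fisher
   transform of the implied correlations) is available behind a flag.

## Estimators

All five operate on first-order Wald ratios (ratio SE σ_Yj/|β̂_Xj|;
second-order SEs behind a flag).

- **IVW**: β̂ = Σw_j r_j / Σw_j, identical to zero-intercept WLS of β̂_Y
  on β̂_X with weights 1/σ²_Y. Default model is multiplicative random
  effects — the fixed-effect SE is inflated by √(Q/(J−1)) when Q exceeds
  its expectation, floored at 1 — matching the dominant practice of the
  field's tooling; `model="fixed"` disables it.
- **MR-Egger**: WLS with intercept on orientation-normalized data
  (β̂_X ≥ 0). The intercept estimates the mean directional pleiotropic
  effect; the slope is consistent under InSIDE. P-values use the normal
  reference by default (t with J−2 df configurable).
- **Weighted median**: ordered ratios interpolated at mid-cumulative
  weight 0.5; consistent while valid instruments hold > 50% of weight.
  SE by seeded parametric bootstrap (default 1000 draws of
  r_j ~ N(r_j, se_j)).
- **Weighted mode**: argmax of a weighted normal-kernel density with
  bandwidth φ × 0.9·min(sd, IQR/1.349)·J^(−1/5) (modified Silverman,
  φ = 1 by default), searched on a 10,000-point grid spanning the ratio
  range ± 3 bandwidths. Degenerate zero-spread input returns the common
  ratio. SE by seeded bootstrap.
- **MR-RAPS**: solves the profile estimating equation
  Σ ψ(t_j)·β̂_Xj/s_j = 0 with
  t_j = (β̂_Yj − ββ̂_Xj)/s_j, s_j² = σ²_Yj + β²σ²_Xj + τ², where ψ is
  identity (l2), Huber (c = 1.345) or Tukey biweight (c = 4.685). With
  overdispersion enabled, τ² solves Σ(ψ(t_j)t_j − δ) = 0 with
  δ = E[ψ(Z)Z] under Z ~ N(0,1) (Gauss–Hermite quadrature), alternating
  with the slope equation to joint convergence. SEs are sandwich-type
  (B/A² with numerical A). Exposure-side uncertainty enters s_j, which
  is what makes the estimator robust to many weak instruments; with l2
  loss, no overdispersion and σ_X → 0 it reduces exactly to fixed-effect
  IVW (asserted in tests).

Heterogeneity: Cochran's Q about the IVW fit (df J−1) and Rücker's Q
about the Egger fit (df J−2), both with first-order weights; Rücker ≤
Cochran always, since the intercept absorbs heterogeneity.

## Sensitivity suite

- **Egger intercept test**: two-sided test of intercept = 0 at α = 0.05.
- **MR-PRESSO**: observed statistic is the weighted residual sum of
  squares of each variant about its leave-one-out IVW fit; the null
  distribution comes from parametric simulation of outcome effects under
  the fitted no-pleiotropy model (default 1000 draws, add-one smoothing,
  so p ≥ 1/(n_sim+1)). When the global test rejects, per-variant
  residuals are referred to their own simulated distributions with
  Bonferroni correction; the distortion test compares the estimate shift
  from removing the flagged set against shifts from removing random
  subsets of the same size. First-order weights (the method's weighting
  order is a documented open choice; second-order is not offered).
- **Leave-one-out**: J IVW re-fits; a variant is influential when its
  omission moves the p-value across the study threshold (the family-wise
  Bonferroni threshold by default).

## Mediation

Two-step MR: step 1 regresses the mediator on the exposure's
instruments, step 2 the outcome on the mediator's instruments, both via
the full stage chain and IVW. The indirect effect is a·b with
first-order delta SE √(a²se²_b + b²se²_a); steps from non-overlapping
samples are treated as independent, so no covariance term is included.
The mediated proportion is indirect/total on the log-effect scale, with
a ratio-delta CI, and is flagged unreliable when |total/se| < 2 (the
ratio expansion degrades). Step 2 is univariable (no adjustment for the
exposure) — a documented limitation: when the mediator's instrument set
overlaps the exposure's signals, step 2 absorbs part of the direct path.
The orchestrated analysis computes mediation only when both the total
and step-1 effects pass the gate (family threshold by default, nominal
0.05 configurable) and reports a failed gate explicitly.

Family-wise correction is user-declared: `n_tests` in the study config
(e.g. 13 for an 8+4+1 family of trait pairs) sets the Bonferroni
threshold α/n_tests.

## Synthetic data generator

The generator works at the summary level. MAFs are uniform on the
configured range (default 0.05–0.5); true per-allele exposure effects
are drawn N(0,1) and rescaled so Σ2f(1−f)β² equals the target
heritability; true outcome effects are β_Y = β·β_X + α_j, with
pleiotropy α_j zero (valid), balanced N(0, sd), directional N(mean, sd)
or instrument-strength-correlated (InSIDE-violating), applied to a
configured fraction of variants and expressed per exposure-increasing
allele (so a directional mean is what the Egger intercept estimates).
Observed effects add N(0, se) noise with se = 1/√(2f(1−f)N) — the SE
model of a standardized trait — and p-values are computed exactly from
β̂/se. The mediation generator emits distinct instrument sets for
exposure and mediator with effects a, b and direct c′ chained through
the three traits. Binary outcomes are emulated directly on the log-odds
scale; alleles are non-palindromic pairs; all draws flow from one seed.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: LD between instruments (LD
matrices are generated separately as block-diagonal toys), sample
overlap, population stratification, allele-frequency differences between
samples, winner's-curse beyond simple threshold selection, strand errors
and genome-build mismatches. Tests verify the statistics, not the messy
provenance of real summary files.

Default study conditions follow the scale of the motivating application:
biobank-sized exposure GWAS (10⁵–10⁶ range), ~100 independent
instruments explaining 2–10% of exposure variance (per-variant F well
above the >10 screen), and case-control outcomes of ~10⁵. Recovery
checks use the stronger end of those ranges so that the known
regression-dilution bias of ratio estimators (attenuation factor
≈ h²/(h² + J/N_exp)) is negligible against Monte-Carlo error; the
calibration and breakdown checks use the weaker end, where the
phenomena under test are visible.

## Numerical choices

- Clumping ties: position then identifier; windows inclusive, 1-based.
- Weighted-median interpolation uses mid-cumulative standardized weights
  (s_j = (cum_j − w_j/2)/Σw).
- RAPS root-finding: Brent's method, bracket expanded from the IVW
  pilot; overdispersion solved on τ² ∈ [0, var-bound] with bisection;
  non-convergence raises with diagnostics rather than returning a value.
- Bootstrap and simulation seeds are mandatory in the pipeline and are
  derived from the master seed via fixed per-stage spawn keys, so adding
  a stage never re-seeds existing ones; reports are therefore
  byte-identical across re-runs (no timestamps are written).
- P-values from normal references are clipped away from exact zero only
  in the generator (where emitted records must satisfy p > 0).
- Degenerate inputs: < 2 instruments → not estimable (pipeline) or
  `EstimationError` (library); radial filter passes through below 2 and
  never reduces below 3; PRESSO requires ≥ 4 and n_sim ≥ 100.

## Known limitations

- No multivariable MR, no correlated-instrument (generalized) IVW, no
  contamination-mixture or Bayesian estimators.
- LD is a user input; the package never computes it from genotypes.
- Proxy alignment requires a sign matrix; unsigned proxies are dropped.
- The Egger intercept inherits finite-sample bias when instruments are
  selected at a threshold (winner's curse); the package does not correct
  for selection.
- Mediation assumes non-overlapping samples for the delta-method SE; with
  overlap the indirect-effect SE is misstated.
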