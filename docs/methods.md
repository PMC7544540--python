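# Methods

## Scope and data model

The package implements the summary-statistics ("two-sample") form of
Mendelian randomization. All inputs are per-SNP association records —
rsID, effect/other allele, effect-allele frequency (optional), beta, SE,
p-value, sample size (optional) — in tab-separated text with configurable
column names, because exposure and outcome tables typically come from
differently formatted GWAS pipelines. Exposure betas are interpreted in SD
units of smoking-initiation prevalence; binary-outcome betas on the
log-odds scale, so causal estimates exponentiate to odds ratios per SD of
exposure. Indels and multi-allelic records are rejected: the estimators
assume biallelic SNPs. Allele frequency and sample size are tolerated as
missing since no estimator requires them; only palindrome orientation and
the EAF-based variance-explained formula use frequencies.

## Instrument selection

Three stages, each counted in a selection log: (1) keep exposure SNPs with
p < 5 × 10⁻⁸ (genome-wide significance; configurable); (2) drop SNPs
absent from the outcome table (no proxy lookup — that belongs upstream);
(3) LD-prune. Pruning collects every stored pair with r² strictly above
the threshold (default 0.1), processes pairs in descending r² (ties broken
by rsid), and within a pair discards the member with the larger exposure
p-value, breaking exact p ties toward the lexicographically larger rsid.
This greedy order is a deterministic completion of the pairwise "drop the
weaker SNP" rule and makes the retained set invariant to the order of the
input table, which a naive first-come scan is not. The strict inequality
at the threshold is deliberate: a pair at exactly r² = 0.1 is kept.

Instrument strength is reported as total variance explained R² (sum of
per-SNP terms) and the joint F statistic
F = (R²/k) / ((1−R²)/(N−k−1)). Two per-SNP R² formulas are offered:
z²/(z² + N − 2) (default; needs no allele frequency) and
2·EAF·(1−EAF)·β² (requires EAF). Note that published strength figures for
this design are not always recoverable from published aggregates: with
R² = 0.023, k = 361, N = 1,232,091 the formula above gives F ≈ 80.3,
whereas 78.5 has been reported for the same inputs; the package reports
the formula value and makes no attempt to match any particular published
figure, since the exact computation behind it is unstated.

## Harmonization

Outcome records are aligned to the exposure's effect allele. Identical
allele pair and orientation: kept. Swapped alleles: outcome beta negated
and EAF complemented. Complementary alleles: treated as a strand flip and
re-compared (a complement plus swap therefore also negates the beta; its
action is recorded as `outcome_sign_flipped`, since the action vocabulary
is flat and the sign change is the datum that matters downstream).
Irreconcilable pairs are dropped and counted.

Palindromic SNPs (A/T, C/G) are ambiguous — a strand flip is
indistinguishable from an allele swap. The default policy
(`drop_ambiguous`) orients by frequency agreement when both EAFs lie
outside [0.42, 0.58] and drops the SNP otherwise (including when either
EAF is missing). `drop_all` and `keep_assume_forward` are available; the
window is configurable. This is standard practice rather than a rule
inherited from any particular analysis, which is why it is a policy knob.

## Estimators

Implemented from closed-form weighted least squares in numpy; no external
MR package is called (statsmodels appears only as a test oracle).

- Wald ratio: β_Y/β_X with first-order SE σ_Y/|β_X|. First-order is the
  default because it makes the IVW-combined ratios algebraically identical
  to the weighted regression through the origin; the second-order term
  (adding β_Y²σ_X²/β_X⁴) is available behind a flag. The first-order
  convention ignores exposure-side noise, which at very large exposure
  effects produces mild regression-dilution attenuation (quantified
  below).
- IVW, multiplicative random effects: point estimate from the
  weighted-through-origin normal equation; SE = fixed-effect SE ×
  √max(1, Q/(k−1)). The overdispersion factor is floored at 1 so the
  reported SE never shrinks below the fixed-effect SE. Normal reference
  for the p-value. One SNP only: falls back to the Wald ratio with a
  warning.
- Weighted median: ratios sorted, inverse-variance weights (β_X²/σ_Y²)
  normalized, estimate interpolated at cumulative weight 1/2 using
  midpoint positions S_j − w_j/2, clamped to the extreme ratios. SE from a
  parametric bootstrap (default 1000 draws) resampling both betas from
  their reported normals; the seed is mandatory and printed SEs are
  reproducible only per seed. The bootstrap scheme is a documented choice;
  published median SEs from other implementations need not match draw for
  draw.
- MR-Egger: SNPs oriented to β_X ≥ 0 before fitting (the intercept is the
  mean directional pleiotropy only under that orientation), weighted
  regression with intercept, SEs inflated by max(1, √(Q/(k−2))), t
  reference with k−2 df for both slope and intercept.
- Multivariable IVW: weighted no-intercept regression of β_Y on all
  exposure columns; SEs inflated by √max(1, Q/(k−K)); rank deficiency is
  detected from the QR diagonal and reported with the offending exposure
  names.

Evidence tiers use strict inequalities on both boundaries (p exactly at
α/m is "suggestive", p exactly at α is "null"), assigning boundary cases
to the less significant tier. The threshold is compared unrounded; display
rounds to 2 significant figures (0.05/14 → 3.6 × 10⁻³).

## Risk translation

A prevalence shift p_ref → p_target is expressed as
Δ = logit(p_ref) − logit(p_target); with the default 0.46 → 0.20 this is
1.226. The predicted proportional risk reduction for an outcome with odds
ratio OR per SD is 1 − OR^(−Δ), i.e. the OR-per-SD is treated as acting
multiplicatively along the log-odds-scale exposure shift. This formula is
a reconstruction: it is fixed by requiring the peripheral-arterial-disease
worked pair (OR 1.81, Δ 1.22 → 52%) to reproduce, and it also reproduces
the other published integer reductions. Comparisons use unrounded values;
display rounds to whole percent. It is a population-level extrapolation,
valid only insofar as the log-odds-linear MR model itself holds across the
whole prevalence range.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the real study's scale — defaults: 361 independent instruments, total
exposure R² = 0.023, exposure GWAS N = 1,232,091, outcome GWAS
N = 367,643. Per-SNP variance-explained shares are exponential-tailed
(normalized Exp(1) draws) so a few strong instruments dominate, as in real
GWAS; an equal-beta mode exists for analytic checks. True exposure betas
are z·σ_X with σ_X = 1/√N_exp and random sign; observed betas add
N(0, σ_X) noise. Outcome SEs are 1/√(N_out·cf·(1−cf)) for case fraction cf
(default 0.25) with ±10% jitter; observed outcome betas are
θ·β_X + α_j + confounder paths + N(0, σ_Y), generated directly on the
log-odds scale (no liability-scale conversion), matching the scale on
which odds ratios are reported.

Direct (pleiotropic) effects α_j are drawn for a configurable fraction of
SNPs, balanced (mean forced to zero) or directional, and are expressed
relative to the exposure-increasing allele — the orientation under which
the Egger intercept estimates their mean — then mapped back to each SNP's
reported allele. An `inside_violation` flag scales α_j with instrument
strength to break the InSIDE assumption. Confounders are generated as
per-SNP betas correlated with the exposure betas at the configured genetic
correlation (defaults: alcohol 0.36, BMI 0.12, education −0.40) with an
independent causal effect on the outcome (default 0, so the baseline
bundle satisfies the exclusion restriction unless a confounded path is
requested).

Structural injections for testing the plumbing: disjoint LD pairs whose
second member's true effect is a correlated copy (r = √r², r² drawn in
(0.15, 0.95)) with a matching LD-table entry — injected before outcome
generation so the duplicate's outcome beta stays consistent; SNPs omitted
from the outcome tables (never LD-pair members, so selection accounting
stays exact); and allele-scrambled outcome records (swap with sign/EAF
flip, or strand complement) recorded in the truth manifest so tests can
verify harmonization restores the original effects exactly.

The study-shaped fixture (378 SNPs, 1 missing, 16 LD pairs → 361 retained)
additionally floors true instrument z-scores at the significance threshold
plus a 1.5-z margin and redraws sampling noise for any SNP whose observed
p would fail 5 × 10⁻⁸. This mirrors the fact that the source instruments
are genome-wide significant by construction; without it the fixture's
selection accounting would be seed-dependent, which would make the count a
property of the draw rather than of the design.

What the generator does **not** emulate: individual-level genotypes,
realistic genome-wide LD (only the injected pairs), allele-frequency-
dependent effect sizes, sample overlap between exposure and outcome GWAS,
population stratification, and case-control ascertainment effects. Tests
passing on these bundles therefore show that the estimators and plumbing
behave as the theory predicts under the stated generating model — not that
real consortium data meet that model's assumptions.

## Numerical and design notes

- Determinism: one `numpy` Generator per bundle, seeded; replicate studies
  derive child seeds via `SeedSequence`. Outputs carry no timestamps, so
  identical config + seed gives byte-identical files.
- Replicate-based checks (type-I error, CI coverage, Egger intercept size,
  median-vs-IVW robustness, MVMR deconfounding) use 100–500 replicates at
  the full 361-SNP scale; these sizes give Monte-Carlo error comfortably
  inside the asserted bands while keeping the whole suite under a minute.
- With the default sizes, first-order Wald SEs imply a regression-dilution
  attenuation of ≈ Σσ_X²/Σβ_X² ≈ 1.3% of θ. This exceeds the Monte-Carlo
  error of a 200-replicate mean at large θ, so mean-recovery assertions
  use an absolute tolerance of 0.02 on θ = log 1.81; CI-coverage checks
  use an atrial-fibrillation-sized effect (log 1.18), where the
  attenuation is negligible relative to the SE.
- Degenerate inputs: zero exposure beta is a domain error for ratio-based
  estimators; all-equal exposure betas are a collinearity error for Egger;
  a single SNP downgrades IVW to the Wald ratio with a warning;
  Q = 0 yields I² = 0 and φ = 1 exactly.
- Validation philosophy: structurally unusable rows (missing or
  nonpositive SE) are dropped and counted at read time; contract
  violations that indicate corrupted data (duplicate rsids, invalid
  alleles, out-of-range frequencies) raise. A p-value inconsistent with
  |beta/SE| by more than 2× in implied z warns but does not fail, since
  published tables round aggressively.

## Known limitations

- No correlated-instrument (LD-aware) IVW; instruments are assumed
  independent after pruning.
- No MR-PRESSO, mode-based, or Steiger-filtered estimators.
- The risk translation assumes the log-odds-linear model globally; it is a
  reconstruction of a published presentation, not a derived identity.
- Harmonization handles biallelic SNPs only; no genome-build liftover.
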