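# Methods

## Model and assumptions

`ivmr` implements two-sample summary-data Mendelian randomization (MR). For
each genetic variant j we observe an estimated variant–exposure effect γ̂_j
with standard error σ_Xj from one GWAS and a variant–outcome effect Γ̂_j
(log-odds of a binary outcome) with standard error σ_Yj from an independent
GWAS. Under the instrumental-variable assumptions (relevance, independence
from confounders, and no effect on the outcome except through the exposure),
each valid instrument identifies the causal effect through the Wald ratio
θ_j = Γ_j/γ_j. The package treats the γ̂_j as measured without error when
weighting and propagating uncertainty (the "NO Measurement Error"
convention of summary-data MR): the first-order ratio SE is s_j = σ_Yj/|γ_j|
and the IVW weight is w_j = γ_j²/σ_Yj² = s_j⁻². This is accurate when
instruments are strong (per-variant F = (γ_j/σ_Xj)² well above ~10) and is
the reason F statistics and variance explained are reported alongside every
analysis.

All estimates are reported as log-ORs per 1 SD of a continuous exposure; for
a binary-liability exposure they can be rescaled to "per doubling of odds"
by multiplying β and SE by ln 2 ≈ 0.693147, which leaves z-ratios and
p-values unchanged.

## Instrument selection

Variants are retained when the exposure p-value is strictly below the
threshold (default 5×10⁻⁸), then intersected with the outcome study and
LD-clumped. Clumping is greedy: the remaining variant with the smallest
p-value (ties broken by chromosome, then position) becomes an index, and
every remaining same-chromosome variant within ±500 kb with r² ≥ 0.01
against it is removed. Retained pairs within a window therefore satisfy
r² < 0.01. Cross-chromosome LD entries are ignored; a *missing* LD entry
within a window is an error rather than an implicit zero, because silent
independence assumptions are a known failure mode. The default order is
intersect-then-clump; `clump_before_intersect` flips it, since published
pipelines differ and the choice can matter when the outcome study has
patchy coverage.

Variance explained per variant defaults to 2·EAF·(1−EAF)·γ_j², exact for a
trait standardized to unit variance (the scale on which per-SD effects are
reported). When no allele frequency is available (e.g. a liability-scale
binary exposure) the fallback F_j/(F_j + n − 2) is used; both are emitted in
the diagnostics table and agree within a few percent for standardized
traits with F ≪ n.

## Harmonization

Outcome records are aligned to the exposure's effect allele by label
matching, trying the strand complement when the labels do not match
directly; a label swap negates the outcome beta and complements the EAF.
Palindromic variants (A/T, C/G) cannot be oriented from labels. The default
policy aligns them by allele frequency when both studies report an EAF
outside the ambiguity band [0.42, 0.58] (configurable); the `drop` policy
excludes them outright. The paper trail matters more than the recovery
rate, so every excluded variant is written to an exclusion report with a
reason, and the pipeline guarantees that each exposure variant appears in
exactly one of {instrument set, exclusion report}. Indels are matched on
exact or swapped labels only. Matching across studies is by verbatim
variant ID; no positional or proxy matching is attempted.

## Estimators

**Random-effects IVW** (main analysis). β̂ = Σw_jθ̂_j/Σw_j, equivalent to a
weighted regression of Γ̂ on γ̂ through the origin with weights 1/σ_Yj². The
fixed-effect SE (Σw_j)^(−1/2) is multiplied by max(1, √(Q/(J−1))), where
Q = Σw_j(θ̂_j − β̂)² is Cochran's Q — the *multiplicative* random-effects
model, floored at 1 so heterogeneity can only widen intervals. A single
instrument degrades to its Wald ratio with a warning.

**MR-Egger.** Weighted regression of Γ̂ on γ̂ *with* an intercept, after
re-signing each variant so γ̂_j > 0 (the fit is otherwise not invariant to
allele coding). The slope estimates θ under the InSIDE assumption
(instrument strength independent of direct effects); the intercept estimates
the average directional pleiotropy of the instruments — note that with a
fraction π of invalid instruments carrying mean direct effect μ, the
intercept's estimand is π·μ, not μ. Both SEs carry the multiplicative
inflation max(1, √(Q_egger/(J−2))). The fit itself is delegated to
statsmodels WLS; the fixed-effect covariance is taken from (X′WX)⁻¹ so the
inflation floor can be applied explicitly (and so exact-fit data do not
produce a zero residual scale).

**Weighted median.** Ratios are sorted, inverse-variance weights normalized
to sum 1, and the midpoint cumulative rank S_j = Σ_{k≤j}w_k − w_j/2 is
interpolated linearly against θ̂ at 0.5 (clamped to the extreme ratios).
With equal weights and odd J this is the textbook median. Consistent when
valid instruments carry >50% of the weight — in the limit of growing GWAS
precision (s_j → 0); at fixed ratio noise a one-sided invalid minority
leaves a bounded quantile shift of order s·z(0.5/p_valid).

**Weighted mode.** Gaussian-kernel weighted density of the ratios with
bandwidth h = factor · 0.9 · min(SD, MAD/0.6745) · J^(−1/5) (Silverman's
rule with a robust scale), evaluated on a 512-point grid spanning the ratios
±3h; the estimate is the density argmax. Exact ties resolve to the smaller
candidate because the grid is ascending. If all ratios coincide the common
value is returned directly.

**Bootstrap SEs** for median and mode: parametric resampling of γ̂_j and Γ̂_j
from normal distributions with their reported SEs, n_boot = 1000 by default
with a recorded seed; CI = estimate ± 1.96·SE. `n_boot = 0` skips the
bootstrap (SE = NaN), which large simulation studies use when only point
estimates are needed.

**Contamination mixture.** Over a grid of ≥1000 candidate values spanning
[min θ̂ − 2·max s, max θ̂ + 2·max s], each variant contributes the larger of
log N(θ̂_j; θ, s_j²) (valid) and log N(θ̂_j; 0, s_j² + ψ²) (invalid); the
profile log-likelihood is the sum of per-variant maxima. The estimate is the
grid argmax; the 95% confidence set is {θ : 2(ℓ_max − ℓ(θ)) ≤ 3.841} and is
reported as a union of intervals — genuinely disjoint sets arise when two
clusters of instruments have comparable support. ψ defaults to 1.5 × SD of
the ratios. The scalar SE reported for table output is the width of the
interval containing the estimate divided by 2·1.96 (a normal-scale
convenience; the confidence set is authoritative). The p-value is the
likelihood-ratio test of θ = 0 against χ²₁.

All five estimators are invariant to re-expressing any subset of variants
for the other allele (simultaneous sign flip of γ_j and Γ_j). Inference uses
the standard normal reference throughout, the convention for summary-data
MR with moderate-to-large instrument counts.

## Power and cross-stratum comparison

The minimum detectable OR treats the IVW log-OR estimate as normal with
variance 1/(N·R²·K(1−K)) — N the GWAS sample size, R² the total variance
explained by the instruments (sum of per-variant r²), K the outcome case
fraction — giving |log OR| = (z_{1−α/2} + z_{power})/√(N·R²·K(1−K)).
Which N to use is a deliberate caller choice (`PowerSpec.n`), because
published analyses are ambiguous between the exposure and outcome study
sizes; the pipeline logs the value used. The outcome-study variant is the
one with a well-defined empirical analogue, and it is the one validated
against the individual-level simulator.

Differences between ancestry strata are tested per method by propagation of
error: diff = β_A − β_B, SE = √(SE_A² + SE_B²), two-sided normal p. No
multiple-testing correction is applied across exposures or methods.

## Synthetic data generator

The generator emulates the two-sample structure the analysis assumes:
MAF ~ U(0.1, 0.5); true effects γ_j = |N(0, 0.08²)| with every effect allele
oriented as the exposure-increasing allele (standard GWAS reporting; it is
also what makes *directional* pleiotropy directional rather than
self-cancelling across random allele codings); invalid instruments receive a
direct outcome effect α_j ~ N(μ_p, τ_p²) (μ_p = 0 under the balanced
regime), entering as Γ_j = θγ_j + α_j; sampling noise uses the large-sample
SEs σ_Xj = (2p_j(1−p_j)·n_exp)^(−1/2) and, for a case-control outcome,
σ_Yj = (2p_j(1−p_j)·n_out·K(1−K))^(−1/2). Outcome effects are generated
directly on the log-odds scale with this variance approximation rather than
through individual-level logistic sampling, which keeps large simulation
studies fast. Optional block LD produces an equicorrelated LD matrix and
correlates the *sampling errors* within a block; true effects remain
independent across variants, a simplification relative to real tag-SNP
structure that matters only for clumping behavior, which is tested
separately.

Default design sizes mirror an African-ancestry two-sample setting
(exposure GWAS ≈ 77 000 participants; outcome 3 734 cases / 18 317
controls, K ≈ 0.169); the European-ancestry comparison stratum in the
validation suite uses 297 626 / 440 328 with K ≈ 0.078. γ_sd = 0.08 with
n_exp = 77 000 puts most candidate variants past genome-wide significance
with selected-variant F statistics in the tens to hundreds, the regime of a
well-powered metabolic-trait GWAS; it is also the regime in which the NOME
approximation underlying the ratio SEs is accurate. What passing simulation
tests do *not* establish: behavior under weak instruments (mean F near 10),
sample overlap between the two GWAS, fine-scale LD misspecification, or
allele-frequency differences between the instrument and reference panels —
none of which the generator emulates.

A separate individual-level simulator backs the power calculation: per
replicate it draws an exposure cohort (standardized genetic score G
explaining R² of the exposure) and an independent outcome cohort whose
disease log-odds are logit(K) + log(OR)·√R²·G, then tests the G–outcome
association with the logistic score test. The causal effect is applied to
the genetically proxied exposure component — exactly the structural model
the closed-form power formula assumes. Including residual exposure variance
inside the logistic would attenuate the marginal slope (non-collapsibility
of the OR), a real-world gap between the formula and a fully generative
disease model; the self-consistency check deliberately excludes it, so the
validation shows internal consistency of the formula, not robustness to
non-collapsibility.

## Numerical and design choices

- Thresholds use strict inequality for significance (p < threshold) and
  removal at r² ≥ r2_max, so retained pairs satisfy r² < r2_max.
- P-values from the generator are floored at 1e-300 to keep them inside
  (0, 1] under extreme z-scores.
- Equicorrelation blocks require −1/(m−1) < r < 1 (positive definiteness);
  violating requests are rejected rather than repaired.
- Weighted-median interpolation clamps at the extreme ratios when 0.5 falls
  outside [S_1, S_J].
- The contamination-mixture grid always contains the exact center of a
  degenerate (all-ratios-equal) instance; a zero-span instance returns a
  point estimate with a zero-width set.
- File output uses `%.12g` formatting, preserving 10 significant digits
  round-trip; run logs contain no timestamps, so a fixed config and seed
  reproduce byte-identical outputs.
- Validation simulation sizes (500 seeds for bias/coverage, 2000 paired
  replicates for difference-test calibration, 1000 replicates per cell of
  the 3×3 power grid) keep Monte-Carlo error a factor of a few below each
  asserted tolerance while the whole suite runs in well under an hour on a
  single core.

## Known limitations

- No proxy-variant lookup for instruments missing from the outcome study,
  no Steiger filtering, no MR-PRESSO/SIMEX, no multivariable or
  bidirectional MR; the package covers the univariable two-sample design
  only.
- LD matrices are accepted as input, never computed from genotypes; no
  liftover or positional ID reconciliation is performed.
- The NOME-based ratio SEs understate uncertainty for weak instruments.
- The Egger intercept test has low power at small J and its estimand under
  partial contamination is the weighted average direct effect, not the
  per-invalid-variant mean.
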