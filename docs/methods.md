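# Methods

## The causal model

For SNP *j* let γⱼ be its true per-allele effect on a standardized
continuous exposure and αⱼ its direct (pleiotropic) effect on the
outcome. The outcome model on the log-odds scale is

  E[b̂ᵧⱼ] = θ·γⱼ + αⱼ,

with θ the causal log-OR per SD of exposure. A SNP is a *valid*
instrument when αⱼ = 0; then the Wald ratio b̂ᵧⱼ/b̂ₓⱼ is a consistent
estimate of θ and the estimators below are different ways of pooling
and robustifying those ratios. Two-sample designs draw b̂ₓ and b̂ᵧ from
independent cohorts, so their sampling errors are uncorrelated.

## Estimators

**IVW.** Weighted through-origin regression of b̂ᵧ on b̂ₓ with weights
1/sᵧ², identical to the 1/se²-weighted mean of Wald ratios. The fixed
model uses SE = 1/√(Σ b̂ₓ²/sᵧ²); the default multiplicative
random-effects model multiplies it by the residual scale √(Q/(k−1))
floored at 1, so it is never anti-conservative relative to fixed.
P-values are normal. With one SNP, IVW is exactly the Wald ratio.

**MR-Egger.** The same regression with an intercept, after orienting
every SNP so b̂ₓ > 0. Under InSIDE (instrument strength independent of
direct effects) the slope estimates θ in the presence of directional
pleiotropy, whose average the intercept estimates. SEs use the
residual scale floored at 1; inference uses t with k−2 df. The fit is
invariant to how alleles were originally oriented because of the b̂ₓ>0
normalization.

**Weighted median.** Ratio estimates are ordered; weights proportional
to inverse ratio variance are cumulated with the midpoint convention
(cumulative weight minus half the own weight, normalized), and the
estimate interpolates linearly at cumulative weight 0.5 — the standard
formulation. It is consistent whenever valid instruments carry more
than half the total weight. Exact invariance to duplicating SNPs holds
when the median lands on a data point; between data points the
interpolated value carries a finite-sample term of the order of the
per-SNP ratio SE. SEs come from a parametric bootstrap (b̂ₓ, b̂ᵧ
resampled from their SEs; default 1000 draws; the seed is a mandatory
argument — there is no hidden global RNG).

**Modes.** The ratio estimates are smoothed with a normal kernel whose
bandwidth is φ times a MAD-robust Silverman rule
(0.9·min(sd, MAD)·k^(−1/5), φ = 1 by default); the estimate is the
density argmax on a 512-point grid spanning the ratios ±3 bandwidths.
The weighted variant weights kernels by inverse ratio variance; the
simple variant uses unit weights. Consistent under ZEMPA (the largest
cluster of ratios is the valid one). Bootstrap SEs as above.

**MR-RAPS.** Solves the profile-score equation
Σⱼ ρ′(tⱼ)·∂tⱼ/∂β = 0 with standardized residuals
tⱼ = (b̂ᵧⱼ − β·b̂ₓⱼ)/√(sᵧⱼ² + β²sₓⱼ² + τ²). Modelling sₓ removes the
regression-dilution bias that attenuates IVW when instruments are weak;
τ² (estimated jointly when overdispersion is on, via
Σ(ρ′(tⱼ)tⱼ − δ)/(sᵧⱼ²+β²sₓⱼ²+τ²) = 0 with δ = E[ρ′(Z)Z]) absorbs
systematic pleiotropy; the Huber ρ (k = 1.345, the default together
with overdispersion) bounds the influence of outliers. Because the
score vanishes in both tails of β (spurious stationary points of the
profile likelihood), the root is found by bounded minimization of the
integrated loss around the IVW start, polished by a local bracketed
root solve; the SE is the M-estimation sandwich. With the l2 loss,
τ² = 0 and sₓ → 0, RAPS reduces exactly to fixed-effect IVW (a tested
identity).

**Heterogeneity and influence.** Cochran's Q over the Wald ratios with
first-order weights (df = k−1) flags pleiotropy-like dispersion; it
requires ≥ 2 instruments. Leave-one-out re-runs IVW with each SNP
omitted. Egger/median/modes/RAPS/leave-one-out require ≥ 3 instruments;
below these thresholds a first-class *not-computed* marker is returned
rather than an exception, because a 2-instrument exposure is a normal,
reportable situation, not an error.

Ratio SEs use the first-order delta method sᵧ/|b̂ₓ| throughout; the
second-order term b̂ᵧ²sₓ²/b̂ₓ⁴ is available by flag.

## Harmonization and clumping

Outcome records are aligned to the exposure's effect allele: identical
allele pairs pass through, swapped pairs flip the sign of b̂ᵧ and
complement the EAF, and complementary-strand labels are resolved for
non-palindromic SNPs. Palindromic (A/T, G/C) variants cannot be
resolved from alleles alone; the default policy retains one only when
both EAFs are present, both lie outside 0.5 ± 0.08, and they agree on
the minor allele — frequencies on opposite sides of 0.5 indicate a
strand flip, which is then corrected. With a missing exposure EAF a
palindromic SNP is dropped; a non-palindromic one harmonizes by allele
identity alone. Every input SNP ends up either retained or in the
exclusion list with a reason (missing_in_outcome, allele_mismatch,
palindromic), an accounting identity the tests enforce.

Clumping is greedy: among records passing the p-value threshold, the
smallest-p SNP (ties broken by chromosome, position, id) indexes a
clump and prunes every same-chromosome SNP within the window (closed
interval, 1-based coordinates) at r² ≥ threshold. Cross-chromosome
pairs are never pruned. Every call re-verifies post hoc that no
retained within-window pair reaches the threshold. The LD matrix is
user-supplied (or synthetic); no reference panel is bundled.

## Meta-analysis and genomic control

Per-SNP cross-cohort pooling uses inverse-variance weights; the
random-effects model adds the DerSimonian–Laird
τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)). Genomic control estimates
λ = median(z²)/median(χ²₁) per cohort and inflates that cohort's SEs by
√λ, floored at 1 (inflation only), applied once on the input side
before pooling. Between-cohort Q with k−1 df accompanies every pooled
SNP. Random-effects SE ≥ fixed SE and fixed pooled SE ≤ the smallest
cohort SE, by construction and by test.

## Instrument strength and power

R² = 2·MAF(1−MAF)·β² per SNP (β in SD units; frequencies above 0.5 are
folded), summed over a clumped set — the sum is only meaningful for
independent SNPs, which is why diagnostics expect clumped input.
F = R²(N−2)/(1−R²). Binary-outcome power uses the two-sided normal
approximation with non-centrality λ = |log OR|·√(N·R²·K(1−K)), K the
case fraction; it equals α at OR = 1 and is invariant under
OR ↔ 1/OR. Inclusion rules: drop SNPs with F < 10; an exposure is
analysis-eligible when set R² > 1% and/or best power > 50%.

## The synthetic generator

`simulate_two_sample` draws MAFs uniformly, scales raw normal effects
so Σ 2pⱼ(1−pⱼ)γⱼ² equals the requested variance explained exactly, and
emits summary statistics directly with the standard asymptotic
variances: Var(b̂ₓ) = 1/(2p(1−p)·Nₓ) for the standardized exposure and
Var(b̂ᵧ) = 1/(2p(1−p)·N·K(1−K)) for the case-control outcome — the
logistic-regression asymptotics, consistent with the power formula
above and equal to 4/(2p(1−p)·n_eff) with n_eff = 4/(1/cases +
1/controls). Invalid instruments receive αⱼ ~ N(mean, sd²), optionally
correlated with γⱼ (an InSIDE violation with configurable slope).
Optional strand-flip and palindromic-variant injection exercises the
harmonizer. All randomness flows from one seed through spawned child
generators, so tables are bit-reproducible; `simulate_study` builds a
whole exposures × outcomes grid with per-pair causal effects on the
same principle. Default cohort sizes mirror a two-biobank
gastrointestinal-infection setting (8,991/399,970 and 25,968/234,437
cases/controls); the default exposure is a micronutrient-like trait
instrumented by a handful of genome-wide-significant SNPs.

What the generator does *not* emulate: LD between instruments beyond
the AR(1) block used for clumping tests (effects are drawn
independently), population stratification, sample overlap between the
two samples, winner's-curse selection of instruments, and SAIGE-style
saddlepoint corrections for extreme case-control imbalance (the normal
asymptotics stand in for them). Passing recovery tests therefore shows
the estimators and pipeline are correct under the stated sampling
model, not that real-data biases of those excluded kinds are handled.

## Study conditions used by the verification battery

* **Calibration** (IVW type-I error, Q ~ χ²): null studies (θ = 0) with
  valid instruments at 2,000 and 5,000 replicates. Q calibration is
  checked at θ = 0 because the first-order ratio SEs deliberately
  ignore the exposure-side term; at θ ≠ 0 that term inflates Q by
  ~θ²·(outcome precision)/(exposure precision), visible to a 5,000-rep
  KS test but immaterial at study scale.
* **Recovery at study scale**: 2 instruments, set R² = 4.36%, exposure
  N = 2,603, outcome counts 34,959/634,407 — the copper-like
  configuration; the median fixed-IVW estimate over 500 replicates
  recovers OR 0.91 to within 0.01 on the log scale.
* **Grid flagging**: 100 replicate 8×3 studies, one causal pair at
  OR 0.91, IVW only, 20 SNPs per exposure with set R² = 15% at
  exposure N = 10,000 (a deliberately strong-instrument condition:
  after the two conservative layers — DerSimonian–Laird per-SNP meta
  and multiplicative-random IVW — copper-strength instruments would
  have only ~2/3 power at the corrected threshold). Genomic control is
  off in these studies: the generator has no stratification, and λ
  estimated from an instruments-only table containing true effects
  would spuriously inflate SEs.
* **Robustness**: the invalid-instrument and directional-pleiotropy
  scenarios are constructed with instruments oriented to the
  exposure-increasing allele, because a direct effect that is constant
  per effect allele cancels on the ratio scale when allele signs are
  random; the weighted-median consistency check uses per-SNP ratio SEs
  ≈ 0.009 so its O(se) finite-sample quantile term sits well inside
  the 0.02 bias bound the claim refers to.

## Numerical choices and edge cases

* Ties, degenerate inputs: clumping ties broken lexicographically;
  b̂ₓ = 0 raises an undefined-ratio error; empty exposure/outcome
  overlap raises an error carrying both table sizes; a single cohort
  passed to the meta-analysis passes through with a warning.
* The bootstrap guards against resampled b̂ₓ = 0 by nudging to the
  smallest positive float.
* MVMR drops an exposure whose effect column is identically zero
  (reported as not computed) so the remaining fit reduces to the
  nested model; genuinely collinear non-zero columns raise a
  collinearity error naming the worst pair. Conditional instrument
  strength per exposure is a Sanderson–Windmeijer-style statistic
  (precision-weighted residual variation of its effects regressed on
  the other exposures', per spare instrument), reported as a
  diagnostic only.
* File dialect: tab-delimited UTF-8, '.' decimals, missing as empty or
  NA; floats are written with `repr` so write→read→write is
  byte-identical.

## Known limitations

* First-order ratio SEs understate uncertainty for very weak
  instruments (use RAPS there; the second-order flag is available).
* The DerSimonian–Laird τ² is noisy with two cohorts — an inherent
  limitation of k = 2 random-effects meta-analysis, inherited by any
  pipeline built on it.
* The binary-outcome power formula assumes a standardized exposure and
  normal test statistics; rare-outcome saddlepoint effects are out of
  scope.
* Proxy-SNP substitution is supported only through a pre-supplied
  subset/exclusion configuration, not LD lookups; no reference LD
  panel ships with the package.
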