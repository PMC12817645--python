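# Methods

This note records the statistical methods implemented in `mrmediate`, the
default parameter choices, and the known limits of each component. Symbols:
for SNP j, βX_j and βY_j are the per-allele effects on exposure and outcome
with standard errors sx_j and sy_j; k is the number of instruments.

## Harmonization

Exposure and outcome tables are merged on rsid and placed on the exposure's
effect-allele frame. Identical allele pairs are kept; swapped pairs
(directly or through the strand complement A↔T, C↔G) negate the outcome
beta and complement its allele frequency. Palindromic variants (A/T, C/G)
cannot be resolved from alleles alone: they are retained only when both
aligned frequencies fall outside 0.5 ± w on the same side of 0.5 (default
w = 0.08; w ≥ 0.5 excludes every palindrome). After alignment, pairs whose
frequencies differ by more than 0.2 are excluded as probable different
variants. Every row carries an `action_taken` label, and the five actions
partition the merged set, so the bookkeeping is auditable.

## Instrument selection

Three stages: association (p < 1e-5 by default, the relaxed threshold used
when genome-wide-significant hits are scarce for molecular traits), greedy
LD clumping (keep the lowest-p SNP, remove same-chromosome neighbours
within 10,000 kb with r² ≥ 0.001; p-ties broken by rsid so results do not
depend on row order), and a weak-instrument filter. Per-SNP variance
explained is

    R² = 2 β² EAF(1−EAF) / (2 N EAF(1−EAF) SE²),

whose frequency factors cancel to β²/(N·SE²) — the frequency-free form is
the fallback when EAF is unreported. F = R²(N−2)/(1−R²); instruments with
F ≤ 10 are dropped. R² ≥ 1 indicates internally inconsistent summary
statistics and is a hard error rather than a silent clip.

## Estimators

All estimators pool per-SNP Wald ratios r_j = βY_j/βX_j (first-order
se sy_j/|βX_j|; a second-order form adding βY²sx²/βX⁴ is available).

- **IVW**: weighted regression of βY on βX through the origin with weights
  1/sy². The default multiplicative random-effects model scales the
  fixed-effect SE by max(1, √(Q/(k−1))), so heterogeneity can widen but
  never narrow the interval. With one SNP the estimate downgrades to the
  Wald ratio and says so.
- **MR-Egger**: the same regression with a free intercept, fitted after
  orienting every SNP to βX ≥ 0 (the intercept is only interpretable on
  that frame). The intercept estimates average directional pleiotropy; its
  test and the slope test use a t reference with k−2 degrees of freedom and
  multiplicative over-dispersion bounded below at 1.
- **Weighted median**: the weight-0.5 quantile of the ratio distribution
  (midpoint-interpolated), consistent while valid instruments carry more
  than half the total weight. SE by parametric bootstrap.
- **Mode estimators**: argmax of a normal-kernel density of the ratios
  (inverse-variance weights for the weighted variant), bandwidth by the
  modified Silverman rule 0.9·min(sd, 1.4826·MAD)·k^(−1/5) on a 2048-point
  grid; consistent when the largest homogeneous instrument group is valid.
  SE by parametric bootstrap.
- **BWMR** (`mrmediate.bwmr`): hierarchical model βX_j ~ N(γ_j, sx_j²),
  βY_j ~ N(θγ_j + α_j, sy_j²) with α_j ~ N(0, τ²) marginalized into the
  outcome variance, priors θ ~ N(0,10²), γ_j ~ N(0,1), τ ~ half-normal(0.25).
  Inference is Metropolis-within-Gibbs (conjugate updates for γ and θ,
  random-walk Metropolis on log τ) — a sampling approximation to the
  variational scheme the method family is usually fitted with. Per-SNP
  Huber-style robustness weights ((2.5/|r|)² beyond 2.5 standardized
  residuals) are refreshed during burn-in, then frozen so the chains target
  a fixed posterior. Two chains; split-chain R̂ > 1.1 flags, never
  suppresses, the result. On clean data BWMR agrees with IVW to a fraction
  of a standard error and τ concentrates near zero.

The battery runner reports whether all five point estimates share one sign
(`direction_concordant`); an incomplete battery is reported as discordant
with the reason, not silently passed.

## Sensitivity diagnostics

- **Cochran's Q** about the fixed-effects IVW estimate (which minimizes Q),
  χ²(k−1) reference.
- **Egger intercept test** as above.
- **MR-PRESSO-style analysis**: observed RSS uses leave-one-out IVW slopes
  (closed form, O(k)); the null distribution comes from parametric draws
  βX* ~ N(βX, sx), βY* ~ N(θ₋ⱼβX, sy) with the leave-one-out slopes
  recomputed per draw. Empirical p-values use the add-one rule
  (1+#)/(n_sim+1); per-SNP outlier tests are Bonferroni-corrected; a
  distortion test compares the outlier-free estimate with equal-sized
  random removals. Requires ≥ 4 SNPs.
- **Leave-one-out IVW** and deterministic scatter/funnel/forest/loo plot
  tables (image rendering is an optional thin layer).

## Two-step mediation

The indirect effect of X on Y through M is β1·β2 with β1 = X→M and
β2 = M→Y, each an IVW estimate from its own instrument-selection and
harmonization chain. The delta-method SE is √(β1²se2² + β2²se1²) with zero
cross-covariance (the legs use separate two-sample estimations); validation
shows it within a fraction of a percent of a 10⁵-draw Monte-Carlo SD when
both legs have |β|/se > 2. The proportion mediated indirect/total is
reported signed and unclamped — published mediation tables contain
sign-inconsistent pathways, and clipping would misrepresent them — with a
flag for sign consistency; it is absent when the total effect is exactly
zero. direct + indirect = total holds exactly by construction.

**Mediator-leg instrument filtering.** Variants associated with the
exposure (exposure p below the instrument threshold) are removed from the
mediator's candidate instruments before the M→Y leg. An exposure-driven
variant reaches the outcome through the direct X→Y path as well as through
M, which enters the M→Y regression as correlated pleiotropy and biases β2
toward β2 + direct/β1; only the mediator's own instruments identify β2.
Simulation confirms the point: without the filter the mediator leg shows
extreme heterogeneity (Q p-values < 1e-30) and the screening gates reject
it; with the filter, indirect-effect coverage of the 2-SE interval is ≈ 95%.

## Screening pipeline

A pair passes the screen when IVW p < 0.05, all five methods agree in
direction, the Egger intercept p > 0.05 and the PRESSO global p > 0.05
(thresholds configurable). Cochran's Q and a reverse-direction IVW p are
recorded but never gate. Because the rule stacks several 5%-level
diagnostics, a perfectly valid pair fails ≈ 10% of the time by
construction — the tests treat pass rates, not single runs, as the
contract. Surviving exposure/mediator pairs feed the mediation table, which
carries an optional Benjamini–Hochberg FDR column across pathways. All
outputs (mediation table, per-pair decisions with reasons, harmonized sets,
estimator tables, run manifest) are byte-stable given identical inputs,
configuration and seed.

## Synthetic data generator

Summary statistics are simulated directly — no individual-level genotypes.
For a standardized trait in N individuals, the sampling SE at minor allele
frequency p is 1/√(2Np(1−p)). Defaults mirror the study sizes that
motivated the design: exposure N = 7,174; mediator N = 3,757; outcome
N = 254,618 with SEs inflated ×2.8 ≈ 1/√(φ(1−φ)) for a case/control design
at case fraction ≈ 0.15. True instrument effects are Laplace-distributed
(sparse architecture: many small, few large effects; spread 0.35 for the
exposure, 0.5 for the mediator's own instruments), capped so no variant
implies R² ≥ 1. The causal structure is

    βX_j = γ_j,   βM_j = α·γ_j + δ_j,   βY_j = θ_direct·γ_j + b·βM_j + α_j

with mediator-specific instruments δ_j (γ = 0) — without them the M→Y leg
is not identifiable, because every exposure-driven variant proxies the
direct path. Horizontal pleiotropy α_j ~ N(μ, sd²) hits a configurable
invalid fraction; μ > 0 ("directional") is applied relative to the
exposure-raising allele, i.e. multiplied by sign(γ_j) — on the raw allele
frame the orientation step of MR-Egger would otherwise cancel a constant
mean to zero. α is independent of γ, so the InSIDE condition holds.
Realism knobs: palindromic allele pairs, allele-swapped rows that
harmonization must undo, 10-SE outcome outliers planted on the strongest
instruments, block-diagonal LD, and per-stream seeding
(`SeedSequence.spawn`) so changing one knob leaves the other draws intact.

Known limits: instrument discovery and effect estimation happen in the same
simulated sample (no discovery/replication split), so selected effects
carry mild winner's curse — visible as a modestly inflated Egger-intercept
rate (~15% at the 5% level) on the small-N mediator leg. The directional
pleiotropy preset uses a 50% invalid fraction, which deliberately violates
the weighted median's valid-weight-majority premise; its low coverage there
is a property of the estimator, reported as-is.

## Validation summary

`tests/test_acceptance.py` and `scripts/acceptance.py` check: published
odds ratios reproduced from log-odds at 3 decimals (5 of 6 reference rows;
the sixth is a documented rounding slip in the source); fixed-effects IVW
equal to the inverse-variance-weighted ratio mean; Q and delta-SE hand
arithmetic; IVW and null-mediation type-I error within [0.02, 0.08] at 200
replicates; recovery of total 0.30 and indirect 0.20 within 2 SE in ≥ 90%
of 100 replicates; weighted-median robustness at 40% invalid weight; Egger
intercept power ≥ 80% under directional pleiotropy; PRESSO detection of a
10-SE outlier; delta vs Monte-Carlo SE within 5%; and byte-identical
pipeline outputs under identical seeds.
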