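# Methods

This note records the models implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic studies do and
do not establish about behaviour on real data.

## Generative model (simulate)

The synthetic study is built to match the regression equations the
estimators assume, so that every recovery test has a well-defined truth.

**LD.** The reference panel is block-diagonal: `n_blocks` blocks of
`snps_per_block` SNPs with AR(1) correlation r_jk = ρ_b^|j−k| inside block
b and zero between blocks. By default each block's ρ_b is drawn uniformly
from (0.0, 0.9). The range matters: with a single ρ shared by all blocks,
every interior SNP has the same LD score and the LD-score regression
degenerates (slope and intercept become confounded); drawing ρ_b per block
gives ℓ_j genuine spread (≈1–10), which is the variation the regression
identifies its slope from. Passing a scalar `rho_ld` reproduces the
constant-ρ construction, which is useful for closed-form checks
(ρ = 0.9, 3 SNPs ⇒ middle ℓ = 1 + 2·0.81 = 2.62). AR(1) blocks are
guaranteed positive definite and have closed-form LD scores. Blocks are
laid out round-robin over chromosomes 1–22, 2 Mb apart, SNPs 5 kb apart;
MAF is uniform on (0.05, 0.5).

**Effects.** SNP j is causal with probability `pi_causal` (default 0.05).
For causal SNPs, standardized effects are drawn as a shared component
f_j ~ N(0, var_factor·c_j) and trait-specific components
u_ij ~ N(0, var_unique_i·c_j), with β_1j = f_j + u_1j and
β_2j = s·f_j + u_2j (s = ±1 sets the sign of the genetic covariance). The
scale factors c_j ∝ (2p_jq_j)^S are normalized to sum to 1 over the causal
set, so E[h²_i] = var_factor + var_unique_i exactly and the exponent S
couples effect-size variance to MAF without changing total heritability
(S = 0: no coupling; S = −1: rare alleles carry larger effects, the
signature of negative selection).

**Summary statistics.** Per block, marginal standardized effects are
b = Rβ and z_i = √N_i·b_i + ε_i with ε ~ N(0, R) and cross-trait noise
covariance ρ_ov·R, ρ_ov = (phenotypic correlation in the overlap) ×
n_overlap/√(N₁N₂) — exactly the LDSC sample-overlap intercept. The unit
marginal noise matches how real GWAS z-scores behave (each marginal
regression's residual variance is ≈ the full phenotypic variance). Binary
traits are simulated directly on this observed 0/1-regression scale;
prevalences enter only through the liability conversion and effective-N
bookkeeping, which keeps the generative model exactly aligned with the
LDSC equations rather than introducing a threshold-model mismatch.

**Defaults.** The default configuration emulates the motivating cohorts at
desk scale: M = 20,000 SNPs (400 blocks × 50), sample sizes 606,825 and
1,138,870 with 363,287 shared participants at phenotypic correlation 0.04
(impairment-aligned), sample prevalences 0.085/0.045, population
prevalences 0.048/0.050, per-trait h² = 0.15 with var_factor = 0.042
(genetic correlation 0.28), S = −0.5. One caveat follows from the scale:
with N ≫ M the LDSC intercept is unidentifiable (the slope term N·h²/M
reaches ~4.5 per unit ℓ and its realization noise swamps the intercept),
so analyses that rely on intercepts are run at N = 50,000 per trait — the
problem size used throughout the test suite and the acceptance script —
with the overlap fraction preserved.

## LD score regression (ldsc)

- Regressions: χ² on ℓ (univariate), z₁z₂ on ℓ (cross). Weights
  1/(ℓ·(1 + N·h²·ℓ/M)²) with h² iterated twice from an unweighted pass;
  cross weights use the product of the two traits' variance factors built
  from the same penultimate h² values the univariate fits used, which
  makes fit_rg(a, a) equal fit_h2(a) exactly.
- M is the number of regression SNPs (the reference implementation uses
  the reference-panel SNP count; at desk scale the two coincide).
- SEs and the 3×3 sampling covariance V of (S₁₁, S₁₂, S₂₂) come from a
  delete-one jackknife over 200 contiguous SNP blocks (configurable),
  shared across the three regressions so V's off-diagonals are honest.
- Liability conversion: h²_liab = h²_obs·K²(1−K)²/(P(1−P)·z²) with z the
  standard-normal density at the K-threshold; for K = P = 0.5 the
  multiplier is π/2 exactly, a useful closed-form check.
- Stratified model: E[χ²_j] = intercept + N·Σ_c τ_c·ℓ(j,c). The intercept
  is left free (standard practice; on confounding-free synthetic data it
  sits at 1, and leaving it free is robust when it does not). Collinear
  annotation columns are excluded from the fit, but heritability shares
  and enrichment are reported for every annotation from the implied
  per-SNP h², so a base + genome-partition input yields partition shares
  that sum to 1 exactly. Enrichment p-values test enrichment ≠ 1 via the
  jackknife; the base row's p is undefined by construction.

Estimator variance at M = 20,000–50,000 is an order of magnitude larger
than at biobank SNP counts; tests therefore compare estimates to truth in
units of their own jackknife SEs, and one recovery check pools three
seeded replicates by inverse variance (same 2-SE criterion, tighter
absolute tolerance, no dependence on a single draw).

## Common-factor mvGWAS (gsem)

The measurement model fixes both loadings to 1, so on a standardized S the
factor variance equals the genetic correlation and the model is
just-identified (fit residual 0); the reported SE of var_F is the
delta-method/sandwich SE under V.

Per SNP, the CPM is a one-parameter GLS fit of (g₁, g₂) on (σ², σ²)' with
error covariance [[v₁₁, v₁₂],[v₁₂, v₂₂]], where g = β·2pq, v = (se·2pq)²
and v₁₂ = ρ_int·se₁·se₂·(2pq)² uses the LDSC cross-trait intercept,
constant across SNPs (an approximation to the reference implementation's
full per-SNP V expansion). χ²_CPM is the GLS residual quadratic form —
equal, algebraically, to Q_b = (g₁−g₂)²/(v₁₁+v₂₂−2v₁₂) since the IPM is
saturated; the equality is verified against both the closed form and a
numeric GLS minimization. Design choices:

- The per-SNP χ² is the naive GLS quadratic form, not a sandwich
  statistic: exact, closed-form, and testable.
- Inputs must be flipped to a common risk direction first; the API
  enforces this with a required `effects_aligned` flag (the factor of a
  sign-discordant pair is not meaningful).
- ρ_int estimates a correlation of estimation noise and is clamped to
  ±0.99 if a noisy desk-scale estimate exceeds 1 in magnitude.
- Q_b is not GC-corrected by default; a flag exists.
- Q_b calibration is sensitive to the overlap term: the null-calibration
  check supplies ρ_ov at its generative value, because a desk-scale
  intercept estimate (SE ≈ 0.1 under a polygenic architecture at
  M = 20,000) shifts the Q_b p<0.05 rate by roughly ±1 percentage point.
  At real-data SNP counts the intercept SE is ~0.01 and the distinction
  disappears.
- The factor summary statistics carry the expected N implied by the
  factor SEs, median of 1/(se²·2pq).

## Cross-method statistics (meta)

S_hom is implemented as the correlated fixed-effects form
(w'R⁻¹z)²/(w'R⁻¹w) with w = √(median N) per trait and R the z-correlation
over SNPs null in both traits (|z| ≤ 1.96). Two properties worth knowing:
with R = CTI = I and equal weights, S_hom equals the squared N-weighted
meta z exactly; and the null-SNP truncation attenuates R's off-diagonal
below the true overlap correlation (a bivariate normal truncated at
±1.96 on both margins has correlation ≈ 0.83ρ at ρ = 0.4) — the tests
compare against the truncated-normal oracle, not ρ itself. √N rather than
N weighting was chosen; the two differ only in relative trait weighting.

## Correlation utilities (corr)

Block Spearman: mean −log₁₀(p) per LD block, Spearman over blocks, SE from
resampling blocks with replacement (pairs resampled jointly; 10,000
cycles). BH-FDR takes an explicit family size m ≥ len(p) so a subset of a
larger test family can be corrected at the family's denominator. Trait
clustering: traits entering at |r_g| > 0.80; distance d = 1 − r_g (signed,
so anticorrelated traits are distant — a deliberate choice, as a factor
representative should not stand in for its anticorrelated partner); Ward
linkage; k by the maximal second difference of the within-cluster sum of
squares (deterministic elbow); the representative is the member most
correlated in absolute value with its cluster's first principal component,
ties broken by name order.

## TWAS (twas)

Z_g = Σ w_l(σ_l/σ_g)z_l with σ_g² = w'Σw over the block-diagonal panel
covariance. Weight alleles are aligned to the summary-statistics effect
allele (weights negated on swap; mismatches dropped). Weight SNPs missing
from the data drop out with σ_g renormalized over the survivors; coverage
below 50% flags the gene. The 17q21.31 inversion filter defaults to
chr17:43.5–45.0 Mb (GRCh37), configurable; intervals are half-open at the
end internally, so a SNP at end+1 bp survives.

## Negative-selection estimator (sbayess)

The likelihood is the summary-data regression form
bhat | β ~ N(Rβ, σ²_e·R/N) with the residual parameter σ²_e defined on
the *marginal* scale — √N(bhat − Rβ) ~ N(0, σ²_e·R), so σ²_e ≈ 1 for
standard GWAS z-scores — and updated from the R⁻¹ quadratic form of the
residual with M degrees of freedom. (Tying σ²_e to the joint-model
1 − h² instead biases h² upward by ~30% on data generated under the
LDSC convention; the marginal definition matches the data actually fed
in.) Priors/updates: spike-and-slab single-site Gibbs for β;
π ~ Beta(1+m, 1+M−m); σ²_β scaled-inverse-χ² with ν₀ = 4 and scale 1/M;
S by random-walk Metropolis with a N(0,1) prior, proposal SD adapted
during burn-in toward ~0.3 acceptance (warning outside [0.1, 0.6]).
Reported h² is the posterior of β'Rβ. Defaults 5,000 iterations / 1,000
burn-in; recovery runs in the suite use 2,000/500, which at M = 20,000
gives posterior SDs for S of ~0.1–0.15. Chains are bitwise reproducible
for a fixed seed on a given platform (numba's internal RNG).

Limitation inherited from the model class: the likelihood requires the
summary statistics to be LD-consistent with the panel. Permuted or
mismatched z-scores are LD-incoherent and get absorbed into β (inflating
h²) rather than into noise; the null behaviour check therefore uses an
LD-consistent null simulation, where the estimator correctly reports
h² < 0.02.

## Degenerate inputs and tie-breaks

Singular per-SNP sampling covariance (|v₁₂| → √(v₁₁v₂₂)) ⇒ SNP skipped
with a logged count; p-values are floored at the smallest positive float
so extreme z never yields p = 0; constant vectors are fatal for Spearman;
all-zero weight vectors are rejected at weight-table construction;
empty locus sets are valid results, an empty SNP intersection is fatal.
Locus ties (equal p) resolve to the first by genomic order.

## What the synthetic study does not show

The generator matches the estimators' assumptions by construction:
block-diagonal AR(1) LD (no long-range LD, no MHC-like pathology), exact
panel/sumstats LD agreement, Gaussian effect sizes, within-study-constant
N, no population stratification or confounding (LDSC intercepts truly 1),
and binary traits on the observed scale without a liability threshold
process. Passing tests therefore demonstrate correctness of the
estimators under their own model, calibration of the null distributions,
and internal consistency across methods — not robustness to LD mismatch,
stratification, or the scale subtleties of real case-control data.
Real-data quantities reported in the motivating study (r_g, locus counts,
enrichment magnitudes, Ŝ) depend on access-restricted cohorts and are not
reproduction targets at desk scale.
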