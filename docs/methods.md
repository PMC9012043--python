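# Methods

## Model

Absolute abundances are assumed log-linear in the covariates: for taxon
`i = 1..m` and sample `s = 1..n`,

    log X_is = u_s α_i + (1, c_s') β_i + ε_is ,

with a single covariate of interest `u` (binary 0/1 or continuous), `d`
numeric adjustment covariates, and independent errors. Reads are a
multinomial draw of the relative abundances with total `N_s`, so only
ratios are observable. After the CLR transform the working model is

    W_is = u_s (α_i − ᾱ) + (1, c_s')(β_i − β̄) + (ε_is − ε̄_s) ,

where the multinomial estimation error is absorbed into the residual. The
per-taxon OLS coefficient of `u` therefore estimates `α_i − ᾱ`: every
taxon's effect carries the same compositional shift `−ᾱ`.

## Estimation and testing

- **Design.** `Z` has columns `(u, 1, c_1..c_d)` in that order; the design
  scalar `ρ̂` is the (1,1) element of `(Z'Z/n)⁻¹` and the residual degrees
  of freedom are `n − d − 2`. One SVD-based least-squares solve is shared
  by all taxa. Residual variances use the divisor `n − d − 2`.
- **Bias correction.** The compositional shift is estimated as the argmax
  of a Gaussian KDE of `{√n α̃_i}`: `α̂_i = α̃_i − mode/√n`. The bandwidth
  defaults to Silverman's rule on the scaled coefficients (user-overridable
  via `RunConfig.bandwidth`); the density is maximized on a 1024-point grid
  spanning `[min − 3h, max + 3h]` with ties broken toward the candidate of
  smallest absolute value (consistent with the mode-at-zero sparsity
  assumption) and the winning cell refined by bounded scalar optimization.
  The estimator is deterministic, shift-equivariant (adding a constant to
  all raw coefficients leaves `α̂` unchanged up to the refinement
  tolerance, about 1e-8 in practice), and sign-equivariant.
- **Testing.** `T_i = √n α̂_i / √(ρ̂ σ̂_i²)`, `p_i = 2 F_{n−d−2}(−|T_i|)`,
  BH adjustment, rejection at `padj ≤ q` (the `≤` convention). Taxa with
  zero residual variance are flagged and assigned `p = 0` with a warning.
- The closed-form conditional covariance of the `α̃_i` (diagonal
  `ρ̂ n⁻¹ m⁻¹ {(m−2)σ_i² + m⁻¹Σσ²}`, off-diagonal
  `ρ̂ n⁻¹ m⁻¹ {−(σ_i²+σ_j²) + m⁻¹Σσ²}`) is implemented for diagnostics and
  is verified against Monte-Carlo covariance in the test suite.

## Preprocessing

- **Filtering** (defaults `min_lib = 1000`, `min_prev = 0.10`): samples
  with fewer than 1000 reads are dropped first, then taxa present in fewer
  than 10% of the *remaining* samples, so prevalence refers to analyzable
  samples. Filtered taxa stay in the output with NA statistics for
  auditability. The filter is a single pass; in pathological tables where
  dropping rare taxa pushes a sample's recomputed library size below the
  threshold, a second application could differ.
- **Winsorization** (off by default, `q = 0.97` when enabled) caps
  per-taxon proportions above their empirical `q`-quantile
  (linear-interpolation quantile) and reconstructs counts by rounding. It
  is applied before zero handling, on the raw proportions.
- **Zero handling.** `pseudo` adds 0.5 to every count; `imputation`
  replaces a zero for taxon `i` in sample `s` by
  `N_s / max{N_k : Y_ik = 0}` so imputed values are proportional to
  library size and the largest-library zero gets exactly 1; `adaptive`
  (default) regresses `log N_s` on `u` by OLS and chooses imputation when
  the two-sided slope p-value is strictly below 0.1, else the pseudo-count.
  The log scale stabilizes the heavy-tailed library sizes; for binary `u`
  the test reduces to a two-sample t-test. A table with no zeros passes
  through untouched — this keeps the pipeline exactly invariant to
  rescaling any sample's counts, which a blanket pseudo-count would break.

## Mixed-effects variant

For paired, replicate, or longitudinal designs each taxon is fit by REML
with the same fixed design plus a random intercept per subject
(random slopes and crossed effects are out of scope). The covariance
`V = σ²(I + λ ZZ')` with `λ = τ²/σ²` has a closed-form block inverse, so
the REML deviance is profiled down to a one-dimensional search over `λ`
(log-scale bounded minimization plus an explicit check of the `λ = 0`
boundary), giving deterministic fits at a few milliseconds per thousand
taxa. Degrees of freedom use the Satterthwaite approximation,
`df = 2 g² / (∇g' I⁻¹ ∇g)` with `g = var(α̂)` and `I` the expected REML
information in `(σ², τ²)`; singular cases fall back to
`n − rank(fixed design) − 1`. The identical mode-based correction is
applied to the `√n`-scaled converged estimates, `T = α̂/se`, and p-values
use each taxon's own df. With one sample per subject the variance split is
unidentifiable and the fit provably collapses to OLS (a warning is
emitted). The solver is cross-checked against an independent
general-purpose REML implementation in the test suite.

## Synthetic-data generator

The generator reproduces a family of study conditions with ground truth:

- Baseline (S0): `log X⁰_is ~ N(β_i⁰, σ_i²)`, differential labels
  `Bernoulli(γ)` with `γ ∈ {0.05, 0.20}` typical, library sizes
  `NB(mean 7645, size 5.3)`, counts multinomial. Defaults `m = 500`,
  `n = 200`.
- Effects: six-point grid `μ ∈ [1.05, 2]`; differential taxa get
  `α = log(fμ)` when their mean baseline proportion exceeds 0.005 and
  `α = log(fμ (0.005/π̄)^{1/3})` otherwise, with `f = 2` for `n ≤ 50` and
  `f = 1` for larger samples — low-abundance taxa are up-weighted so power
  is not dominated by abundant ones. All effects share one sign by default
  (a deliberately strong compositional effect); a flag flips the sign.
- Designs: binary `u` (C0), standard normal `u` (C1), or binary `u`
  confounded by a Rademacher and a normal covariate through a logistic
  link with per-taxon confounder coefficients `N((1,2)', I)` (C2).
- Variants: zero-inflated abundances (S1, 30% of entries forced to zero),
  block-correlated log-abundance noise (S2: blocks of 20 split into two
  sub-blocks of 10; +0.5 within, −0.5 between; positive definite by
  construction), gamma abundances (S3, shapes
  `η_i = π_i⁰(1/θ⁰ − 1)`, `θ⁰ = 0.003`), small feature size (S4: m = 50,
  NB(1500, 5.3) libraries), very small n (S5, small-sample effect
  formula), 10-fold library-size difference between groups (S6:
  NB(5000, 5.3) vs NB(50000, 5.3)), negative-binomial counts (S7), and
  subject-level random intercepts `τ_i² = a_i σ_i²`, `a_i ~ U(0,1)`, with
  paired pre/post samples (S8.1) or replicate samples with subject-level
  `u` (S8.2: 2 replicates per subject for `n ≤ 50`, else 4).
- Baseline parameters are a documented synthetic stand-in:
  `β_i⁰ ~ N(0, 3²)`, `σ_i ~ U(0.5, 2)`, chosen so the baseline count
  matrix is 65–75% zeros, typical of species-level tables (the test suite
  asserts a wide 55–85% band); S3/S7 shape and dispersion stand-ins derive
  from the softmax of `β⁰` as documented in `gen_baseline`. Users can
  inject explicit parameter vectors instead.

What the generator does *not* emulate: taxonomic structure, phylogenetic
correlation, real-data zero patterns beyond the S1 mechanism, batch
effects, or effect-size distributions estimated from a particular cohort.
Passing tests therefore demonstrate correctness of the estimator under the
stated generative models, not performance guarantees on any given real
dataset.

## Evaluation protocol

Per run, `FDP = FP / max(R, 1)` and `TPR = TP / max(#differential, 1)`
with the number of truly differential taxa taken from the realized dataset
(labels are random per run). Replicates are aggregated as means with
normal-approximation 95% CIs; 100 runs is the default. The acceptance
script reports the 100-run mean FDP of the baseline scenario, which sits
at the nominal 0.05 level (0.047–0.057 across seeds in our runs, always
within Monte-Carlo error of nominal).

## Numerical and design choices

- Rank deficiency in the design is detected by a machine-epsilon-scaled
  singular-value cutoff and reported with the offending column names.
- Only one covariate of interest per run; testing several variables means
  separate runs.
- Results are sorted by raw p-value with ties broken by taxon ID;
  identical inputs and configuration give bit-identical output.
- Effects are reported on the natural-log scale (`alpha_debiased`) and as
  `log2fc` for the user-facing fold-change column.
- The mode-recovery property holds at the CLR-model level; in the full
  count pipeline, pseudo-counts attenuate the realized effects of heavily
  zero-inflated taxa, so the estimated shift tracks the realized
  compositional shift of the count data rather than the nominal mean of
  the generator's `α` vector. Null taxa still center at zero, which is
  what FDR control requires.
- Mode estimation needs a feature dimension large enough for the KDE to
  localize: a warning is emitted for `m < 50`, and results on such tables
  (e.g., phylum-level aggregates) should not be trusted.
- Finite-sample FDR control is not guaranteed; control is asymptotic in
  `(m, n)` and empirical at the study scales above. Extremely dense signal
  (well beyond 20% differential taxa) breaks the mode-at-zero assumption.

## Problem sizes used in the test suite

Unit tests use small matrices; the simulation-based checks use the default
study scale (m = 500, n = 200) with 10–100 replicate runs, and the
Monte-Carlo covariance check uses m = 10, n = 100 with 2000 replicates.
The full suite runs in about a minute on one CPU.
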