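# Methods

## Two-sample MR model

All estimators operate on an allele-harmonized instrument panel of k
variants with exposure effects `bx ± se_x` and outcome effects
`by ± se_y`.  Each instrument's Wald ratio `r_i = by_i/bx_i` estimates
the causal effect `b_xy` when the instrument is valid; horizontal
pleiotropy adds a direct term `alpha_i` to `by_i`, displacing the ratio
by `alpha_i/bx_i`.

- **IVW**: weighted least squares of `by` on `bx` through the origin,
  weights `1/se_y²`.  The default "fixed" standard error is
  `(Σ bx²/se_y²)^(-1/2)`; the "multiplicative" option inflates it by
  `max(1, sqrt(Q/(k-1)))` with Q the Cochran statistic of the ratios.
  The fixed model is the default because it is the textbook estimator
  whose null miscalibration under pervasive pleiotropy the benchmark is
  designed to expose.  Normal reference.
- **MR-Egger**: WLS of `by` on `bx` with intercept, weights `1/se_y²`,
  after re-orienting instruments so `bx ≥ 0` (making the fit invariant
  to effect-allele orientation).  The intercept estimates average
  directional pleiotropy.  t reference with k−2 df, following the
  method's original formulation.
- **Weighted median**: order the ratios, form cumulative mid-weights
  `s_i = Σ_{j≤i} w_j − w_i/2` from normalized inverse-variance weights
  (first-order ratio variance `se_y²/bx²`), and interpolate at
  `s = 1/2`.  Consistent while valid instruments carry ≥ 50% of the
  weight.
- **Mode**: argmax of a normal-kernel density over the ratios,
  bandwidth `phi · 0.9·min(sd, IQR/1.349)·k^(-1/5)` (modified Silverman;
  `phi` = `bandwidth_factor`, default 1), located on a 512-point grid
  and refined by golden-section search.  The weighted variant weights
  each ratio by its inverse first-order variance.  Consistent under the
  zero-modal-pleiotropy assumption.

### Bootstrap uncertainty for median and mode

The median and mode have no convenient closed-form variance.  Their se
is the standard deviation of `n_boot` (default 1000) bootstrap
re-estimates, with a t(k−1) reference for the Wald p-value
(Hartung–Knapp-style small-sample correction).  The default resampling
scheme draws instruments with replacement — the nonparametric bootstrap,
which is consistent for non-smooth statistics and captures
between-instrument heterogeneity.  A parametric scheme that redraws
`(bx, by)` from their stated normal errors around the observed values is
available (`boot_scheme="parametric"`) but is not the default: for
non-linear statistics it re-noises already-noisy ratios, double-counting
sampling error and overstating the se by roughly sqrt(2) under
homogeneity (measured null rejection ~0.01-0.03 instead of 0.05; the
instrument bootstrap with the t reference measures 0.058/0.043 for
median/mode under the null calibration conditions).

## GSMR2-style estimator

Ratios are combined by GLS: `b_xy = (1'V⁻¹r)/(1'V⁻¹1)`,
`se = (1'V⁻¹1)^(-1/2)`, where `V_ij = R_ij sqrt(v_i v_j)` with R the
instrument LD correlation (identity when absent).  The ratio variance is
the delta-method form with its second-order term evaluated under the
fitted homogeneous model: `v_i = (se_y² + b0²·se_x²)/bx²`, where `b0` is
a provisional inverse-variance estimate.  Evaluating that term at the
observed `by` instead (the naive plug-in `se_y²/bx² + by²se_x²/bx⁴`)
overstates `v_i` under the no-heterogeneity hypothesis and deflates the
Cochran statistic by a few percent; the fitted-model form keeps
`E[Q] ≈ k−1` under both null and causal homogeneous models while
agreeing with the plug-in to first order.

Filtering proceeds in two stages with defaults
`heidi_p_threshold = 0.01`, `global_p_threshold = 0.05`,
`min_instruments = 5`:

1. **HEIDI-outlier stage** — each ratio is tested against a robust
   reference, the weighted median of the ratios (resistant to < 50%
   invalid weight; chosen over the top-instrument ratio because the
   target failure mode is directional pleiotropy, which can corrupt any
   single instrument).  `d_i = r_i − b_ref` with `var(d_i) ≈ v_i`
   (the covariance between `r_i` and `b_ref` is second-order and
   ignored); p from the 1-df chi-squared of `d_i²/v_i`; all instruments
   below the threshold are removed simultaneously, never dropping below
   `min_instruments` (least-significant offenders are retained first).
2. **Global stage** — generalized Cochran test
   `Q = (r − b̂1)'V⁻¹(r − b̂1)` on k−1 df; while `p < 0.05` and more
   than `min_instruments` remain, the instrument with the largest share
   `d_i·(V⁻¹d)_i` of the quadratic form is removed and the model
   re-fitted.  Q is non-increasing under removal at a fixed variance
   profile; because the provisional `b0` is re-fitted per panel the
   realized sequence can deviate by O(0.05), which does not affect
   termination (k strictly decreases).

The exact statistic and removal schedule are this package's
realization; tests assert the behavioural claims (outlier recovery,
bias reduction under directional pleiotropy, null calibration of Q)
rather than equality with any external implementation.

## Summary-statistic simulator

Standardized scale throughout: unit-variance genotypes and phenotypes,
so a GWAS estimate with sample size n is `N(beta, 1/n)` with
`se = 1/sqrt(n)`.  Allele frequencies are drawn Uniform(0.05, 0.5) for
realism of the records but do not enter the standardized-scale noise
model.  Exposure effects are drawn normal and rescaled so the valid and
invalid subsets explain exactly `(1−s)·h2_x` and `s·h2_x`
(`s = invalid_var_share`) — scenario labels are exact per replicate.
Direct effects are `alpha_i = alpha_mean + alpha_sd·(rho·z_i +
sqrt(1−rho²)·eps_i)` for invalid instruments (z the standardized
exposure effects, eps iid normal), hitting mean/SD/correlation targets
in expectation only: exact per-replicate standardization of alpha would
force it orthogonal to the exposure effects and cancel the pleiotropy
noise out of ratio estimators, erasing the FPR inflation the benchmark
measures.  Outcome effects are `beta_y = b_xy·beta_x + alpha`; sampling
errors of the two GWAS are correlated per variant by `overlap_corr`.

Defaults: k = 100 candidate instruments, n_x = n_y = 1e5, h2_x = 0.1
(calibration scenarios use k = 50).  These are declared stand-ins for
the benchmark's scenario axes.  The harness selects instruments from
the exposure statistics alone at p < 5e-8, runs each method, and
reports rejection rate at alpha, mean estimate, bias, empirical SD and
mean model se; per-replicate failures are counted, never silently
dropped.  FDR reporting uses Benjamini–Hochberg within exposure-wise
families at 0.01/0.05 — a step-up FDR procedure standing in for
local-FDR/q-value estimation, which requires a large p-value ensemble
to fit its null component; the substitution is noted in the output.

What the simulator does not emulate: LD between variants (instruments
are independent by construction; the LD-aware GLS path is exercised
with synthetic correlation matrices), minor-allele-frequency-dependent
effect sizes, selection on the outcome, and binary-trait liability
scales.  Calibration results therefore speak to estimator behaviour
under the stated generative model, not to any specific real GWAS.

## Dose-response simulation and diagnostic

Cohorts carry m = 50 independent biallelic variants
(dosages Binomial(2, f), f ~ Uniform(0.05, 0.5)), an exposure
`x = Σ beta_j·g̃_j + e` standardized to unit variance with the SNP part
explaining h2_x = 0.3, and an outcome that is linear (`y = b_xy·x + ε`)
or quadratic (`y = b_xy·(x + x²) + ε`) with b_xy = 0.2.  The quadratic
form scales both terms by b_xy so the stated causal-effect magnitude
governs the whole dose-response curve; the unscaled `y = x² + x + ε`
variant is available by option.  The residual SD defaults to the value
giving unit outcome variance (`var(x + x²) = 3` for standard-normal x).
Cohort size n = 10,000 and the remaining defaults are declared
stand-ins.

Pipeline per replicate: ten exposure quantile groups (rank-based, ties
by stable order), group 1 = never-consumer controls; disease = outcome
above its 80th percentile (the dichotomization rule is this package's
choice); per-group odds ratios against controls from the 2×2 closed
form (identical to a logistic fit on one binary indicator;
Haldane–Anscombe 0.5 correction for empty cells, flagged); turning
point = argmin of the per-group mean-outcome profile (boundary minima
are flagged as "no interior turning point", in which case the consumer
groups are split at their midpoint so both strata remain defined);
moderate stratum = groups between control and the turning point, heavy
= groups above it; contrast GWAS (stratum cases vs controls, 0/1 on the
observed scale) and a disease GWAS over the same included subjects;
genetic correlation between stratum membership and disease within each
stratum.

Genetic correlation uses a no-LD moment estimator (the simulated panel
is LD-free, so LD-score regression machinery is unnecessary):
`h2 = Σ(b² − se²)`, `cov_g = Σ(b_a·b_b)`, `r_g = cov_g/sqrt(h2_a·h2_b)`,
with a delete-one-block jackknife se over 20 variant blocks.  Estimates
outside [−1, 1] are reported with a flag (clipped at ±1.5); non-positive
heritability estimates leave r_g undefined and flagged.  The
dosage-dependence verdict for a replicate requires opposite-sign
per-stratum *genetic covariances* with both individually significant
(|z| ≥ 1.96): the covariance carries the sign of r_g but remains
well-defined when a within-stratum heritability estimate is noisy, and
requiring significance keeps the verdict rate at the test's level under
a null (no-effect) simulation, where raw sign discordance alone would
fire half the time.

## Data handling

The `.ma` dialect (`SNP A1 A2 freq b se p N`, whitespace-delimited on
read, tabs on write) matches the GCTA/GSMR ecosystem.  Validation drops
and logs records with non-positive se, frequencies outside (0,1),
identical or non-ACGT alleles, duplicate ids, p outside (0,1], or p
inconsistent with |b/se| beyond 10% relative tolerance on the z scale.
Harmonization resolves outcome alleles against the exposure in the
order exact match → swap (flip sign, 1−eaf) → strand complement →
complement+swap → drop; palindromic (A/T, C/G) variants with exposure
eaf within 0.08 of 0.5 are excluded — a conservative standard-practice
window, since strand cannot be resolved from frequency there.
Instrument selection keeps p strictly below the threshold (default
5e-8) and greedily clumps by ascending p at r² < 0.01, with a stable
id tie-break so the output is invariant to input row order.

The per-instrument profile reports the Wald ratio with the first-order
delta se `se_y/|bx|` by default; the second-order form (adding
`by²se_x²/bx⁴`) is available by option.  Instruments with `bx = 0` are
flagged rather than raised.

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; simulator outputs are bit-reproducible given the config.
- The GLS solver uses a Cholesky factorization and names the smallest
  eigenvalue when the ratio covariance is not positive definite.
- Near-duplicate instruments (LD → 1) drive the GLS se up to the
  single-instrument se, not beyond: a duplicated instrument adds no
  information.
- Replicate counts in the test suite are scaled to keep the default run
  fast (hundreds of replicates for behavioural properties; the
  calibration checks use 1000); the reported rates carry the matching
  binomial Monte-Carlo error.
- Weak-instrument bias is not corrected; with the default simulated
  instrument strengths (per-variant chi-squared ≫ 30) it is negligible,
  and the same-cohort dose-response GWAS design cancels it from ratio
  estimators exactly.
- Reverse-direction MR in `bidirectional_mr` reports an explicit
  "no-instrument" marker when nothing passes selection rather than
  failing the run.
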