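# Methods

This note records the statistical model, the defaults and the numerical
choices behind `nanopotency`, and where the synthetic data generator is and
is not realistic.

## 1. Normalization model

Raw plate data arrive as one row per well with keys
`experiment_id, cell_type, particle, dose, endpoint, role, signal`, where
`role ∈ {cells, no_cells, lysed_control}`.

**Blank correction.** For each
(experiment × cell type × particle × dose × endpoint) stratum, the mean of
the `no_cells` wells is subtracted from each `cells` well. The blank model is
additive: signal = background + biology. Corrected values below zero are
floored at 0 and a warning is emitted — negative corrected signal is assay
noise around the blank, not a meaningful response.

**Fold effect.** Within each (experiment × cell type × endpoint), FE is the
blank-corrected signal divided by the grand mean of all zero-dose `cells`
wells in that stratum. All particles in one experiment therefore share one
control denominator — the layout of a shared control group per plate. FE ≤ 0
is clipped to 10⁻⁶ (with a warning) so it survives the log step of fitting;
the clip is far below any observable response and only fires when a strong
responder at high dose is blanked to zero.

**%LDH.** 100 × released signal / mean of the `lysed_control` wells of the
same experiment × cell type, the conventional percent-of-maximum scale.

**Replicates.** Duplicate wells are averaged per experiment × dose before
fitting; experiments remain separate so each contributes its own dose curve.

## 2. Potency model

FE(d) = (d + 1)^β, one free parameter per particle × cell type × endpoint.
The +1 shift pins FE(0) = 1, consistent with normalization to the zero-dose
control, and keeps the model defined at d = 0. β is signed: ATP and CTB are
*decreasing* endpoints (β ≤ 0 for a toxicant), LDH is *increasing* (β ≥ 0).

**Fitting.** Least squares in FE space (not log space), i.e. minimize
Σᵢ (FEᵢ − (dᵢ+1)^β)², by bounded scalar minimization over β ∈ [−5, 5]
(Brent, `xatol = 10⁻¹²`) followed by at most three guarded Gauss–Newton
steps; the polish takes the bracketing solver's answer to machine precision
without risking divergence (steps are only accepted if they reduce the SSE).
The bound ±5 is far outside any plausible cytotoxicity exponent on this dose
scale. A closed-form log-space estimator,
β = Σ xᵢyᵢ / Σ xᵢ² with x = ln(d+1), y = ln FE, is available as
`method="loglinear"` and serves as an independent cross-check; on noise-free
data the two agree to ≤ 10⁻⁹. The standard error comes from the Gauss–Newton
linearization (σ̂² (JᵀJ)⁻¹).

**Preconditions.** At least three distinct doses including 0, and strictly
positive FE; otherwise a typed error is raised rather than a silent NaN.

**Consensus and ranking.** β_avg = (|β_ATP| + |β_LDH| + |β_CTB|)/3. Ranking
uses full-precision β_avg, descending; exact ties (rare) break
lexicographically by particle name and the tie is recorded. Rounding before
ranking is never done — the bundled reference screen contains a pair
separated by 0.001/3 that rounds to a false tie at three decimals.

## 3. Determinant association

Pearson r with listwise deletion of missing descriptor values; n ≥ 3 and
nonzero variance are enforced. Correlations use the *signed* β so that the
direction of the relationship is interpretable.

Backward stepwise OLS: fit all predictors (z-scored, intercept included),
repeatedly drop the predictor with the largest t-test p-value above
`alpha_remove = 0.10`, stop when all remaining p ≤ 0.10. The relatively
liberal 0.10 suits tiny screens (n = 6 particles) where 0.05 would empty most
models. Designs with n < p + 2 are rejected with a pointer to pairwise
correlation; rank-deficient designs raise a collinearity error naming the
aliased columns.

## 4. Group inference

Two-way fixed-effects ANOVA (type II sums of squares) on balanced designs
only; unbalanced input is rejected because type II/III choices would change
answers silently. `transform="auto"` runs Shapiro–Wilk on the raw-fit
residuals at α = 0.05 and switches to a rank transform (midranks over the
whole response) on failure — a pragmatic nonparametric fallback for skewed
fold effects. Exactly constant responses short-circuit to F = 0, p = 1
(avoiding 0/0 from floating-point sums of squares).

Multiplicity uses the Holm–Šidák stepdown: sort p ascending,
p̃₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(m−i+1), enforce monotonicity with a running maximum,
cap at 1. It dominates Bonferroni–Holm slightly and is exact under
independence.

## 5. Stress and secretome

GSH/GSSG: the oxidative-stress statistic is the fold change of the
GSH : GSSG ratio versus the untreated control; values < 1 indicate oxidative
stress. Secretome matrices hold per-protein fold changes vs control;
responders are filtered two-sided at a cutoff c > 1 (keep if fc ≥ c or
fc ≤ 1/c, boundary inclusive). Clustering log₂-transforms the matrix first
(so up- and down-regulation are symmetric), uses correlation distance
(1 − r) by default — profiles matter more than magnitudes — with average
linkage; euclidean/complete are available. Constant rows are rejected by
name (correlation distance is undefined for them).

## 6. Synthetic data generator

signal = blank_level + L · (d+1)^β · exp(ε), ε ~ N(0, σ²), with σ = 0.1
(≈10% CV, typical of luminescence viability assays). Defaults: dose grid
(0, 5, 10, 20, 40, 80, 100), 3 independent experiments × 2 duplicate wells,
control level L ~ lognormal around 1000 with 15% CV, blank level 20, lysed
totals around 4000. The control level L is drawn once per
(cell type × endpoint × experiment) and shared by all particles in that
experiment — matching a shared plate control group and making the noise-free
pipeline round trip exact. Planted β values default to the signed exponents
of the bundled reference screen.

**Realism and limits.** The generator is multiplicative-noise only: no
edge effects, no dose-dependent variance, no well position effects, no
particle–assay optical interference (a real concern for nanoparticles), and
the power law holds exactly at all doses (no plateaus or hormesis). It is a
calibration instrument for the estimators, not a plate simulator.

`simulate_descriptors` builds descriptors with a chosen correlation r to
potency via r·z_β + √(1−r²)·z_noise; `simulate_stress_and_proteins` plants
GSH/GSSG suppression factors (split √s across GSH down and GSSG up),
pinned responder proteins and block-structured secretion profiles.

## 7. Problem sizes and budgets

All defaults target the screen geometry the package was built around: ≤ ~10
particles, 2–3 cell types, 3 endpoints, ~7 doses, 3 experiments. Monte-Carlo
checks (β recovery, ANOVA type-I rate) use 1000 replicates, enough for
±0.01–0.02 precision on means and rates while keeping the acceptance script
to a few seconds.

## 8. Limitations

- The one-parameter power law cannot represent thresholds, plateaus or
  biphasic responses; β is a *potency summary*, not a mechanistic curve.
- Consensus averaging weights the three endpoints equally by |β|, which
  mixes viability and membrane-damage scales by fiat.
- Associations over n = 6–8 particles are descriptive; stepwise p-values at
  these sizes are not confirmatory evidence.
- The ANOVA rank fallback changes the tested hypothesis from means to
  stochastic ordering; the `transform` field of the result records when this
  happened.
- The generator's idealizations (Section 6) mean estimator performance on it
  is an upper bound on real-plate performance.
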