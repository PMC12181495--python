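# Methods

## Model and procedure

The clock treats a bulk RNA-seq sample as a vector of independent Poisson
counts whose rates are set by gene-specific relative frequencies that drift
smoothly with age.

Training proceeds in three steps on a gene × sample count matrix with
per-sample ages in months:

1. **Frequency normalization.** Each count is divided by its sample's
   total count, giving relative frequencies that are comparable across
   sequencing depths. Samples with zero total are rejected rather than
   silently dropped.
2. **Gene selection.** Each gene's frequency vector is correlated with age
   by the Spearman rank correlation (average ranks for ties). Ranking by
   |ρ| favours consistently monotone genes without assuming linearity.
   Genes with undefined ρ (constant frequency or constant age input) carry
   no signal and are excluded, as are genes with ρ exactly 0; their counts
   are logged. The top `n_genes` survive (default 12).
3. **Trend fitting.** Each selected gene's (age, frequency) points are
   smoothed by LOWESS and the fit is tabulated at the discrete age grid.
   The likelihood can only be evaluated where the reference is tabulated,
   so the default grid is the sorted unique training ages.

Prediction evaluates, for each grid age x, the joint Poisson log-likelihood
of the sample's observed counts at the model genes, with rates
λ_g(x) = f̂_g(x) · N where N is the sample's library size. The grid argmax
is the point estimate; exact ties resolve to the youngest age. The full
log-pmf including the −ln k! term is computed so reported likelihoods are
proper probabilities, although that term is constant in age and cannot move
the argmax. The posterior reported alongside is the log-sum-exp-normalized
profile, i.e. a flat prior over grid ages.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `tau` | 0.7 | LOWESS smoothing fraction: each local regression uses the `ceil(tau·n)` nearest points. Small values overfit wiggles; values near 1 approach one global line. 0.7 balances the two for lifespan-scale designs with ~10 distinct ages. |
| `n_genes` | 12 | reference panel size. A small panel of top-ranked genes is typically enough; accuracy is insensitive to moderate increases. |
| `age_grid` | `"auto"` | months at which the reference is tabulated; `auto` = sorted unique training ages. |
| `freq_floor` | 1e-12 | lower clamp on fitted frequencies. A LOWESS fit may dip to or below zero at a grid age; a zero rate would make any nonzero observed count infinitely improbable, so fits are clamped at this floor. |
| `lambda_scale` | `"full"` | library size used for rates at prediction: the total over all the sample's genes (`full`, matching the denominator the reference frequencies were defined against) or over the intersected model genes only (`intersection`). |
| `robust_iters` | 3 | LOWESS bisquare robustifying passes (the common default). |

Elastic Net baseline defaults: α grid {1e-5 … 100}, l1-ratio 0–1 in steps
of 0.1, LOOCV mean absolute error as the selection score, iteration caps
10 000 (pass 1) and 100 000 (pass 2), random seed 42.

## Numerical choices

- **LOWESS details.** Tricube weights on distance scaled by the window's
  k-th nearest distance; weighted linear fit, falling back to the weighted
  mean when the window's weighted x-variance vanishes. If the robustness
  weights zero out an entire window (possible for small τ, where tricube
  already vanishes at the window edge), the fit drops the robustness
  weights there; if the distance weights themselves vanish (targets
  equidistant from all window points), the nearest points are weighted
  uniformly. Robustifying stops early when the median absolute residual
  falls below 1e-10 of the data's magnitude — residuals at machine
  precision carry no outlier information, and bisquare-reweighting rounding
  noise would make results depend on floating-point evaluation order.
- **Ties.** Equal |ρ| in gene ranking breaks by lexicographic gene ID;
  equal log-likelihood at the argmax breaks to the youngest grid age. Both
  rules exist purely for determinism.
- **Degenerate inputs.** All-zero sample columns, empty gene
  intersections, fewer than 3 points for LOWESS, and non-increasing age
  grids are rejected with explicit errors; in batch prediction and LOOCV,
  per-sample/per-fold failures are recorded and do not abort the run.
- **Metrics.** Two R² variants are reported — squared Pearson correlation
  and the coefficient of determination 1 − SS_res/SS_tot — because the two
  differ under calibration offsets and published clock papers are not
  always explicit about which they use. With constant true ages the
  correlation quantities are undefined and returned as NaN; the MAE is
  still computed.
- **Leakage.** LOOCV rebuilds everything per fold: gene selection, LOWESS
  fits and (for the baseline) standardization statistics come from the
  training fold only. Features with zero variance within a training fold
  are dropped for that fold rather than standardized by a zero scale.

## The synthetic-data generator

The generator emulates the statistical structure the clock assumes: signal
genes whose relative frequency follows a smooth monotone curve in age
(logistic, exponential-saturating or power shapes, rising or falling),
noise genes with age-constant frequency, samples placed on a discrete age
grid, and counts drawn independently as Poisson(frequency × library size).
A single "rest_of_transcriptome" filler gene absorbs the remaining
frequency mass so frequencies sum to one and the frequency normalization of
simulated data reproduces the generative frequencies in expectation.

Signal genes are drawn in up/down pairs sharing shape and amplitude, so the
aggregate signal mass is age-invariant and the filler gene carries no age
trend. Without this, the filler — a single feature holding ~97% of the
library — would inherit the (inverted) aggregate trend and dominate gene
selection, a situation with no analogue in real data, where the
rest-of-transcriptome is thousands of individually weak features.

Default conditions (30 signal genes with base frequencies 1–3 × 10⁻⁴ and
trend amplitudes 3–9 × 10⁻⁴, 20 noise genes, ages 1, 3, 6, …, 27 months ×
4 samples, library size 10⁵) give per-gene counts of roughly 10–120 with
two- to eight-fold changes across the lifespan — strong but not
caricatured age signal. A gamma-mixed Poisson overdispersion knob
(`dispersion`) exists for stress-testing but is off by default, since
parameter recovery under the model's own assumptions is what separates
estimator bugs from model misspecification.

What the generator does *not* emulate: overdispersion beyond the optional
knob, gene–gene correlation, batch and sex effects, varying library-size
distributions, and any attempt to mimic real tissue-specific expression
parameters. Passing recovery tests on this data therefore demonstrates the
estimator is correct and well-conditioned, not that real tissues will show
the same accuracy.

## Problem sizes used in checks

The shipped evaluation runs use the default simulated design (51 genes ×
40 samples) for the clock's LOOCV and its 20-replicate recovery check, and
a 2-replicates-per-age variant (31 genes × 20 samples) for the Elastic Net
grid search, whose 88-point hyperparameter grid times a leave-one-out loop
is by far the most expensive step. These sizes keep a full evaluation in
the tens of seconds while leaving all method behaviour intact.

## Known limitations

- Predictions are restricted to the tabulated grid: no interpolation
  between grid ages, and ages outside the training range cannot be
  returned. The grid resolution bounds the achievable MAE from below.
- The Poisson assumption equates mean and variance; real bulk RNA-seq is
  typically overdispersed. A negative-binomial likelihood would be the
  natural extension and the generator's dispersion knob anticipates it.
- With very deep libraries the likelihood becomes extremely concentrated;
  model misfit (not sampling noise) then dominates errors, and the
  posterior's sharpness should not be read as calibrated uncertainty.
- Gene selection by marginal |ρ| ignores redundancy between genes; the
  panel is not guaranteed to be the most informative set of its size.
- The Elastic Net baseline selects hyperparameters on the same
  leave-one-out loop it reports, mirroring the common practice it is meant
  to represent; its accuracy is therefore mildly optimistic compared to a
  nested scheme.
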