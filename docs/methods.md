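# Methods

This note documents the models implemented in `epiwalk`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Data model

A complete binary genotype-fitness map assigns fitness to all `2^L`
combinations of `L` biallelic sites.  The canonical order everywhere in the
package is binary-integer order with site 0 as the leftmost (most
significant) character, so the ancestral genotype `0...0` has index 0 and the
fully derived genotype `1...1` has index `2^L − 1`.  Fitness is taken as
supplied (relative fitness, growth rate, or any positive proxy); per-genotype
replicate measurements, when present, define the mean and the sample standard
deviation (a single replicate is recorded as std 0 and later floored by the
resampling module).  Incomplete hypercubes, multi-allelic sites and diploid
genotypes are out of scope.

## Scale removal

Mutational effects need not combine additively on the measured scale; global
curvature that is not removed is absorbed by the interaction terms and
inflates apparent epistasis.  The scale model is a three-parameter power
transform linking the additive expectation to observation,

    F_obs = ((F_add + A)^λ − 1) / (λ · GM^(λ−1)) + B ,

with `GM` the geometric mean of `F_add + A`.  Three points matter:

* **`GM` is not a free parameter.**  It is recomputed from `(A, F_add)`
  inside the objective at every step, keeping the model exactly
  three-parameter.
* **The additive model is regressed on the observed scale** (ordinary least
  squares of fitness on the 0/1 mutation indicators, with intercept), and the
  transform is then fitted between this additive prediction and observation.
  Because the regression happens on the curved scale, the two-stage fit
  recovers a generating additive-plus-scale map only approximately (relative
  error below ~1% in the package's tests) — exactness would require a
  fixed-point iteration that the standard protocol does not use.
* **λ itself is weakly identified.**  Over the narrow fitness range of a real
  map, curvature can be described equally well by many `(λ, A, B)`
  combinations (as λ grows with A, the family approaches an exponential
  scale; as λ → 0 it approaches a log scale).  The optimizer may therefore
  settle anywhere on a flat ridge, including the λ bound.  The *composed*
  transform over the data range — what linearization actually uses — is
  stable; individual parameter values should not be over-interpreted.

Fitting uses bounded trust-region nonlinear least squares (`scipy`
`least_squares`, analytic Jacobian, `x_scale="jac"`), with λ ∈ (0, 10],
`A > −min(F_add)` so the power and the geometric mean stay defined, `B` free;
initialization is λ = 1 (affine), a small positive base shift, `B = 0`; the
convergence tolerance is 1e-10 on the objective and the fit is deterministic.
A fit that exhausts 20 000 function evaluations raises an error carrying the
best parameters found.

Linearization applies the exact inverse transform to observed fitness.  Two
domain edges are handled explicitly rather than silently:

* back-transforming truncated linear fitness whose base `F + A` is
  non-positive clips the base to 1e-9 (the transform's infimum) and counts
  the clip in `EpistasisRemover.n_clipped_` and the run manifest;
* linearizing an observed value below the fitted transform's infimum does the
  symmetric clip inside the pipeline (the domain edge maps to `−A`, so a
  marginal overshoot lands near there); the standalone `linearize` function
  raises unless asked to clip.

## Epistatic decomposition

The linearized fitness vector is decomposed as `β = X⁻¹ F_linear` over all
site subsets, grouped by ascending order and lexicographic within order.  Two
encodings are provided: the **global** (Walsh/Hadamard) basis encodes alleles
as −1/+1, uses the geometric center of the map as reference, and is
orthogonal — `XᵀX = 2^L I`, so the solve is the analytic `Xᵀ/2^L` and
per-order variance contributions are exactly additive; the **local** basis
encodes alleles as 0/1 relative to the ancestral genotype and is solved
directly.  The variance partition ϕ and the trajectory divergence θ are
computed on the global basis; the local basis serves the
predict-from-the-ancestor analysis, where coefficients up to order *k* are
precisely what measuring all ≤*k*-mutant fitness values in the ancestral
background would give.

`ϕ_i = ρ_i² − ρ_{i−1}²`, with `ρ_x²` the squared Pearson correlation between
`F_linear` and the order-*x* truncated model *on the linear scale* (not
back-transformed).  `ρ_0² := 0`: correlation against a constant is undefined,
and this convention makes `ϕ_1` the variance explained by the additive model.
A truncated model with zero variance is likewise assigned `ρ² = 0`.  ϕ can be
negative at an order whose inclusion moves the truncated model away from the
observations.

## Trajectories

Under strong selection / weak mutation the population is monomorphic and
evolves by sequential fixations; a forward trajectory is an ordered sequence
of distinct sites mutating 0 → 1 from the ancestral genotype.  Fixation
probability is the classic haploid form `π = (1 − e^(−s)) / (1 − e^(−Ns))`
with `s = w_to/w_from − 1`, the analytic limit `1/N` at `s = 0`, and `π = 0`
into genotypes at or below the lethal-fitness threshold (default 0, where the
selection coefficient is undefined).  The published form of this model is
occasionally printed with the opposite sign convention for `s`; the form used
here is the one under which beneficial mutations fix with probability
approaching `1 − e^(−s)` as N grows.

A trajectory's weight is the product of its step probabilities, accumulated
in log space so that strongly deleterious steps (whose probabilities
underflow doubles, e.g. `e^(−10000)`) remain comparable; probabilities are
the weights normalized across all enumerated trajectories of the same length.
Exact zeros — and hence the "no accessible trajectories" error — arise only
from lethal genotypes.  Population size is never part of the data; the
default `N = 1e6` describes a large asexual population, and
`sensitivity_sweep` recomputes every θ and overlap across a user-supplied N
grid and reports the maximum deviation per statistic.  Note that at large N
the trajectory distribution through a map containing deleterious steps
becomes extremely concentrated, so θ between two nearly identical such maps
can jump between ~0 and ~1: θ is a property of the evolutionary regime, not a
smooth function of fitness, and its resampling distributions can be
multimodal.

θ is the total-variation distance `½ Σ |p_a − p_b|`: 0 for identical
distributions, 1 for disjoint supports, and in between the fraction of
trajectory probability density shifted.  A raw squared-difference variant is
available behind a flag for sensitivity analysis.  The prediction overlap for
*k*-step evolution is `100 · (1 − θ)` between the *k*-step distributions of
the original map and a map truncated in the local basis, each normalized
within its own length-*k* trajectory set.

## Resampling

Pseudoreplicate maps are independent Gaussian draws per genotype, centered on
the measured means.  The sampling width is the standard error of the mean
when replicates are present and the raw std otherwise; zero widths are
floored at 1e-6 of the map's fitness range (warned and recorded).  Each
pseudoreplicate goes through the *complete* pipeline — additive fit, scale
refit, decomposition, truncation, trajectories — yielding a (ϕ, θ) pair per
order; equal-tailed percentile intervals summarize the spread.  Failed
pseudoreplicates (optimizer or domain failures) are logged, skipped and
counted.

The null distribution at order *k* starts from the source map truncated to
order *k − 1* — no epistasis at the tested order — with the source map's
per-genotype uncertainty re-attached, so its pseudoreplicates show the
apparent ϕ and θ that noise alone produces.  The p-value of order *k* is the
upper-tail percentile of the experimental θ mode on the null θ samples
(large θ is the alternative of interest).  The mode is estimated by a
Gaussian KDE with Silverman bandwidth, argmax on a 512-point grid, with a
histogram fallback for degenerate samples.

Two caveats.  First, with n null samples the smallest resolvable p is 1/n
(a reported 0 means "below 1/n").  Second, the procedure is approximately —
not exactly — calibrated, and the deviation is anti-conservative.  The
experimental map's means already contain one realized draw of measurement
noise at the tested order and pseudoreplication adds a second, while the
null base map (being a truncation) contains none; on top of that, the
experimental side is summarized by a mode over noise-inflated θ samples
whereas the null side contributes its raw samples.  Both effects make the
experimental θ mode stochastically exceed the null distribution even when
the tested order carries no true signal: in the package's own check
(50 generator seeds, 4-site maps with interactions only up to order 2,
Gaussian replicate noise), the order-3 p-values concentrate well below 0.5
rather than distributing uniformly.  p-values from this procedure are
therefore evidence scores to be read qualitatively — clear separation vs
overlap with noise — not frequentist error rates; a strongly injected
signal is still detected at p below the 1/n resolution, and orders whose
signal is genuinely absent but whose p lands at, say, 0.1 should not be
declared significant on that basis.  The scale fits inside the resampling
loop use an objective tolerance of 1e-8 (the point-estimate default is
1e-10): per-fit differences are below 1e-4 in ϕ and 2e-3 in θ — far under
the resampling spread — and flat-ridge fits run about three times faster.

## Synthetic maps

The generator emulates the statistical structure of adaptive experimental
maps: linear-scale fitness built from coefficients in the orthogonal global
basis, an optional power-law distortion, Gaussian replicate noise.  Defaults:
baseline fitness 1.0, linear-scale fitness std 0.2 (a ~1.0–1.5 fitness
range), 3 replicates, first-order effects drawn positive (mutations sampled
from an adaptive episode are beneficial on average; without this, random-sign
effect draws make most full-length paths deleterious and trajectory
distributions collapse onto single paths, which is not the regime the
experimental maps occupy).  When a per-order variance budget is requested,
order-k draws are rescaled so `Σ_{|S|=k} β_S²` matches the budget exactly —
orthogonality makes per-order variances additive, so the budget is hit to
machine precision and serves as ground truth for ϕ.

What the generator does **not** emulate: genotype-specific error variance
(noise is homoscedastic unless a per-genotype std vector is supplied),
non-Gaussian measurement error, correlated replicate structure, and any
particular biochemical origin of the interactions.  Tests passing on
synthetic maps therefore establish the correctness of the algebra and the
propagation machinery, not the biological fidelity of any one dataset.

## Problem sizes used in the tests and the acceptance script

The test suite and `scripts/acceptance.py` run on maps of 3–5 sites; the
calibration check uses 50 generator seeds at 100 pseudoreplicates each and
the headline resampling runs use 500 pseudoreplicates (the analysis defaults
to 10 000 via `RunConfig`, which is what a production run on a real dataset
should use).  The Monte-Carlo trajectory oracle uses 10^6 proposed walks on a
3-site map.  These sizes were chosen so each check completes in seconds to a
few minutes on one CPU while leaving the Monte-Carlo error well below the
tolerances being asserted.

## Known limitations

* Maps must be complete; there is no partial/regularized estimation for
  missing genotypes.
* One scale family (the power transform); no model comparison across scale
  families.
* SSWM only: no clonal interference, recombination, back-mutation, or
  finite-N drift simulation beyond the fixation formula itself.
* Per-order p-values are not corrected for multiple testing across orders.
* λ is reported as fitted but, per above, only the composed transform is
  identified; comparing λ values across datasets is not meaningful.
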