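# epiwalk

**High-order epistasis in complete genotype-fitness maps, and what it does to
adaptive evolutionary trajectories.**

## The problem

A complete binary genotype-fitness map measures fitness for *every*
combination of *L* mutations — all 2^L genotypes between an ancestral
(all-wildtype) and a derived (all-mutant) state. Such maps contain not only
the individual (additive) effects of mutations and their pairwise
interactions, but also *high-order epistasis*: three-, four-, and five-way
interactions. These terms are usually small. Do they matter for evolution?

`epiwalk` answers that question quantitatively. It decomposes a map into a
global nonlinear measurement scale plus epistatic interaction coefficients at
every order, computationally removes the orders you choose, and measures how
the removal reshapes the probabilities of adaptive trajectories under
strong-selection/weak-mutation (SSWM) population genetics. It is aimed at
researchers analyzing combinatorially complete mutant libraries
(experimental evolution, protein or regulatory variants, antibiotic
resistance) who want to know how much of evolutionary predictability each
order of interaction carries.

## The model

1. **Scale removal.** Observed fitness is modeled as a monotone power
   transform of an additive expectation:
   `F_obs = ((F_add + A)^λ − 1) / (λ·GM^(λ−1)) + B`, with `F_add` the
   least-squares additive fit and `GM` the geometric mean of `F_add + A`.
   Inverting the fitted transform ("linearizing") removes global curvature
   that would otherwise masquerade as epistasis.
2. **Decomposition.** The linearized fitness vector is written exactly as
   `F_linear = X β`, with `X` a complete design over all site subsets.  The
   *global* (Walsh/Hadamard, ±1 encoding) basis gives background-averaged
   coefficients and is orthogonal (`XᵀX = 2^L·I`); the *local* (0/1,
   ancestral-referenced) basis gives coefficients measured in the ancestral
   background.
3. **Truncation.** Setting all coefficients above order *k* to zero and
   re-applying the forward transform yields a map with high-order epistasis
   removed but the original scale intact.  The variance partition
   `ϕ_i = ρ_i² − ρ_{i−1}²` (squared Pearson correlation between observed and
   order-*i*-truncated linear fitness) says how much each order explains.
4. **Trajectories.** Under SSWM, evolution is a chain of fixation events with
   Gillespie fixation probability `π = (1 − e^(−s)) / (1 − e^(−N·s))`,
   `s = w_to/w_from − 1`.  A forward trajectory's probability is the product
   of its step fixation probabilities, normalized over all ordered paths of
   the same length.  The divergence between two maps' trajectory
   distributions is the total-variation distance
   `θ = ½ Σ |p_a − p_b| ∈ [0, 1]` — the fraction of trajectory probability
   density that moves when epistasis is added or removed.
5. **Uncertainty.** Gaussian pseudoreplicates propagate per-genotype
   measurement error into confidence intervals on ϕ and θ; "null" maps
   (truncated fitness + original error bars) show how much apparent epistasis
   and trajectory change noise alone produces, giving a p-value per order.

A synthetic-map generator with exact per-order variance control (a property
of the orthogonal basis) provides ground truth for every stage.

## Worked example

```python
from epiwalk import (MapSpec, generate_map, EpistasisRemover,
                     EvolutionParams, trajectory_probabilities, theta,
                     prediction_overlap)

# a 32-genotype map: decaying interaction spectrum, power-law scale,
# triplicate measurements with Gaussian noise
spec = MapSpec(
    n_sites=5,
    beta_spec={1: 0.94, 2: 0.038, 3: 0.012, 4: 0.009, 5: 0.001},
    scale=(2.5, 1.0, 0.0),
    noise_sd=0.01,
    n_replicates=3,
    seed=1,
)
gmap, truth, truth_scale = generate_map(spec)

rem = EpistasisRemover(basis="global").fit(gmap)
print("fitted scale: lambda=%.3f  A=%.3f  B=%.3f"
      % (rem.scale_.lam_, rem.scale_.A_, rem.scale_.B_))
for k, phi_k in enumerate(rem.phi_profile(), start=1):
    print("order %d explains %5.1f%% of fitness variance" % (k, 100 * phi_k))

params = EvolutionParams(N=1e6)
d_add = trajectory_probabilities(rem.truncated_map(1), params)
d_pair = trajectory_probabilities(rem.truncated_map(2), params)
print("theta(additive, pairwise) = %.3f" % theta(d_add, d_pair))
print("2-step overlap, additive model: %.1f%%"
      % prediction_overlap(gmap, 1, 2, params))
```

prints

```
fitted scale: lambda=10.000  A=10.621  B=-0.469
order 1 explains  93.9% of fitness variance
order 2 explains   3.8% of fitness variance
order 3 explains   1.3% of fitness variance
order 4 explains   0.8% of fitness variance
order 5 explains   0.1% of fitness variance
theta(additive, pairwise) = 0.374
2-step overlap, additive model: 84.0%
```

The decomposition recovers the injected spectrum: the additive terms explain
~94% of variance, yet removing the interactions still shifts 37% of the
trajectory probability density (θ = 0.374), and fitness measured only on
single mutants of the ancestor would mispredict 16% of two-step evolution.
(The fitted shape parameter sits on its upper bound here: over a narrow
fitness range many (λ, A) pairs describe the same curvature, so the
*composed* transform — not λ alone — is the identified object; see
`docs/methods.md`.)

The same analysis runs from the shell on any map in the documented JSON
schema:

```bash
epiwalk simulate spec.json --out map.json
epiwalk analyze map.json --reps 1000 --seed 0 --out results/
epiwalk overlap-grid map.json
```

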