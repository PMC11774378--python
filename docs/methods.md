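# Methods

This note documents the statistical model, the estimation algorithms, the
synthetic-data generator, and the numerical and design choices made where
the design was genuinely open.

## Data model and preprocessing

All analysis operates on *fatty acid signatures* (FAS): compositional
vectors of proportions over a named set of fatty acids (FAs), summing
to 1. Columns are always matched by FA name, never by position, across
predator, prey and calibration files. Signature CSVs in the percent
dialect (every row sum in 95–105) are divided by 100 on load; files whose
row sums are neither all near 1 nor all near 100 are rejected rather than
guessed at.

Diet estimation uses a subset of the measured FAs (the dietary FAs —
those acquired primarily from diet rather than synthesized de novo). The
subset must be re-completed to a composition in one of two ways:

- **multiplicative normalization** — keep the subset columns and divide
  each row by its subset sum; ratios within the subset are preserved, but
  ratios to the discarded mass are lost;
- **augmentation** — append one pseudo-component (`augmented`) equal to
  1 minus the subset sum; no rescaling occurs, so every pairwise ratio
  among retained FAs is preserved exactly and the vector stays
  compositional.

**Zero replacement.** Both distances require strictly positive inputs, so
zeros (censored trace FAs) are replaced *before* any distance is taken:
every zero cell becomes `0.9 ×` the smallest non-zero proportion found
anywhere in the prey reference matrix (one global floor, applied to
predator rows too), and only rows that had a replacement are rescaled
multiplicatively back to sum 1; zero-free rows pass through bit-identical.
The floor fraction (default 0.9) is configurable. The pipeline order is
fixed as zero-replace → complete → transform; when augmentation produces
an exactly-zero augmented component (subset exhausts the row), the
component is re-floored from the prey data.

**Calibration coefficients (CCs).** Predator metabolism is modelled by a
strictly positive per-FA multiplier vector `c`. Two inverse transforms
move signatures between spaces, each followed by renormalization:
prey space `x_i ← (x_i / c_i) / Σ_j (x_j / c_j)` and predator space
`m_i ← (m_i c_i) / Σ_j (m_j c_j)`. Both are invariant to uniform
rescaling of `c`, which drives the identifiability constraint of the
joint model (below).

**Augmented-component CC.** A fixed-CC analysis with augmentation needs a
coefficient for the pseudo-component, which no feeding trial provides.
Since the augmented proportion is a pooled mixture of the excluded FAs,
its coefficient is taken as the mean of the excluded FAs' coefficients
weighted by their proportions in the overall prey mean signature. This is
a documented convention, not an estimate; it affects only fixed-CC
augmented runs, and only through one of K+1 coordinates of the transform.

**Group means** are arithmetic means of completed member signatures. This
preserves the sum-to-1 closure and matches how the mixture model is
defined (a diet-weighted average of prey signatures is an arithmetic
average); compositional (geometric) means are deliberately not used.

## Distances

- **Symmetrized Kullback–Leibler**: `Σ_i (x_i − y_i) ln(x_i / y_i)`,
  natural log. Non-negative, symmetric, zero iff equal; *not* a metric
  (no triangle inequality), and sensitive to both absolute and relative
  differences.
- **Aitchison**: Euclidean distance between centered log-ratio (clr)
  transforms, `‖clr(x) − clr(y)‖`. A true metric on the simplex,
  invariant to positive rescaling of either argument, driven purely by
  relative differences.

Zero handling is deliberately *not* done inside the distance functions:
they raise on non-positive input, keeping preprocessing auditable in one
place.

## Fixed-CC diet estimation

Each predator's diet solves

```
min_{pi}  D( x_adj , pi @ M_adj )   s.t.  pi >= 0,  sum(pi) = 1
```

where `(x_adj, M_adj)` are the predator signature and the G×K matrix of
group means placed in the configured estimation space. Predator-space
modeling is *transform-then-mix*: each prey mean is CC-transformed (and
renormalized) first, then mixed. Transforming the mixture instead is not
equivalent — renormalization makes the two differ by a reweighting of the
mixing weights — and transform-then-mix is the reading consistent with
the estimation-space framing in the QFASA literature (prey signatures are
moved into the predator space, where the observed signature lives).

The solver is SLSQP with the simplex constraint, analytic gradients for
both distances, `ftol = 1e-12`, and a multi-start policy: the uniform
composition, each of the G vertices, and seeded Dirichlet(1) interior
points up to `n_restarts = 10`; the best objective wins, ties broken by
first found. Optimizer failure after all restarts is flagged on the
estimate, never silent. Estimates for identical inputs are identical
(restart seeds are shared across rows).

Group-level estimates are pooled to species by summing member-group
proportions; row sums are conserved exactly.

## Joint estimation of diets and CCs

The CC-unconditional model estimates one shared `c` and all diets by
minimizing the summed Aitchison distance, over predators, between each
observed signature and its mixture of c-transformed prey means (predator
space, transform-then-mix). Uniform rescaling of `c` leaves every
renormalized transform unchanged, so the likelihood surface has an exact
scale ray; the anchor `sum(c) = K` (mean coefficient 1) is imposed for
identifiability and verified not to affect fitted compositions.

The optimizer alternates three steps, each accepted only if it does not
increase the objective (so the reported objective trace is monotone
non-increasing by construction):

1. **Full-parameter quasi-Newton polish.** All diets and CCs are updated
   together by L-BFGS in an unconstrained parametrization — row-wise
   softmax for the diets, `c = K·softmax(β)` for the CCs — with analytic
   gradients (verified against finite differences in the test suite).
   This step does the bulk of the descent: plain block-coordinate
   alternation on this problem zigzags at a crawl (measured ≈7% objective
   decrease per round, sublinear), because the diets and CCs are strongly
   coupled.
2. **Exact CC block**: SLSQP over `c` at fixed diets, with the sum
   constraint and analytic gradient.
3. **Exact diet block**: per-predator simplex SLSQP at fixed `c`,
   warm-started, which lands exact boundary solutions (true zeros in pi)
   that the softmax parametrization can only approach.

Outer iteration stops when the objective falls below `1e-9`, when the
per-round relative decrease falls below `1e-8`, or after 50 rounds.
Multi-start over CC initializations (all-ones plus seeded log-normal
draws, default 4 starts total) guards against local minima; the fit is
deterministic given the seed. On noiseless synthetic data the optimum is
recovered to ~1e-10 in both diets and CCs.

## Diagnostics

- **psi** — the share of total pairwise prey-signature distance occurring
  within prey groups: numerator = sum of all within-group pairwise
  distances, denominator = that plus all cross-group pairwise distances,
  each unordered pair counted once. Ranges in [0, 1]; small values mean
  tight, well-separated groups. Computed for either distance measure.
- **LOPO** (leave-one-prey-out) — each prey signature is held out, *only
  its own group's mean* is recomputed without it, and the signature is
  diet-estimated against all G means under the fixed-CC configuration
  (in the predator space, the held-out signature is first CC-transformed,
  since a consumed prey item is observed through predator metabolism).
  The attribution matrix reports mean estimated proportions by true
  group. Note that exact invariance under duplicating every group member
  cannot hold: a held-out row's duplicate remains in its group and shifts
  the leave-one-out mean by O(1/n); the effect vanishes with group size.
  LOPO is defined only for the fixed-CC model (under the joint model the
  CCs would change with each held-out fit).
- **Out-of-range proportion** — the fraction of (predator, component)
  cells strictly outside the [min, max] range of the G group means for
  that component, with predators and means placed in the *estimation
  space* of the configuration being diagnosed (using estimated CCs for a
  joint fit). A mixture of means can never leave that range
  component-wise, so any positive value flags an assumption violation.
  The choice of space is a design decision: it makes the statistic speak
  to the model actually fitted.
- **Fit distances and method comparison** — per-predator distances
  between observed (space-adjusted) signatures and fitted mixtures;
  recomputation from stored diets equals the stored objectives, and their
  sum equals the joint objective for the same parameters. Cross-method
  comparison reports per-species Pearson correlations of pooled
  estimates; zero-variance species are reported as missing (NaN), never
  coerced to 0. For runs sharing a distance measure the share of
  predators with a smaller fit distance and the summed-distance ratio are
  added; for a joint run compared against a fixed-CC run this ratio is at
  most 1, because the fixed CCs are a feasible point of the joint
  problem.

## Prey-grouping permutation ANOVA

Group equality is tested directly from the pairwise distance matrix via
the one-way pseudo-F

```
SS_total  = (1/N) Σ_{i<j} d²_ij
SS_within = Σ_k (1/n_k) Σ_{i<j ∈ k} d²_ij
F = ((SS_total − SS_within)/(g−1)) / (SS_within/(N−g))
```

with squared distances in the sums of squares. When the number of
distinct label assignments (the multinomial coefficient `N!/Π n_k!`,
computed in exact big-integer arithmetic) does not exceed the replicate
cap (default 100,000), *all* assignments are enumerated and the p-value
is exact, with the observed assignment counted; otherwise label
permutations are sampled uniformly and the add-one rule
`p = (1 + #{F_perm ≥ F_obs}) / (1 + reps)` avoids zero p-values and makes
the test exactly level-α under exchangeability. Perfect separation
(`SS_within = 0`) yields an infinite statistic, which the permutation
comparison handles naturally; an all-zero distance matrix is an error.
Pairwise tests run the same machinery per group pair and report raw
p-values by default (an optional Holm adjustment is available). Only the
single-factor design is implemented; a stratified (within-species)
variant is future work.

## Synthetic-data generator

The generator realizes exactly the data-generating process the estimators
assume, so that estimation error on its output isolates algorithmic error:

- **Prey library**: a baseline composition is drawn as a normalized
  exponential of a standard normal vector; group centers are
  logistic-normal displacements of the baseline with log-scale
  `separation`; members are logistic-normal perturbations of their center
  with log-scale `within_spread`. Logistic-normal (rather than Dirichlet)
  noise is used because it perturbs log-ratios — the geometry the
  Aitchison distance measures — and gives independent control of spread.
- **CCs**: log-normal draws with log-scale `cc_spread`, rescaled to
  `sum(c) = K`; zero spread gives the all-ones vector.
- **Predators**: diets drawn from a symmetric Dirichlet
  (`diet_concentration`, default 1 = uniform on the simplex); the
  noiseless signature is the diet-weighted mixture of the library's
  *empirical* group means, formed in the prey space and CC-transformed
  (`mixture_space="prey"`, the generative reading) or formed directly
  from CC-transformed means (`mixture_space="predator"`, an exact mixture
  in the estimation space, used for exact-recovery checks); observation
  noise is logistic-normal with log-scale `noise_spread`.
- An optional `censor_threshold` zeroes cells below a threshold to create
  realistic missing trace FAs for exercising zero replacement.

Defaults (G=6 groups, K=32 components, 20 prey per group, 50 predators,
`within_spread=0.15`, `separation=0.6`, `cc_spread=0.2`,
`noise_spread=0.01`) emulate a desk-scale marine-mammal prey library:
clearly differentiated prey types with moderate within-type variation,
CCs scattered within roughly ±40% of 1, and small residual noise. All
stages are deterministic given the seed, with independent per-stage
streams.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: real FA profiles of particular species;
correlated measurement error across FAs within a chromatography run;
between-individual CC heterogeneity (the model's own assumption of one
shared `c` is built in); prey types absent from the library; temporal or
spatial structure in prey signatures. Recovery results on synthetic data
bound algorithmic error only, not ecological error.

## Problem sizes and tolerances

The shipped test suite and acceptance script run at desk scale, chosen so
each check isolates one property: distance oracles on 1,000 random pairs
(1e-10 agreement); noiseless recovery with G=6, K=32, 50 predators across
all four distance-by-space configurations (max error < 1e-4); a
1e-4-step grid-search oracle for G=2; psi enumeration on libraries of
~20; permutation-ANOVA null calibration over 500 simulated datasets with
999 permutations each (type-I error within [0.03, 0.07] at α=0.05); and
joint-model recovery with 100 predators at `noise_spread=0.01`
(≥90% of CCs within 5%, diet RMSE < 0.05 — measured results are about an
order of magnitude better).

## Known limitations

- No uncertainty quantification: neither bootstrap intervals for diets
  nor standard errors for estimated CCs.
- The joint objective is non-convex; the multi-start policy is a
  safeguard, not a guarantee of the global optimum.
- The chi-square distance and prey clustering not keyed to labelled
  covariates are out of scope.
- The augmented-component CC convention for fixed-CC augmented runs
  (prey-mean-weighted mean of excluded coefficients) is a reasoned
  default with no external calibration.
- KL-distance estimation in the prey space can be sensitive to the zero
  floor, since replaced values enter the distance directly.
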