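# Methods

This note documents the models and procedures implemented in `actipath`,
the defaults and why they were chosen, the numerical choices that matter,
and what the synthetic benchmarks do and do not establish.

## Problem setting

Given a tabular dataset (rows = individuals, columns = continuous and
discrete explanatory variables plus one response), a schema declares which
explanatory variables are *intervenable* — modifiable directly or
indirectly, like BMI or blood glucose, unlike age or height — and in which
clinically sensible direction. The goal is, for one individual, an ordered
sequence of single-variable unit changes that improves the response
predicted by a machine-learning model, while keeping every intermediate
state plausible under the data distribution.

## Preprocessing

* 80/20 train/test split (`floor(n·0.8)` training rows; optional grouped
  splitting so that, e.g., all records of one participant land on one
  side).
* Missing cells are tracked by an explicit mask, never a sentinel number;
  they are filled with the training median (continuous) or training modal
  category (discrete; ties broken by schema category order). Chained /
  multiple imputation is deliberately out of scope.
* Continuous explanatory variables are standardized by training mean and
  standard deviation (ddof = 0). The response is never standardized; the
  surrogate's scale constants (`σ`, the intercept prior) absorb its units.
* Before surrogate fitting, training rows with any continuous explanatory
  value outside mean ± 3 sd (training statistics) are dropped. The filter
  applies only to the surrogate's training table — the predictor sees all
  rows — because its purpose is MCMC stability, not predictor accuracy.
  The response and discrete variables never trigger removal.

## Step 1: prediction model

Any object with `task` and `predict_frame(values) -> vector` works; the
planner and surrogate are model-agnostic (a closed-form stub exercises the
same code paths in the tests). The default engine is XGBoost with a small
fivefold-cross-validated grid (`n_estimators` ∈ {100, 300}, `max_depth`
∈ {2, 4}, `learning_rate` ∈ {0.05, 0.1}), scored by RMSE (regression) or
AUC (classification); the grid is configurable and can be bypassed with
fixed parameters. Discrete variables are one-hot encoded inside this
module only, so the surrogate sees raw categories. Held-out metrics:
RMSE and R² (regression), AUC (classification). The held-out RMSE is not
just a report — it fixes the surrogate's response noise scale.

## Step 2: stochastic surrogate

A K-component mixture of experts is fitted to the *training* rows'
standardized explanatory values together with the prediction model's
in-sample outputs (not the observed response): the surrogate approximates
the model, not the data. Generative process per instance:

* component `k ~ Categorical(π)`, `π ~ Dirichlet(1)`;
* `x_cont ~ N(m_k, Σ_k)` with diagonal Σ_k; `m_k ~ N(0, 5)` per
  coordinate, half-Cauchy(0, 2.5) priors on the diagonal scales;
* each discrete variable `x_disc,j ~ Categorical(φ_j,k)`,
  `φ_j,k ~ Dirichlet(1)`;
* response head `y ~ N(μ_k, σ)` with
  `μ_k = β_1,k + η_2,kᵀ x_cont + η_3,kᵀ x_disc(one-hot)`,
  `η ~ Laplace(0, 1)`, `β_1,k ~ N(ȳ, 5·sd(y))`, and `σ = RMSE_test / 2`
  fixed, tying the surrogate's tolerance to the predictor's demonstrated
  accuracy. Classification uses `y ~ Bernoulli(logistic(μ_k))` with
  `β_1,k ~ N(0, 5)`; the surrogate then trains on predicted class labels
  at threshold 0.5 (a flag switches to a probability-weighted Bernoulli
  term).

Scale conventions: the second parameter of every normal prior above is a
standard deviation (the convention of Stan-family samplers, for which
these priors are idiomatic weakly-informative choices), and the
half-Cauchy prior is placed on the standard deviations of Σ_k's diagonal;
the fitted model stores variances.

### Sampler

The component label is marginalized analytically and all remaining
parameters are sampled by univariate slice sampling within a Gibbs scan,
on unconstrained scales (stick-breaking with log-Jacobian for simplexes,
log-sd for scales). This design was chosen over data-augmentation Gibbs
because the marginalized form stays exact at *any* likelihood temperature
— the WBIC computation needs a tempered posterior — and slice sampling
needs no step-size tuning. Chains (default 4) are initialized from
k-means cluster statistics with small jitter; defaults are iteration =
1500 with warm-up = 500 per chain. Per-scalar updates refresh cached
per-component likelihood terms in O(n), so a full fit of the 3D benchmark
(n = 480, K = 2) takes seconds.

Convergence reporting: split-chain potential scale reduction per scalar
parameter block, plus R-hat of the total log-likelihood. Mixture
posteriors are invariant under component relabeling, so per-component
R-hats across chains can be inflated by label switching even when every
chain has mixed; the log-likelihood R-hat is the label-invariant summary.
For the same reason, parameter-recovery checks align component labels to
the truth per draw (best permutation) before averaging.

### Density evaluation

The probability of a joint state (x, y) is the posterior-predictive
density: the mixture density averaged over posterior draws, computed in
the log domain via log-mean-exp. Densities — not parameters — are
averaged, because parameter averaging is meaningless under label
switching and breaks multimodal posteriors. The response term is included
by default ("probability of given values of explanatory and response
variables"); a flag evaluates the explanatory-only density, since the
planning literature is ambiguous about whether a node's probability
should score the predicted response too. Draws can be evenly thinned for
planning speed.

### Model selection

WBIC = E[−log L(data | θ)] under the posterior sampled at inverse
temperature β = 1/log n; lower is better. K ranges over 1–8 by default.
Each K gets an independent, reproducible seed substream. WBIC needs
log n > 1, i.e. n ≥ 3.

## Step 3: path planning

The intervenable variables span a lattice centred on the instance: step
0.2 in standardized units (0.2 σ in original units), bounds at the
training data's observed min/max per variable clamped to ±4 σ from the
origin (the surrogate is untrustworthy under extrapolation; bounds are
configurable). Non-intervention variables stay frozen. Node cost is
−log p(node); path cost sums over **all** nodes including the start (a
constant offset that changes no argmin but makes exp(−cost) a true
product of nodal probabilities).

The search finalizes the cheapest reached node, relaxes its neighbours
(`cost(child) = cost(parent) − log p(child)`), and stops after L
finalizations (default 20 000) or frontier exhaustion. Min-cost
finalization (uniform-cost/Dijkstra) was chosen over literal FIFO
expansion because single-pass FIFO cost updates cannot guarantee the
per-node optimality the method's definition promises; a FIFO mode is kept
behind a flag for fidelity experiments. L counts node finalizations — the
only reading under which "the optimal path within L iterations" is
well-defined. Re-finalization is forbidden, which is optimal for
nonnegative costs. The destination is the finalized node with the best
predicted response (direction per objective); ties break by minimum cost,
then lexicographically smallest offset. If the start node is already
best, the path is a single node and the termination reason records it.
Node evaluations (one predictor call + one surrogate density per state)
are the hotspot; they are batched per neighbour list and memoized per
offset vector.

## Actionability score

`score = log A(optimal) − mean_i log A(baseline_i)` over n (default 10)
random Manhattan-shortest baseline paths between the optimal path's
endpoints — i.e. the log ratio of the optimal path's actionability to the
baselines' geometric mean. "Random shortest" means a uniformly random
interleaving of exactly the per-variable unit moves required (the only
family of monotone shortest lattice paths), sampled by shuffling the move
multiset. Both endpoints' probabilities are included in every path's
product, consistent with the definition. Consequences:

* an optimal path that moves one variable monotonically has a single
  possible baseline — itself — so its score is exactly 0;
* if the optimal path is longer than the Manhattan distance, baselines
  simply have fewer nodes and are scored as defined (no per-node
  normalization);
* a baseline node of probability zero makes the score +∞, which is
  reported with a flag rather than raised.

Comparator paths for clinician-style assessment take exactly the planned
path's step count, choosing the intervened variable uniformly at random
per step and moving it one cell in its schema-declared direction
(variables at their bound are resampled). Nine comparators per instance
by default. Predicted-response changes of planned vs comparator paths are
compared by a two-tailed Welch's t-test (unequal variances,
Welch–Satterthwaite degrees of freedom; delegated to
`scipy.stats.ttest_ind(equal_var=False)`).

## Synthetic benchmarks

`generate_synthetic3d` draws 200 points from each of three trivariate
normals and sets `y = x1 + x2 + x3 + N(0, 2)` (600 rows total; component
counts are fixed, not multinomial). The component means — (0,0,0),
(0.8,0.8,0.4), (4,4,3), identity covariances — are an artifact choice
(recorded in the generator's metadata, fully configurable): the first two
clusters overlap heavily enough that a fitted mixture resolves them as
one component (WBIC selects K = 2), while the straight line from the
high-response cluster to the low-response clusters crosses a low-density
gap, which is exactly the situation where density-aware planning beats
straight-line recourse. `generate_mixture_table` generalizes this to
arbitrary dimension, per-component categorical tables for discrete
columns, threshold rules for binary responses, and uniformly planted
missingness.

What passing on these benchmarks shows: correct mechanics (parameter
recovery, WBIC consistency, planner optimality, score laws) under data
that match the surrogate's own model family. What it does not show:
robustness to real health data — non-Gaussian marginals, correlated
covariance structure the diagonal-Σ mixture cannot express, informative
missingness, and measurement error are all absent from the generator.

## Numerical choices

* Simplex draws must sum to 1 within 1e-8 and scales be positive (checked
  on every draw at model construction).
* Densities are clipped at 1e-300 before logs; log-mean-exp and
  log-sum-exp are used everywhere probabilities combine.
* Standardize ∘ de-standardize round-trips to < 1e-12; planner costs
  recompute to < 1e-9.
* Slice sampler: Neal's stepping-out (width 1.0; 0.7 on log-scales;
  response-intercept width matched to sd(y)) with shrinkage, max 20
  step-outs, interval collapse guard at 1e-12.
* Deterministic seeds everywhere: chain seeds spawn from a root
  `SeedSequence`; per-K WBIC substreams derive as `seed·1000 + K`
  (mod 2³¹).

## Problem sizes used in the shipped checks

The test suite and the reproduction script run reduced-but-honest
configurations chosen as the smallest sizes at which each property is
stable: WBIC selection over K = 1–4 with 300 iterations (100 warm-up),
one chain; recovery and final fits with 400 iterations (150 warm-up), two
chains; planning with L ≤ 600 and 60 thinned draws. The full-size
defaults (K up to 8, iteration 1500/500, four chains, L = 20 000) are the
package defaults and run in minutes per instance.

## Known limitations

* Diagonal per-component covariance: within-component correlation is not
  modelled (mixtures compensate only partially).
* Intervenable variables must be continuous in this version; discrete
  interventions are not planned.
* The surrogate is fitted to in-sample predictions; cross-fitted
  predictions would reduce optimism but are not implemented.
* Path planning treats interventions as unconstrained unit moves; joint
  clinical constraints on intermediate states (e.g. "never raise x while
  y is high") and goal-directed (A*-style) search are out of scope.
* No causal claims: paths are probable trajectories under the observed
  joint distribution, not estimated effects of interventions.
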