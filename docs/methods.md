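# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model class

A model is a rooted expression tree over named features. Every node owns a
small vector of learnable parameters:

| node | computes | params |
| --- | --- | --- |
| feature leaf | `w*x + b` | 2 |
| `add` | `u + v + c` | 1 |
| `multiply` | `u*v + c` | 1 |
| `tanh` | `a*tanh(u) + b` | 2 |
| `exp` | `a*exp(u) + b` | 2 |
| `inverse` | `a/u + b` | 2 |
| `gaussian1` | `a*exp(-u^2) + b` | 2 |
| `gaussian2` | `a*exp(-u^2 - v^2) + b` | 2 |
| `linear` | `a*u + b` | 2 |

For classification the root value is passed through the logistic function,
so the model is a probability and the fitted tree is a maximum-likelihood
model under the Bernoulli likelihood. For regression the root value is the
prediction and the loss is mean squared error.

Two parameterization choices deserve comment.

**Binary nodes carry an output offset.** A product of two leaf affines
`(w1*x+b1)(w2*y+b2)` can never realise `x*y - c` with `c != 0` unless it
also introduces unwanted linear terms; the extra offset makes hyperbolic
("hotspot") decision boundaries expressible at the cost of one parameter.

**Function nodes scale their output, not their input.** The input centring
and scaling a `tanh` or Gaussian needs is already supplied by its child's
affine map (`a*exp(-u^2)+b` over a leaf `w*x+c` is a full four-parameter
Gaussian bump with centre `-c/w` and width `1/|w|`). The *output* affine is
what an input-affine scheme cannot replace: without it a `tanh` node's
output is confined to (-1, 1), so through the logistic wrapper the model
could never leave (0.27, 0.73), and a Gaussian-peak model could not even
express a class base rate below one half. Measured on collinear fixtures,
the input-affine alternative costs wrapped single-feature models ~2.6 BIC
units from range truncation alone.

Display (`to_string`) suppresses all affine parameters and prints
commutative arguments in lexicographic feature order, matching the
convention of printed model tables (`MAPT*(AJAP1 + SERPINE2.1)`,
`exp(-a - b)` for the bivariate Gaussian). Canonical signatures flatten
associative `add`/`multiply` chains and sort commutative arguments, so two
trees that print identically are one model for uniqueness purposes.

## Fitting

Parameters are fitted by first-order descent on the mean loss: plain
gradient descent (default for standalone fits: 1000 iterations, learning
rate 0.1, stop when the loss changes by < 1e-6) or Adam (used by the
search, 80 iterations, rate 0.1) — Adam reaches the same optima on these
few-parameter problems in far fewer iterations, which matters when a
search fits tens of thousands of candidates. Gradients are computed by an
exact reverse-mode sweep over the tree and are validated against central
finite differences on trees covering every operator.

Fitting internally standardises each feature to z-scores and folds the
standardisation back into the leaf parameters exactly on return
(`w*(x-mu)/sd + b == (w/sd)*x + (b - w*mu/sd)`). This makes the
optimisation invariant to raw feature magnitude — raw omics scales reach
10^4–10^5, where fixed-step descent otherwise diverges or stalls — without
changing the model class. Leaf weights initialise from N(0, 1/sd) in
z-space, offsets at zero, function-node output affines at identity.
The reported train loss is recomputed at the returned (raw-scale)
parameters, so BIC/AIC are exactly recomputable from
`(train_loss, n_params, n)`.

Numerical guards: `exp` arguments are capped at 60, `inverse` denominators
floored at 1e-12 in magnitude, and classification outputs clipped to
(1e-15, 1-1e-15); the backward pass propagates zero gradient wherever a
guard is active, keeping forward and backward consistent. A non-finite
loss or gradient raises a divergence signal and the candidate is discarded
by the search.

## Search

`run_search` is an evolutionary loop with a learned categorical proposal:

* **Priors**: feature weights ∝ MI(feature; target) + 0.1 nats. The
  additive smoothing dominates estimator noise when no feature carries
  signal (keeping the proposal near uniform) while still letting a
  genuinely informative feature stand out; every weight is floored at
  1e-4 after normalisation.
* **Sampling**: trees grow recursively; at each position an operator is
  drawn with probability 0.6 (depth permitting) or a leaf otherwise, with
  features drawn from the learned distribution and re-used once the
  `max_features` budget is exhausted. Defaults: `max_features=3`,
  `max_depth=3`, matching the shape of typical published signatures.
* **Generations**: population 200, 20 elites kept, 40% mutated elites
  (one edit: feature swap, operator swap, grow, prune), the rest fresh
  samples, for 30 generations. Each distinct signature is fitted once and
  cached in a hall of fame, so elites are never refitted and the best
  score is non-increasing by construction.
* **Reinforcement**: tokens (features, operators) appearing in an elite
  have their weight multiplied by 1.2 once per elite containing them,
  then re-floored and renormalised. Untouched tokens keep their relative
  order. This is a transparent stand-in for proposal learning: repeated
  reinforcement drives the distribution to a floor-bounded extreme point.
* **Ranking**: BIC by default (`2*n*L̄ + k*ln n`); ties break by fewer
  parameters, then lexicographic signature, making the output a total
  order and the whole run deterministic given the seed.
* `linear` is excluded from the sampled operator set (a pure affine is
  already expressible through leaf parameters; sampling it only pays
  penalty) but remains available to the parser and evaluator.

The ten returned models are intentionally *plural*: with BIC ranking they
are all defensible descriptions, often one mechanism represented by
several collinear features plus genuinely distinct alternatives.

## Interpretation

* **Mutual information**: plug-in estimate on an equal-frequency
  (quantile-binned) joint histogram, 10 bins per axis, natural log.
  Quantile bins make the estimate invariant to monotone transforms and
  robust to heavy-tailed scales; vectors with ≤ 10 distinct values use
  exact value bins, so MI of a discrete variable with itself is exactly
  its entropy. The plug-in bias at these settings is ≈ (B-1)²/(2n) nats
  (≈ 0.02 at n = 2000), well inside the calibration tolerances asserted
  in the tests. The same estimator serves feature priors and node signal
  flow; no bias correction is applied.
* **Signal flow**: MI between each node's activation vector and the
  target, labelled by the node's sub-expression; the root value is the
  model's overall signal. The data-processing-style statement "root MI ≥
  leaf MI" is asserted only on constructions where the target depends on
  the combination — it is not a theorem for binned estimates.
* **Partial dependence / decision boundaries** are *exact* model
  evaluations on grids (no data averaging); fixed covariates default to
  training medians, with a helper for the 0.25/0.50/0.75-quantile
  convention. The reported threshold crossing is the smallest grid value
  with probability > 0.5, so its resolution is the grid spacing.
* **Class densities**: Gaussian KDE with Silverman bandwidth per class;
  the overlap coefficient is the trapezoid integral of the pointwise
  minimum on a grid padded by three bandwidths.

## Validation

Stratified splitting allocates `round(f*n_stratum)` test rows per stratum
(exact to one sample). K-fold CV shuffles rows once by seed, stratifies by
class, and — critically — runs a completely fresh search per fold, so
feature priors, sampling state and every fitted parameter derive from that
fold's training rows only. This is what the leak check verifies: a column
equal to the target on a fold's test rows but noise on its training rows
cannot raise test AUC, because nothing upstream of prediction ever sees
test rows. The summary statistic is mean ± sd over folds of the rank-1
model's test AUC. AUC itself is the Mann–Whitney rank statistic with ties
counted one half; confusion matrices threshold at 0.5 (predict 1 when
strictly above). Multiclass targets reduce to one-vs-rest with the class
of maximal probability and lowest-index tie-break.

## Synthetic data

The generators define the study conditions under which the package's
claims are tested; they emulate the *statistical* shape of clinical omics
tables (wide, collinear, imbalanced, planted low-dimensional signal), not
their biology — no assay noise model, batch effects, cohort structure or
count distributions. Passing tests therefore demonstrate correctness of
the machinery under known generative truth, not performance on any real
dataset.

* **Planted formulas**: features iid N(0, 1) (optionally rescaled to
  omics magnitudes to exercise scale-aware fitting); the target is
  Bernoulli with probability `logreg(f(X))` of the planted tree, or
  `f(X) + N(0, σ²)` for regression. The canonical recovery condition is
  `logreg(2·x1 + 3·x2 − 1)` at n = 300 with 50 noise features. An
  optional class-balance constraint resamples up to 100 times and errors
  if unsatisfiable.
* **Collinear blocks**: one-factor construction
  `feature = sqrt(ρ)·factor + sqrt(1−ρ)·noise`, giving within-block
  correlation ρ (default 0.8, the range typical of co-regulated omics
  groups) and zero across blocks; exactly one block's factor drives the
  target through a logistic link with coefficient 0.65. That coefficient
  was chosen by an explicit regime computation: one representative per
  block is the BIC-optimal description only when the likelihood gain from
  averaging two ρ = 0.8 block-mates stays below the 2·ln n cost of the
  cheapest competing single-feature elaborations (upper bound on the
  slope), while the informative block must still dominate all noise
  features in every draw (lower bound). 0.65 is the centre of that
  window, a realistic standalone-biomarker effect (single-feature
  AUC ≈ 0.74). Block strength heterogeneity across draws can still
  occasionally promote a within-block pair over a weak single — this is
  BIC behaving correctly on an unlucky draw, not an engine failure.

## Problem sizes and determinism

Default search conditions (population 200, 30 generations, Adam 80
iterations per fit) complete a 300 × 52 search in a few seconds and the
full acceptance recomputation in about a minute on one CPU; these sizes
were chosen as the smallest at which the planted and collinear regimes are
stable across seeds. All randomness flows from a single integer seed
through `numpy.random.Generator`; per-fold and per-stage seeds derive via
`SeedSequence` spawn keys, and two runs with the same seed, configuration
and input produce byte-identical model JSON.

## Known limitations

* Inputs must be numeric; categorical covariates need prior encoding.
* No crossover/recombination; the generation scheme is elites + mutations
  + fresh samples only.
* The proposal-learning rule (multiplicative reinforcement with a floor)
  is a transparent substitute for more sophisticated schemes; no
  exploration temperature or decay is implemented.
* Signature uniqueness is structural (up to commutative/associative
  reordering), not functional: structurally distinct trees that implement
  the same function (e.g. through duplicated columns) count as different
  models and can co-occur in the returned list.
* The binned MI estimator is biased upward at small n; node-level MI
  values should be compared within a model, not across sample sizes.
* Display simplification is purely notational; no algebraic rewriting or
  symbolic simplification is performed.
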