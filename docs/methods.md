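# Methods

## Problem formulation

Each disease `i` contributes a black-box risk model `M_i : X_i → [0, 1]`
trained on its own tabular feature set. Feature sets overlap but need not
coincide; the search space is the de-duplicated union `X_Δ` in
first-appearance order across the configured disease list, which fixes the
genome layout deterministically. A candidate solution is a full assignment
over `X_Δ`; model `i` sees only the projection onto `X_i` in its training
column order, so genes outside `X_i` cannot move objective `i`.

Constraints resolve per feature, in priority order: a fixed constant
(degenerate interval, the feature is excluded from variation entirely — not
merely re-clipped after operators, so immutability is exact by
construction); an explicit window clipped to the default bounds; a
multiplicative ±10 % window around a user anchor value, again clipped (for a
negative anchor the endpoints are swapped before clipping so lower ≤ upper);
otherwise the full default bounds or discrete domain. A window wholly
outside the defaults, an anchor on a non-continuous feature, or a feature
both fixed and windowed are configuration errors raised before any
optimisation starts.

## Risk models

Preprocessing is median imputation for numeric columns (fitted on the
training split), one-hot expansion with a recorded category → column map for
declared categorical columns (an unseen category at predict time maps to an
all-zero block and is logged), and dropping of identifier columns. The
transform is idempotent: re-applying it to its own output changes nothing,
which makes the train-time and search-time paths share one code path safely.

Candidates (logistic regression, gradient boosting, XGBoost, AdaBoost,
LightGBM by default; the list is pluggable and the optimizer depends only on
the adapter contract) are trained on an 80:20 seeded split and scored with
MAE/MSE/RMSE/R², ROC AUC and accuracy. Error metrics are computed on
thresholded 0/1 predictions (threshold 0.5 by default), which makes
MAE = MSE = 1 − accuracy an exact structural identity; ROC AUC uses the
continuous scores under its standard definition and decides selection
(ties: higher accuracy, then candidate order). A single-class test split
leaves ROC AUC undefined rather than substituting a number. No resampling is
applied by default; a random-oversampling switch exists for heavily
imbalanced outcomes.

## The optimizer

Canonical NSGA-II with the usual operator suite, all configurable:
simulated binary crossover (η_c = 15) and polynomial mutation (η_m = 20,
per-gene probability 1/k over the free genes) for continuous genes; uniform
exchange and uniform re-draw for binary/categorical genes, since SBX is
undefined off the real line; crossover probability 0.9; binary tournament
under the crowded-comparison order with a seeded coin flip on full ties.
Offspring falling outside bounds are clipped to the boundary (simple,
deterministic, preserves the box constraints); duplicate genomes are
permitted. Termination is a fixed generation count; an optional
no-improvement early stop exists but is off by default. Non-dominated
sorting uses a vectorised pairwise-domination matrix (O(n²m) time, O(n²)
memory — cheap up to a few thousand members); crowding distance is the
standard normalised cuboid sum with infinite boundaries and zero
contribution from zero-range objectives. Environmental selection admits
whole fronts in rank order and truncates the straddling front by descending
crowding with a stable index tie-break, so a fixed seed reproduces runs
bit-identically. Because the per-objective best member is always
non-dominated and front 0 is always retained, every per-objective minimum is
non-increasing across generations — the elitism property the tests assert.

## Penalty ranking

The penalty `L(x) = Σ w_i P_i + λ Σ_{i<j} max(0, P_i − P_j)` ranks the final
front post hoc; it is not part of the GA fitness (the search minimises the
raw probability vector, and the scalarisation is applied to the converged
front). The gap term is deliberately asymmetric — it charges only for the
earlier-listed disease's risk exceeding the later one's — so `disease_order`
is a required explicit configuration field rather than an implicit dict
order. The n > 2 pairwise form is this package's extension; at n = 2 it
reduces exactly to `w₁P₁ + w₂P₂ + λ·max(0, P₁ − P₂)`. Ties on penalty break
by descending crowding distance, then stable front position.

## Synthetic data and oracles

The generator emulates the stroke/diabetes structure: a 15-feature union,
10 features for the stroke-like disease and 8 for the diabetes-like one,
sharing exactly {age, avg_glucose_level, bmi}; continuous features uniform
in their default bounds, discrete features uniform over their domains; one
master subject table is sampled and each disease table is a column
projection of it, so shared features are consistent across tables by
construction. Outcomes are Bernoulli under per-disease logistic truths on
features rescaled to [0, 1] (categorical features carry per-label effects).
Logistic truths were chosen because they make the end-to-end claims
analytic: the box-constrained risk minimiser puts each free feature at the
bound opposite its coefficient sign, and the true Pareto front is
computable.

The default coefficients are epidemiologically plausible: age, glucose and
BMI raise both risks (magnitudes within the generator's default [−2, 2]
range on the rescaled features), disease-specific features carry the rest,
and intercepts put prevalence near 5 % (stroke-like) and 35 %
(diabetes-like). A consequence worth stating: with agreeing signs on all
shared features the two optima are compatible and the true Pareto front
degenerates toward a single point. Genuine trade-off fronts are therefore
exercised separately with opposite-sign toy truths, where the front is a
curve traced by the conflicting feature.

`analytic_pareto` does not enumerate the full box blindly: any feature
affecting only one disease, or one that both diseases prefer moved the same
way, must sit at its joint minimiser on every Pareto point (moving it there
improves one objective without hurting the other), so only genuinely
conflicting features are grid-enumerated before the brute-force
non-domination filter. This reduction is exact for monotone separable
truths; the tests confirm it against a full 2-D grid on a conflicting toy.
A guard rejects grids above 10⁶ points.

What the generator does *not* emulate: the real datasets' marginal
distributions, feature correlations and missingness patterns (beyond an
optional null-injection switch for exercising imputation). Passing the
recovery tests therefore demonstrates that the search machinery finds the
constrained optima of a known risk surface — not that recommendations on
real clinical data are accurate or actionable; those inherit whatever the
trained models learned, including their blind spots outside the training
distribution.

## Numerical choices and problem sizes

Default test/verification scales: training tables of 2,000–5,000 rows;
convergence checks at population 500 × 40 generations; recovery checks at
population 200 × 40 generations against a tolerance of 0.05 absolute
probability (both for the distance of the best recommendation's true risks
to the analytic minima and for the nearest-neighbour distance of the front,
mapped through the truth, to the analytically sampled front). Sorting-oracle
equivalence is checked exactly on 50 random populations of up to 200 members
with 2–3 objectives. The logistic-only candidate zoo is used in the
end-to-end checks because the synthetic truth is itself logistic, making
logistic regression well-specified and the recovery target sharp; the full
zoo is exercised in the training example and unit tests.

Degenerate inputs: an all-fixed problem yields a constant trace and the
fixed point as its only recommendation; a front smaller than the requested
number of counterfactuals returns what exists and logs a warning; SBX
degenerates to cloning for identical parents; a zero objective range
contributes zero crowding.

## Known limitations

- Box bounds and fixedness are the only plausibility constraints — no
  causal or actionability model links features (glucose can move without
  insulin moving), and extreme-but-in-bounds recommendations are reported
  as the method's literal output.
- Risk models are trusted as black boxes; the optimizer will happily exploit
  regions where a model extrapolates badly. Tree ensembles in particular are
  flat outside the training hull.
- The penalty's asymmetric gap term is a presentation-layer ranking, not an
  optimisation target; two fronts with identical membership always rank the
  same way regardless of how the GA reached them.
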