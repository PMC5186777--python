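# Methods

## Model and assumptions

The network has five discrete nodes. `W`, the world state (the familiar
container with surprise contents), is a constant token: every quantity
the model computes is conditioned on it, so it contributes no probability
factor. `V_S`, the child's own visual access, is hard evidence fixed to 1
— the task protocol guarantees the child saw the contents — and likewise
contributes factor 1. The three latent/queried nodes are binary: `B_S`
(own belief), `V_O` (attributed visual access) and `B_O` (attributed
belief), all coded 1 for the true state (contents seen / true belief).

Conditionals:

* `P(B_S=0 | V_S=1, W) = δ` — the child loses the updated belief with
  small probability δ (attention/working-memory error).
* `P(V_O=0 | V_S=1) = π_V` — with probability `1−π_V` the child projects
  her own visual access onto the other agent.
* `P(B_O | V_O, B_S, W) = π_B·P(B_O|V_O,W) + (1−π_B)·P(B_O|B_S)` — a
  mixture gated by π_B. The theory branch `P(B_O|V_O,W)` mirrors the
  child's own belief-formation rule applied to the other: an agent who
  looked inside holds the true belief up to the same memory error δ; an
  agent who did not holds the default (false) belief except with
  probability ε, the attributed chance of expecting unusual contents.
  The simulation branch `P(B_O|B_S)` is a deterministic identity copy of
  the self belief — its stochasticity is already carried by the `1−π_B`
  gate weight.

Both complementary entries of every conditional are materialized into
explicit tables at build time (`build_cpts`) and checked to normalize to
1 within 1e-12; this makes enumeration trivial and catches transcription
bugs. Marginalizing `V_O` and `B_S` (four assignments) yields

    π_FB = P(B_O=0 | V_S=1, W) = π_B·π_V·(1−ε) + (1−π_B·π_V)·δ,

which splits exactly into a theory term `π_B·[π_V(1−ε) + (1−π_V)δ]` and a
simulation term `(1−π_B)·δ`. The product approximation `π_FB ≈ π_B·π_V`
has signed error `(1−π_Bπ_V)δ − π_Bπ_V·ε`, bounded in magnitude by
`max(δ, ε)`; with δ = ε = 0 the relation is exactly bilinear in
(π_B, π_V). π_FB is non-decreasing in both π_B and π_V whenever
`δ + ε < 1`, since `∂π_FB/∂(π_Bπ_V) = 1 − ε − δ`.

Parameter values of exactly 0 or 1 are legal (the noiseless limits use
them); only out-of-range values and NaN are rejected.

## Likelihood, priors, and MAP estimation

A group's data are correct/total counts `(k, n)` on three ToM-scale
tasks: diverse beliefs (DB), knowledge access (KA), and the
unexpected-contents false-belief task (FB). Children's responses are
modeled as independent Bernoulli trials with success probabilities π_B,
π_V and π_FB, giving a product-of-binomials likelihood. π_FB inside the
likelihood always uses the full closed form, never the product
approximation — the approximation is a derived insight, not the model.
Boundary counts (k = 0 or k = n) are handled exactly via the convention
0·log 0 = 0 (scipy's `xlogy`/`xlog1py`); a success probability of 0 with
k > 0 (or 1 with k < n) yields a log likelihood of −∞, which is a legal
value distinct from a validation error.

Priors are independent betas. Defaults: Beta(1, 19) on δ and ε —
asymmetric with mode 0 and mean 0.05, encoding that the task's control
questions make large error rates unlikely — and flat Beta(1, 1) on π_B
and π_V. All eight shapes are overridable through `PriorConfig`, so
sensitivity to this choice is exposed rather than hidden. The beta log
density is evaluated with explicit boundary conventions: finite at an
endpoint iff the corresponding shape equals 1 (e.g. Beta(1, 19) at 0 has
density 19), −∞ where the density vanishes.

`fit_map` maximizes the log posterior over the open hypercube via
L-BFGS-B on the logit transform of each parameter (a monotone bijection,
so the argmax is unchanged; no Jacobian is added because the MAP is
defined in the original parameterization). Transformed variables are
bounded to ±30, keeping expit within ~1e-13 of the interval boundary. Ten
restarts start from the empirical plug-in point (observed DB/KA
proportions, prior modes for δ/ε) plus a scrambled Halton
low-discrepancy set seeded by the run configuration; the start points
themselves are also candidates, so the returned MAP can never fall below
the plug-in point. Convergence tolerance is 1e-8 on the objective. MAP
coordinates within 1e-6 of 0 or 1 are reported as-is with a boundary
flag. Each group is fitted independently with identical priors; there is
no hierarchical pooling.

`fit_map_grid` is the independent oracle: exhaustive evaluation on a grid
with steps 0.01 over π_B, π_V on [0, 1] and 0.005 over δ, ε on [0, 0.25]
(the priors concentrate the noise parameters near 0). Evaluation is
vectorized in chunks over δ to bound memory; ties break toward the
lexicographically smallest (δ, ε, π_B, π_V), realized by scanning δ in
ascending order with strict-improvement updates and C-order argmax.

### Resolution of the optimizer/grid comparison

Agreement between `fit_map` and `fit_map_grid` is one grid step for π_B
and π_V. For δ and ε one step is *not* attainable even by a perfect
optimizer: rounding π_B and π_V to the 0.01 grid perturbs their product
by up to `|dprod| ≤ (0.01/2)(π_B+π_V) + 0.01²/4`, and along the level set
of π_FB the grid's conditionally optimal noise parameters shift by
`|dδ| = |dprod|·(1−ε−δ)/(1−π_Bπ_V)` and `|dε| = |dprod|·(1−ε−δ)/(π_Bπ_V)`,
which can exceed the 0.005 noise step (observed: a 0.0072 δ-discrepancy
on a dataset where the optimizer's posterior strictly beat the grid's).
`grid_agreement_tolerance` implements one step plus this propagated
bound for the noise coordinates, and the comparison additionally asserts
the optimizer's posterior value is never below the grid's.

## Synthetic data

The simulator defines the study conditions end to end. `ancestral_sample`
forward-samples the network itself (b_s, then v_o, then b_o from the
mixture CPT) with one seeded generator per call. `simulate_cohort` draws
per-child 0/1 task outcomes as independent Bernoulli trials with
probabilities π_B, π_V, π_FB, one independent sub-stream per task (so
adding a task never perturbs earlier draws); `simulate_study_counts` sums
them into binomial counts. `synthetic_tom_scale_table` assembles a
four-age-group cross-sectional study with generating parameters rising
from (π_B, π_V) = (0.45, 0.40) at the youngest group to (0.90, 0.85) at
the oldest, δ = ε = 0.02 throughout, and 25 children per task per group —
the near-chance-to-near-ceiling span and the cohort sizes typical of
ToM-scale studies of 3–6-year-olds.

What the simulator deliberately does **not** emulate: within-child
correlation across tasks (the model's own independence assumption — real
cohorts plausibly violate it), age as a continuous covariate,
longitudinal trajectories, item-level or scalogram structure, and the
diverse-desires task. Passing recovery tests therefore shows the fitting
machinery is correct *under the model's assumptions*, not that real
cohorts satisfy them; fits to real tables should be read with the
independence caveat in mind.

Because no per-child counts are published for the behavioral studies the
model addresses, the repository ships no transcribed data; all fixtures
are generated at run time from documented parameters.

## Problem sizes and numerical choices

The verification suite uses: 1000 uniform random parameter quadruples for
the closed-form/enumeration, decomposition and approximation-bound
checks (tolerance 1e-12); n = 100 000 ancestral samples per setting with
a 3-binomial-standard-error band; 100 replicate cohorts of 2000 children
per task at truth (0.8, 0.7, 0.02, 0.02) for recovery (mean within ±0.01,
RMSE ≤ 0.02); and 20 simulated datasets of 500 children per task for the
optimizer/grid cross-check. These sizes make every check sharp while the
whole suite completes in about a minute.

Known limitations: MAP point estimates only (no credible intervals or
MCMC); the five-node structure is hard-coded — no generic network engine,
and no change-of-location variant (which would need desire/action nodes);
δ and ε are only weakly identified from three counts and lean on their
priors, which is why recovery guarantees are stated for π_B and π_V.
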