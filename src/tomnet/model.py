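"""Causal Bayesian network model of children's false belief reasoning.

The model treats a child's answer on the unexpected-contents false belief
task as probabilistic inference on a five-node discrete Bayesian network
that jointly represents two internal models of belief formation: one of the
self and one of the other agent.  The nodes are

* ``W``   — the true world state (the familiar container holding surprise
  contents); fixed throughout,
* ``V_S`` — the child's own visual access to the contents (evidence,
  always 1: the protocol guarantees the child saw inside),
* ``B_S`` — the child's own belief (1 = true belief, 0 = false belief),
* ``V_O`` — the visual access the child attributes to the other agent,
* ``B_O`` — the belief the child attributes to the other agent.

Edges ``V_S -> V_O`` and ``B_S -> B_O`` encode the true-belief default:
young children tend to project their own (usually true) mental states onto
others.  Four probabilities parameterize the network:

* ``pi_B``    — degree of attributing *different* beliefs to others; gates a
  mixture between a theory-based branch (reason through the other's own
  belief-formation model) and a simulation-based branch (copy one's own
  belief onto the other),
* ``pi_V``    — degree of correctly identifying the other's visual access,
* ``delta``   — probability of failing to maintain one's updated belief,
* ``epsilon`` — attributed chance that the other expects non-default
  contents without having looked inside.

Marginalizing the latent nodes yields the closed-form false-belief success
probability

    pi_FB = pi_B * pi_V * (1 - epsilon) + (1 - pi_B * pi_V) * delta

which, for small ``delta`` and ``epsilon``, is approximately the product
``pi_B * pi_V`` — false belief understanding as a multiplicative effect of
understanding diverse beliefs and knowledge access.

The module is organised in the order the method runs: network construction
and exact inference; forward simulation of cohorts of children; binomial
likelihood, beta priors and MAP estimation; tabular I/O and the reporting
workflow behind the command-line interface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betaln, expit, gammaln, logit, xlog1py, xlogy
from scipy.stats import qmc

__all__ = [
    "ModelParams",
    "NetworkState",
    "CptSet",
    "build_cpts",
    "joint_probability",
    "predict_false_belief_enumeration",
    "predict_false_belief_closed_form",
    "strategy_decomposition",
    "approximate_false_belief",
    "SimulatedCohort",
    "ancestral_sample",
    "simulate_cohort",
    "simulate_study_counts",
    "synthetic_tom_scale_table",
    "DEFAULT_AGE_PROFILES",
    "StudyData",
    "PriorConfig",
    "FitConfig",
    "GridResolution",
    "FitResult",
    "FitError",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "fit_map",
    "fit_map_grid",
    "grid_agreement_tolerance",
    "predicted_vs_observed",
    "StudyTable",
    "StudyTableError",
    "StudyTableFormatError",
    "StudyTableSchemaError",
    "StudyTableIntegrityError",
    "RunConfig",
    "read_study_table",
    "write_study_table",
    "run_fit_command",
    "run_predict_command",
    "TASKS",
    "STUDY_TABLE_COLUMNS",
]

# --------------------------------------------------------------------------
# Configuration constants & logging
# --------------------------------------------------------------------------

logger = logging.getLogger("tomnet")

#: Tasks of the ToM scale the model addresses, in canonical order:
#: diverse beliefs, knowledge access, unexpected-contents false belief.
TASKS: tuple[str, ...] = ("DB", "KA", "FB")

#: Required header of a study table CSV, in this exact order.
STUDY_TABLE_COLUMNS: tuple[str, ...] = (
    "study_id", "group_id", "task", "n_correct", "n_total",
)

#: Tolerance below which a MAP coordinate counts as sitting on the boundary.
BOUNDARY_TOL = 1e-6

#: Absolute tolerance for internal normalization self-checks.
NORMALIZATION_TOL = 1e-12

#: Bound on the unconstrained (logit-space) optimization variables; expit of
#: the bound is within ~1e-13 of the unit-interval boundary.
LOGIT_BOUND = 30.0


class FitError(RuntimeError):
    """Raised when every optimizer restart fails to converge.

    Carries the per-restart diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics: list[dict]):
        super().__init__(message)
        self.diagnostics = diagnostics


# --------------------------------------------------------------------------
# Domain types: parameters and network states
# --------------------------------------------------------------------------

_PARAM_FIELDS = ("pi_B", "pi_V", "delta", "epsilon")


@dataclass(frozen=True)
class ModelParams:
    """The four probabilities that fully parameterize the network.

    Parameters
    ----------
    pi_B : float
        Degree of attributing different beliefs to others (gates the
        theory-based branch of the mixture).
    pi_V : float
        Degree of correctly identifying others' visual access.
    delta : float
        Probability of failing to maintain one's own updated belief.
    epsilon : float
        Attributed chance the other expects non-default contents.

    All fields must lie in the closed interval [0, 1]; the limiting values
    0 and 1 are legal (the model's noiseless limits use them), while
    out-of-range values and NaN are rejected with an error naming the field.
    """

    pi_B: float
    pi_V: float
    delta: float
    epsilon: float

    def __post_init__(self) -> None:
        for name in _PARAM_FIELDS:
            value = getattr(self, name)
            value = float(value)
            if not (0.0 <= value <= 1.0):  # also rejects NaN
                raise ValueError(
                    f"parameter {name!r} must lie in [0, 1], got {value!r}"
                )
            object.__setattr__(self, name, value)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.pi_B, self.pi_V, self.delta, self.epsilon)


@dataclass(frozen=True)
class NetworkState:
    """A joint assignment of the latent binary nodes under fixed evidence.

    ``v_s`` is always 1: every inference path in the model conditions on the
    child having seen the contents.  ``w`` is a constant token for the fixed
    world state and carries no probability.
    """

    v_o: int
    b_s: int
    b_o: int
    v_s: int = 1
    w: str = "unexpected-contents"

    def __post_init__(self) -> None:
        for name in ("v_o", "b_s", "b_o"):
            value = getattr(self, name)
            if value not in (0, 1):
                raise ValueError(
                    f"state field {name!r} must be 0 or 1, got {value!r}"
                )
            object.__setattr__(self, name, int(value))
        if self.v_s != 1:
            raise ValueError("v_s is hard evidence and must equal 1")


# --------------------------------------------------------------------------
# Conditional probability tables and exact inference
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CptSet:
    """Materialized conditional probability tables of the network.

    Attributes
    ----------
    p_bs_given_vs : ndarray, shape (2,)
        ``p_bs_given_vs[b_s]`` is P(B_S = b_s | V_S = 1, W).
    p_vo_given_vs : ndarray, shape (2,)
        ``p_vo_given_vs[v_o]`` is P(V_O = v_o | V_S = 1).
    p_bo_given_vo_bs : ndarray, shape (2, 2, 2)
        ``p_bo_given_vo_bs[v_o, b_s, b_o]`` is P(B_O = b_o | V_O, B_S, W),
        the pi_B-gated mixture of the theory branch (other's own
        belief-formation model) and the simulation branch (identity copy of
        the self belief).

    Both complementary entries of every conditional are stored explicitly
    and checked for normalization, which catches transcription bugs.
    """

    p_bs_given_vs: np.ndarray
    p_vo_given_vs: np.ndarray
    p_bo_given_vo_bs: np.ndarray

    def __post_init__(self) -> None:
        for name, table, axis in (
            ("p_bs_given_vs", self.p_bs_given_vs, 0),
            ("p_vo_given_vs", self.p_vo_given_vs, 0),
            ("p_bo_given_vo_bs", self.p_bo_given_vo_bs, 2),
        ):
            if np.any(table < 0) or np.any(table > 1):
                raise ValueError(f"CPT {name!r} has entries outside [0, 1]")
            sums = table.sum(axis=axis)
            if not np.allclose(sums, 1.0, rtol=0.0, atol=NORMALIZATION_TOL):
                raise ValueError(
                    f"CPT {name!r} does not normalize over its child: {sums!r}"
                )


def build_cpts(params: ModelParams) -> CptSet:
    """Construct the three conditional probability tables of the network.

    The self-belief table puts probability ``delta`` on having lost the
    updated (true) belief; the attributed-visual-access table puts
    ``1 - pi_V`` on wrongly projecting one's own access onto the other.  The
    other-belief table is the mixture: with weight ``pi_B`` the theory
    branch — the other's own belief-formation model, in which an agent who
    looked inside holds the true belief up to memory noise ``delta`` and an
    agent who did not holds the default (false) belief up to misconception
    chance ``epsilon`` — and with weight ``1 - pi_B`` a deterministic copy
    of the self belief.
    """
    d, e = params.delta, params.epsilon

    p_bs = np.array([d, 1.0 - d])
    p_vo = np.array([params.pi_V, 1.0 - params.pi_V])

    # theory branch, indexed [v_o, b_o]
    theory = np.array([
        [1.0 - e, e],        # V_O = 0: default (false) belief up to epsilon
        [d, 1.0 - d],        # V_O = 1: true belief up to delta
    ])
    # simulation branch: identity copy of b_s, indexed [b_s, b_o]
    copy = np.eye(2)

    p_bo = (
        params.pi_B * theory[:, np.newaxis, :]
        + (1.0 - params.pi_B) * copy[np.newaxis, :, :]
    )
    return CptSet(p_bs_given_vs=p_bs, p_vo_given_vs=p_vo, p_bo_given_vo_bs=p_bo)


def joint_probability(state: NetworkState, params: ModelParams) -> float:
    """Probability of one joint latent assignment under the evidence.

    Returns P(B_O | V_O, B_S, W) * P(V_O | V_S=1) * P(B_S | V_S=1, W) for
    the given assignment.  W is a constant token and V_S = 1 is hard
    evidence, so both contribute factor 1.
    """
    cpts = build_cpts(params)
    return float(
        cpts.p_bo_given_vo_bs[state.v_o, state.b_s, state.b_o]
        * cpts.p_vo_given_vs[state.v_o]
        * cpts.p_bs_given_vs[state.b_s]
    )


def predict_false_belief_enumeration(params: ModelParams) -> float:
    """P(B_O = 0 | V_S = 1, W) by explicit summation over the latent nodes.

    Marginalizes V_O and B_S over their four joint assignments.  Serves as
    the brute-force cross-check for the closed form.
    """
    cpts = build_cpts(params)
    total = 0.0
    for v_o in (0, 1):
        for b_s in (0, 1):
            total += (
                cpts.p_bo_given_vo_bs[v_o, b_s, 0]
                * cpts.p_vo_given_vs[v_o]
                * cpts.p_bs_given_vs[b_s]
            )
    return float(total)


def predict_false_belief_closed_form(params: ModelParams) -> float:
    """The closed-form false-belief success probability.

    pi_FB = pi_B * pi_V * (1 - epsilon) + (1 - pi_B * pi_V) * delta
    """
    prod = params.pi_B * params.pi_V
    return float(prod * (1.0 - params.epsilon) + (1.0 - prod) * params.delta)


def strategy_decomposition(params: ModelParams) -> tuple[float, float]:
    """Split pi_FB into its theory-based and simulation-based contributions.

    Returns ``(theory_term, simulation_term)`` where

    * theory_term     = pi_B * (pi_V * (1 - epsilon) + (1 - pi_V) * delta)
    * simulation_term = (1 - pi_B) * delta

    Their sum equals :func:`predict_false_belief_closed_form`.  ``pi_B``
    acts as a gate: with probability ``pi_B`` the child reasons through the
    other's own belief-formation model, otherwise she simulates with her own
    and projects the result.
    """
    theory = params.pi_B * (
        params.pi_V * (1.0 - params.epsilon) + (1.0 - params.pi_V) * params.delta
    )
    simulation = (1.0 - params.pi_B) * params.delta
    return (float(theory), float(simulation))


def approximate_false_belief(pi_B: float, pi_V: float) -> float:
    """The multiplicative approximation pi_FB ~ pi_B * pi_V.

    Exact when ``delta = epsilon = 0``.  In general the signed error is
    ``(1 - pi_B*pi_V) * delta - pi_B*pi_V * epsilon``, a convex combination
    bounded in magnitude by ``max(delta, epsilon)``.
    """
    for name, value in (("pi_B", pi_B), ("pi_V", pi_V)):
        if not (0.0 <= float(value) <= 1.0):
            raise ValueError(f"parameter {name!r} must lie in [0, 1], got {value!r}")
    return float(pi_B) * float(pi_V)


# --------------------------------------------------------------------------
# Forward simulation: network samples and synthetic cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedCohort:
    """Per-child task outcomes for one simulated group of children.

    Each child contributes one 0/1 indicator per task (success on diverse
    beliefs, knowledge access, false belief).  Outcomes are independent
    Bernoulli trials across children and across tasks, with success
    probabilities pi_B, pi_V and pi_FB respectively — the model's own
    assumption of no within-child correlation.
    """

    n_children: int
    db_success: np.ndarray
    ka_success: np.ndarray
    fb_success: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError(f"n_children must be >= 1, got {self.n_children}")
        for name in ("db_success", "ka_success", "fb_success"):
            arr = getattr(self, name)
            if arr.shape != (self.n_children,) or not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name!r} must be a 0/1 vector of length n_children")

    def counts(self) -> tuple[int, int, int]:
        """Successes per task (DB, KA, FB); each is at most n_children."""
        return (
            int(self.db_success.sum()),
            int(self.ka_success.sum()),
            int(self.fb_success.sum()),
        )


def ancestral_sample(
    params: ModelParams, n: int, seed: int
) -> list[NetworkState]:
    """Draw joint network states by forward (ancestral) sampling.

    Each state fixes ``v_s = 1`` (the protocol guarantees the child saw the
    contents), then samples ``b_s`` from P(B_S | V_S=1, W), ``v_o`` from
    P(V_O | V_S=1), and ``b_o`` from the mixture CPT given its parents.
    Identical ``(params, n, seed)`` yield identical output.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cpts = build_cpts(params)
    rng = np.random.default_rng(seed)
    # P(B_S=0)=delta, P(V_O=0)=pi_V: a uniform draw below the 0-probability
    # maps to state 0.
    b_s = (rng.random(n) >= cpts.p_bs_given_vs[0]).astype(int)
    v_o = (rng.random(n) >= cpts.p_vo_given_vs[0]).astype(int)
    p_bo0 = cpts.p_bo_given_vo_bs[v_o, b_s, 0]
    b_o = (rng.random(n) >= p_bo0).astype(int)
    return [
        NetworkState(v_o=int(v), b_s=int(bs), b_o=int(bo))
        for v, bs, bo in zip(v_o, b_s, b_o)
    ]


def simulate_cohort(params: ModelParams, n: int, seed: int) -> SimulatedCohort:
    """Simulate per-child task outcomes for a cohort of ``n`` children.

    Task success probabilities are pi_B (diverse beliefs), pi_V (knowledge
    access) and pi_FB (false belief, via the closed form).  Each task draws
    from its own child stream of the seed, so adding a task never perturbs
    earlier draws.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    pi_fb = predict_false_belief_closed_form(params)
    streams = np.random.SeedSequence(seed).spawn(3)
    outcomes = []
    for p, stream in zip((params.pi_B, params.pi_V, pi_fb), streams):
        rng = np.random.default_rng(stream)
        outcomes.append((rng.random(n) < p).astype(int))
    return SimulatedCohort(
        n_children=n,
        db_success=outcomes[0],
        ka_success=outcomes[1],
        fb_success=outcomes[2],
        seed=int(seed),
    )


def simulate_study_counts(
    params: ModelParams, n_per_task: int, seed: int, label: str = "simulated"
) -> "StudyData":
    """Synthesize correct/total counts for the three ToM-scale tasks.

    Counts are the sums of the per-child Bernoulli indicators of
    :func:`simulate_cohort`, hence Binomial(n, pi_B), Binomial(n, pi_V) and
    Binomial(n, pi_FB) with independent streams per task.
    """
    cohort = simulate_cohort(params, n_per_task, seed)
    k_db, k_ka, k_fb = cohort.counts()
    return StudyData(
        label=label,
        k_db=k_db, n_db=n_per_task,
        k_ka=k_ka, n_ka=n_per_task,
        k_fb=k_fb, n_fb=n_per_task,
    )


#: Generating parameters for a synthetic cross-sectional study with four
#: preschool age groups.  pi_B and pi_V rise from near chance toward ceiling
#: across ages, mirroring the developmental progression ToM-scale studies
#: report; delta and epsilon stay at the small control-question error rates
#: the task procedure enforces.
DEFAULT_AGE_PROFILES: dict[str, ModelParams] = {
    "age3": ModelParams(pi_B=0.45, pi_V=0.40, delta=0.02, epsilon=0.02),
    "age4": ModelParams(pi_B=0.60, pi_V=0.55, delta=0.02, epsilon=0.02),
    "age5": ModelParams(pi_B=0.80, pi_V=0.70, delta=0.02, epsilon=0.02),
    "age6": ModelParams(pi_B=0.90, pi_V=0.85, delta=0.02, epsilon=0.02),
}


def synthetic_tom_scale_table(
    seed: int,
    n_per_task: int = 25,
    profiles: dict[str, ModelParams] | None = None,
    study_id: str = "synthetic",
) -> "StudyTable":
    """Build a synthetic multi-group study table from known parameters.

    One group per profile, ``n_per_task`` children per task per group
    (cohort sizes of 20–30 per age group are typical of ToM-scale studies).
    The generating parameters being known makes end-to-end recovery
    checkable.
    """
    if profiles is None:
        profiles = DEFAULT_AGE_PROFILES
    rows = []
    for i, (group_id, params) in enumerate(profiles.items()):
        data = simulate_study_counts(
            params, n_per_task, seed=int(seed) + i, label=group_id
        )
        for task, k, n in (
            ("DB", data.k_db, data.n_db),
            ("KA", data.k_ka, data.n_ka),
            ("FB", data.k_fb, data.n_fb),
        ):
            rows.append((study_id, group_id, task, k, n))
    frame = pd.DataFrame(rows, columns=list(STUDY_TABLE_COLUMNS))
    return StudyTable(frame=frame)


# --------------------------------------------------------------------------
# Likelihood, priors and posterior
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyData:
    """Correct/total counts on the three ToM-scale tasks for one group.

    ``k_db/n_db`` — diverse beliefs, ``k_ka/n_ka`` — knowledge access,
    ``k_fb/n_fb`` — unexpected-contents false belief.  The observed
    proportions correct estimate pi_B, pi_V and pi_FB respectively.
    """

    label: str
    k_db: int
    n_db: int
    k_ka: int
    n_ka: int
    k_fb: int
    n_fb: int

    def __post_init__(self) -> None:
        for task in ("db", "ka", "fb"):
            k = getattr(self, f"k_{task}")
            n = getattr(self, f"n_{task}")
            if n < 1:
                raise ValueError(f"n_{task} must be >= 1, got {n}")
            if not (0 <= k <= n):
                raise ValueError(
                    f"k_{task} must satisfy 0 <= k <= n_{task}, got k={k}, n={n}"
                )

    def observed_proportions(self) -> tuple[float, float, float]:
        return (self.k_db / self.n_db, self.k_ka / self.n_ka, self.k_fb / self.n_fb)


@dataclass(frozen=True)
class PriorConfig:
    """Beta prior hyperparameters for the four model parameters.

    Defaults: Beta(1, 19) on delta and epsilon — asymmetric with mode at 0
    and mean 0.05, making small noise values most likely — and flat
    Beta(1, 1) on pi_B and pi_V.
    """

    a_delta: float = 1.0
    b_delta: float = 19.0
    a_eps: float = 1.0
    b_eps: float = 19.0
    a_piB: float = 1.0
    b_piB: float = 1.0
    a_piV: float = 1.0
    b_piV: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = float(getattr(self, f.name))
            if not (value > 0.0):
                raise ValueError(
                    f"prior shape {f.name!r} must be strictly positive, got {value!r}"
                )
            object.__setattr__(self, f.name, value)

    def shapes(self) -> dict[str, tuple[float, float]]:
        """Shape pairs keyed like ModelParams fields."""
        return {
            "pi_B": (self.a_piB, self.b_piB),
            "pi_V": (self.a_piV, self.b_piV),
            "delta": (self.a_delta, self.b_delta),
            "epsilon": (self.a_eps, self.b_eps),
        }

    def mode(self, param: str) -> float:
        """Prior mode for one parameter; 0.5 for the flat prior."""
        a, b = self.shapes()[param]
        if a > 1.0 and b > 1.0:
            return (a - 1.0) / (a + b - 2.0)
        if a <= 1.0 < b:
            return 0.0
        if b <= 1.0 < a:
            return 1.0
        return 0.5


def _binom_logpmf(k: float, n: float, p) -> np.ndarray | float:
    """log Binomial(k; n, p) with exact 0*log(0) = 0 boundary handling.

    The binomial coefficient is included as a constant.  Vectorizes over
    ``p``.
    """
    coeff = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    return coeff + xlogy(k, p) + xlog1py(n - k, -np.asarray(p, dtype=float))


def _beta_logpdf(x: float, a: float, b: float) -> float:
    """log Beta density with explicit boundary conventions.

    At x = 0 the density is finite iff a == 1 (value b), diverges for a < 1
    and vanishes (log = -inf) for a > 1; symmetrically at x = 1.
    """
    norm = -betaln(a, b)
    if x == 0.0:
        if a < 1.0:
            return math.inf
        if a > 1.0:
            return -math.inf
        return norm
    if x == 1.0:
        if b < 1.0:
            return math.inf
        if b > 1.0:
            return -math.inf
        return norm
    return norm + (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x)


def log_likelihood(params: ModelParams, data: StudyData) -> float:
    """Joint log likelihood of the three task counts.

    Children's responses are independent Bernoulli trials with success
    probabilities pi_B (DB), pi_V (KA) and pi_FB (FB, always via the full
    closed form — never the product approximation).  Returns -inf when a
    success probability is 0 with k > 0, or 1 with k < n; that is a legal
    likelihood value, distinct from a validation error.
    """
    pi_fb = predict_false_belief_closed_form(params)
    total = (
        _binom_logpmf(data.k_db, data.n_db, params.pi_B)
        + _binom_logpmf(data.k_ka, data.n_ka, params.pi_V)
        + _binom_logpmf(data.k_fb, data.n_fb, pi_fb)
    )
    return float(total)


def log_prior(params: ModelParams, priors: PriorConfig) -> float:
    """Sum of the four beta log densities (normalizing constants included)."""
    shapes = priors.shapes()
    return float(sum(
        _beta_logpdf(getattr(params, name), *shapes[name]) for name in _PARAM_FIELDS
    ))


def log_posterior(
    params: ModelParams, data: StudyData, priors: PriorConfig
) -> float:
    """Unnormalized log posterior: log likelihood plus log prior."""
    lp = log_prior(params, priors)
    if lp == -math.inf:
        return -math.inf
    ll = log_likelihood(params, data)
    return ll + lp


# --------------------------------------------------------------------------
# MAP estimation: multistart optimizer and exhaustive grid oracle
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_map`.

    ``n_restarts`` local searches start from a fixed scrambled
    low-discrepancy point set (plus the empirical plug-in point);
    ``tol`` is the convergence tolerance on the objective; ``seed`` makes
    the start set, and hence the whole fit, deterministic.
    """

    n_restarts: int = 10
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not (self.tol > 0.0):
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class GridResolution:
    """Grid specification for the exhaustive MAP oracle.

    Defaults: step 0.01 over pi_B and pi_V on [0, 1]; step 0.005 over delta
    and epsilon restricted to [0, noise_max] (the priors concentrate the
    noise parameters near 0, so a short range suffices).  Explicit value
    arrays override the stepped grids when given.
    """

    pi_step: float = 0.01
    noise_step: float = 0.005
    noise_max: float = 0.25
    pi_B_values: Sequence[float] | None = None
    pi_V_values: Sequence[float] | None = None
    delta_values: Sequence[float] | None = None
    epsilon_values: Sequence[float] | None = None

    def grids(self) -> dict[str, np.ndarray]:
        def stepped(stop: float, step: float) -> np.ndarray:
            return np.round(np.arange(0.0, stop + step / 2.0, step), 10)

        out = {
            "pi_B": self.pi_B_values,
            "pi_V": self.pi_V_values,
            "delta": self.delta_values,
            "epsilon": self.epsilon_values,
        }
        for name, values in out.items():
            if values is None:
                if name in ("pi_B", "pi_V"):
                    values = stepped(1.0, self.pi_step)
                else:
                    values = stepped(self.noise_max, self.noise_step)
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty grid for {name!r}")
            out[name] = arr
        return out  # type: ignore[return-value]

    def step(self, name: str) -> float:
        return self.pi_step if name in ("pi_B", "pi_V") else self.noise_step


@dataclass(frozen=True)
class FitResult:
    """Outcome of a MAP fit.

    ``fitted_proportions`` is the (pi_B, pi_V, pi_FB) triple at the MAP,
    with pi_FB computed by :func:`predict_false_belief_closed_form` on the
    MAP parameters (same code path as prediction).  ``boundary_flags``
    marks MAP coordinates sitting on the unit-interval boundary.
    """

    map_params: ModelParams
    log_posterior_at_map: float
    fitted_proportions: tuple[float, float, float]
    observed_proportions: tuple[float, float, float]
    n_restarts_converged: int
    method: str
    boundary_flags: dict[str, bool] = field(default_factory=dict)
    diagnostics: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        p = self.map_params
        return {
            "pi_B": p.pi_B,
            "pi_V": p.pi_V,
            "delta": p.delta,
            "epsilon": p.epsilon,
            "log_posterior": self.log_posterior_at_map,
            "fitted": list(self.fitted_proportions),
            "observed": list(self.observed_proportions),
            "method": self.method,
            "boundary_flags": self.boundary_flags,
        }


def _make_result(
    params: ModelParams,
    value: float,
    data: StudyData,
    method: str,
    n_converged: int,
    diagnostics: list[dict],
) -> FitResult:
    pi_fb = predict_false_belief_closed_form(params)
    flags = {
        name: bool(min(getattr(params, name), 1.0 - getattr(params, name)) < BOUNDARY_TOL)
        for name in _PARAM_FIELDS
    }
    return FitResult(
        map_params=params,
        log_posterior_at_map=float(value),
        fitted_proportions=(params.pi_B, params.pi_V, pi_fb),
        observed_proportions=data.observed_proportions(),
        n_restarts_converged=n_converged,
        method=method,
        boundary_flags=flags,
        diagnostics=diagnostics,
    )


def _plugin_start(data: StudyData, priors: PriorConfig) -> np.ndarray:
    """Empirical-proportion plug-in point, clipped to the open interval."""
    eps = 1e-4
    obs = data.observed_proportions()
    return np.array([
        float(np.clip(obs[0], eps, 1.0 - eps)),
        float(np.clip(obs[1], eps, 1.0 - eps)),
        float(np.clip(priors.mode("delta"), eps, 1.0 - eps)),
        float(np.clip(priors.mode("epsilon"), eps, 1.0 - eps)),
    ])


def fit_map(
    data: StudyData,
    priors: PriorConfig | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """MAP estimate of (pi_B, pi_V, delta, epsilon) from task counts.

    Maximizes the log posterior over the open unit hypercube by bounded
    L-BFGS-B on the logit transform of each parameter (the transform is a
    monotone bijection, so the argmax is unchanged).  Local searches start
    from the empirical plug-in point and a scrambled Halton set; the best
    terminal point wins, which in particular guarantees a log posterior at
    least as high as at the plug-in point.  Deterministic given
    ``config.seed``.

    Raises
    ------
    FitError
        If every restart fails to converge; carries per-restart diagnostics.
    """
    priors = priors or PriorConfig()
    config = config or FitConfig()

    def objective(theta: np.ndarray) -> float:
        p = expit(theta)
        params = ModelParams(*p)
        return -log_posterior(params, data, priors)

    eps = 1e-4
    starts = [_plugin_start(data, priors)]
    if config.n_restarts > 1:
        halton = qmc.Halton(d=4, scramble=True, seed=config.seed)
        pts = halton.random(config.n_restarts - 1)
        starts.extend(np.clip(pts, eps, 1.0 - eps))

    best_theta: np.ndarray | None = None
    best_value = math.inf
    n_converged = 0
    diagnostics: list[dict] = []
    bounds = [(-LOGIT_BOUND, LOGIT_BOUND)] * 4
    for i, start in enumerate(starts):
        theta0 = logit(np.asarray(start))
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": config.tol, "gtol": 1e-10, "maxiter": 500},
        )
        diagnostics.append({
            "restart": i,
            "success": bool(res.success),
            "fun": float(res.fun),
            "nit": int(res.nit),
            "message": str(res.message),
        })
        if res.success:
            n_converged += 1
        # the start itself is also a candidate, so the MAP can never fall
        # below a named plug-in point
        for theta, value in ((theta0, objective(theta0)), (res.x, float(res.fun))):
            if value < best_value:
                best_value = value
                best_theta = np.asarray(theta)

    if n_converged == 0:
        raise FitError("no optimizer restart converged", diagnostics)

    assert best_theta is not None
    params = ModelParams(*expit(best_theta))
    return _make_result(
        params, -best_value, data, "optimizer", n_converged, diagnostics
    )


def fit_map_grid(
    data: StudyData,
    priors: PriorConfig | None = None,
    resolution: GridResolution | None = None,
) -> FitResult:
    """Exhaustive-grid MAP: the independent oracle for :func:`fit_map`.

    Evaluates the log posterior at every grid point and returns the argmax;
    ties break toward the lexicographically smallest
    (delta, epsilon, pi_B, pi_V).  The evaluation is vectorized in chunks
    over delta to bound memory.
    """
    priors = priors or PriorConfig()
    resolution = resolution or GridResolution()
    grids = resolution.grids()
    g_pib, g_piv = grids["pi_B"], grids["pi_V"]
    g_d, g_e = grids["delta"], grids["epsilon"]
    shapes = priors.shapes()

    # 1-D pieces: per-parameter likelihood terms and priors
    ll_db = _binom_logpmf(data.k_db, data.n_db, g_pib)
    ll_ka = _binom_logpmf(data.k_ka, data.n_ka, g_piv)
    pr_pib = np.array([_beta_logpdf(x, *shapes["pi_B"]) for x in g_pib])
    pr_piv = np.array([_beta_logpdf(x, *shapes["pi_V"]) for x in g_piv])
    pr_d = np.array([_beta_logpdf(x, *shapes["delta"]) for x in g_d])
    pr_e = np.array([_beta_logpdf(x, *shapes["epsilon"]) for x in g_e])

    base = (
        (ll_db + pr_pib)[np.newaxis, :, np.newaxis]
        + (ll_ka + pr_piv)[np.newaxis, np.newaxis, :]
        + pr_e[:, np.newaxis, np.newaxis]
    )  # shape (n_eps, n_pib, n_piv)
    prod = g_pib[:, np.newaxis] * g_piv[np.newaxis, :]

    best_value = -math.inf
    best_index: tuple[int, int, int, int] | None = None
    for di, d in enumerate(g_d):  # ascending delta: first strict max wins
        pi_fb = prod[np.newaxis, :, :] * (1.0 - g_e[:, np.newaxis, np.newaxis]) + (
            1.0 - prod[np.newaxis, :, :]
        ) * d
        total = base + pr_d[di] + _binom_logpmf(data.k_fb, data.n_fb, pi_fb)
        flat = np.argmax(total)  # first occurrence in C order: lex (eps, piB, piV)
        value = float(total.flat[flat])
        if value > best_value:
            best_value = value
            ei, bi, vi = np.unravel_index(flat, total.shape)
            best_index = (di, int(ei), int(bi), int(vi))

    if best_index is None or best_value == -math.inf:
        # every grid point has zero posterior; report the lexicographic
        # smallest point as the documented tie-break
        best_index = (0, 0, 0, 0)
        best_value = -math.inf
    di, ei, bi, vi = best_index
    params = ModelParams(
        pi_B=float(g_pib[bi]), pi_V=float(g_piv[vi]),
        delta=float(g_d[di]), epsilon=float(g_e[ei]),
    )
    return _make_result(params, best_value, data, "grid", 0, [])


def grid_agreement_tolerance(
    name: str, params: ModelParams, resolution: GridResolution
) -> float:
    """How far the grid argmax can legitimately sit from the continuous MAP.

    For pi_B and pi_V this is one grid step.  For delta and epsilon it is
    one step **plus** the propagated pi-grid quantization: the grid rounds
    pi_B and pi_V to multiples of ``pi_step``, perturbing their product by
    up to ``|d prod| <= (pi_step/2)(pi_B + pi_V) + pi_step^2/4``, and along
    the level set of the false-belief probability

        pi_FB = prod * (1 - epsilon) + (1 - prod) * delta

    the conditionally optimal noise parameters shift by

        |d delta|   = |d prod| * (1 - epsilon - delta) / (1 - prod),
        |d epsilon| = |d prod| * (1 - epsilon - delta) / prod.

    Without this term a per-coordinate one-step comparison of optimizer and
    grid can fail even when both found their true argmax.
    """
    step = resolution.step(name)
    if name in ("pi_B", "pi_V"):
        return step
    prod = params.pi_B * params.pi_V
    dprod = (
        resolution.pi_step / 2.0 * (params.pi_B + params.pi_V)
        + resolution.pi_step ** 2 / 4.0
    )
    slack = 1.0 - params.epsilon - params.delta
    if name == "delta":
        return step + dprod * abs(slack) / max(1.0 - prod, 1e-12)
    return step + dprod * abs(slack) / max(prod, 1e-12)


def predicted_vs_observed(result: FitResult, data: StudyData) -> pd.DataFrame:
    """Three-row comparison of observed and fitted proportions per task.

    Columns: task (DB, KA, FB), observed k/n, fitted value (pi_B, pi_V,
    pi_FB at the MAP) and the absolute difference — the tabular analogue of
    a grouped observed-vs-fitted bar chart.
    """
    observed = data.observed_proportions()
    fitted = result.fitted_proportions
    return pd.DataFrame({
        "task": list(TASKS),
        "observed": [float(o) for o in observed],
        "fitted": [float(f) for f in fitted],
        "abs_diff": [abs(float(o) - float(f)) for o, f in zip(observed, fitted)],
    })


# --------------------------------------------------------------------------
# Tabular I/O, run configuration and the reporting workflow
# --------------------------------------------------------------------------


class StudyTableError(ValueError):
    """Base class for study-table input problems."""


class StudyTableFormatError(StudyTableError):
    """The file is not parseable CSV."""


class StudyTableSchemaError(StudyTableError):
    """Header or column content violates the schema."""


class StudyTableIntegrityError(StudyTableError):
    """Counts or row combinations violate table invariants."""


@dataclass(frozen=True)
class StudyTable:
    """Long-format study table: one row per (study, group, task).

    A group is fittable only when all three tasks are present; each
    (study_id, group_id) has at most one row per task and n_correct never
    exceeds n_total.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_study_frame(self.frame)

    def fittable_groups(self) -> list[tuple[str, str, StudyData]]:
        """Groups with all three tasks, as StudyData, preserving file order."""
        out = []
        for (study_id, group_id), sub in self.frame.groupby(
            ["study_id", "group_id"], sort=False
        ):
            by_task = {row.task: row for row in sub.itertuples()}
            if set(by_task) != set(TASKS):
                continue
            out.append((
                str(study_id),
                str(group_id),
                StudyData(
                    label=f"{study_id}/{group_id}",
                    k_db=int(by_task["DB"].n_correct), n_db=int(by_task["DB"].n_total),
                    k_ka=int(by_task["KA"].n_correct), n_ka=int(by_task["KA"].n_total),
                    k_fb=int(by_task["FB"].n_correct), n_fb=int(by_task["FB"].n_total),
                ),
            ))
        return out

    def incomplete_groups(self) -> list[tuple[str, str]]:
        out = []
        for (study_id, group_id), sub in self.frame.groupby(
            ["study_id", "group_id"], sort=False
        ):
            if set(sub["task"]) != set(TASKS):
                out.append((str(study_id), str(group_id)))
        return out


def _validate_study_frame(frame: pd.DataFrame) -> None:
    if list(frame.columns) != list(STUDY_TABLE_COLUMNS):
        raise StudyTableSchemaError(
            f"header must be exactly {','.join(STUDY_TABLE_COLUMNS)}, "
            f"got {','.join(map(str, frame.columns))}"
        )
    # file line numbers: data row i sits on line i + 2 (header is line 1)
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        if row.task not in TASKS:
            raise StudyTableSchemaError(
                f"line {line}: unknown task {row.task!r} (expected one of {TASKS})"
            )
        try:
            k, n = int(row.n_correct), int(row.n_total)
        except (TypeError, ValueError):
            raise StudyTableSchemaError(
                f"line {line}: n_correct and n_total must be integers"
            ) from None
        if n < 1:
            raise StudyTableIntegrityError(f"line {line}: n_total must be >= 1, got {n}")
        if not (0 <= k <= n):
            raise StudyTableIntegrityError(
                f"line {line}: n_correct={k} outside [0, n_total={n}]"
            )
    dup = frame.duplicated(subset=["study_id", "group_id", "task"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise StudyTableIntegrityError(
            f"line {line}: duplicate task row for its (study_id, group_id)"
        )


def read_study_table(path: str | Path) -> StudyTable:
    """Read and validate a study table CSV.

    The header must be exactly ``study_id,group_id,task,n_correct,n_total``.
    Malformed CSV, schema violations and integrity violations raise
    distinct error classes, each naming the offending file line.
    """
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise StudyTableFormatError(f"cannot parse {path}: {exc}") from exc
    if list(frame.columns) == list(STUDY_TABLE_COLUMNS):
        frame = frame.astype(
            {"study_id": str, "group_id": str, "task": str}
        )
        # integer parsing is validated row-wise for precise line numbers
        _validate_study_frame(frame)
        frame = frame.astype({"n_correct": int, "n_total": int})
    return StudyTable(frame=frame)


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write a study table as CSV (comma-separated, UTF-8, no index)."""
    table.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible fit run needs: priors, optimizer, seed, paths."""

    priors: PriorConfig = field(default_factory=PriorConfig)
    n_restarts: int = 10
    tol: float = 1e-8
    seed: int = 0
    out_dir: str = "results"
    make_figure: bool = False

    def fit_config(self) -> FitConfig:
        return FitConfig(n_restarts=self.n_restarts, tol=self.tol, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        priors = d.pop("priors", {})
        return cls(priors=PriorConfig(**priors), **d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_fit_command(table: StudyTable, config: RunConfig) -> dict:
    """Fit every fittable group and assemble the run report.

    Returns the report dict and writes ``results.json`` and ``summary.csv``
    (plus, when ``config.make_figure``, a grouped observed-vs-fitted bar
    figure) under ``config.out_dir``.  The report carries per-group MAP
    fits, the combined observed-vs-fitted table, and the overall linear
    correlation between observed and fitted proportions across all groups
    and tasks.  All randomness flows from the single config seed, so equal
    configs give byte-identical reports.
    """
    logger.info(
        "fit run: config_hash=%s seed=%d", config.config_hash(), config.seed
    )
    for study_id, group_id in table.incomplete_groups():
        logger.warning(
            "skipping unfittable group %s/%s (missing tasks)", study_id, group_id
        )
    groups = table.fittable_groups()
    if not groups:
        raise StudyTableIntegrityError("no fittable group: every group lacks a task")

    fit_cfg = config.fit_config()
    results: dict[str, dict] = {}
    comparison_rows: list[dict] = []
    observed_all: list[float] = []
    fitted_all: list[float] = []
    for study_id, group_id, data in groups:
        result = fit_map(data, config.priors, fit_cfg)
        logger.info(
            "group %s/%s: log_posterior=%.6f restarts_converged=%d",
            study_id, group_id,
            result.log_posterior_at_map, result.n_restarts_converged,
        )
        results[f"{study_id}/{group_id}"] = result.to_json_dict()
        comparison = predicted_vs_observed(result, data)
        for row in comparison.itertuples(index=False):
            comparison_rows.append({
                "study_id": study_id,
                "group_id": group_id,
                "task": row.task,
                "observed": row.observed,
                "fitted": row.fitted,
                "abs_diff": row.abs_diff,
            })
            observed_all.append(row.observed)
            fitted_all.append(row.fitted)

    correlation = float(np.corrcoef(observed_all, fitted_all)[0, 1])
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_groups_fitted": len(groups),
        "groups": results,
        "comparison": comparison_rows,
        "observed_fitted_correlation": correlation,
    }

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "results.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n"
    )
    pd.DataFrame(comparison_rows).to_csv(out_dir / "summary.csv", index=False)
    if config.make_figure:
        _write_comparison_figure(comparison_rows, out_dir / "observed_vs_fitted.png")
    return report


def _write_comparison_figure(rows: list[dict], path: Path) -> None:
    # lazy import keeps headless runs free of any display backend
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = pd.DataFrame(rows)
    labels = [
        f"{r}/{g}\n{t}"
        for r, g, t in zip(frame["study_id"], frame["group_id"], frame["task"])
    ]
    x = np.arange(len(frame))
    width = 0.4
    fig, ax = plt.subplots(figsize=(max(6.0, 0.6 * len(frame)), 4.0))
    ax.bar(x - width / 2, frame["observed"], width, label="observed",
           color="darkorange")
    ax.bar(x + width / 2, frame["fitted"], width, label="fitted",
           color="seagreen")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_predict_command(params: ModelParams) -> dict:
    """Evaluate the false-belief prediction for one parameter setting.

    Pure function of its inputs; returns pi_FB, the theory/simulation
    decomposition, and the product approximation with its signed error.
    """
    pi_fb = predict_false_belief_closed_form(params)
    theory, simulation = strategy_decomposition(params)
    product = approximate_false_belief(params.pi_B, params.pi_V)
    return {
        "pi_B": params.pi_B,
        "pi_V": params.pi_V,
        "delta": params.delta,
        "epsilon": params.epsilon,
        "pi_FB": pi_fb,
        "theory_term": theory,
        "simulation_term": simulation,
        "product_approximation": product,
        "approximation_error": pi_fb - product,
    }
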