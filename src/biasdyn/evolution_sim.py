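"""Between-generation evolutionary dynamics and fixation experiments.

A generation step is one full round of the within-generation choice
process; iterating it gives Wright–Fisher-like dynamics of the
phenotype composition.  Two engines step the dichotomous model: the
``full`` engine runs the exact sequential process, while the ``dmd``
engine draws the next composition directly from the class-aggregated
Dirichlet-multinomial (one beta-binomial draw per generation), which is
distributionally identical under homogeneity and orders of magnitude
faster.  A haploid Wright–Fisher simulator with the effective
parameters (s, Ne) serves as an external reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .bias_core import (
    AlphaSpec,
    BiasParams,
    ErrorModel,
    TraitPopulation,
    evaluate_bias,
    relative_success,
)
from .choice_process import run_choice_process, run_choice_process_dichotomous
from .diffusion_theory import CycleSelection  # noqa: F401  (re-export convenience)
from .polya_dmd import dmd_concentrations, sample_betabinomial_transition, sample_dmd

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentSchedule",
    "FixationOutcome",
    "EstimateWithCI",
    "FixationSummary",
    "apply_environment",
    "step_generation",
    "blended_transmission",
    "run_fixation_experiment",
    "wright_fisher_reference",
]


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Periodic (k, l) environment.

    For the first ``k`` generations of each cycle the invading phenotype
    ``A_hat`` is favoured by success bias; for the following ``l`` the
    bias optimum sits on the resident phenotype instead.  ``l = 0`` is a
    constant environment.  Every replicate starts at cycle position 1
    (invader favoured first).
    """

    k: int
    l: int = 0

    def __post_init__(self) -> None:
        if self.k < 0 or self.l < 0 or self.k + self.l < 1:
            raise ValueError("need k, l >= 0 and k + l >= 1")

    @property
    def cycle_length(self) -> int:
        return self.k + self.l

    def invader_favoured(self, t: int) -> bool:
        """Whether generation t (1-based) favours the invader."""
        return (t - 1) % self.cycle_length < self.k

    @classmethod
    def constant(cls) -> "EnvironmentSchedule":
        return cls(k=1, l=0)


def apply_environment(
    env: EnvironmentSchedule, t: int, A: float, params: BiasParams
) -> float:
    """Effective relative success ``beta_t`` of the resident phenotype.

    While the invader is favoured, ``beta_t = beta(A) / beta(A_hat) < 1``.
    When the environment flips, the bias optimum moves onto the resident
    trait, which by symmetry of the Gaussian bias swaps the two roles:
    the resident's relative success becomes the reciprocal,
    ``beta_t = beta(A_hat) / beta(A) = 1 / beta > 1``.
    """
    beta, _ = relative_success(A, params)
    return beta if env.invader_favoured(t) else 1.0 / beta


def step_generation(
    state: TraitPopulation,
    engine: str,
    env: EnvironmentSchedule,
    t: int,
    alpha: AlphaSpec | float,
    error_model: ErrorModel,
    params: BiasParams,
    rng: np.random.Generator,
) -> TraitPopulation:
    """Advance one generation with the chosen engine.

    Dichotomous states map the copiers of ``A_hat`` to the next ``X``;
    absorbed states (X in {0, N}) are returned unchanged.  Continuous
    states ignore the environment schedule (the optimum is fixed).
    """
    if state.mode == "dichotomous":
        N, X = state.N, state.X
        if X in (0, N):
            return state
        a = float(alpha.values) if isinstance(alpha, AlphaSpec) else float(alpha)
        beta_t = apply_environment(env, t, state.A, params)
        if engine == "full":
            _, K_hat = run_choice_process_dichotomous(N, X, a, beta_t, rng)
            new_X = K_hat
        elif engine == "dmd":
            new_X = sample_betabinomial_transition(N, X, a, beta_t, rng)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        return TraitPopulation.dichotomous(N, new_X, state.A)

    aspec = alpha if isinstance(alpha, AlphaSpec) else AlphaSpec.scalar(alpha)
    if engine == "full":
        _, new_traits = run_choice_process(state, aspec, error_model, params, rng)
    elif engine == "dmd":
        if aspec.structure != "scalar":
            raise ValueError("dmd engine requires a scalar alpha")
        a = float(aspec.values)
        if a >= 1.0:
            from .bias_core import draw_estimation_errors

            e = draw_estimation_errors(error_model, 1, rng)[0]
            w = evaluate_bias(state.traits + e, params)
            counts = rng.multinomial(state.N, w / w.sum())
        else:
            e = 0.0
            if error_model.sharing == "global_constant" and error_model.eta > 0:
                e = rng.normal(0.0, error_model.eta)
            counts = sample_dmd(dmd_concentrations(state, a, e, params), rng)
        new_traits = np.repeat(state.traits, counts)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return TraitPopulation.continuous(new_traits)


def blended_transmission(
    traits: TraitPopulation | np.ndarray,
    error_model: ErrorModel,
    params: BiasParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Deterministic Boyd–Richerson blending (the averaging variant).

    Each copier's new trait is the success-bias-weighted average of its
    error-perturbed estimates of all role-model traits.  With no
    estimation error all copiers acquire the same blended value; the
    operation is an averaging contraction.
    """
    values = traits.traits if isinstance(traits, TraitPopulation) else np.asarray(traits, float)
    n = values.size
    if error_model.eta > 0.0 and error_model.sharing != "none":
        if rng is None:
            raise ValueError("estimation error requires an rng")
        from .bias_core import draw_estimation_errors

        e = draw_estimation_errors(error_model, n, rng)
    else:
        e = np.zeros(n)
    estimates = values[np.newaxis, :] + e[:, np.newaxis]  # copier i's view
    weights = evaluate_bias(estimates, params)
    weights = weights / weights.sum(axis=1, keepdims=True)
    return (weights * estimates).sum(axis=1)


@dataclass(frozen=True)
class FixationOutcome:
    """One replicate: did the invader fix, and after how many generations."""

    fixed: bool
    time: int
    censored: bool = False


@dataclass(frozen=True)
class EstimateWithCI:
    """Point estimate with a confidence interval."""

    point: float
    lower: float
    upper: float
    confidence: float
    n_replicates: int

    def overlaps(self, other: "EstimateWithCI") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class FixationSummary:
    """Fixation-probability and conditional-time estimates of an experiment."""

    fixation_prob: EstimateWithCI
    conditional_time: EstimateWithCI | None
    n_censored: int
    outcomes: list[FixationOutcome] | None = None


def _summarise(
    outcomes: list[FixationOutcome], confidence: float, keep_outcomes: bool
) -> FixationSummary:
    n = len(outcomes)
    n_fixed = sum(o.fixed for o in outcomes)
    n_censored = sum(o.censored for o in outcomes)
    if n_censored:
        logger.info("%d/%d replicates censored at max_generations", n_censored, n)
    lo, hi = proportion_confint(n_fixed, n, alpha=1 - confidence, method="wilson")
    prob = EstimateWithCI(n_fixed / n, float(lo), float(hi), confidence, n)
    cond: EstimateWithCI | None = None
    if n_fixed > 0:
        times = np.array([o.time for o in outcomes if o.fixed], dtype=float)
        mean = float(times.mean())
        if n_fixed > 1:
            from scipy.stats import norm

            half = float(norm.ppf(0.5 + confidence / 2) * times.std(ddof=1) / math.sqrt(n_fixed))
        else:
            half = float("inf")
        cond = EstimateWithCI(mean, mean - half, mean + half, confidence, n_fixed)
    else:
        logger.warning("no fixations observed: conditional time undefined")
    return FixationSummary(prob, cond, n_censored, outcomes if keep_outcomes else None)


def run_fixation_experiment(
    N: int,
    alpha: float,
    A: float,
    params: BiasParams,
    env: EnvironmentSchedule | None = None,
    x0: float | None = None,
    engine: str = "dmd",
    n_replicates: int = 10_000,
    max_generations: int | None = None,
    rng: np.random.Generator | int | None = None,
    confidence: float = 0.95,
    keep_outcomes: bool = False,
) -> FixationSummary:
    """Fixation probability and conditional time of an invading ``A_hat``.

    Starts every replicate from ``X0 = round(x0 N)`` optimal-phenotype
    individuals (default a single invader) and iterates generations
    until absorption.  Replicates hitting ``max_generations`` (default
    ``100 N``) without absorbing are counted as losses and reported in
    ``n_censored``.  An integer ``rng`` seeds independent per-replicate
    streams so results are reproducible and extendable.
    """
    env = env or EnvironmentSchedule.constant()
    X0 = 1 if x0 is None else round(x0 * N)
    if not 1 <= X0 <= N:
        raise ValueError("x0 * N must round to an integer in [1, N]")
    max_generations = max_generations or 100 * N
    rngs = _replicate_rngs(rng, n_replicates)

    beta, _ = relative_success(A, params)
    constant_env = env.l == 0
    outcomes: list[FixationOutcome] = []
    for rep_rng in rngs:
        X = X0
        t = 0
        while True:
            t += 1
            beta_t = beta if constant_env else apply_environment(env, t, A, params)
            if engine == "dmd":
                X = sample_betabinomial_transition(N, X, alpha, beta_t, rep_rng)
            elif engine == "full":
                _, X = run_choice_process_dichotomous(N, X, alpha, beta_t, rep_rng)
            else:
                raise ValueError(f"unknown engine {engine!r}")
            if X == N:
                outcomes.append(FixationOutcome(True, t))
                break
            if X == 0:
                outcomes.append(FixationOutcome(False, t))
                break
            if t >= max_generations:
                outcomes.append(FixationOutcome(False, t, censored=True))
                break
    return _summarise(outcomes, confidence, keep_outcomes)


def wright_fisher_reference(
    Ne_effective: float,
    s: float,
    x0: float,
    n_replicates: int = 10_000,
    max_generations: int | None = None,
    rng: np.random.Generator | int | None = None,
    confidence: float = 0.95,
    keep_outcomes: bool = False,
) -> FixationSummary:
    """Haploid Wright–Fisher with the effective (s, Ne) parameters.

    The chain tracks a real-valued frequency: each generation samples
    ``Binomial(M, x / (x + (1 - x)(1 - s))) / M`` with ``M = round(Ne)``.
    The initial frequency may therefore lie off the M-lattice (needed to
    compare against invasions with ``x0 = 1/N`` when ``Ne << N``).
    """
    M = round(Ne_effective)
    if M < 2:
        raise ValueError("round(Ne) must be >= 2")
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie in (0, 1)")
    max_generations = max_generations or 1000 * M
    rngs = _replicate_rngs(rng, n_replicates)

    outcomes: list[FixationOutcome] = []
    for rep_rng in rngs:
        x = x0
        t = 0
        while True:
            t += 1
            p = x / (x + (1.0 - x) * (1.0 - s))
            x = rep_rng.binomial(M, p) / M
            if x == 1.0:
                outcomes.append(FixationOutcome(True, t))
                break
            if x == 0.0:
                outcomes.append(FixationOutcome(False, t))
                break
            if t >= max_generations:
                outcomes.append(FixationOutcome(False, t, censored=True))
                break
    return _summarise(outcomes, confidence, keep_outcomes)


def _replicate_rngs(
    rng: np.random.Generator | int | None, n: int
) -> list[np.random.Generator]:
    """Independent per-replicate streams from one root seed.

    Given an integer seed, replicate i always receives the same stream
    regardless of how many replicates are requested; given a Generator,
    streams are spawned from it sequentially.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        ss = np.random.SeedSequence(int(rng))
        return [np.random.default_rng(child) for child in ss.spawn(n)]
    return rng.spawn(n)
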