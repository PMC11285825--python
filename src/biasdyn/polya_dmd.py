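"""Pólya-urn equivalence and Dirichlet-multinomial (DMD) sampling.

With a shared estimation error and a homogeneous success-bias weight
``alpha < 1``, the sequential choice process is *exactly* a Pólya urn
with initial (real-valued) ball counts ``o_j = alpha' * beta(A_j + e)``
where ``alpha' = alpha / (1 - alpha)``: each copier's choice returns a
ball of the chosen colour plus one more.  The urn's final count vector
is Dirichlet-multinomial with the unnormalised weights as
concentrations, so whole generations can be sampled in one draw instead
of N sequential ones.  The total concentration carries the prestige
strength: it sets the overdispersion relative to the multinomial, which
is what produces the reduced effective population size
``Ne = alpha N + (1 - alpha)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bias_core import BiasParams, TraitPopulation, evaluate_bias

__all__ = [
    "UrnSpec",
    "DMDSpec",
    "alpha_ratio",
    "dmd_concentrations",
    "dmd_concentrations_dichotomous",
    "sample_dmd",
    "betabinomial_transition",
    "sample_betabinomial_transition",
    "dmd_loglik",
    "shuffle_test",
    "ShuffleTestResult",
]


@dataclass(frozen=True)
class UrnSpec:
    """A Pólya urn: M colours with positive initial weights, N draws."""

    initial_weights: np.ndarray
    draws: int

    @property
    def M(self) -> int:
        return self.initial_weights.size

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.initial_weights) <= 0):
            raise ValueError("urn weights must be positive")


@dataclass(frozen=True)
class DMDSpec:
    """Dirichlet-multinomial: ``trials`` draws, per-colour concentrations."""

    trials: int
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.concentrations) < 0):
            raise ValueError("concentrations must be nonnegative")


def alpha_ratio(alpha: float) -> float:
    """Success-bias weight ratio ``alpha' = alpha / (1 - alpha)``."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha' is finite only for 0 <= alpha < 1")
    return alpha / (1.0 - alpha)


def dmd_concentrations(
    traits: TraitPopulation | np.ndarray,
    alpha: float,
    shared_error: float,
    params: BiasParams,
) -> DMDSpec:
    """Urn weights / DMD concentrations for a trait population.

    Continuous: ``o_j = alpha' * beta(A_j + e)`` per role-model.
    Dichotomous: two class-aggregated concentrations, ``alpha' * X`` for
    the optimal phenotype and ``alpha' * (N - X) * beta`` for the
    suboptimal one.  ``alpha = 1`` has no finite urn weights (the
    multinomial limit, handled by callers); ``alpha = 0`` yields all-zero
    concentrations, the degenerate everybody-copies-one-model limit.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha=1 is the multinomial limit; no finite urn weights")
    ap = alpha_ratio(alpha)
    if isinstance(traits, TraitPopulation) and traits.mode == "dichotomous":
        from .bias_core import relative_success

        beta, _ = relative_success(traits.A, params)
        conc = np.array([ap * traits.X, ap * (traits.N - traits.X) * beta])
        return DMDSpec(trials=traits.N, concentrations=conc)
    values = traits.traits if isinstance(traits, TraitPopulation) else np.asarray(traits, float)
    conc = ap * evaluate_bias(values + shared_error, params)
    return DMDSpec(trials=values.size, concentrations=np.atleast_1d(conc))


def dmd_concentrations_dichotomous(
    N: int, X: int, beta: float, alpha: float
) -> tuple[float, float]:
    """Class concentrations ``(c_A_hat, c_A)`` for a dichotomous state."""
    ap = alpha_ratio(alpha)
    return ap * X, ap * (N - X) * beta


def sample_dmd(spec: DMDSpec, rng: np.random.Generator) -> np.ndarray:
    """One count vector from the DMD; entries sum to ``spec.trials``.

    Sampled as gamma-normalised Dirichlet weights followed by a
    multinomial draw.  The gamma route (rather than ``rng.dirichlet``)
    stays usable for the very small concentrations produced by strong
    prestige bias.  All-zero concentrations degenerate to all copiers
    following a single uniformly chosen role-model.
    """
    conc = np.asarray(spec.concentrations, dtype=float)
    counts = np.zeros(conc.size, dtype=np.int64)
    if conc.sum() == 0.0:
        counts[rng.integers(conc.size)] = spec.trials
        return counts
    g = rng.standard_gamma(conc)
    total = g.sum()
    if total == 0.0:  # complete underflow: mass to the largest concentration
        counts[int(np.argmax(conc))] = spec.trials
        return counts
    return rng.multinomial(spec.trials, g / total)


def betabinomial_transition(N: int, X: int, alpha: float, beta: float) -> np.ndarray:
    """Pmf of next generation's optimal-phenotype count ``X'`` (0..N).

    Class aggregation of the DMD: ``X' ~ BetaBin(N, alpha' X,
    alpha' (N - X) beta)``.  ``X = 0`` and ``X = N`` are absorbing.
    ``alpha = 1`` reduces to ``Binomial(N, X / (X + (N - X) beta))``;
    ``alpha = 0`` puts mass X/N on fixation and 1 - X/N on loss (the
    first copier chooses uniformly and everyone follows).
    """
    pmf = np.zeros(N + 1)
    if X <= 0 or X >= N:
        pmf[0 if X <= 0 else N] = 1.0
        return pmf
    if alpha >= 1.0:
        p = X / (X + (N - X) * beta)
        return stats.binom.pmf(np.arange(N + 1), N, p)
    if alpha <= 0.0:
        pmf[N] = X / N
        pmf[0] = 1.0 - X / N
        return pmf
    c_hat, c_a = dmd_concentrations_dichotomous(N, X, beta, alpha)
    return stats.betabinom.pmf(np.arange(N + 1), N, c_hat, c_a)


def sample_betabinomial_transition(
    N: int, X: int, alpha: float, beta: float, rng: np.random.Generator
) -> int:
    """One draw of ``X'`` from :func:`betabinomial_transition`."""
    if X <= 0 or X >= N:
        return X
    if alpha >= 1.0:
        return int(rng.binomial(N, X / (X + (N - X) * beta)))
    if alpha <= 0.0:
        return N if rng.random() < X / N else 0
    c_hat, c_a = dmd_concentrations_dichotomous(N, X, beta, alpha)
    g1 = rng.standard_gamma(c_hat)
    g2 = rng.standard_gamma(c_a)
    total = g1 + g2
    p = c_hat / (c_hat + c_a) if total == 0.0 else g1 / total
    return int(rng.binomial(N, p))


def dmd_loglik(counts: np.ndarray, spec: DMDSpec) -> float:
    """Exact Dirichlet-multinomial log pmf of a count vector."""
    counts = np.asarray(counts)
    conc = np.asarray(spec.concentrations, dtype=float)
    if counts.size != conc.size:
        raise ValueError("counts and concentrations must have the same length")
    if counts.sum() != spec.trials:
        raise ValueError("counts must sum to the number of trials")
    return float(stats.dirichlet_multinomial.logpmf(counts, conc, spec.trials))


@dataclass
class HistogramFit:
    """Observed vs DMD-expected distribution of copier counts.

    ``observed[k]`` is the average (over replicates) number of
    role-models that ended the choice process with exactly k copiers;
    ``expected[k]`` is the Dirichlet-multinomial prediction
    ``sum_j P(K_j = k)`` under matched concentrations.
    """

    observed: np.ndarray
    expected: np.ndarray
    n_replicates: int

    @property
    def max_abs_difference(self) -> float:
        """Largest histogram discrepancy, in role-models."""
        return float(np.abs(self.observed - self.expected).max())


def copier_count_histogram_fit(
    traits: np.ndarray,
    alpha: float,
    eta: float,
    n_replicates: int,
    params: BiasParams,
    rng: np.random.Generator,
) -> HistogramFit:
    """Validate the DMD against repeated runs of the sequential process.

    Each replicate draws one shared estimation error ``e ~ N(0, eta^2)``,
    runs the full within-generation choice process on the perturbed
    traits, and tallies how many role-models received k copiers.  The
    expected histogram under the matched beta-binomial marginals is
    accumulated alongside, so the comparison pairs each replicate with
    its own error draw.
    """
    from .bias_core import AlphaSpec, ErrorModel
    from .choice_process import run_choice_process

    traits = np.asarray(traits, dtype=float)
    n = traits.size
    alpha_spec = AlphaSpec.scalar(alpha)
    no_error = ErrorModel(0.0, "none")
    k = np.arange(n + 1)
    observed = np.zeros(n + 1)
    expected = np.zeros(n + 1)
    for _ in range(n_replicates):
        e = rng.normal(0.0, eta) if eta > 0 else 0.0
        perturbed = traits + e
        state, _ = run_choice_process(perturbed, alpha_spec, no_error, params, rng)
        observed += np.bincount(state.K.astype(int), minlength=n + 1)
        conc = alpha_ratio(alpha) * evaluate_bias(perturbed, params)
        total = conc.sum()
        expected += stats.betabinom.pmf(k[:, None], n, conc[None, :],
                                        total - conc[None, :]).sum(axis=1)
    return HistogramFit(observed / n_replicates, expected / n_replicates,
                        n_replicates)


@dataclass
class ShuffleTestResult:
    """Outcome of the parameter-shuffle likelihood test."""

    loglik_true: float
    logliks_shuffled: np.ndarray
    n_shuffles: int

    @property
    def percentile(self) -> float:
        """Fraction of shuffles whose likelihood falls below the true one."""
        return float(np.mean(self.logliks_shuffled < self.loglik_true))


def shuffle_test(
    observed_counts: np.ndarray,
    spec: DMDSpec,
    n_shuffles: int,
    rng: np.random.Generator,
) -> ShuffleTestResult:
    """Likelihood of the counts under the true vs shuffled concentrations.

    If the counts really came from the DMD with the given concentration
    vector, the true ordering should fit better (higher likelihood)
    than random permutations of the same concentrations; the returned
    percentile should then be close to 1.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    ll_true = dmd_loglik(observed_counts, spec)
    conc = np.asarray(spec.concentrations, dtype=float)
    lls = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = DMDSpec(spec.trials, rng.permutation(conc))
        lls[s] = dmd_loglik(observed_counts, shuffled)
    return ShuffleTestResult(ll_true, lls, n_shuffles)
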