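"""The within-generation sequential role-model choice process.

Copiers choose one by one (i = 1..N); each choice updates the copier
counts ``K_{i,j}`` and thereby the prestige term of every later
copier's influence.  This module runs that process exactly and provides
the exact marginal distribution of a single role-model's copier count
via the generalized-binomial dynamic-programming recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bias_core import (
    AlphaSpec,
    BiasParams,
    ErrorModel,
    TraitPopulation,
    dichotomous_choice_prob,
    draw_estimation_errors,
    evaluate_bias,
)

__all__ = [
    "ChoiceState",
    "GBDSpec",
    "MarginalPmf",
    "run_choice_process",
    "run_choice_process_dichotomous",
    "gbd_marginal_pmf",
    "expected_copiers",
]


@dataclass
class ChoiceState:
    """Final (or intermediate) state of the choice process.

    ``K[j]`` is the number of copiers that chose role-model j after
    ``step_i`` copiers have chosen; ``assignments[i-1]`` is the index
    chosen by copier i.
    """

    K: np.ndarray
    step_i: int
    assignments: np.ndarray

    def __post_init__(self) -> None:
        if self.K.sum() != self.step_i:
            raise ValueError("copier counts must sum to the number of copiers")


@dataclass(frozen=True)
class GBDSpec:
    """Parameters of a generalized binomial distribution GenBin(n, p, theta).

    ``theta`` (the correlation between successive trials) is stored for
    completeness but unused: the marginal pmf is computed by the exact
    recurrence, which does not need it.
    """

    n_trials: int
    p_first: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_first <= 1.0:
            raise ValueError("p_first must lie in [0, 1]")


@dataclass
class MarginalPmf:
    """Exact marginal pmf table Q_j(k, i) for one role-model.

    ``table[i, k]`` is P(K_{i,j} = k); row ``i`` covers k = 0..i.
    """

    table: np.ndarray  # shape (steps + 1, steps + 1), lower-triangular support

    @property
    def steps(self) -> int:
        return self.table.shape[0] - 1

    def pmf(self, step: int | None = None) -> np.ndarray:
        """Row of the table at ``step`` (default: final step), length step+1."""
        i = self.steps if step is None else step
        return self.table[i, : i + 1]


def _pick(cum_weights: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an index proportionally to weights given their cumsum."""
    u = rng.random() * cum_weights[-1]
    return int(np.searchsorted(cum_weights, u, side="right"))


def run_choice_process(
    traits: TraitPopulation | np.ndarray,
    alpha: AlphaSpec,
    error_model: ErrorModel,
    params: BiasParams,
    rng: np.random.Generator,
) -> tuple[ChoiceState, np.ndarray]:
    """Run the sequential choice process for a continuous-trait population.

    Returns the final :class:`ChoiceState` (``sum(K) = N``) and the
    next-generation trait vector: each copier inherits its chosen
    role-model's *true* trait value — estimation error affects only the
    choice, never what is transmitted.
    """
    if isinstance(traits, TraitPopulation):
        if traits.mode != "continuous":
            raise ValueError("run_choice_process expects a continuous population")
        trait_values = traits.traits
    else:
        trait_values = np.asarray(traits, dtype=float)
    n = trait_values.size
    errors = draw_estimation_errors(error_model, n, rng)

    K = np.zeros(n)
    assignments = np.empty(n, dtype=np.int64)

    homogeneous = alpha.structure == "scalar"
    shared_error = error_model.sharing in ("none", "global_constant") or error_model.eta == 0.0
    if homogeneous and shared_error:
        # fast path: numerator changes only by +(1 - alpha) at the chosen index
        a = float(alpha.values)
        numer = a * evaluate_bias(trait_values + errors[0], params)
        if numer.sum() <= 0.0 and a == 0.0:
            numer = None  # pure prestige: uniform first copier, then follow the crowd
        for i in range(n):
            if numer is None:
                weights = K if K.sum() > 0 else np.ones(n)
            else:
                weights = numer
            j = _pick(np.cumsum(weights), rng)
            assignments[i] = j
            K[j] += 1
            if numer is not None:
                numer[j] += 1.0 - a
    else:
        from .bias_core import influence_vector

        for i in range(1, n + 1):
            G = influence_vector(trait_values, K, i, alpha, errors[i - 1], params)
            j = _pick(np.cumsum(G.probabilities), rng)
            assignments[i - 1] = j
            K[j] += 1

    new_traits = trait_values[assignments]
    return ChoiceState(K=K, step_i=n, assignments=assignments), new_traits


def run_choice_process_dichotomous(
    N: int,
    X: int,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Sequential choice process for the dichotomous-trait model.

    Returns ``(K_A, K_A_hat)``: the number of copiers adopting the
    suboptimal phenotype A and the optimal phenotype A_hat; the two sum
    to N.
    """
    if not 0 <= X <= N:
        raise ValueError(f"need 0 <= X <= N, got X={X}, N={N}")
    K_A = 0
    for i in range(1, N + 1):
        p_A = dichotomous_choice_prob(N, X, K_A, i, alpha, beta)
        if rng.random() < p_A:
            K_A += 1
    return K_A, N - K_A


def gbd_marginal_pmf(
    N: int,
    focal_weight: float,
    other_weight_total: float,
    up_to_step: int | None = None,
) -> MarginalPmf:
    """Exact marginal distribution of one role-model's copier count.

    Under homogeneous ``alpha`` and shared estimation error the
    step-conditional probability that copier i chooses the focal
    role-model given k previous copiers chose it is
    ``(o_j + k) / (i - 1 + o_j + o_rest)`` with ``o_j`` the focal urn
    weight (``alpha' * beta_j``) and ``o_rest`` the total weight of the
    other role-models.  The recurrence

    ``Q(k, i) = p_i(k-1) Q(k-1, i-1) + (1 - p_i(k)) Q(k, i-1)``

    is iterated to ``up_to_step`` (default N).  Pure success bias
    (``alpha = 1``, infinite weights) has no finite urn weight: callers
    should use the binomial limit instead.
    """
    if focal_weight <= 0 or other_weight_total <= 0:
        raise ValueError("urn weights must be positive (alpha=1 has no finite "
                         "weights; use the binomial limit)")
    m = N if up_to_step is None else up_to_step
    if m > N:
        raise ValueError("up_to_step cannot exceed N")
    o = float(focal_weight)
    total = o + float(other_weight_total)
    table = np.zeros((m + 1, m + 1))
    table[0, 0] = 1.0
    k = np.arange(m + 1)
    for i in range(1, m + 1):
        p = (o + k) / (i - 1 + total)  # success prob given k previous choices
        row = table[i - 1] * (1.0 - p)
        row[1:] += table[i - 1, :-1] * p[:-1]
        row[i + 1:] = 0.0
        table[i] = row / row.sum()  # renormalise against roundoff
    return MarginalPmf(table=table)


def expected_copiers(
    traits: TraitPopulation | np.ndarray,
    alpha: AlphaSpec,
    shared_error: float,
    params: BiasParams,
) -> np.ndarray:
    """Expected final copier counts ``E[K_{N,j}] = N * G_{1,j}``.

    Valid when the error is shared by all copiers and ``alpha`` depends
    at most on the role-model.  Under homogeneous ``alpha`` this equals
    ``beta(A_j + e) / mean_beta``, the relative-fitness form.  In the
    pure-prestige limit (all ``alpha_j = 0``) every role-model expects
    exactly one copier: prestige bias is frequency independent.
    """
    if isinstance(traits, TraitPopulation):
        trait_values = traits.traits
    else:
        trait_values = np.asarray(traits, dtype=float)
    n = trait_values.size
    if alpha.structure == "per_pair":
        raise ValueError("expected_copiers requires alpha constant across copiers")
    a = alpha.for_copier(1, n)
    numer = a * evaluate_bias(trait_values + shared_error, params)
    W = numer.sum()
    if W <= 0.0:
        return np.ones(n)
    return n * numer / W
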