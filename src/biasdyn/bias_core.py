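"""Trait representations and transmission-bias primitives.

Cultural transmission is modelled as oblique copying: each of N naive
copiers adopts the trait of exactly one role-model from the previous
generation.  Two biases shape the choice:

* **success bias** — role-models whose trait lies closer to an optimum
  ``A_hat`` are preferred, mediated by a Gaussian bias function
  ``beta(A) = b * exp(-(A - A_hat)^2 / (2 J))``;
* **prestige bias** — role-models that have already attracted many
  copiers in the current round of choices are preferred.

The mixing between the two is controlled by the success-bias weight
``alpha`` in [0, 1]: ``alpha = 1`` is pure success bias, ``alpha = 0``
pure prestige bias.  This module holds the parameter containers and the
influence (choice-probability) computations shared by the continuous-
and dichotomous-trait models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "BiasParams",
    "TraitPopulation",
    "AlphaSpec",
    "ErrorModel",
    "InfluenceVector",
    "evaluate_bias",
    "relative_success",
    "influence_vector",
    "dichotomous_choice_prob",
    "draw_estimation_errors",
]


@dataclass(frozen=True)
class BiasParams:
    """Parameters of the Gaussian success-bias function.

    Attributes
    ----------
    b : float
        Bias amplitude (maximum bias value, attained at the optimum).
    J : float
        Bias width; larger J means success discriminates less between
        trait values.
    a_hat : float
        Optimal trait value ``A_hat``.
    """

    b: float = 1.0
    J: float = 1.0
    a_hat: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"bias amplitude b must be positive, got {self.b}")
        if self.J <= 0:
            raise ValueError(f"bias width J must be positive, got {self.J}")


@dataclass
class TraitPopulation:
    """One generation's trait values.

    Either a vector of continuous trait values, or a dichotomous count
    state: ``X`` individuals carry the optimal phenotype ``A_hat`` and
    ``N - X`` carry the suboptimal phenotype with trait value ``A``.
    """

    mode: Literal["continuous", "dichotomous"]
    traits: np.ndarray | None = None
    N: int | None = None
    X: int | None = None
    A: float | None = None

    @classmethod
    def continuous(cls, traits: np.ndarray) -> "TraitPopulation":
        traits = np.asarray(traits, dtype=float)
        if traits.ndim != 1 or traits.size < 1:
            raise ValueError("continuous traits must be a non-empty 1-d vector")
        return cls(mode="continuous", traits=traits, N=traits.size)

    @classmethod
    def dichotomous(cls, N: int, X: int, A: float) -> "TraitPopulation":
        if not 0 <= X <= N:
            raise ValueError(f"need 0 <= X <= N, got X={X}, N={N}")
        return cls(mode="dichotomous", N=int(N), X=int(X), A=float(A))

    @classmethod
    def standard_normal(cls, N: int, rng: np.random.Generator) -> "TraitPopulation":
        """Initial population A(0) ~ N(0, 1)."""
        return cls.continuous(rng.standard_normal(N))


@dataclass(frozen=True)
class AlphaSpec:
    """Structure of the success-bias weight ``alpha``.

    ``scalar``: one value for everyone; ``per_role_model``: a length-N
    vector ``alpha_j`` (a property of the role-model); ``per_pair``: an
    N x N matrix ``alpha[i-1, j]`` for copier i and role-model j.
    """

    structure: Literal["scalar", "per_role_model", "per_pair"]
    values: float | np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("all success-bias weights must lie in [0, 1]")
        expected_ndim = {"scalar": 0, "per_role_model": 1, "per_pair": 2}[self.structure]
        if vals.ndim != expected_ndim:
            raise ValueError(
                f"alpha structure {self.structure!r} expects ndim {expected_ndim}, "
                f"got shape {vals.shape}"
            )

    @classmethod
    def scalar(cls, alpha: float) -> "AlphaSpec":
        return cls("scalar", float(alpha))

    @classmethod
    def per_role_model(cls, alphas: np.ndarray) -> "AlphaSpec":
        return cls("per_role_model", np.asarray(alphas, dtype=float))

    @classmethod
    def per_pair(cls, alphas: np.ndarray) -> "AlphaSpec":
        return cls("per_pair", np.asarray(alphas, dtype=float))

    def for_copier(self, step_i: int, n: int) -> np.ndarray:
        """Length-``n`` vector of weights copier ``step_i`` (1-based) uses."""
        if self.structure == "scalar":
            return np.full(n, float(self.values))
        if self.structure == "per_role_model":
            vals = np.asarray(self.values, dtype=float)
            if vals.size != n:
                raise ValueError("per_role_model alpha length must equal N")
            return vals
        vals = np.asarray(self.values, dtype=float)
        return vals[step_i - 1, :]


@dataclass(frozen=True)
class ErrorModel:
    """Estimation error on role-model traits.

    Copier i perceives role-model j's trait as ``A_j + e_i`` with
    ``e_i ~ N(0, eta^2)``.  ``sharing`` controls how draws are shared:

    * ``per_copier`` — one independent draw per copier, applied to all
      role-models seen by that copier;
    * ``global_constant`` — a single draw shared by every copier (the
      homogeneity assumption under which the urn/GBD results are exact);
    * ``none`` — no error (equivalent to ``eta = 0``).
    """

    eta: float = 0.0
    sharing: Literal["per_copier", "global_constant", "none"] = "none"

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError(f"eta must be nonnegative, got {self.eta}")


@dataclass
class InfluenceVector:
    """Choice probabilities ``G_i`` over role-models plus normaliser ``W_i``."""

    probabilities: np.ndarray
    normalizer: float

    def __post_init__(self) -> None:
        p = self.probabilities
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("influence probabilities must be a distribution")


def evaluate_bias(trait_value, params: BiasParams):
    """Gaussian bias ``b * exp(-(A - A_hat)^2 / (2 J))``; accepts arrays."""
    a = np.asarray(trait_value, dtype=float)
    out = params.b * np.exp(-((a - params.a_hat) ** 2) / (2.0 * params.J))
    return out if out.ndim else float(out)


def relative_success(trait_A: float, params: BiasParams) -> tuple[float, float]:
    """Relative success ``beta = beta(A)/beta(A_hat)`` and ``s = 1 - beta``.

    ``s`` is the effective selection coefficient against the suboptimal
    phenotype; normalising by ``beta(A_hat)`` makes the dichotomous
    model independent of the amplitude ``b``.
    """
    beta = evaluate_bias(trait_A, params) / evaluate_bias(params.a_hat, params)
    return float(beta), float(1.0 - beta)


def influence_vector(
    traits: np.ndarray,
    K: np.ndarray,
    step_i: int,
    alpha: AlphaSpec,
    error: float,
    params: BiasParams,
) -> InfluenceVector:
    """Influence of every role-model in the eyes of copier ``step_i``.

    ``G_{i,j} \\propto alpha_{i,j} * beta(A_j + e_i) + (1 - alpha_{i,j}) * K_{i-1,j}``,
    normalised to sum to one.  ``K`` holds the copier counts after
    ``step_i - 1`` copiers have chosen.  If every numerator is zero
    (pure prestige before any choice has been made) the choice falls
    back to uniform 1/N, the ``alpha -> 0+`` limit for the first copier.
    """
    traits = np.asarray(traits, dtype=float)
    K = np.asarray(K, dtype=float)
    n = traits.size
    if K.size != n:
        raise ValueError("K must have the same length as traits")
    if np.any(K < 0) or K.sum() != step_i - 1:
        raise ValueError("K entries must be >= 0 and sum to step_i - 1")
    a = alpha.for_copier(step_i, n)
    numer = a * evaluate_bias(traits + error, params) + (1.0 - a) * K
    W = float(numer.sum())
    if W <= 0.0:
        return InfluenceVector(np.full(n, 1.0 / n), float(n))
    return InfluenceVector(numer / W, W)


def dichotomous_choice_prob(
    N: int,
    X: int,
    K_A: int,
    step_i: int,
    alpha: float,
    beta: float,
    error: float = 0.0,
    A: float | None = None,
    params: BiasParams | None = None,
) -> float:
    """Probability that copier ``step_i`` copies the suboptimal phenotype A.

    ``G_{i,A} = [alpha (N-X) beta + (1-alpha) K_A] /
    [alpha (N-X) beta + alpha X + (1-alpha) (i-1)]``, where ``beta`` is
    the relative success of A (``beta(A_hat) = 1`` normalisation).  The
    complement is the probability of copying ``A_hat``.

    The ``error`` hook perturbs both phenotype estimates by a shared
    ``e``; it requires the trait value ``A`` and ``params`` to recompute
    the relative success ``beta(A + e) / beta(A_hat + e)``.
    """
    if not 0 <= X <= N:
        raise ValueError(f"need 0 <= X <= N, got X={X}, N={N}")
    if not 0 <= K_A <= step_i - 1:
        raise ValueError("need 0 <= K_A <= step_i - 1")
    if error != 0.0:
        if A is None or params is None:
            raise ValueError("error hook requires trait value A and params")
        beta = float(
            evaluate_bias(A + error, params)
            / evaluate_bias(params.a_hat + error, params)
        )
    numer = alpha * (N - X) * beta + (1.0 - alpha) * K_A
    denom = alpha * (N - X) * beta + alpha * X + (1.0 - alpha) * (step_i - 1)
    if denom <= 0.0:
        # pure prestige, first copier: uniform over role-models
        return (N - X) / N
    return numer / denom


def draw_estimation_errors(
    model: ErrorModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-copier estimation errors ``e_i`` for ``n`` copiers.

    ``per_copier`` gives n independent N(0, eta^2) draws;
    ``global_constant`` one draw repeated n times; ``none`` zeros.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.sharing == "none" or model.eta == 0.0:
        return np.zeros(n)
    if model.sharing == "global_constant":
        return np.full(n, rng.normal(0.0, model.eta))
    return rng.normal(0.0, model.eta, size=n)
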