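"""Diffusion-approximation analytics and an exact Markov-chain oracle.

The dichotomous model's per-generation frequency change has mean
``s x (1 - x)`` and variance ``x (1 - x) / Ne`` with the effective
selection coefficient ``s = 1 - beta`` and effective population size
``Ne = alpha N + (1 - alpha)``: success bias plays the role of natural
selection and prestige bias the role of genetic drift.  Plugging these
into the classical diffusion results gives closed-form fixation
probabilities and quadrature expressions for the conditional fixation
time, in constant and periodically changing environments.  An exact
absorbing-Markov-chain solver over the beta-binomial transition serves
as the finite-N oracle for all of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .polya_dmd import betabinomial_transition

__all__ = [
    "EffectiveParams",
    "CycleSelection",
    "effective_params",
    "fixation_probability",
    "conditional_fixation_time",
    "cycle_selection",
    "fixation_probability_changing",
    "markov_oracle",
    "MarkovOracleResult",
]

_EXP_CLIP = 700.0  # |exponent| beyond this saturates expm1 safely


@dataclass(frozen=True)
class EffectiveParams:
    """Wright–Fisher-equivalent parameters of the cultural model."""

    s: float
    Ne: float

    @property
    def S(self) -> float:
        """Composite scaled selection ``S = Ne * s``."""
        return self.Ne * self.s


@dataclass(frozen=True)
class CycleSelection:
    """Selection accumulated over one (k, l) environmental cycle."""

    k: int
    l: int
    s_bar: float  # per-generation average selection (1/n) sum(1 - beta_t)
    Sn: float  # cumulative scaled selection Ne * n * s_bar
    betas: np.ndarray  # the per-generation beta_t series, length n

    @property
    def n(self) -> int:
        return self.k + self.l


def effective_params(alpha: float, beta: float, N: int) -> EffectiveParams:
    """``s = 1 - beta`` and ``Ne = alpha N + (1 - alpha)``.

    For N >> 1, ``Ne ~ alpha N``: prestige bias shrinks the effective
    population size and hence amplifies drift.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return EffectiveParams(s=1.0 - beta, Ne=alpha * N + (1.0 - alpha))


def _expm1_clipped(z: float) -> float:
    return float(np.expm1(np.clip(z, -_EXP_CLIP, _EXP_CLIP)))


def fixation_probability(x: float, s: float, Ne: float) -> float:
    """Kimura fixation probability with effective parameters.

    ``pi(x) = (1 - exp(-2 s Ne x)) / (1 - exp(-2 s Ne))``; the neutral
    limit ``s -> 0`` gives ``pi(x) = x``.  Evaluated with expm1 and
    exponent clipping so it stays stable for |S| up to ~1e3.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    if x in (0.0, 1.0):
        return x
    S = s * Ne
    if S == 0.0:
        return x
    return _expm1_clipped(-2.0 * S * x) / _expm1_clipped(-2.0 * S)


def conditional_fixation_time(
    x: float, s: float, Ne: float, quad_tol: float = 1e-8
) -> float:
    """Expected generations to fixation, conditioned on fixation.

    Computed from the sojourn-time (Green's function) construction for
    the diffusion with drift ``s xi (1 - xi)`` and variance
    ``xi (1 - xi) / Ne``, conditioned on absorption at 1:

    ``T(x) = J1(x) + ((1 - pi(x)) / pi(x)) * J2(x)``

    where J1 integrates the conditioned sojourn density above x and J2
    below x.  The integrands are arranged in expm1 form so no
    exponential overflows for moderate |S|; the neutral case has a
    closed form.
    """
    if not 0.0 < x < 1.0:
        raise ValueError("conditional fixation time requires 0 < x < 1")
    S = s * Ne
    if S == 0.0:
        # neutral: J1 = 2 Ne (1 - x); J2 integral solves in closed form
        j1 = 2.0 * Ne * (1.0 - x)
        j2 = 2.0 * Ne * (-x - np.log1p(-x))
        return j1 + (1.0 - x) / x * j2

    a = 2.0 * S
    denom = -_expm1_clipped(-a)  # 1 - exp(-2S)
    prefac = 2.0 * Ne / (a * denom)

    def integrand_above(xi: float) -> float:
        # u(xi) (1 - u(xi)) e^{a xi} * denom  (bounded for all S)
        return (
            (-np.expm1(np.clip(-a * xi, -_EXP_CLIP, _EXP_CLIP)))
            * (-np.expm1(np.clip(-a * (1.0 - xi), -_EXP_CLIP, _EXP_CLIP)))
            / (xi * (1.0 - xi))
        )

    ratio = (-_expm1_clipped(-a * (1.0 - x))) / (-_expm1_clipped(-a * x))

    def integrand_below(xi: float) -> float:
        # u(xi)^2 e^{a xi} e^{-a x} * denom^2 / (1 - e^{-a x}) ... bounded:
        em = np.expm1(np.clip(-a * xi, -_EXP_CLIP, _EXP_CLIP))
        return em * em * np.exp(np.clip(a * (xi - x), -_EXP_CLIP, _EXP_CLIP)) / (
            xi * (1.0 - xi)
        )

    j1, err1 = integrate.quad(
        integrand_above, x, 1.0, epsabs=quad_tol, epsrel=1e-10, limit=200
    )
    j2, err2 = integrate.quad(
        integrand_below, 0.0, x, epsabs=quad_tol, epsrel=1e-10, limit=200
    )
    T = prefac * (j1 + ratio * j2)
    if not np.isfinite(T) or T <= 0.0:
        raise RuntimeError(
            f"quadrature failed: T={T}, errors=({err1}, {err2}), S={S}, x={x}"
        )
    return float(T)


def cycle_selection(k: int, l: int, beta: float, Ne: float) -> CycleSelection:
    """Average selection over one (k, l) environmental cycle.

    For ``k`` generations the invader is favoured (``beta_t = beta``);
    for the next ``l`` the optimum sits on the resident, which under the
    symmetric swap makes the invader's disadvantage the reciprocal
    (``beta_t = 1 / beta``).  ``s_bar = (1/n) sum(1 - beta_t)``;
    ``Sn = Ne * n * s_bar``.  ``l = 0`` recovers the constant
    environment, and ``k = l`` cancels to first order in ``1 - beta``.
    """
    if k < 0 or l < 0 or k + l < 1:
        raise ValueError("need k, l >= 0 and k + l >= 1")
    betas = np.concatenate([np.full(k, beta), np.full(l, 1.0 / beta)])
    n = k + l
    s_bar = float(np.mean(1.0 - betas))
    return CycleSelection(k=k, l=l, s_bar=s_bar, Sn=Ne * n * s_bar, betas=betas)


def fixation_probability_changing(x: float, cycle: CycleSelection, Ne: float) -> float:
    """Fixation probability under a periodic (k, l) environment.

    The constant-environment formula evaluated at the cycle-average
    selection coefficient: ``pi~(x) = (1 - e^{-2 s_bar Ne x}) /
    (1 - e^{-2 s_bar Ne})``.  Reduces exactly to
    :func:`fixation_probability` when ``l = 0``.
    """
    return fixation_probability(x, cycle.s_bar, Ne)


@dataclass
class MarkovOracleResult:
    """Exact absorption quantities of the (N+1)-state beta-binomial chain."""

    fixation_prob: np.ndarray  # index X = 0..N
    conditional_time: np.ndarray  # mean generations to fixation given fixation

    def from_count(self, X: int) -> tuple[float, float]:
        return float(self.fixation_prob[X]), float(self.conditional_time[X])


def markov_oracle(N: int, alpha: float, beta: float) -> MarkovOracleResult:
    """Exact fixation probability and conditional time for every start X.

    Builds the full transition matrix from
    :func:`~biasdyn.polya_dmd.betabinomial_transition`, solves the
    absorption system for fixation probabilities, and the h-transformed
    (conditioned-on-fixation) system for mean absorption times.  Dense
    linear algebra: intended for N up to a few hundred.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    P = np.vstack([betabinomial_transition(N, X, alpha, beta) for X in range(N + 1)])
    trans = np.arange(1, N)  # transient states
    Q = P[np.ix_(trans, trans)]
    r = P[trans, N]
    h_t = np.linalg.solve(np.eye(N - 1) - Q, r)
    h = np.concatenate([[0.0], h_t, [1.0]])

    # condition on fixation: P~(x,y) = P(x,y) h_y / h_x on {h > 0}
    with np.errstate(divide="ignore", invalid="ignore"):
        Qc = Q * h_t[np.newaxis, :] / h_t[:, np.newaxis]
    t_t = np.linalg.solve(np.eye(N - 1) - Qc, np.ones(N - 1))
    t = np.concatenate([[np.nan], t_t, [0.0]])
    return MarkovOracleResult(fixation_prob=h, conditional_time=t)
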