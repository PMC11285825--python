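"""Per-copier optimal success-bias weight.

A rational copier can tune its own success-bias weight: before
choosing, copier i evaluates, for each candidate ``alpha`` on a grid,
the expected squared distance between the trait it would copy and the
optimum ``A_hat``, using its noisy estimates of the role-model traits
and the current prestige counts.  It then chooses a role-model with the
minimising weight.  Because the objective is a ratio of two functions
linear in ``alpha``, the argmin sits at an endpoint: each copier
effectively decides whether the crowd's current choices beat a fresh
success-biased draw.  Averaged over replicates this produces the
characteristic decline of the mean optimal weight with copier index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bias_core import BiasParams, evaluate_bias

__all__ = [
    "AlphaChoice",
    "AdaptiveCurves",
    "optimal_alpha",
    "run_adaptive_choice_experiment",
]


@dataclass(frozen=True)
class AlphaChoice:
    """One copier's optimised weight and the error it realised."""

    copier_index: int
    alpha_star: float
    realized_error: float


@dataclass
class AdaptiveCurves:
    """Per-copier-index curves averaged over replicates."""

    copier_index: np.ndarray
    mean_alpha_star: np.ndarray | None
    mean_abs_error: np.ndarray
    n_replicates: int
    eta: float

    def late_copier_error(self, fraction: float = 0.1) -> float:
        """Mean absolute error over the last ``fraction`` of copiers."""
        tail = max(1, int(round(fraction * self.copier_index.size)))
        return float(self.mean_abs_error[-tail:].mean())


def _objective_on_grid(
    base: np.ndarray, K: np.ndarray, sq_err: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Expected squared error at each grid alpha.

    ``f(a) = (a * sum(base * d) + (1-a) * sum(K * d)) /
    (a * sum(base) + (1-a) * sum(K))`` with ``d`` the squared distances;
    grid points with a degenerate (non-positive) normaliser fall back to
    the uniform choice, whose expected error is ``mean(d)``.
    """
    P = float(base @ sq_err)
    R = float(base.sum())
    Q = float(K @ sq_err)
    S = float(K.sum())
    denom = grid * R + (1.0 - grid) * S
    numer = grid * P + (1.0 - grid) * Q
    with np.errstate(divide="ignore", invalid="ignore"):
        f = numer / denom
    f[denom <= 0.0] = sq_err.mean()
    return f


def optimal_alpha(
    trait_estimates: np.ndarray,
    K: np.ndarray,
    params: BiasParams,
    grid_resolution: int = 101,
    weight_form: str = "bias",
) -> float:
    """Minimising success-bias weight for the next copier.

    ``weight_form="bias"`` (default) weighs candidates by the bias
    values ``beta(A_{i,j})``, consistent with the influence used for the
    actual choice; ``"literal"`` weighs by the raw trait values, which
    is only meaningful for positive traits.  Ties (within relative
    1e-9) break towards the *largest* alpha, so a copier with no usable
    crowd information relies on success bias.
    """
    trait_estimates = np.asarray(trait_estimates, dtype=float)
    K = np.asarray(K, dtype=float)
    sq_err = (params.a_hat - trait_estimates) ** 2
    if weight_form == "bias":
        base = evaluate_bias(trait_estimates, params)
    elif weight_form == "literal":
        base = trait_estimates
    else:
        raise ValueError(f"unknown weight_form {weight_form!r}")
    grid = np.linspace(0.0, 1.0, grid_resolution)
    f = _objective_on_grid(base, K, sq_err, grid)
    fmin = f.min()
    close = f <= fmin + 1e-9 * max(abs(fmin), 1e-30)
    return float(grid[np.nonzero(close)[0][-1]])


def run_adaptive_choice_experiment(
    N: int,
    eta: float,
    n_replicates: int,
    mode: str = "optimal",
    alpha_const: float | None = None,
    params: BiasParams | None = None,
    rng: np.random.Generator | int | None = None,
    grid_resolution: int = 101,
    weight_form: str = "bias",
) -> AdaptiveCurves:
    """Within-generation choice with adaptive or constant weights.

    Each replicate draws N role-model traits from N(0, 1) and runs the
    sequential choice process; every copier perceives traits with its
    own error ``e_i ~ N(0, eta^2)`` (shared across role-models).  In
    ``optimal`` mode each copier picks its weight by
    :func:`optimal_alpha` before choosing; in ``constant`` mode all use
    ``alpha_const``.  Realised error is scored against the *true*
    chosen trait, ``|A_chosen - A_hat|``, while the optimisation sees
    only the copier's estimates.
    """
    if mode not in ("optimal", "constant"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "constant" and alpha_const is None:
        raise ValueError("constant mode requires alpha_const")
    if N < 2:
        raise ValueError("need N >= 2")
    params = params or BiasParams()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    grid = np.linspace(0.0, 1.0, grid_resolution)
    sum_alpha = np.zeros(N)
    sum_err = np.zeros(N)
    for _ in range(n_replicates):
        traits = rng.standard_normal(N)
        abs_err_true = np.abs(traits - params.a_hat)
        errors = rng.normal(0.0, eta, size=N) if eta > 0 else np.zeros(N)
        K = np.zeros(N)
        for i in range(N):
            est = traits + errors[i]
            base = evaluate_bias(est, params)  # Eq-2.10-style choice weights
            if mode == "optimal":
                sq = (params.a_hat - est) ** 2
                f = _objective_on_grid(
                    base if weight_form == "bias" else est, K, sq, grid
                )
                fmin = f.min()
                close = f <= fmin + 1e-9 * max(abs(fmin), 1e-30)
                a = float(grid[np.nonzero(close)[0][-1]])
            else:
                a = float(alpha_const)
            weights = a * base + (1.0 - a) * K
            total = weights.sum()
            if total <= 0.0:
                j = int(rng.integers(N))
            else:
                cum = np.cumsum(weights)
                j = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            K[j] += 1
            sum_alpha[i] += a
            sum_err[i] += abs_err_true[j]

    return AdaptiveCurves(
        copier_index=np.arange(1, N + 1),
        mean_alpha_star=sum_alpha / n_replicates if mode == "optimal" else None,
        mean_abs_error=sum_err / n_replicates,
        n_replicates=n_replicates,
        eta=eta,
    )
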