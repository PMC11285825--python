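import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from conftest import chi2_pvalue

from biasdyn import (
    AlphaSpec,
    BiasParams,
    DMDSpec,
    ErrorModel,
    alpha_ratio,
    betabinomial_transition,
    dmd_concentrations,
    dmd_concentrations_dichotomous,
    dmd_loglik,
    evaluate_bias,
    gbd_marginal_pmf,
    run_choice_process,
    sample_betabinomial_transition,
    sample_dmd,
    shuffle_test,
)

NO_ERROR = ErrorModel(0.0, "none")


class TestConcentrations:
    def test_alpha_half_gives_raw_bias(self, params, rng):
        traits = rng.standard_normal(5)
        spec = dmd_concentrations(traits, 0.5, 0.0, params)
        np.testing.assert_allclose(spec.concentrations, evaluate_bias(traits, params))

    def test_dichotomous_substitution(self):
        c_hat, c_a = dmd_concentrations_dichotomous(1000, 1, 0.995, 0.01)
        ap = 0.01 / 0.99
        assert c_hat == pytest.approx(ap * 1)
        assert c_a == pytest.approx(ap * 999 * 0.995)

    def test_alpha_one_rejected(self, params):
        with pytest.raises(ValueError):
            dmd_concentrations(np.zeros(3), 1.0, 0.0, params)
        with pytest.raises(ValueError):
            alpha_ratio(1.0)

    def test_alpha_zero_degenerate(self, params):
        spec = dmd_concentrations(np.zeros(3), 0.0, 0.0, params)
        assert np.all(spec.concentrations == 0.0)


class TestSampleDmd:
    def test_counts_conserved(self, rng):
        spec = DMDSpec(50, np.array([0.2, 1.0, 3.0]))
        for _ in range(20):
            assert sample_dmd(spec, rng).sum() == 50

    def test_mean_is_n_times_first_influence(self, rng):
        spec = DMDSpec(40, np.array([1.0, 2.0, 5.0]))
        draws = np.array([sample_dmd(spec, rng) for _ in range(10_000)])
        expect = 40 * spec.concentrations / spec.concentrations.sum()
        se = draws.std(axis=0, ddof=1) / math.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - expect) < 3.5 * se)

    def test_degenerate_prestige_limit(self, rng):
        counts = sample_dmd(DMDSpec(9, np.zeros(4)), rng)
        assert counts.max() == 9

    def test_tiny_concentrations_survive(self, rng):
        """Strong prestige (alpha ~ 0.01) gives concentrations ~ 1e-2 per
        colour; sampling must not underflow into invalid draws."""
        spec = DMDSpec(100, np.full(200, 0.01))
        counts = sample_dmd(spec, rng)
        assert counts.sum() == 100 and np.all(counts >= 0)

    def test_marginal_matches_gbd_recurrence(self, rng):
        """DMD marginal of one colour equals the sequential-process DP pmf."""
        conc = np.array([0.8, 1.7, 0.5, 2.0])
        N = 30
        pmf = gbd_marginal_pmf(N, conc[0], conc[1:].sum()).pmf()
        draws = np.array([sample_dmd(DMDSpec(N, conc), rng)[0] for _ in range(5000)])
        observed = np.bincount(draws, minlength=N + 1).astype(float)
        assert chi2_pvalue(observed, 5000 * pmf) > 0.001


class TestSequentialEqualsDmd:
    def test_full_count_vector_distribution(self, params, rng):
        """Under homogeneous alpha and shared error the sequential choice
        process and the DMD are the same distribution (exact urn
        equivalence), checked on the full joint count vector for N=4."""
        traits = np.array([1.1, 0.6, -0.2, 1.4])
        alpha = 0.5
        spec = dmd_concentrations(traits, alpha, 0.0, params)
        reps = 6000
        freq: dict[tuple, int] = {}
        for _ in range(reps):
            state, _ = run_choice_process(traits, AlphaSpec.scalar(alpha),
                                          NO_ERROR, params, rng)
            key = tuple(int(k) for k in state.K)
            freq[key] = freq.get(key, 0) + 1
        vectors = [v for v in itertools.product(range(5), repeat=4) if sum(v) == 4]
        expected = np.array([reps * math.exp(dmd_loglik(np.array(v), spec))
                             for v in vectors])
        observed = np.array([freq.get(v, 0) for v in vectors], dtype=float)
        assert chi2_pvalue(observed, expected) > 0.001


class TestBetaBinomialTransition:
    def test_absorbing_boundaries(self):
        for X, target in ((0, 0), (10, 10)):
            pmf = betabinomial_transition(10, X, 0.5, 0.9)
            assert pmf[target] == 1.0 and pmf.sum() == 1.0

    def test_symmetric_two_copier_uniform(self):
        np.testing.assert_allclose(betabinomial_transition(2, 1, 0.5, 1.0),
                                   np.full(3, 1 / 3), rtol=1e-10)

    def test_alpha_one_binomial(self):
        pmf = betabinomial_transition(20, 5, 1.0, 0.8)
        p = 5 / (5 + 15 * 0.8)
        np.testing.assert_allclose(pmf, stats.binom.pmf(np.arange(21), 20, p))

    def test_alpha_zero_all_or_nothing(self):
        pmf = betabinomial_transition(10, 3, 0.0, 0.9)
        assert pmf[10] == pytest.approx(0.3) and pmf[0] == pytest.approx(0.7)

    @pytest.mark.parametrize("alpha", [0.01, 0.1, 0.5, 1.0])
    def test_neutral_variance_is_drift_term(self, alpha):
        """At beta=1 the variance of x' is exactly x(1-x)/Ne with
        Ne = alpha N + (1 - alpha): prestige inflates drift."""
        N, X = 200, 80
        pmf = betabinomial_transition(N, X, alpha, 1.0)
        x = np.arange(N + 1) / N
        mean = float(pmf @ x)
        var = float(pmf @ x**2 - mean**2)
        Ne = alpha * N + (1 - alpha)
        assert mean == pytest.approx(X / N, rel=1e-9)
        assert var == pytest.approx((X / N) * (1 - X / N) / Ne, rel=1e-9)

    def test_sampler_matches_pmf(self, rng):
        N, X, alpha, beta = 50, 20, 0.3, 0.9
        draws = np.array([sample_betabinomial_transition(N, X, alpha, beta, rng)
                          for _ in range(6000)])
        expected = 6000 * betabinomial_transition(N, X, alpha, beta)
        observed = np.bincount(draws, minlength=N + 1).astype(float)
        assert chi2_pvalue(observed, expected) > 0.001

    def test_class_aggregation_of_dmd(self, rng):
        """Summing DMD counts over a class of equal-concentration
        role-models reproduces the beta-binomial class transition."""
        N, X, alpha, beta = 30, 12, 0.4, 0.9
        c_hat, c_a = dmd_concentrations_dichotomous(N, X, beta, alpha)
        conc = np.concatenate([np.full(X, c_hat / X), np.full(N - X, c_a / (N - X))])
        draws = np.array([sample_dmd(DMDSpec(N, conc), rng)[:X].sum()
                          for _ in range(6000)])
        expected = 6000 * betabinomial_transition(N, X, alpha, beta)
        observed = np.bincount(draws, minlength=N + 1).astype(float)
        assert chi2_pvalue(observed, expected) > 0.001


class TestDmdLoglik:
    def test_single_colour_certain(self):
        assert dmd_loglik(np.array([5]), DMDSpec(5, np.array([2.0]))) == pytest.approx(0.0)

    def test_uniform_urn_log_third(self):
        ll = dmd_loglik(np.array([1, 1]), DMDSpec(2, np.array([1.0, 1.0])))
        assert ll == pytest.approx(math.log(1 / 3))

    def test_permutation_invariance(self, rng):
        conc = np.array([0.5, 1.5, 3.0, 0.2])
        counts = np.array([3, 1, 4, 2])
        perm = rng.permutation(4)
        assert dmd_loglik(counts, DMDSpec(10, conc)) == pytest.approx(
            dmd_loglik(counts[perm], DMDSpec(10, conc[perm])))

    def test_against_manual_gamma_formula(self):
        """Independent log-gamma evaluation of the DMD pmf."""
        conc = np.array([0.7, 2.2, 1.1])
        counts = np.array([4, 3, 3])
        n, c0 = 10, conc.sum()
        manual = (gammaln(n + 1) + gammaln(c0) - gammaln(n + c0)
                  + np.sum(gammaln(counts + conc) - gammaln(counts + 1) - gammaln(conc)))
        assert dmd_loglik(counts, DMDSpec(10, conc)) == pytest.approx(manual, rel=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            dmd_loglik(np.array([1, 1]), DMDSpec(2, np.array([1.0])))


class TestShuffleTest:
    def test_equal_concentrations_tie(self, rng):
        spec = DMDSpec(20, np.full(5, 1.3))
        res = shuffle_test(np.array([4, 4, 4, 4, 4]), spec, 50, rng)
        assert np.all(res.logliks_shuffled == res.loglik_true)

    def test_true_parameters_fit_best(self, rng):
        """Counts generated from the true concentrations: the unshuffled
        ordering should beat nearly all permutations."""
        conc = np.exp(rng.normal(0, 1.5, size=100))
        spec = DMDSpec(100, conc)
        counts = sample_dmd(spec, rng)
        res = shuffle_test(counts, spec, 500, rng)
        assert res.percentile >= 0.99

    def test_shuffled_origin_not_extreme(self, rng):
        conc = np.exp(rng.normal(0, 1.5, size=100))
        wrong = DMDSpec(100, rng.permutation(conc))
        counts = sample_dmd(wrong, rng)
        res = shuffle_test(counts, DMDSpec(100, conc), 500, rng)
        assert res.percentile < 0.99
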