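"""Core model components against hand computations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from enigma import (
    CovariateTable,
    EnigmaParameters,
    OtuTable,
    ParameterLayout,
    linear_predictor,
    log_posterior,
    log_prior,
    mixture_loglik,
    multinomial_loglik,
    softmax,
)


def enumerate_count_vectors(total, k):
    """All nonnegative integer K-vectors summing to `total` (brute-force oracle)."""
    if k == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in enumerate_count_vectors(total - first, k - 1):
            yield (first,) + rest


class TestSoftmax:
    def test_symmetry_and_shift(self):
        assert np.allclose(softmax([0.0, 0.0]), [0.5, 0.5])
        for c in (-3.0, 0.0, 7.5):
            assert np.allclose(softmax([c, c, c]), [1 / 3] * 3)

    def test_hand_example(self):
        out = softmax(np.log([1.0, 2.0, 7.0]))
        assert np.allclose(out, [0.1, 0.2, 0.7], atol=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            softmax([np.inf, 0.0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(arrays(float, 5, elements=st.floats(-50, 50)))
    def test_simplex_and_shift_invariance(self, v):
        p = softmax(v)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.allclose(softmax(v + 11.3), p, atol=1e-10)

    def test_large_logits_stable(self):
        p = softmax(np.array([1000.0, 0.0, -1000.0]))
        assert np.isfinite(p).all() and abs(p.sum() - 1.0) < 1e-12


class TestLinearPredictor:
    def test_zero_covariates_leave_baseline(self):
        g = np.array([0.5, -0.5])
        out = linear_predictor(g, np.zeros(3), np.ones((3, 2)))
        assert np.allclose(out, g)

    def test_hand_matrix_product(self):
        g = np.array([1.0, 2.0])
        B = np.array([[0.1, 0.2], [1.0, -1.0]])
        assert np.allclose(linear_predictor(g, [1, 0], B), g + B[0])
        assert np.allclose(linear_predictor(g, [1, 1], B), g + B[0] + B[1])

    def test_shape_error(self):
        with pytest.raises(ValueError):
            linear_predictor(np.zeros(2), np.zeros(2), np.ones((3, 2)))


class TestMultinomialLoglik:
    def test_degenerate_probability_floored(self):
        ll = multinomial_loglik([5, 0, 0], [1.0, 0.0, 0.0], include_constant=True)
        assert abs(ll) < 1e-9

    def test_two_outcome_hand_value(self):
        ll = multinomial_loglik([1, 1], [0.5, 0.5], include_constant=True)
        assert np.isclose(ll, np.log(0.5), atol=1e-12)

    def test_positive_count_on_zero_probability_is_finite_huge_negative(self):
        ll = multinomial_loglik([1, 1], [1.0, 0.0])
        assert ll < -600 and np.isfinite(ll)

    @pytest.mark.parametrize("total,k", [(1, 2), (3, 2), (5, 3), (4, 3)])
    def test_normalization_by_exhaustive_enumeration(self, total, k):
        rng = np.random.default_rng(total * 10 + k)
        p = rng.dirichlet(np.ones(k))
        mass = sum(
            np.exp(multinomial_loglik(np.array(y), p, include_constant=True))
            for y in enumerate_count_vectors(total, k)
        )
        assert abs(mass - 1.0) < 1e-10


class TestMixtureLoglik:
    def test_single_component_reduces_to_multinomial(self, toy_tables):
        Y, X = toy_tables
        params = EnigmaParameters(
            pi=np.array([1.0]),
            gamma=np.array([[0.2, -0.1, 0.4]]),
            B=np.array([[0.3, 0.0, -0.2]]),
        )
        expected = sum(
            multinomial_loglik(
                Y.counts[n],
                softmax(linear_predictor(params.gamma[0], X.design[n], params.B)),
                include_constant=True,
            )
            for n in range(Y.n_samples)
        )
        assert np.isclose(mixture_loglik(Y, X, params), expected, atol=1e-10)

    def test_degenerate_weight_ignores_other_component(self, toy_tables):
        Y, X = toy_tables
        g1 = np.array([[0.2, -0.1, 0.4]])
        p2 = EnigmaParameters(
            pi=np.array([1.0, 0.0]),
            gamma=np.vstack([g1, [[5.0, -3.0, 1.0]]]),
            B=np.zeros((1, 3)),
        )
        p1 = EnigmaParameters(pi=np.array([1.0]), gamma=g1, B=np.zeros((1, 3)))
        assert np.isclose(mixture_loglik(Y, X, p2), mixture_loglik(Y, X, p1), atol=1e-10)

    def test_matches_plain_arithmetic_oracle(self, toy_tables, toy_params):
        from scipy.stats import multinomial as sp_multinomial

        Y, X = toy_tables
        p = toy_params
        expected = 0.0
        for n in range(Y.n_samples):
            lik = 0.0
            for l in range(p.n_classes):
                probs = softmax(p.gamma[l] + X.design[n] @ p.B)
                lik += p.pi[l] * sp_multinomial.pmf(Y.counts[n], Y.counts[n].sum(), probs)
            expected += np.log(lik)
        assert np.isclose(mixture_loglik(Y, X, p), expected, atol=1e-8)

    def test_label_permutation_invariance(self, toy_tables, toy_params):
        Y, X = toy_tables
        p = toy_params
        swapped = EnigmaParameters(
            pi=p.pi[::-1].copy(), gamma=p.gamma[::-1].copy(), B=p.B, sigma=p.sigma, tau=p.tau
        )
        assert np.isclose(mixture_loglik(Y, X, p), mixture_loglik(Y, X, swapped), atol=1e-10)

    def test_shift_invariance_of_likelihood_but_not_posterior(self, toy_tables, toy_params):
        Y, X = toy_tables
        p = toy_params
        shifted = EnigmaParameters(
            pi=p.pi, gamma=p.gamma + 2.5, B=p.B, sigma=p.sigma, tau=p.tau
        )
        assert np.isclose(
            mixture_loglik(Y, X, p), mixture_loglik(Y, X, shifted), atol=1e-8
        )
        assert log_posterior(Y, X, shifted) < log_posterior(Y, X, p)

    def test_logsumexp_agrees_with_naive_summation(self, toy_tables, toy_params):
        from scipy.stats import multinomial as sp_multinomial

        Y, X = toy_tables
        p = toy_params
        naive = 0.0
        for n in range(Y.n_samples):
            naive += np.log(
                sum(
                    p.pi[l]
                    * sp_multinomial.pmf(
                        Y.counts[n], Y.counts[n].sum(), softmax(p.gamma[l] + X.design[n] @ p.B)
                    )
                    for l in range(p.n_classes)
                )
            )
        assert np.isclose(mixture_loglik(Y, X, p), naive, atol=1e-8)


class TestLogPrior:
    def test_uniform_dirichlet_constant(self):
        from scipy.special import gammaln

        for pi in ([0.5, 0.5], [0.2, 0.3, 0.5]):
            L = len(pi)
            p = EnigmaParameters(
                pi=np.array(pi), gamma=np.zeros((L, 2)), B=np.zeros((1, 2))
            )
            gauss = -0.5 * 1 * 2 * np.log(2 * np.pi) - 0.5 * L * 2 * np.log(2 * np.pi)
            assert np.isclose(log_prior(p), gauss + gammaln(L), atol=1e-12)

    def test_single_beta_closed_form(self):
        p = EnigmaParameters(
            pi=np.array([1.0]), gamma=np.zeros((1, 2)), B=np.array([[1.0, 0.0]])
        )
        gamma_term = -0.5 * 2 * np.log(2 * np.pi)
        beta_term = -np.log(2 * np.pi) - 0.5
        assert np.isclose(log_prior(p), gamma_term + beta_term, atol=1e-12)

    def test_invalid_scales(self):
        with pytest.raises(ValueError):
            EnigmaParameters(pi=np.array([1.0]), gamma=np.zeros((1, 2)), sigma=-1.0)


class TestLogPosterior:
    def test_composition_of_verified_parts(self, toy_tables, toy_params):
        Y, X = toy_tables
        assert np.isclose(
            log_posterior(Y, X, toy_params),
            mixture_loglik(Y, X, toy_params) + log_prior(toy_params),
            atol=1e-12,
        )

    def test_prior_independent_of_data(self, toy_tables, toy_params):
        Y, X = toy_tables
        Y2 = OtuTable(counts=2 * Y.counts)
        lp1 = log_posterior(Y, X, toy_params) - mixture_loglik(Y, X, toy_params)
        lp2 = log_posterior(Y2, X, toy_params) - mixture_loglik(Y2, X, toy_params)
        assert np.isclose(lp1, lp2, atol=1e-12)


class TestContainers:
    def test_count_table_validation(self):
        with pytest.raises(ValueError):
            OtuTable(counts=np.array([[1, -1]]))
        with pytest.raises(ValueError):
            OtuTable(counts=np.array([[0, 0], [1, 2]]))
        with pytest.raises(ValueError):
            OtuTable(counts=np.array([[1.5, 2.0]]))
        with pytest.raises(ValueError):
            OtuTable(counts=np.array([[1, 2]]), sample_ids=("a",), taxon_ids=("t", "t"))

    def test_design_must_be_binary(self):
        with pytest.raises(ValueError):
            CovariateTable(design=np.array([[0.5]]))

    def test_relative_abundances_rows_sum_to_one(self):
        Y = OtuTable(counts=np.array([[2, 3], [1, 0]]))
        assert np.allclose(Y.relative_abundances().sum(axis=1), 1.0)


class TestParameterLayout:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(1, 4), st.integers(2, 5), st.integers(0, 3), st.booleans())
    def test_pack_unpack_roundtrip(self, L, K, M, estimate_scales):
        rng = np.random.default_rng(L * 100 + K * 10 + M)
        layout = ParameterLayout(L=L, K=K, M=M, estimate_scales=estimate_scales)
        params = EnigmaParameters(
            pi=rng.dirichlet(np.ones(L)),
            gamma=rng.standard_normal((L, K)),
            B=rng.standard_normal((M, K)),
            sigma=0.7,
            tau=1.3,
        )
        back = layout.unpack(layout.pack(params), sigma=0.7, tau=1.3)
        assert np.allclose(back.pi, params.pi, atol=1e-12)
        assert np.allclose(back.gamma, params.gamma, atol=1e-12)
        assert np.allclose(back.B, params.B, atol=1e-12)
        assert np.isclose(back.sigma, 0.7) and np.isclose(back.tau, 1.3)

    def test_dim_is_free_parameter_count(self):
        assert ParameterLayout(L=3, K=100, M=1).dim == 2 + 300 + 100
        assert ParameterLayout(L=3, K=100, M=0).dim == 2 + 300
        assert ParameterLayout(L=2, K=5, M=1, estimate_scales=True).dim == 1 + 10 + 5 + 2
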