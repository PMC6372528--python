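"""Likelihood machinery, EM estimation, and decoding for the covariate HMM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from sathmm import (
    EMControl,
    EmissionParams,
    HMMParams,
    InitialLogitModel,
    TransitionLogitModel,
    e_step,
    fit_em,
    m_step,
    params_from_probs,
    sequence_loglik,
    softmax,
    viterbi,
)
from sathmm.data_model import design_matrices
from sathmm.iohmm import SIGMA_FLOOR, fit_weighted_multinomial
from sathmm.reference import model_b_params

from conftest import brute_force_loglik, brute_force_viterbi, random_params


def _intercept_designs(n, T, q_init=0, q_trans=0):
    X = np.ones((n, 1 + q_init))
    H = np.ones((n, T, 1 + q_trans))
    return X, H


class TestSoftmax:
    def test_symmetry_and_closed_form(self):
        np.testing.assert_allclose(softmax([0.0, 0.0, 0.0]), np.full(3, 1 / 3))
        np.testing.assert_allclose(softmax([np.log(2), 0.0]), [2 / 3, 1 / 3])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.floats(-100, 100),
    )
    def test_shift_invariance_and_normalization(self, logits, c):
        base = softmax(logits)
        shifted = softmax(np.asarray(logits) + c)
        np.testing.assert_allclose(base, shifted, atol=1e-12)
        assert base.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(base > 0)


class TestLogitBlocks:
    def test_zero_coefficients_give_uniform(self):
        params = random_params(np.random.default_rng(0), 3)
        zero = HMMParams(
            emissions=params.emissions,
            init=InitialLogitModel(np.zeros((1, 3))),
            trans=TransitionLogitModel(np.zeros((3, 1, 3))),
        )
        np.testing.assert_allclose(zero.init.probs(np.ones(1)), np.full(3, 1 / 3))
        np.testing.assert_allclose(
            zero.trans.matrices(np.ones(1)), np.full((3, 3), 1 / 3)
        )

    def test_intercept_logits_reproduce_reported_initial_probs(self):
        pi = model_b_params().init.probs(np.ones(1))
        np.testing.assert_allclose(pi, [0.36, 0.45, 0.19], atol=1e-12)

    def test_intercept_logits_reproduce_probability_rows(self):
        probs = [0.93, 0.05, 0.02]
        params = params_from_probs(
            mu=[0.2, 0.5, 0.8], sigma=[0.1, 0.1, 0.1],
            init_probs=[1 / 3] * 3,
            trans_probs=[probs, [0.04, 0.92, 0.04], [0.04, 0.06, 0.90]],
        )
        np.testing.assert_allclose(
            params.trans.matrices(np.ones(1))[0], probs, atol=1e-12
        )

    def test_rows_sum_to_one_for_any_coefficients(self):
        rng = np.random.default_rng(3)
        params = random_params(rng, 3, trans_covariates=("f", "r"))
        H = np.column_stack([np.ones(20), rng.random((20, 2))])
        P = params.trans.matrices(H)
        np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        params = random_params(np.random.default_rng(0), 3)
        with pytest.raises(ValueError, match="design width"):
            params.init.probs(np.ones(4))
        with pytest.raises(ValueError, match="design width"):
            params.trans.matrices(np.ones(2))

    def test_reference_column_must_be_zero(self):
        with pytest.raises(ValueError, match="reference"):
            InitialLogitModel(np.array([[1.0, 0.5, 0.0]]), (), 0)

    def test_reference_class_invariance(self):
        """Shifting every logit column by a constant vector (re-pinning the
        reference to another class) leaves all probabilities unchanged."""
        rng = np.random.default_rng(7)
        params = random_params(rng, 3, trans_covariates=("f",))
        coef = params.trans.coef.copy()
        # re-express relative to class 2
        coef2 = coef - coef[:, :, [2]]
        other = TransitionLogitModel(coef2, ("f",), reference=2)
        H = np.column_stack([np.ones(5), rng.random(5)])
        np.testing.assert_allclose(
            params.trans.matrices(H), other.matrices(H), atol=1e-12
        )


class TestSequenceLoglik:
    def test_single_state_is_sum_of_gaussian_logpdfs(self):
        params = params_from_probs([0.5], [0.1], [1.0], [[1.0]])
        y = np.array([0.4, 0.5, 0.6])
        X, H = _intercept_designs(1, 3)
        expected = norm.logpdf(y, 0.5, 0.1).sum()
        assert sequence_loglik(params, y, X[0], H[0]) == pytest.approx(expected)

    def test_single_item_marginal_mixture(self):
        params = model_b_params()
        y = np.array([0.5])
        X, H = _intercept_designs(1, 1)
        pi = params.init.probs(X[0])
        expected = np.log(
            np.sum(pi * norm.pdf(0.5, params.emissions.mu, params.emissions.sigma))
        )
        assert sequence_loglik(params, y, X[0], H[0]) == pytest.approx(expected)

    @pytest.mark.parametrize("n_states,T", [(2, 5), (3, 6)])
    def test_forward_matches_path_enumeration(self, n_states, T):
        rng = np.random.default_rng(11)
        params = random_params(rng, n_states, trans_covariates=("f",))
        y = rng.uniform(0.1, 1.0, T)
        I = np.ones(1)
        H = np.column_stack([np.ones(T), rng.random(T)])
        expected = brute_force_loglik(params, y, I, H)
        got = sequence_loglik(params, y, I, H)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_finite_at_sigma_floor(self):
        params = params_from_probs(
            [1 / 7, 0.5, 0.9], [SIGMA_FLOOR, 0.1, 0.1],
            [1 / 3] * 3, np.full((3, 3), 1 / 3),
        )
        y = np.full(10, 1.0)  # far from the floored state
        X, H = _intercept_designs(1, 10)
        assert np.isfinite(sequence_loglik(params, y, X[0], H[0]))

    def test_empty_sequence_rejected(self):
        params = model_b_params()
        with pytest.raises(ValueError):
            sequence_loglik(params, [], np.ones(1), np.ones((0, 1)))


class TestEStep:
    def test_gamma_normalization_and_xi_marginalization(self):
        rng = np.random.default_rng(5)
        params = random_params(rng, 3, trans_covariates=("f",))
        n, T = 12, 8
        y = rng.uniform(0.1, 1.0, (n, T))
        X = np.ones((n, 1))
        H = np.dstack([np.ones((n, T)), rng.random((n, T))])
        gamma, xi, ll = e_step(params, y, X, H)
        np.testing.assert_allclose(gamma.sum(axis=2), 1.0, atol=1e-10)
        # xi summed over the destination reproduces gamma at the origin item
        np.testing.assert_allclose(xi.sum(axis=3), gamma[:, :-1, :], atol=1e-10)
        np.testing.assert_allclose(xi.sum(axis=2), gamma[:, 1:, :], atol=1e-10)
        assert np.isfinite(ll)

    def test_single_state_gamma_is_one(self):
        params = params_from_probs([0.5], [0.1], [1.0], [[1.0]])
        y = np.random.default_rng(0).uniform(0, 1, (4, 6))
        X, H = _intercept_designs(4, 6)
        gamma, _, _ = e_step(params, y, X, H)
        np.testing.assert_allclose(gamma, 1.0)

    def test_separated_emissions_give_one_hot_gamma(self):
        params = params_from_probs(
            [0.1, 0.5, 0.9], [SIGMA_FLOOR, SIGMA_FLOOR, SIGMA_FLOOR],
            [1 / 3] * 3, np.full((3, 3), 1 / 3),
        )
        y = np.array([[0.1, 0.9, 0.5, 0.1]])
        X, H = _intercept_designs(1, 4)
        gamma, _, _ = e_step(params, y, X, H)
        np.testing.assert_allclose(gamma[0], np.eye(3)[[0, 2, 1, 0]], atol=1e-8)

    def test_total_loglik_is_sum_of_sequence_logliks(self):
        rng = np.random.default_rng(9)
        params = random_params(rng, 2)
        y = rng.uniform(0.1, 1.0, (5, 4))
        X, H = _intercept_designs(5, 4)
        _, _, total = e_step(params, y, X, H)
        per_seq = sum(
            sequence_loglik(params, y[i], X[i], H[i]) for i in range(5)
        )
        assert total == pytest.approx(per_seq, abs=1e-9)


class TestWeightedMultinomial:
    def test_intercept_only_closed_form(self):
        W = np.array([[2.0, 1.0, 1.0], [2.0, 3.0, 1.0]])
        coef = fit_weighted_multinomial(np.ones((2, 1)), W, reference=0)
        p = softmax(coef[0])
        np.testing.assert_allclose(p, W.sum(axis=0) / W.sum(), atol=1e-12)

    def test_matches_sklearn_on_expanded_data(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(21)
        n, M = 300, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        true = rng.normal(size=(3, M))
        true[:, 0] = 0
        W = softmax(X @ true, axis=1)  # fractional class memberships
        coef = fit_weighted_multinomial(X, W, reference=0, ridge=1e-6)
        # expand: one row per (observation, class) with weight W[i, m]
        Xe = np.repeat(X[:, 1:], M, axis=0)
        ye = np.tile(np.arange(M), n)
        we = W.ravel()
        lr = sklearn.LogisticRegression(C=1e6, max_iter=2000, tol=1e-10)
        lr.fit(Xe, ye, sample_weight=we)
        ours = softmax(X @ coef, axis=1)
        theirs = lr.predict_proba(X[:, 1:])
        np.testing.assert_allclose(ours, theirs, atol=1e-4)


class TestMStep:
    def test_known_states_give_per_state_sample_moments(self):
        rng = np.random.default_rng(2)
        n, T, M = 20, 10, 2
        y = rng.uniform(0, 1, (n, T))
        states = rng.integers(0, M, (n, T))
        gamma = np.eye(M)[states]
        xi = gamma[:, :-1, :, None] * gamma[:, 1:, None, :]
        X, H = _intercept_designs(n, T)
        params0 = random_params(rng, M)
        new = m_step(gamma, xi, y, X, H, params0)
        for m in range(M):
            np.testing.assert_allclose(
                new.emissions.mu[m], y[states == m].mean(), atol=1e-12
            )

    def test_intercept_only_transitions_equal_normalized_counts(self):
        rng = np.random.default_rng(4)
        n, T, M = 15, 8, 3
        gamma = rng.dirichlet(np.ones(M), size=(n, T))
        xi = gamma[:, :-1, :, None] * gamma[:, 1:, None, :]
        y = rng.uniform(0, 1, (n, T))
        X, H = _intercept_designs(n, T)
        params0 = random_params(rng, M)
        new = m_step(gamma, xi, y, X, H, params0)
        P = new.trans.matrices(np.ones(1))
        counts = xi.sum(axis=(0, 1))
        np.testing.assert_allclose(
            P, counts / counts.sum(axis=1, keepdims=True), atol=1e-10
        )


class TestFitEM:
    def test_single_state_converges_to_pooled_moments(self, small_cohort):
        _, dataset, _ = small_cohort
        fit = fit_em(dataset, 1, control=EMControl(max_iter=5))
        y = dataset.scaled_matrix().ravel()
        assert fit.params.emissions.mu[0] == pytest.approx(y.mean(), abs=1e-10)
        assert fit.params.emissions.sigma[0] == pytest.approx(y.std(), abs=1e-10)

    def test_loglik_trace_is_monotone(self, small_cohort):
        _, dataset, _ = small_cohort
        fit = fit_em(
            dataset, 3, init_covariates=("d", "p", "dp"),
            trans_covariates=("f", "r", "fr"),
            control=EMControl(max_iter=40, tol=1e-10, seed=0),
        )
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) >= -1e-8 * (1 + np.abs(trace[:-1])))

    def test_recovers_generating_emissions(self, study_cohort):
        """3-state EM at study size recovers the generating means within
        0.02 and intercept-only diagonal transitions within 0.03."""
        config, dataset, _ = study_cohort
        from sathmm.effects import relabel_states

        fit = fit_em(dataset, 3, control=EMControl(seed=1, n_restarts=2))
        rel, _ = relabel_states(fit.params)
        np.testing.assert_allclose(
            rel.emissions.mu, [0.19, 0.51, 0.86], atol=0.02
        )
        P = rel.trans.matrices(np.ones(1))
        np.testing.assert_allclose(
            np.diag(P), [0.93, 0.92, 0.90], atol=0.03
        )

    def test_serialization_round_trip(self, small_cohort, tmp_path):
        import json

        _, dataset, _ = small_cohort
        fit = fit_em(dataset, 2, control=EMControl(max_iter=20, seed=0))
        path = tmp_path / "fit.json"
        fit.save(path)
        payload = json.loads(path.read_text())
        restored = HMMParams.from_dict(payload["params"])
        np.testing.assert_allclose(restored.emissions.mu, fit.params.emissions.mu)
        np.testing.assert_allclose(restored.init.coef, fit.params.init.coef)
        np.testing.assert_allclose(restored.trans.coef, fit.params.trans.coef)
        assert payload["aic"] == pytest.approx(fit.aic)


class TestViterbi:
    def test_single_state_constant_path(self):
        params = params_from_probs([0.5], [0.1], [1.0], [[1.0]])
        y = np.array([0.2, 0.8, 0.5])
        path, _ = viterbi(params, y, np.ones(1), np.ones((3, 1)))
        assert np.array_equal(path, [0, 0, 0])

    @pytest.mark.parametrize("n_states,T", [(2, 6), (3, 6)])
    def test_matches_path_enumeration(self, n_states, T):
        rng = np.random.default_rng(13)
        params = random_params(rng, n_states, trans_covariates=("f",))
        y = rng.uniform(0.1, 1.0, T)
        I = np.ones(1)
        H = np.column_stack([np.ones(T), rng.random(T)])
        expected_path, expected_lp = brute_force_viterbi(params, y, I, H)
        path, lp = viterbi(params, y, I, H)
        assert np.array_equal(path, expected_path)
        assert lp == pytest.approx(expected_lp, abs=1e-9)

    def test_ties_break_toward_lowest_state(self):
        # fully exchangeable two-state model: every path is equally likely
        params = params_from_probs(
            [0.5, 0.5], [0.1, 0.1], [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]]
        )
        y = np.array([0.5, 0.5, 0.5])
        path, _ = viterbi(params, y, np.ones(1), np.ones((3, 1)))
        assert np.array_equal(path, [0, 0, 0])

    def test_same_level_decodes_by_context(self):
        """A mid-scale observation inherits its state from its neighbors:
        level 4 surrounded by high choices decodes higher than level 4
        surrounded by low choices."""
        params = model_b_params()
        X = np.ones(1)
        high = np.array([6, 6, 4, 6, 6]) / 7.0
        low = np.array([1, 1, 4, 1, 1]) / 7.0
        H = np.ones((5, 1))
        path_high, _ = viterbi(params, high, X, H)
        path_low, _ = viterbi(params, low, X, H)
        assert path_high[2] > path_low[2]
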