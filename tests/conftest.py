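"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from sathmm import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort for fast estimation tests."""
    config = SimConfig(n_participants=80, n_items=15, seed=2024)
    dataset, states = simulate_dataset(config)
    return config, dataset, states


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the study's size (583 x 40) from the default generator."""
    config = SimConfig(seed=8675309)
    dataset, states = simulate_dataset(config)
    return config, dataset, states


# ---------------------------------------------------------------------------
# brute-force oracles (path enumeration; independent of the forward pass)


def _path_logprob(params, path, y, I, H):
    pi = params.init.probs(np.asarray(I, float))
    P = params.trans.matrices(np.asarray(H, float)[1:])
    lp = np.log(pi[path[0]])
    for t in range(1, len(path)):
        lp += np.log(P[t - 1, path[t - 1], path[t]])
    mu = params.emissions.mu
    sigma = params.emissions.sigma
    for t, s in enumerate(path):
        lp += norm.logpdf(y[t], mu[s], sigma[s])
    return lp


def brute_force_loglik(params, y, I, H):
    """log of the explicit sum over all M^T latent paths."""
    M = params.n_states
    T = len(y)
    lps = [
        _path_logprob(params, path, y, I, H)
        for path in itertools.product(range(M), repeat=T)
    ]
    return logsumexp(lps)


def brute_force_viterbi(params, y, I, H):
    """argmax over all enumerated paths (unique-maximizer inputs only)."""
    M = params.n_states
    T = len(y)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(M), repeat=T):
        lp = _path_logprob(params, path, y, I, H)
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


def random_params(rng, n_states=3, init_covariates=(), trans_covariates=()):
    """Generic (tie-free) covariate-dependent HMM parameters."""
    from sathmm import EmissionParams, HMMParams, InitialLogitModel, TransitionLogitModel

    M = n_states
    mu = np.sort(rng.uniform(0.1, 0.9, M))
    sigma = rng.uniform(0.05, 0.2, M)
    init_coef = rng.normal(0, 1, (1 + len(init_covariates), M))
    init_coef[:, 0] = 0.0
    trans_coef = rng.normal(0, 1, (M, 1 + len(trans_covariates), M))
    trans_coef[:, :, 0] = 0.0
    return HMMParams(
        emissions=EmissionParams(mu, sigma),
        init=InitialLogitModel(init_coef, tuple(init_covariates), 0),
        trans=TransitionLogitModel(trans_coef, tuple(trans_covariates), 0),
    )
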