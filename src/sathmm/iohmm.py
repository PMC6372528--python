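"""Covariate-dependent Gaussian hidden Markov model: likelihood, EM, decoding.

The observed sequence y_{i,1..T} (scaled difficulty choices) is modeled as
conditionally independent Gaussian emissions given a latent first-order Markov
chain S_{i,j} in {1..M}.  Both the initial-state distribution and the
transition matrix are multinomial-logistic functions of observed covariates,

    P(S_1 = m | I)            = softmax_m(a_m + b_m' I),
    P(S_j = m | S_{j-1}=l, h) = softmax_m(c_lm + d_lm' h),

so the transition matrix varies by participant and item.  One latent class is
the reference class whose logit column is pinned to zero for identifiability.

Estimation is by EM: the E-step runs a scaled forward-backward recursion with
per-item transition matrices; the M-step consists of gamma-weighted Gaussian
moments for the emissions and weighted multinomial-logistic fits for the
initial-state block and for each origin state's transition block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

SIGMA_FLOOR = 1e-3  # on the y = level/7 scale; guards constant sequences
RIDGE = 1e-6  # tiny slope ridge in the inner multinomial fits


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction) along ``axis``."""
    z = np.asarray(logits, dtype=float)
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class EmissionParams:
    """State-conditional Gaussian means and SDs on the y scale."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have equal length")
        if np.any(self.sigma < SIGMA_FLOOR):
            raise ValueError(f"sigma below floor {SIGMA_FLOOR}")


@dataclass
class InitialLogitModel:
    """Multinomial-logit block for the initial state.

    ``coef`` has shape (1 + q_I, M): an intercept row followed by one row per
    covariate; column ``reference`` is identically zero.
    """

    coef: np.ndarray
    covariates: tuple[str, ...] = ()
    reference: int = 0

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        self.covariates = tuple(self.covariates)
        if self.coef.shape[0] != 1 + len(self.covariates):
            raise ValueError("coef rows must be 1 + number of covariates")
        if not np.allclose(self.coef[:, self.reference], 0.0):
            raise ValueError("reference-class column must be zero")

    def probs(self, X: np.ndarray) -> np.ndarray:
        """Initial-state probabilities for design ``X`` of shape (..., 1+q_I)."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.coef.shape[0]:
            raise ValueError(
                f"design width {X.shape[-1]} != {self.coef.shape[0]} coefficients"
            )
        return softmax(X @ self.coef, axis=-1)


@dataclass
class TransitionLogitModel:
    """Per-origin-state multinomial-logit blocks for the transitions.

    ``coef`` has shape (M, 1 + q_h, M): axis 0 is the origin state l, axis 1
    the intercept-plus-covariate rows, axis 2 the destination state m.  For
    every origin, column ``reference`` is identically zero.
    """

    coef: np.ndarray
    covariates: tuple[str, ...] = ()
    reference: int = 0

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        self.covariates = tuple(self.covariates)
        M = self.coef.shape[0]
        if self.coef.shape != (M, 1 + len(self.covariates), M):
            raise ValueError("coef must have shape (M, 1+q_h, M)")
        if not np.allclose(self.coef[:, :, self.reference], 0.0):
            raise ValueError("reference-class column must be zero")

    def matrices(self, H: np.ndarray) -> np.ndarray:
        """Row-stochastic transition matrices for design ``H`` (..., 1+q_h).

        Returns an array of shape (..., M, M); entry [..., l, m] is the
        probability of moving from state l to state m.
        """
        H = np.asarray(H, dtype=float)
        if H.shape[-1] != self.coef.shape[1]:
            raise ValueError(
                f"design width {H.shape[-1]} != {self.coef.shape[1]} coefficients"
            )
        logits = np.einsum("...q,lqm->...lm", H, self.coef)
        return softmax(logits, axis=-1)


@dataclass
class HMMParams:
    """Complete parameter set of the covariate-dependent HMM."""

    emissions: EmissionParams
    init: InitialLogitModel
    trans: TransitionLogitModel

    def __post_init__(self):
        M = self.n_states
        if self.init.coef.shape[1] != M or self.trans.coef.shape[0] != M:
            raise ValueError("logit blocks inconsistent with number of states")

    @property
    def n_states(self) -> int:
        return len(self.emissions.mu)

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "mu": self.emissions.mu.tolist(),
            "sigma": self.emissions.sigma.tolist(),
            "init": {
                "coef": self.init.coef.tolist(),
                "covariates": list(self.init.covariates),
                "reference": self.init.reference,
            },
            "trans": {
                "coef": self.trans.coef.tolist(),
                "covariates": list(self.trans.covariates),
                "reference": self.trans.reference,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            emissions=EmissionParams(np.array(d["mu"]), np.array(d["sigma"])),
            init=InitialLogitModel(
                np.array(d["init"]["coef"]),
                tuple(d["init"]["covariates"]),
                d["init"]["reference"],
            ),
            trans=TransitionLogitModel(
                np.array(d["trans"]["coef"]),
                tuple(d["trans"]["covariates"]),
                d["trans"]["reference"],
            ),
        )


def params_from_probs(
    mu,
    sigma,
    init_probs,
    trans_probs,
    init_covariates=(),
    trans_covariates=(),
    reference: int = 0,
) -> HMMParams:
    """Intercept-only parameters (optionally with zero-slope covariate rows)
    whose logits reproduce the given initial/transition probabilities."""
    init_probs = np.asarray(init_probs, dtype=float)
    trans_probs = np.asarray(trans_probs, dtype=float)
    M = len(init_probs)
    a = np.log(init_probs) - np.log(init_probs[reference])
    init_coef = np.zeros((1 + len(init_covariates), M))
    init_coef[0] = a
    trans_coef = np.zeros((M, 1 + len(trans_covariates), M))
    for l in range(M):
        trans_coef[l, 0] = np.log(trans_probs[l]) - np.log(trans_probs[l, reference])
    return HMMParams(
        emissions=EmissionParams(np.asarray(mu, float), np.asarray(sigma, float)),
        init=InitialLogitModel(init_coef, tuple(init_covariates), reference),
        trans=TransitionLogitModel(trans_coef, tuple(trans_covariates), reference),
    )


# ---------------------------------------------------------------------------
# weighted multinomial logistic regression (inner M-step solver)


class MultinomialFitError(RuntimeError):
    """Inner logistic fit failed to converge."""


def fit_weighted_multinomial(
    X: np.ndarray,
    W: np.ndarray,
    reference: int = 0,
    ridge: float = RIDGE,
    coef0: np.ndarray | None = None,
    maxiter: int = 200,
    label: str = "",
) -> np.ndarray:
    """Maximize the weighted multinomial log-likelihood.

    ``X`` is (n, P) with a leading intercept column; ``W`` is (n, M) with
    nonnegative fractional class weights (each row is an expected class
    membership, not necessarily summing to one).  A ridge penalty ``ridge`` is
    applied to slope rows only.  Returns coefficients of shape (P, M) with the
    reference column pinned at zero.

    With an intercept-only design the weighted MLE is closed form: the logits
    of the normalized pooled weights.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    n, P = X.shape
    M = W.shape[1]
    if P == 1:
        p = W.sum(axis=0)
        p = np.maximum(p / p.sum(), 1e-12)
        coef = np.zeros((1, M))
        coef[0] = np.log(p) - np.log(p[reference])
        return coef

    free = [m for m in range(M) if m != reference]
    wtot = W.sum(axis=1)

    def unpack(theta):
        C = np.zeros((P, M))
        C[:, free] = theta.reshape(P, M - 1)
        return C

    def objective(theta):
        C = unpack(theta)
        L = X @ C
        lse = logsumexp(L, axis=1)
        nll = -(W * L).sum() + (wtot * lse).sum()
        nll += 0.5 * ridge * np.sum(C[1:] ** 2)
        Pm = softmax(L, axis=1)
        G = X.T @ (Pm * wtot[:, None] - W)
        G[1:] += ridge * C[1:]
        return nll, G[:, free].ravel()

    if coef0 is not None:
        theta0 = np.asarray(coef0, dtype=float)[:, free].ravel()
    else:
        theta0 = np.zeros(P * (M - 1))
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7})
    # L-BFGS hitting maxiter is tolerable inside EM (the outer loop refines),
    # but a genuinely failed line search is not.
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise MultinomialFitError(
            f"multinomial fit {label or '(unnamed)'} failed after "
            f"{res.nit} iterations: {res.message}"
        )
    return unpack(res.x)


# ---------------------------------------------------------------------------
# likelihood machinery (vectorized over participants)


def _log_emissions(y: np.ndarray, emissions: EmissionParams) -> np.ndarray:
    """Log N(y_t; mu_m, sigma_m) with shape (..., M)."""
    y = np.asarray(y, dtype=float)
    return norm.logpdf(y[..., None], loc=emissions.mu, scale=emissions.sigma)


def _forward_backward(pi, trans, logB):
    """Scaled forward-backward for a batch of sequences.

    Parameters: ``pi`` (n, M) initial probabilities, ``trans`` (n, T-1, M, M)
    per-item transition matrices (slab j is the transition into item j+2,
    1-based), ``logB`` (n, T, M) emission log-densities.

    Returns ``gamma`` (n, T, M), ``xi`` (n, T-1, M, M) and per-sequence
    log-likelihoods (n,).  Per-item max-subtraction on ``logB`` plus per-step
    normalization makes underflow impossible for finite inputs.
    """
    n, T, M = logB.shape
    shift = logB.max(axis=2)  # (n, T)
    B = np.exp(logB - shift[:, :, None])

    alpha = np.empty((n, T, M))
    c = np.empty((n, T))
    a = pi * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = np.einsum("nl,nlm->nm", alpha[:, t - 1], trans[:, t - 1]) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((n, T, M))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]
        beta[:, t] = np.einsum("nlm,nm->nl", trans[:, t], bb) / c[:, t + 1, None]

    gamma = alpha * beta
    xi = (
        alpha[:, :-1, :, None]
        * trans
        * (B[:, 1:] * beta[:, 1:])[:, :, None, :]
        / c[:, 1:, None, None]
    )
    loglik = np.log(c).sum(axis=1) + shift.sum(axis=1)
    return gamma, xi, loglik


def _dataset_inputs(params: HMMParams, y: np.ndarray, X_init: np.ndarray, H: np.ndarray):
    pi = params.init.probs(X_init)  # (n, M)
    trans = params.trans.matrices(H[:, 1:, :])  # (n, T-1, M, M)
    logB = _log_emissions(y, params.emissions)  # (n, T, M)
    return pi, trans, logB


def e_step(params: HMMParams, y: np.ndarray, X_init: np.ndarray, H: np.ndarray):
    """Posterior summaries for a batch: gamma, xi, total log-likelihood."""
    pi, trans, logB = _dataset_inputs(params, y, X_init, H)
    gamma, xi, ll = _forward_backward(pi, trans, logB)
    return gamma, xi, float(ll.sum())


def sequence_loglik(params: HMMParams, y: Sequence[float], I: np.ndarray, H: np.ndarray) -> float:
    """Marginal log-likelihood of one sequence under the model."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[1] == 0:
        raise ValueError("empty sequence")
    _, _, ll = e_step(params, y, np.atleast_2d(I), H[None, :, :])
    return ll


def m_step(
    gamma: np.ndarray,
    xi: np.ndarray,
    y: np.ndarray,
    X_init: np.ndarray,
    H: np.ndarray,
    params: HMMParams,
) -> HMMParams:
    """Maximize the expected complete-data log-likelihood.

    Emissions are gamma-weighted pooled moments; the initial block is a
    weighted multinomial fit of gamma at item 1 on the initial design; each
    origin state's transition block is a weighted multinomial fit of the xi
    slabs on the transition design.  Previous coefficients warm-start the
    inner fits.
    """
    M = params.n_states
    w = gamma.reshape(-1, M)  # (n*T, M)
    yy = y.reshape(-1)
    tot = w.sum(axis=0)
    mu = (w * yy[:, None]).sum(axis=0) / tot
    var = (w * (yy[:, None] - mu) ** 2).sum(axis=0) / tot
    sigma = np.maximum(np.sqrt(var), SIGMA_FLOOR)

    init_coef = fit_weighted_multinomial(
        X_init, gamma[:, 0, :], reference=params.init.reference,
        coef0=params.init.coef, label="initial state",
    )

    n, T, _ = gamma.shape
    Ht = H[:, 1:, :].reshape(n * (T - 1), -1)
    trans_coef = np.zeros_like(params.trans.coef)
    for l in range(M):
        Wl = xi[:, :, l, :].reshape(n * (T - 1), M)
        trans_coef[l] = fit_weighted_multinomial(
            Ht, Wl, reference=params.trans.reference,
            coef0=params.trans.coef[l], label=f"transitions from state {l}",
        )

    return HMMParams(
        emissions=EmissionParams(mu, sigma),
        init=InitialLogitModel(init_coef, params.init.covariates, params.init.reference),
        trans=TransitionLogitModel(trans_coef, params.trans.covariates, params.trans.reference),
    )


# ---------------------------------------------------------------------------
# EM driver


@dataclass
class EMControl:
    """EM control settings: relative-loglik tolerance, iteration cap, restarts."""

    tol: float = 1e-8
    max_iter: int = 500
    n_restarts: int = 1
    seed: int | None = None
    jitter_sd: float = 0.05


@dataclass
class FitResult:
    """A fitted model: parameters, fit statistics, posteriors, decoded paths."""

    params: HMMParams
    loglik: float
    n_params: int
    n_obs: int
    gamma: np.ndarray
    xi: np.ndarray
    trace: list[float]
    converged: bool
    n_iter: int
    model_name: str = ""
    restart: int = 0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "restart": self.restart,
            "trace": self.trace,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def initial_params(
    y: np.ndarray,
    n_states: int,
    init_covariates=(),
    trans_covariates=(),
    rng: np.random.Generator | None = None,
    jitter_sd: float = 0.0,
) -> HMMParams:
    """Deterministic EM starting point: emission means at the (m-0.5)/M
    quantiles of pooled y, SDs at the pooled SD, all logit coefficients zero.
    A nonzero ``jitter_sd`` perturbs the means (restart mechanism)."""
    yy = np.asarray(y, dtype=float).ravel()
    qs = (np.arange(n_states) + 0.5) / n_states
    mu = np.quantile(yy, qs)
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("jittered initialization needs an rng")
        mu = mu + rng.normal(0.0, jitter_sd, size=n_states)
    sigma = np.full(n_states, max(yy.std(), 10 * SIGMA_FLOOR))
    init_coef = np.zeros((1 + len(init_covariates), n_states))
    trans_coef = np.zeros((n_states, 1 + len(trans_covariates), n_states))
    return HMMParams(
        emissions=EmissionParams(mu, sigma),
        init=InitialLogitModel(init_coef, tuple(init_covariates)),
        trans=TransitionLogitModel(trans_coef, tuple(trans_covariates)),
    )


class EMFitError(RuntimeError):
    def __init__(self, message, traces=None):
        super().__init__(message)
        self.traces = traces or []


def _em_once(y, X_init, H, params: HMMParams, control: EMControl):
    trace: list[float] = []
    ll_old = -np.inf
    gamma = xi = None
    converged = False
    for it in range(control.max_iter + 1):
        gamma, xi, ll = e_step(params, y, X_init, H)
        trace.append(ll)
        if it > 0 and abs(ll - ll_old) / (1.0 + abs(ll)) < control.tol:
            converged = True
            break
        if it == control.max_iter:
            break
        params = m_step(gamma, xi, y, X_init, H, params)
        ll_old = ll
    return params, trace[-1], gamma, xi, trace, converged


def fit_em(
    dataset,
    n_states: int,
    init_covariates=(),
    trans_covariates=(),
    control: EMControl | None = None,
    accumulation: str = "inclusive",
    model_name: str = "",
) -> FitResult:
    """Fit the covariate-dependent HMM to a :class:`ProcessDataset` by EM.

    Runs ``control.n_restarts`` EM passes (the first from the deterministic
    start, the rest from seed-controlled jittered starts) and returns the
    highest-log-likelihood solution, with posteriors and the iteration trace.
    """
    from .data_model import design_matrices  # local import to avoid a cycle
    from .ladder import count_params

    control = control or EMControl()
    y = dataset.scaled_matrix()
    X_init, H = design_matrices(dataset, init_covariates, trans_covariates, accumulation)
    rng = np.random.default_rng(control.seed)

    best = None
    failures = []
    for restart in range(max(1, control.n_restarts)):
        start = initial_params(
            y, n_states, init_covariates, trans_covariates,
            rng=rng, jitter_sd=(control.jitter_sd if restart > 0 else 0.0),
        )
        try:
            params, ll, gamma, xi, trace, converged = _em_once(
                y, X_init, H, start, control
            )
        except (MultinomialFitError, FloatingPointError) as exc:
            failures.append((restart, str(exc)))
            continue
        if best is None or ll > best.loglik:
            best = FitResult(
                params=params, loglik=ll,
                n_params=count_params(n_states, len(init_covariates), len(trans_covariates)),
                n_obs=dataset.n_obs,
                gamma=gamma, xi=xi, trace=trace, converged=converged,
                n_iter=len(trace) - 1, model_name=model_name, restart=restart,
            )
    if best is None:
        raise EMFitError(
            f"all {control.n_restarts} EM restarts failed", traces=failures
        )
    return best


# ---------------------------------------------------------------------------
# decoding


def viterbi(params: HMMParams, y: Sequence[float], I: np.ndarray, H: np.ndarray):
    """Most probable state path for one sequence (0-based states).

    Works in log space with the participant's per-item transition matrices;
    ties break toward the lower state index.  Returns ``(path, logp)``.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    logB = _log_emissions(y, params.emissions)  # (T, M)
    logpi = np.log(params.init.probs(np.asarray(I, float)))
    logP = np.log(params.trans.matrices(H[1:, :]))  # (T-1, M, M)

    M = params.n_states
    delta = logpi + logB[0]
    back = np.zeros((T, M), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logP[t - 1]  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest origin index
        delta = cand[back[t], np.arange(M)] + logB[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    logp = float(delta[path[T - 1]])
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, logp


def decode_dataset(params: HMMParams, dataset, accumulation: str = "inclusive") -> np.ndarray:
    """Viterbi paths for every record; returns an (n, T) integer array."""
    from .data_model import build_design

    paths = []
    for rec in dataset:
        I, H = build_design(rec, params.init.covariates, params.trans.covariates, accumulation)
        path, _ = viterbi(params, rec.scaled_levels(), I, H)
        paths.append(path)
    return np.stack(paths)
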