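"""Reference parameter estimates and fit statistics from the motivating study.

The original cohort (583 adults, 40-item self-adapted test) is not publicly
deposited, but the fitted models were reported in full: emission moments,
initial-state and transition logit coefficient blocks, log-likelihoods, and
information criteria for the six-rung ladder A..B3.  They serve three roles
here: inputs to the effect-evaluation module, generating values for the
synthetic cohort, and anchors for validation.

Conventions: states are in ascending-mean order low (L), medium (M), high
(H); the logit reference class is the medium state (index 1), whose
coefficient column is zero throughout.  Coefficient blocks are given as
(1 + q) x M arrays, intercept row first, matching the covariate order of the
:mod:`sathmm.ladder` definitions.
"""

from __future__ import annotations

import numpy as np

from .iohmm import EmissionParams, HMMParams, InitialLogitModel, TransitionLogitModel, params_from_probs

#: cohort size of the original study
STUDY_N_PARTICIPANTS = 583
STUDY_N_ITEMS = 40
STUDY_N_OBS = STUDY_N_PARTICIPANTS * STUDY_N_ITEMS

#: reported per-model fit statistics (k = free parameters)
REPORTED_FIT = {
    "A": {"k": 7, "loglik": 8336.474, "aic": -16658.95, "bic": -16602.55},
    "B": {"k": 14, "loglik": 13625.771, "aic": -27223.54, "bic": -27110.74},
    "B1": {"k": 20, "loglik": 13661.399, "aic": -27282.80, "bic": -27121.66},
    "B2a": {"k": 26, "loglik": 13679.344, "aic": -27306.69, "bic": -27097.20},
    "B2b": {"k": 38, "loglik": 13771.316, "aic": -27466.63, "bic": -27160.46},
    "B3": {"k": 62, "loglik": 13805.653, "aic": -27487.31, "bic": -26987.77},
}

#: reported likelihood-ratio tests, (restricted, general) -> (chi2, delta df)
REPORTED_LRT = {
    ("B", "B1"): (71.26, 6),
    ("B1", "B2a"): (35.89, 6),
    ("B1", "B2b"): (219.83, 18),
    ("B2b", "B3"): (68.67, 24),
}

REFERENCE_CLASS = 1  # medium state

_MU_3 = np.array([0.19, 0.51, 0.86])
_SIGMA_B = np.array([0.07, 0.12, 0.13])
_SIGMA_B2B = np.array([0.07, 0.11, 0.13])

_PI_B = np.array([0.36, 0.45, 0.19])
_TRANS_B = np.array(
    [
        [0.93, 0.05, 0.02],
        [0.04, 0.92, 0.04],
        [0.04, 0.06, 0.90],
    ]
)

_INIT_COV = ("d", "p", "dp")

_INIT_B1 = np.array(
    [
        [1.74, 0.0, -3.21],
        [0.05, 0.0, -2.29],
        [-3.06, 0.0, 3.15],
        [0.60, 0.0, 2.56],
    ]
)
_INIT_B2A = np.array(
    [
        [1.77, 0.0, -3.16],
        [-0.01, 0.0, -2.39],
        [-3.07, 0.0, 3.10],
        [0.62, 0.0, 2.68],
    ]
)
_INIT_B2B = np.array(
    [
        [1.75, 0.0, -3.13],
        [0.03, 0.0, -2.16],
        [-3.11, 0.0, 3.04],
        [0.62, 0.0, 2.35],
    ]
)
_INIT_B3 = np.array(
    [
        [1.75, 0.0, -3.14],
        [0.08, 0.0, -1.99],
        [-3.07, 0.0, 3.07],
        [0.49, 0.0, 2.10],
    ]
)

# transition blocks, axis order (origin, [1; covariates], destination)
_TRANS_B2A = np.array(
    [
        [[2.54, 0.0, -1.13], [0.60, 0.0, 0.21]],
        [[-3.17, 0.0, -2.96], [-0.05, 0.0, -0.19]],
        [[-0.39, 0.0, 2.74], [-0.16, 0.0, 0.0]],
    ]
)
_TRANS_B2B = np.array(
    [
        [
            [2.96, 0.0, -1.35],
            [-2.95, 0.0, 1.33],
            [-0.52, 0.0, -0.66],
            [4.12, 0.0, -0.33],
        ],
        [
            [-1.21, 0.0, -3.30],
            [-1.90, 0.0, 0.84],
            [-4.12, 0.0, -1.37],
            [4.41, 0.0, 1.42],
        ],
        [
            [0.24, 0.0, 2.93],
            [-0.96, 0.0, -1.59],
            [-2.36, 0.0, -0.04],
            [3.31, 0.0, 2.03],
        ],
    ]
)
_TRANS_B3 = np.array(
    [
        [
            [1.77, 0.0, -1.33],
            [3.67, 0.0, -1.04],
            [-1.32, 0.0, 1.98],
            [1.60, 0.0, -0.42],
            [1.01, 0.0, -1.87],
            [-4.65, 0.0, -0.07],
            [-5.90, 0.0, 0.89],
            [7.92, 0.0, 1.28],
        ],
        [
            [-0.91, 0.0, -3.32],
            [-0.94, 0.0, 0.06],
            [-1.90, 0.0, 1.77],
            [-5.33, 0.0, -1.71],
            [5.38, 0.0, 0.83],
            [0.58, 0.0, -2.59],
            [2.81, 0.0, 0.66],
            [-2.63, 0.0, 2.10],
        ],
        [
            [0.91, 0.0, 3.43],
            [-2.56, 0.0, -1.58],
            [-2.13, 0.0, -3.36],
            [-3.65, 0.0, -0.11],
            [5.48, 0.0, 3.78],
            [4.08, 0.0, 4.82],
            [4.30, 0.0, 0.71],
            [-6.77, 0.0, -4.79],
        ],
    ]
)


def model_a_params() -> HMMParams:
    """Reported 2-state intercept-only estimates."""
    return params_from_probs(
        mu=[0.19, 0.62],
        sigma=[0.07, 0.22],
        init_probs=[0.33, 0.67],
        trans_probs=[[0.96, 0.04], [0.02, 0.98]],
        reference=1,
    )


def model_b_params() -> HMMParams:
    """Reported 3-state intercept-only estimates (also the default generating
    values for the synthetic cohort)."""
    return params_from_probs(
        mu=_MU_3,
        sigma=_SIGMA_B,
        init_probs=_PI_B,
        trans_probs=_TRANS_B,
        reference=REFERENCE_CLASS,
    )


def _with_blocks(sigma, init_coef, trans_coef, trans_cov) -> HMMParams:
    base = params_from_probs(
        mu=_MU_3,
        sigma=sigma,
        init_probs=_PI_B,
        trans_probs=_TRANS_B,
        reference=REFERENCE_CLASS,
    )
    init = InitialLogitModel(init_coef, _INIT_COV, REFERENCE_CLASS)
    if trans_coef is None:
        trans = base.trans
    else:
        trans = TransitionLogitModel(trans_coef, trans_cov, REFERENCE_CLASS)
    return HMMParams(
        emissions=EmissionParams(_MU_3.copy(), np.asarray(sigma, float)),
        init=init,
        trans=trans,
    )


def model_b1_params() -> HMMParams:
    return _with_blocks(_SIGMA_B, _INIT_B1, None, ())


def model_b2a_params() -> HMMParams:
    return _with_blocks(_SIGMA_B, _INIT_B2A, _TRANS_B2A, ("d",))


def model_b2b_params() -> HMMParams:
    return _with_blocks(_SIGMA_B2B, _INIT_B2B, _TRANS_B2B, ("f", "r", "fr"))


def model_b3_params() -> HMMParams:
    return _with_blocks(
        _SIGMA_B2B, _INIT_B3, _TRANS_B3, ("d", "f", "r", "fr", "df", "dr", "dfr")
    )


REFERENCE_PARAMS = {
    "A": model_a_params,
    "B": model_b_params,
    "B1": model_b1_params,
    "B2a": model_b2a_params,
    "B2b": model_b2b_params,
    "B3": model_b3_params,
}
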