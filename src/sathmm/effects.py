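"""Expected-probability summaries of fitted logit blocks.

Turns the multinomial-logit coefficient blocks of a fitted model into the
quantities practitioners read off: initial-state probabilities over a grid of
goal condition and pre-test score, and transition matrices over a grid of
condition, accumulated confidence, and accumulated correctness — with the
per-origin stay/upward/downward masses that summarize each matrix.  States
are always reported in ascending-emission-mean order (L, M, H for M = 3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iohmm import EmissionParams, HMMParams, InitialLogitModel, TransitionLogitModel

_BASE_ORDER = ("d", "p", "f", "r")

#: evaluation grid used for the published-figure summaries
DEFAULT_GRID = {"d": (0, 1), "p": (0.0, 0.25, 0.5, 0.75, 1.0), "f": (0.0, 1.0), "r": (0.0, 1.0)}


def state_labels(n_states: int) -> list[str]:
    """Ascending-mean state labels: L/M/H for 3 states, S1..SM otherwise."""
    if n_states == 2:
        return ["L", "H"]
    if n_states == 3:
        return ["L", "M", "H"]
    return [f"S{i + 1}" for i in range(n_states)]


def relabel_states(params: HMMParams) -> tuple[HMMParams, np.ndarray]:
    """Reorder states by ascending emission mean.

    Returns the permuted parameters and the permutation ``perm`` such that
    new state k is old state ``perm[k]``.  Coefficient columns, transition
    origin blocks, and the reference-class index are carried along, so every
    probability the model assigns is unchanged.  Tied means keep their
    original relative order.
    """
    mu = params.emissions.mu
    perm = np.argsort(mu, kind="stable")
    emissions = EmissionParams(mu[perm], params.emissions.sigma[perm])
    new_ref_init = int(np.argwhere(perm == params.init.reference)[0, 0])
    init = InitialLogitModel(
        params.init.coef[:, perm], params.init.covariates, new_ref_init
    )
    new_ref_trans = int(np.argwhere(perm == params.trans.reference)[0, 0])
    trans = TransitionLogitModel(
        params.trans.coef[np.ix_(perm, range(params.trans.coef.shape[1]), perm)],
        params.trans.covariates,
        new_ref_trans,
    )
    return HMMParams(emissions=emissions, init=init, trans=trans), perm


def _base_covariates(names: tuple[str, ...]) -> list[str]:
    letters = {ch for name in names for ch in name}
    return [b for b in _BASE_ORDER if b in letters]


def _derive(point: dict[str, float], names: tuple[str, ...]) -> np.ndarray:
    """Design row [1, covariates...] with interactions as products of factors."""
    vals = [1.0]
    for name in names:
        prod = 1.0
        for ch in name:
            prod *= point[ch]
        vals.append(prod)
    return np.array(vals)


def _grid_points(names: tuple[str, ...], grid: dict | None) -> list[dict[str, float]]:
    bases = _base_covariates(names)
    grid = dict(grid) if grid else {}
    for g in grid:
        if g not in bases:
            raise ValueError(
                f"grid covariate {g!r} is not in the model (bases: {bases})"
            )
    axes = [tuple(grid.get(b, DEFAULT_GRID[b])) for b in bases]
    return [dict(zip(bases, combo)) for combo in itertools.product(*axes)]


@dataclass
class EffectTable:
    """Tidy expected-probability tables over a covariate grid."""

    probs: pd.DataFrame
    masses: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.probs.to_csv(path, index=False)


def expected_initial(params: HMMParams, grid: dict | None = None) -> EffectTable:
    """Initial-state probabilities at each grid point.

    One row per grid point with columns ``p_<label>`` for each ascending-mean
    state label; rows sum to one.
    """
    params, _ = relabel_states(params)
    labels = state_labels(params.n_states)
    points = _grid_points(params.init.covariates, grid)
    rows = []
    for pt in points:
        X = _derive(pt, params.init.covariates)
        pi = params.init.probs(X)
        rows.append({**pt, **{f"p_{lab}": pi[k] for k, lab in enumerate(labels)}})
    return EffectTable(probs=pd.DataFrame(rows))


def expected_transitions(params: HMMParams, grid: dict | None = None) -> EffectTable:
    """Transition matrices at each grid point, tidily, with aggregates.

    ``probs`` holds one row per grid point x origin x destination; ``masses``
    aggregates each origin row into stay (diagonal), upward (toward higher
    difficulty states), and downward mass, which partition the row.
    """
    params, _ = relabel_states(params)
    labels = state_labels(params.n_states)
    points = _grid_points(params.trans.covariates, grid)
    prob_rows, mass_rows = [], []
    for pt in points:
        H = _derive(pt, params.trans.covariates)
        P = params.trans.matrices(H)
        for l, from_lab in enumerate(labels):
            for m, to_lab in enumerate(labels):
                prob_rows.append(
                    {**pt, "from": from_lab, "to": to_lab, "prob": P[l, m]}
                )
            mass_rows.append(
                {
                    **pt,
                    "from": from_lab,
                    "stay": P[l, l],
                    "up": float(P[l, l + 1 :].sum()),
                    "down": float(P[l, :l].sum()),
                }
            )
    return EffectTable(probs=pd.DataFrame(prob_rows), masses=pd.DataFrame(mass_rows))


def transition_masses_at(params: HMMParams, **covariates) -> pd.DataFrame:
    """Stay/up/down masses per origin state at a single covariate setting."""
    grid = {k: (v,) for k, v in covariates.items()}
    return expected_transitions(params, grid).masses
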