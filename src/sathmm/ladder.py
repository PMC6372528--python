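"""The six-model comparison ladder: definitions, parameter counts, AIC/BIC/LRT.

The ladder grows from an intercept-only 2-state model (A) to a 3-state model
whose initial-state block is driven by goal condition and pre-test score and
whose transition blocks are driven by condition, accumulated confidence,
accumulated correctness, and all their interactions (B3):

    A    M=2, no covariates
    B    M=3, no covariates
    B1   M=3, initial ~ d + p + dp
    B2a  B1  + transitions ~ d
    B2b  B1  + transitions ~ f + r + fr
    B3   B1  + transitions ~ d + f + r + fr + df + dr + dfr

Nested rungs are compared by likelihood-ratio tests along the chain
B<B1, B1<B2a, B1<B2b, B2b<B3, and all rungs by AIC/BIC with the BIC sample
size taken as the total number of item observations (participants x items).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .iohmm import EMControl, FitResult, fit_em


@dataclass(frozen=True)
class ModelDef:
    """One rung: state count plus covariate sets for the two logit blocks."""

    name: str
    n_states: int
    init_covariates: tuple[str, ...] = ()
    trans_covariates: tuple[str, ...] = ()

    def nests(self, other: "ModelDef") -> bool:
        """True if ``self`` is nested in (restricted relative to) ``other``."""
        return (
            self.n_states == other.n_states
            and set(self.init_covariates) <= set(other.init_covariates)
            and set(self.trans_covariates) <= set(other.trans_covariates)
        )


MODEL_LADDER: dict[str, ModelDef] = {
    "A": ModelDef("A", 2),
    "B": ModelDef("B", 3),
    "B1": ModelDef("B1", 3, ("d", "p", "dp")),
    "B2a": ModelDef("B2a", 3, ("d", "p", "dp"), ("d",)),
    "B2b": ModelDef("B2b", 3, ("d", "p", "dp"), ("f", "r", "fr")),
    "B3": ModelDef(
        "B3", 3, ("d", "p", "dp"), ("d", "f", "r", "fr", "df", "dr", "dfr")
    ),
}

#: nested pairs tested by LRT, (restricted, general)
LRT_CHAIN: tuple[tuple[str, str], ...] = (
    ("B", "B1"),
    ("B1", "B2a"),
    ("B1", "B2b"),
    ("B2b", "B3"),
)


def count_params(n_states: int, q_init: int, q_trans: int) -> int:
    """Free-parameter count: 2M emission moments, (1+q_I) coefficients for
    each of M-1 non-reference initial classes, and (1+q_h) coefficients for
    each of M(M-1) non-reference transition targets."""
    M = n_states
    return 2 * M + (1 + q_init) * (M - 1) + (1 + q_trans) * M * (M - 1)


def count_params_def(model: ModelDef) -> int:
    return count_params(
        model.n_states, len(model.init_covariates), len(model.trans_covariates)
    )


def aic(loglik: float, k: int) -> float:
    return -2.0 * loglik + 2.0 * k


def bic(loglik: float, k: int, n_obs: int) -> float:
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + k * np.log(n_obs)


def lrt(
    loglik_restricted: float,
    loglik_general: float,
    k_restricted: int,
    k_general: int,
) -> dict:
    """Likelihood-ratio test of nested fits: chi2 = 2*(llg - llr), df = dk.

    Uses the naive chi-square reference distribution; regularity conditions
    for covariate tests in latent Markov models are asserted, not proven.
    """
    if k_general <= k_restricted:
        raise ValueError("general model must have more parameters than restricted")
    chi2_stat = 2.0 * (loglik_general - loglik_restricted)
    df = k_general - k_restricted
    p = float(chi2.sf(chi2_stat, df)) if chi2_stat > 0 else 1.0
    return {"chi2": chi2_stat, "df": df, "p": p}


@dataclass
class ComparisonTable:
    """Fits plus the comparison frame mirroring the published layout."""

    fits: dict[str, FitResult] = field(default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None):
        payload = self.table.to_dict(orient="records")
        if path is None:
            return payload
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def comparison_frame(
    stats: dict[str, dict], n_obs: int, chain=LRT_CHAIN
) -> pd.DataFrame:
    """Assemble the AIC/BIC/LRT table from per-model {k, loglik} entries.

    Separated from the fitting so it can also be applied to externally
    reported log-likelihoods.
    """
    rows = []
    for name, st in stats.items():
        rows.append(
            {
                "model": name,
                "k": st["k"],
                "loglik": st["loglik"],
                "aic": aic(st["loglik"], st["k"]),
                "bic": bic(st["loglik"], st["k"], n_obs),
                "lrt_vs": None,
                "chi2": np.nan,
                "delta_df": np.nan,
                "p": np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    for restricted, general in chain:
        if restricted in stats and general in stats:
            res = lrt(
                stats[restricted]["loglik"],
                stats[general]["loglik"],
                stats[restricted]["k"],
                stats[general]["k"],
            )
            idx = frame.index[frame["model"] == general][0]
            frame.loc[idx, ["lrt_vs", "chi2", "delta_df", "p"]] = (
                restricted,
                res["chi2"],
                res["df"],
                res["p"],
            )
    return frame


def fit_ladder(
    dataset,
    models=None,
    control: EMControl | None = None,
    accumulation: str = "inclusive",
) -> ComparisonTable:
    """Fit the requested rungs (default: all six) with shared EM control and
    return the comparison table with the LRT chain filled in."""
    names = list(models) if models is not None else list(MODEL_LADDER)
    control = control or EMControl()
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for name in names:
        mdef = MODEL_LADDER[name]
        try:
            fits[name] = fit_em(
                dataset,
                mdef.n_states,
                mdef.init_covariates,
                mdef.trans_covariates,
                control=control,
                accumulation=accumulation,
                model_name=name,
            )
        except Exception as exc:  # annotate per rung, keep going
            errors[name] = str(exc)
    stats = {name: {"k": fit.n_params, "loglik": fit.loglik} for name, fit in fits.items()}
    frame = comparison_frame(stats, dataset.n_obs)
    if errors:
        err_frame = pd.DataFrame(
            [{"model": name, "error": msg} for name, msg in errors.items()]
        )
        frame = frame.merge(err_frame, on="model", how="outer")
    return ComparisonTable(fits=fits, table=frame)
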