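"""Synthetic cohort generator mirroring the self-adapted test's data structure.

The generator draws, per participant, a goal condition and a pre-test score,
then walks the latent chain of the covariate-dependent HMM forward: at each
item the latent state is drawn from the initial-state or transition logit
model, a continuous difficulty preference is drawn from the state's Gaussian
and discretized to the 7-level grid, correctness is drawn from the chosen
level's success probability (with an optional ability shift on the logit
scale from the pre-test score), and a confidence rating is produced by a
linear link to correctness with Gaussian noise, rounded to the instrument's
0.1 grid.

Defaults reproduce the study conditions: 583 participants x 40 items,
balanced conditions, truncated-normal pre-test scores (mean 0.75, SD 0.16,
range 0.22..1), 3-state generating parameters with emission means
(0.19, 0.51, 0.86) and sticky intercept-only transitions (diagonal
0.93/0.92/0.90), per-level success probabilities 92..16%, and a confidence
link calibrated so that the pooled confidence-correctness point-biserial
correlation is about 0.60.

Transition covariates, when the generating parameters carry slopes, are
accumulated in lagged mode (history through the previous item): a generative
transition into item j can only condition on what happened before item j.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import truncnorm

from .data_model import N_LEVELS, ProcessDataset, TestRecord
from .iohmm import HMMParams
from .reference import model_b_params

#: per-level probability of a correct answer, levels 1..7
DEFAULT_LEVEL_SUCCESS = (0.92, 0.80, 0.68, 0.55, 0.41, 0.30, 0.16)


@dataclass
class SimConfig:
    """Generating parameters and noise model for a synthetic cohort.

    The confidence channel is ``clip(round10(base + gain*correct + noise))``;
    ``conf_gain`` and ``conf_noise_sd`` are calibrated to a pooled
    point-biserial correlation of ~0.60 between confidence and correctness.
    ``ability_slope`` shifts the per-level success logit by
    ``slope * (pretest - 0.75)`` so stronger participants succeed more often
    at every level; 0 turns the modulation off.
    """

    n_participants: int = 583
    n_items: int = 40
    condition_prob: float = 0.5
    pretest_mean: float = 0.75
    pretest_sd: float = 0.16
    pretest_bounds: tuple[float, float] = (0.22, 1.0)
    true_params: HMMParams = field(default_factory=model_b_params)
    level_success: tuple[float, ...] = DEFAULT_LEVEL_SUCCESS
    ability_slope: float = 1.0
    conf_base: float = 0.33
    conf_gain: float = 0.37
    conf_noise_sd: float = 0.24
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig requires an explicit seed")
        if len(self.level_success) != N_LEVELS:
            raise ValueError(f"level_success must have {N_LEVELS} entries")
        if not all(0.0 <= s <= 1.0 for s in self.level_success):
            raise ValueError("level_success entries must be probabilities")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_params"] = self.true_params.to_dict()
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return np.log(p / (1 - p))


def _design_row(names, values: dict[str, float]) -> np.ndarray:
    row = [1.0]
    for name in names:
        prod = 1.0
        for ch in name:
            prod *= values[ch]
        row.append(prod)
    return np.array(row)


def draw_correct(level: int, pretest: float, config: SimConfig, rng: np.random.Generator) -> int:
    """Bernoulli response at a level, with the ability-modulated success rate."""
    logit = _logit(config.level_success[level - 1])
    logit += config.ability_slope * (pretest - 0.75)
    p = 1.0 / (1.0 + np.exp(-logit))
    return int(rng.random() < p)


def draw_confidence(correct: int, config: SimConfig, rng: np.random.Generator) -> float:
    """Confidence on the 0.1 grid, linearly linked to correctness."""
    raw = config.conf_base + config.conf_gain * correct + rng.normal(0.0, config.conf_noise_sd)
    return float(np.clip(np.round(raw * 10) / 10, 0.0, 1.0))


def simulate_participant(
    config: SimConfig,
    condition: int,
    pretest: float,
    rng: np.random.Generator,
    participant_id: str = "sim",
) -> tuple[TestRecord, np.ndarray]:
    """One synthetic record plus its true latent path (0-based states)."""
    params = config.true_params
    M = params.n_states
    T = config.n_items
    levels = np.empty(T, dtype=int)
    correct = np.empty(T, dtype=int)
    confidence = np.empty(T)
    states = np.empty(T, dtype=int)

    sum_correct = 0.0
    sum_conf = 0.0
    d = float(condition)
    for j in range(T):
        if j == 0:
            vals = {"d": d, "p": float(pretest)}
            pi = params.init.probs(_design_row(params.init.covariates, vals))
            states[j] = rng.choice(M, p=pi)
        else:
            # lagged accumulation: history through item j (1-based j-1..)
            vals = {
                "d": d,
                "p": float(pretest),
                "r": sum_correct / j,
                "f": sum_conf / j,
            }
            P = params.trans.matrices(_design_row(params.trans.covariates, vals))
            states[j] = rng.choice(M, p=P[states[j - 1]])
        m = states[j]
        y = rng.normal(params.emissions.mu[m], params.emissions.sigma[m])
        levels[j] = int(np.clip(np.round(y * N_LEVELS), 1, N_LEVELS))
        correct[j] = draw_correct(levels[j], pretest, config, rng)
        confidence[j] = draw_confidence(correct[j], config, rng)
        sum_correct += correct[j]
        sum_conf += confidence[j]

    record = TestRecord(
        participant_id=participant_id,
        condition=int(condition),
        pretest=float(pretest),
        levels=levels,
        correct=correct,
        confidence=confidence,
    )
    return record, states


def simulate_dataset(config: SimConfig) -> tuple[ProcessDataset, np.ndarray]:
    """A full synthetic cohort; returns (dataset, true state paths (n, T)).

    Fully reproducible from ``config.seed``; the true paths are retained so
    decoding accuracy can be evaluated against the generating chain.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.pretest_bounds
    a = (lo - config.pretest_mean) / config.pretest_sd
    b = (hi - config.pretest_mean) / config.pretest_sd
    conditions = (rng.random(config.n_participants) < config.condition_prob).astype(int)
    pretests = truncnorm.rvs(
        a, b, loc=config.pretest_mean, scale=config.pretest_sd,
        size=config.n_participants, random_state=rng,
    )
    records, paths = [], []
    for i in range(config.n_participants):
        rec, st = simulate_participant(
            config, conditions[i], pretests[i], rng, participant_id=f"sim{i + 1:04d}"
        )
        records.append(rec)
        paths.append(st)
    return ProcessDataset(records), np.stack(paths)


def write_simulation(config: SimConfig, data_path, states_path=None) -> ProcessDataset:
    """Simulate and write the standard CSV (plus optional true-state CSV)."""
    dataset, states = simulate_dataset(config)
    dataset.write_csv(data_path)
    if states_path is not None:
        import pandas as pd

        rows = []
        for i, rec in enumerate(dataset):
            for j in range(rec.n_items):
                rows.append((rec.participant_id, j + 1, int(states[i, j]) + 1))
        pd.DataFrame(rows, columns=["participant", "item", "state"]).to_csv(
            states_path, index=False
        )
    return dataset
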