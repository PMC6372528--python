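"""Sequence-level descriptive summaries of difficulty-choice process data.

Covers the standard pre-modeling checks for this kind of data: the pooled
choice distribution over the seven levels, the most frequent complete
sequences by condition, per-condition counts of upward/downward manifest
moves, the correlations tying difficulty, correctness and confidence
together, and the lag structure of the residuals after removing participant
and item effects (the empirical motivation for a first-order Markov model).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import N_LEVELS, ProcessDataset, TestRecord


def choice_distribution(dataset: ProcessDataset) -> np.ndarray:
    """Pooled proportion of choices at each level 1..7 (sums to one)."""
    levels = dataset.levels_matrix().ravel()
    counts = np.bincount(levels, minlength=N_LEVELS + 1)[1:]
    return counts / counts.sum()


def transition_counts(record: TestRecord) -> dict[str, int]:
    """Counts of strict upward and downward moves in the manifest levels."""
    diffs = np.diff(record.levels)
    return {"up": int(np.sum(diffs > 0)), "down": int(np.sum(diffs < 0))}


def mean_transition_counts(dataset: ProcessDataset) -> pd.DataFrame:
    """Average up/down move counts per participant, split by condition."""
    rows = [
        {"condition": rec.condition, **transition_counts(rec)} for rec in dataset
    ]
    frame = pd.DataFrame(rows)
    return frame.groupby("condition", as_index=False)[["up", "down"]].mean()


def frequent_sequences(dataset: ProcessDataset, k: int = 10) -> dict[int, pd.DataFrame]:
    """Top-k most frequent complete level sequences per condition.

    Exact-match grouping; ranked by count with ties broken by first
    occurrence.  Returns one frame per condition with the sequence (as a
    dash-joined string), its count, and its within-condition proportion.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = {}
    for cond in sorted({rec.condition for rec in dataset}):
        seen: dict[tuple, list] = {}
        n_cond = 0
        for order, rec in enumerate(r for r in dataset if r.condition == cond):
            n_cond += 1
            key = tuple(rec.levels)
            if key not in seen:
                seen[key] = [0, order]
            seen[key][0] += 1
        ranked = sorted(seen.items(), key=lambda kv: (-kv[1][0], kv[1][1]))[:k]
        out[cond] = pd.DataFrame(
            [
                {
                    "sequence": "-".join(map(str, key)),
                    "count": cnt,
                    "proportion": cnt / n_cond,
                }
                for key, (cnt, _) in ranked
            ]
        )
    return out


def association_stats(dataset: ProcessDataset) -> dict[str, float]:
    """Pooled item-level correlations.

    Point-biserial correlations (Pearson with the 0/1 variable) of level and
    of confidence with correctness, and the Pearson correlation of level with
    confidence.
    """
    level = dataset.levels_matrix().ravel().astype(float)
    correct = dataset.correct_matrix().ravel().astype(float)
    conf = dataset.confidence_matrix().ravel()
    for name, v in (("level", level), ("correct", correct), ("confidence", conf)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}")
    return {
        "r_level_correct": float(stats.pearsonr(level, correct)[0]),
        "r_confidence_correct": float(stats.pearsonr(conf, correct)[0]),
        "r_level_confidence": float(stats.pearsonr(level, conf)[0]),
    }


def residual_acf(dataset: ProcessDataset, max_lag: int = 10) -> np.ndarray:
    """Average per-participant autocorrelation of two-way-demeaned choices.

    Residuals are ``y_ij - rowmean_i - colmean_j + grandmean`` (participant
    and item fixed effects removed by demeaning).  The ACF at lags
    1..max_lag is computed per participant and averaged; participants with a
    constant choice sequence, or a (numerically) constant residual sequence,
    carry no lag information and are excluded with a warning.
    """
    y = dataset.scaled_matrix()
    if dataset.n_items <= max_lag:
        raise ValueError("max_lag must be smaller than the sequence length")
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    acfs = []
    n_excluded = 0
    raw_constant = np.ptp(y, axis=1) == 0  # no within-person variation at all
    for i, row in enumerate(resid):
        r0 = row - row.mean()
        denom = np.dot(r0, r0)
        if raw_constant[i] or denom < 1e-12:
            n_excluded += 1
            continue
        acfs.append(
            [np.dot(r0[:-lag], r0[lag:]) / denom for lag in range(1, max_lag + 1)]
        )
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} participants with degenerate residual variance"
        )
    if not acfs:
        raise ValueError("no participant with nondegenerate residuals")
    return np.mean(acfs, axis=0)


def summarize(dataset: ProcessDataset, k_sequences: int = 10, max_lag: int = 10) -> dict:
    """Full descriptive summary as a JSON-serializable dict."""
    freq = frequent_sequences(dataset, k_sequences)
    return {
        "n_participants": dataset.n_participants,
        "n_items": dataset.n_items,
        "choice_distribution": choice_distribution(dataset).tolist(),
        "mean_transitions_by_condition": mean_transition_counts(dataset).to_dict(
            orient="records"
        ),
        "frequent_sequences": {
            str(cond): frame.to_dict(orient="records") for cond, frame in freq.items()
        },
        "associations": association_stats(dataset),
        "residual_acf": residual_acf(dataset, max_lag).tolist(),
    }


def write_summary(dataset: ProcessDataset, path, **kwargs) -> None:
    with open(path, "w") as fh:
        json.dump(summarize(dataset, **kwargs), fh, indent=2)
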