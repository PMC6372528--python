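"""Dataset container, scaling conventions, covariate construction, and CSV I/O.

The data are long-format process records from a self-adapted test: for each
participant and item, the chosen difficulty level (integer 1..7), whether the
answer was correct (0/1), and a confidence rating (0..100 in steps of 10 on
disk, stored internally on [0, 1]).  Each participant additionally carries a
goal-condition indicator ``d`` (1 = performance goal, 0 = learning goal) and a
pre-test proportion correct ``p`` in [0, 1].

Difficulty levels are analyzed on the scale ``y = level / 7`` so that all
model variables live on comparable unit-interval scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_LEVELS = 7

#: canonical CSV column order
CSV_COLUMNS = ["participant", "item", "level", "correct", "confidence", "condition", "pretest"]

#: covariates admissible in the initial-state regression, in reporting order
INIT_COVARIATES = ("d", "p", "dp")
#: covariates admissible in the transition regression, in reporting order
TRANS_COVARIATES = ("d", "f", "r", "fr", "df", "dr", "dfr")


class DataValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


@dataclass
class TestRecord:
    """One participant's complete item-by-item record.

    Parameters
    ----------
    participant_id : str
        Opaque unique identifier.
    condition : int
        Goal condition, 1 = performance, 0 = learning.
    pretest : float
        Pre-test proportion correct in [0, 1].
    levels : ndarray of int
        Chosen difficulty level per item, values in 1..7.
    correct : ndarray of int
        Correctness indicator per item, 0/1.
    confidence : ndarray of float
        Confidence per item on [0, 1] (0.1 grid in the study instrument).
    """

    participant_id: str
    condition: int
    pretest: float
    levels: np.ndarray
    correct: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        self.correct = np.asarray(self.correct, dtype=int)
        self.confidence = np.asarray(self.confidence, dtype=float)
        T = len(self.levels)
        if T < 1:
            raise DataValidationError(f"participant {self.participant_id}: empty sequence")
        if not (len(self.correct) == len(self.confidence) == T):
            raise DataValidationError(
                f"participant {self.participant_id}: sequences of unequal length"
            )
        if self.condition not in (0, 1):
            raise DataValidationError(
                f"participant {self.participant_id}: condition must be 0 or 1"
            )
        if not 0.0 <= self.pretest <= 1.0:
            raise DataValidationError(
                f"participant {self.participant_id}: pretest outside [0, 1]"
            )
        if np.any((self.levels < 1) | (self.levels > N_LEVELS)):
            bad = int(np.argmax((self.levels < 1) | (self.levels > N_LEVELS)))
            raise DataValidationError(
                f"participant {self.participant_id}, item {bad + 1}: "
                f"level {self.levels[bad]} outside 1..{N_LEVELS}"
            )
        if np.any((self.correct != 0) & (self.correct != 1)):
            raise DataValidationError(
                f"participant {self.participant_id}: correct must be 0/1"
            )
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise DataValidationError(
                f"participant {self.participant_id}: confidence outside [0, 1]"
            )

    @property
    def n_items(self) -> int:
        return len(self.levels)

    def scaled_levels(self) -> np.ndarray:
        """Difficulty on the analysis scale y = level / 7, values on {1/7,...,1}."""
        return self.levels / N_LEVELS


@dataclass
class ProcessDataset:
    """A cohort of :class:`TestRecord` sharing a common item count."""

    records: list[TestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise DataValidationError("dataset has no records")
        T = self.records[0].n_items
        ids = set()
        for rec in self.records:
            if rec.n_items != T:
                raise DataValidationError(
                    f"participant {rec.participant_id}: item count {rec.n_items} != {T}"
                )
            if rec.participant_id in ids:
                raise DataValidationError(f"duplicate participant id {rec.participant_id}")
            ids.add(rec.participant_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_participants(self) -> int:
        return len(self.records)

    @property
    def n_items(self) -> int:
        return self.records[0].n_items

    @property
    def n_obs(self) -> int:
        """Total item-level observations (participants x items)."""
        return self.n_participants * self.n_items

    # --- array views used by the estimation code -------------------------

    def levels_matrix(self) -> np.ndarray:
        return np.stack([r.levels for r in self.records])

    def scaled_matrix(self) -> np.ndarray:
        return np.stack([r.scaled_levels() for r in self.records])

    def correct_matrix(self) -> np.ndarray:
        return np.stack([r.correct for r in self.records])

    def confidence_matrix(self) -> np.ndarray:
        return np.stack([r.confidence for r in self.records])

    def conditions(self) -> np.ndarray:
        return np.array([r.condition for r in self.records])

    def pretests(self) -> np.ndarray:
        return np.array([r.pretest for r in self.records])

    # --- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table; confidence reported back on the 0-100 scale."""
        rows = []
        for rec in self.records:
            for j in range(rec.n_items):
                rows.append(
                    (
                        rec.participant_id,
                        j + 1,
                        int(rec.levels[j]),
                        int(rec.correct[j]),
                        int(round(rec.confidence[j] * 100)),
                        rec.condition,
                        rec.pretest,
                    )
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def accumulate(values: Sequence[float], mode: str = "inclusive") -> np.ndarray:
    """Running mean of a unit-interval sequence.

    In ``inclusive`` mode entry j (1-based) is ``mean(values[1..j])``.  In
    ``lagged`` mode it is ``mean(values[1..j-1])``; the first entry has no
    history and is returned as NaN (the transition design never consumes it).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("accumulate expects a nonempty 1-d sequence")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("accumulate expects values in [0, 1]")
    inclusive = np.cumsum(v) / np.arange(1, v.size + 1)
    if mode == "inclusive":
        return inclusive
    if mode == "lagged":
        out = np.empty_like(inclusive)
        out[0] = np.nan
        out[1:] = inclusive[:-1]
        return out
    raise ValueError(f"unknown accumulation mode {mode!r}")


def _covariate_values(record: TestRecord, mode: str) -> dict[str, np.ndarray]:
    """Per-item values of the base covariates and their products."""
    T = record.n_items
    d = np.full(T, float(record.condition))
    p = np.full(T, float(record.pretest))
    r = accumulate(record.correct, mode)
    f = accumulate(record.confidence, mode)
    if mode == "lagged":
        # item 1 has no history; the slot is never used by the transition
        # design (transitions start at item 2) but must not propagate NaN
        r = np.where(np.isnan(r), 0.0, r)
        f = np.where(np.isnan(f), 0.0, f)
    return {
        "d": d,
        "p": p,
        "dp": d * p,
        "r": r,
        "f": f,
        "fr": f * r,
        "df": d * f,
        "dr": d * r,
        "dfr": d * f * r,
    }


def build_design(
    record: TestRecord,
    init_covariates: Iterable[str] = (),
    trans_covariates: Iterable[str] = (),
    mode: str = "inclusive",
) -> tuple[np.ndarray, np.ndarray]:
    """Design vectors for one participant.

    Returns ``(I, H)`` where ``I`` has shape (1 + q_I,) — a leading intercept
    followed by the requested participant-level covariates — and ``H`` has
    shape (T, 1 + q_h) with row j holding the transition covariates evaluated
    at item j+1 (1-based).  Row 0 of ``H`` is never consumed: transitions are
    defined for items 2..T.
    """
    init_covariates = list(init_covariates)
    trans_covariates = list(trans_covariates)
    for name in init_covariates:
        if name not in INIT_COVARIATES:
            raise ValueError(f"unknown initial-state covariate {name!r}")
    for name in trans_covariates:
        if name not in TRANS_COVARIATES:
            raise ValueError(f"unknown transition covariate {name!r}")
    vals = _covariate_values(record, mode)
    I = np.concatenate([[1.0], [vals[name][0] for name in init_covariates]])
    H = np.column_stack(
        [np.ones(record.n_items)] + [vals[name] for name in trans_covariates]
    )
    return I, H


def design_matrices(
    dataset: ProcessDataset,
    init_covariates: Iterable[str] = (),
    trans_covariates: Iterable[str] = (),
    mode: str = "inclusive",
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked designs for a whole cohort: shapes (n, 1+q_I) and (n, T, 1+q_h)."""
    Is, Hs = [], []
    for rec in dataset:
        I, H = build_design(rec, init_covariates, trans_covariates, mode)
        Is.append(I)
        Hs.append(H)
    return np.stack(Is), np.stack(Hs)


def load_dataset(path, validate_grid: bool = True) -> ProcessDataset:
    """Read the long-format CSV and return a validated :class:`ProcessDataset`.

    Expected columns: participant, item, level, correct, confidence (0-100),
    condition, pretest.  Items must be contiguous 1..T within each
    participant, and T must be common across participants.  Confidence is
    rescaled to [0, 1]; with ``validate_grid`` it must sit on the study's
    10-point grid.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing columns: {missing}")
    records = []
    for pid, grp in df.groupby("participant", sort=False):
        grp = grp.sort_values("item")
        items = grp["item"].to_numpy()
        T = len(items)
        if not np.array_equal(items, np.arange(1, T + 1)):
            raise DataValidationError(
                f"participant {pid}: items are not contiguous 1..{T}"
            )
        conf_raw = grp["confidence"].to_numpy(dtype=float)
        if np.any((conf_raw < 0) | (conf_raw > 100)):
            raise DataValidationError(f"participant {pid}: confidence outside 0..100")
        if validate_grid and np.any(np.mod(conf_raw, 10) != 0):
            bad_item = int(grp["item"].to_numpy()[np.argmax(np.mod(conf_raw, 10) != 0)])
            raise DataValidationError(
                f"participant {pid}, item {bad_item}: confidence not on the 10-point grid"
            )
        cond = grp["condition"].unique()
        pre = grp["pretest"].unique()
        if len(cond) != 1 or len(pre) != 1:
            raise DataValidationError(
                f"participant {pid}: condition/pretest vary within participant"
            )
        records.append(
            TestRecord(
                participant_id=str(pid),
                condition=int(cond[0]),
                pretest=float(pre[0]),
                levels=grp["level"].to_numpy(),
                correct=grp["correct"].to_numpy(),
                confidence=conf_raw / 100.0,
            )
        )
    return ProcessDataset(records)
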