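"""Per-trial strategy labelling and per-participant classification.

A cohort is a DataFrame with one row per participant and columns
``participant_id, gender, ethnicity_raw, ethnicity_pooled, response_mode,
answer_t1..answer_t4`` where answers are quadrant codes (FL/FR/BL/BR).
Turn directions come from the trial plan, not from the answer sheet.

Each answer maps to exactly one strategy label (the strategy-quadrant map
is a bijection per turn direction), and a participant is classified as a
strategy user when the same label occurs in at least 75% of their trials
(3 of 4); otherwise they carry no preference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, InvalidParameterError
from .geometry import (
    DEFAULT_TRIAL_PLAN,
    Quadrant,
    Strategy,
    strategy_quadrant_map,
)

__all__ = [
    "NO_PREFERENCE",
    "CLASSIFICATIONS",
    "ANSWER_COLUMNS",
    "LABEL_COLUMNS",
    "ExclusionLog",
    "AnswerFrequencies",
    "TransitionCounts",
    "pool_ethnicity",
    "label_answer",
    "classify_participant",
    "preprocess_cohort",
    "answer_frequencies",
    "transition_counts",
    "any_label_share",
]

NO_PREFERENCE = "no-preference"
#: Participant-level classifications (the four strategies plus no-preference).
CLASSIFICATIONS: tuple[str, ...] = tuple(s.value for s in Strategy) + (NO_PREFERENCE,)

ANSWER_COLUMNS = tuple(f"answer_t{i}" for i in range(1, 5))
LABEL_COLUMNS = tuple(f"label_t{i}" for i in range(1, 5))
_DEMOGRAPHICS = ("gender", "ethnicity_raw")


def pool_ethnicity(raw: str) -> str:
    """Pool raw ethnicity into Caucasian / Chinese / Other."""
    return raw if raw in ("Caucasian", "Chinese") else "Other"


def label_answer(turn_angle: float, answer: Quadrant | str) -> Strategy:
    """The unique strategy whose predicted quadrant equals the answer.

    >>> label_answer(-60, "BL")
    <Strategy.TURNER: 'turner'>
    """
    answer = Quadrant(answer)
    inverse = {q: s for s, q in strategy_quadrant_map(float(turn_angle)).items()}
    return inverse[answer]


def classify_participant(
    labels: Sequence[Strategy | str], threshold: float = 0.75
) -> str:
    """Classify a participant from their per-trial strategy labels.

    The participant is a user of the strategy appearing in at least
    ``ceil(threshold * n_trials)`` trials; with 4 trials and the default
    threshold that is 3.  If no label (or more than one, for other trial
    counts) reaches the cut, the classification is no-preference.
    """
    labels = [Strategy(l).value for l in labels]
    if not labels:
        raise InvalidParameterError("at least one trial label is required")
    need = math.ceil(threshold * len(labels))
    winners = [
        s for s in set(labels) if labels.count(s) >= need
    ]
    return winners[0] if len(winners) == 1 else NO_PREFERENCE


@dataclass(frozen=True)
class ExclusionLog:
    """Counts at each preprocessing step."""

    n_input: int
    n_missing_excluded: int
    n_spinner_excluded: int
    n_analysis: int


def _missing_mask(cohort: pd.DataFrame) -> pd.Series:
    valid_answers = {q.value for q in Quadrant}
    bad = pd.Series(False, index=cohort.index)
    for col in _DEMOGRAPHICS:
        values = cohort[col] if col in cohort else pd.Series(np.nan, index=cohort.index)
        bad |= values.isna() | (values.astype("string").str.strip().fillna("") == "")
    for col in ANSWER_COLUMNS:
        values = cohort[col] if col in cohort else pd.Series(np.nan, index=cohort.index)
        bad |= ~values.isin(valid_answers)
    return bad


def _attach_labels(
    cohort: pd.DataFrame, trial_plan: Sequence[float], threshold: float
) -> pd.DataFrame:
    out = cohort.copy()
    for angle, a_col, l_col in zip(trial_plan, ANSWER_COLUMNS, LABEL_COLUMNS):
        inverse = {
            q.value: s.value
            for s, q in strategy_quadrant_map(float(angle)).items()
        }
        out[l_col] = out[a_col].map(inverse)
    out["classification"] = [
        classify_participant(row, threshold=threshold)
        for row in out[list(LABEL_COLUMNS)].to_numpy()
    ]
    return out


def preprocess_cohort(
    cohort: pd.DataFrame,
    trial_plan: Sequence[float] = DEFAULT_TRIAL_PLAN,
    threshold: float = 0.75,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Filter, label and classify a raw cohort table.

    Rows missing gender, ethnicity, or any trial answer are removed first;
    the survivors are labelled and classified; spinner-classified
    participants are then removed (their data are too sparse to model).
    Surviving rows keep their original order, and the operation is
    idempotent.
    """
    n_input = len(cohort)
    kept = cohort.loc[~_missing_mask(cohort)].copy()
    n_missing = n_input - len(kept)
    if kept.empty:
        raise EmptyCohortError("no participants remain after missing-data filtering")
    kept["ethnicity_pooled"] = kept["ethnicity_raw"].map(pool_ethnicity)
    kept = _attach_labels(kept, trial_plan, threshold)
    spinner = kept["classification"] == Strategy.SPINNER.value
    n_spinner = int(spinner.sum())
    analysis = kept.loc[~spinner].copy()
    if analysis.empty:
        raise EmptyCohortError("no participants remain after spinner exclusion")
    log = ExclusionLog(
        n_input=n_input,
        n_missing_excluded=n_missing,
        n_spinner_excluded=n_spinner,
        n_analysis=len(analysis),
    )
    return analysis, log


@dataclass(frozen=True)
class AnswerFrequencies:
    """Per-trial and pooled strategy-label counts for a classified cohort."""

    per_trial_counts: pd.DataFrame  # trials x 4 strategy labels
    n_participants: int

    @property
    def pooled_counts(self) -> pd.Series:
        return self.per_trial_counts.sum(axis=0)

    @property
    def per_trial_proportions(self) -> pd.DataFrame:
        return self.per_trial_counts.div(self.per_trial_counts.sum(axis=1), axis=0)

    def pooled_proportions(self) -> dict[str, Fraction]:
        """Pooled label shares as exact rationals (they sum to 1 exactly)."""
        counts = self.pooled_counts
        total = int(counts.sum())
        return {k: Fraction(int(v), total) for k, v in counts.items()}


def answer_frequencies(
    cohort: pd.DataFrame, trial_plan: Sequence[float] = DEFAULT_TRIAL_PLAN
) -> AnswerFrequencies:
    """Tabulate per-trial and pooled strategy-label proportions."""
    if not set(LABEL_COLUMNS) <= set(cohort.columns):
        cohort = _attach_labels(cohort, trial_plan, threshold=0.75)
    strategies = [s.value for s in Strategy]
    rows = {}
    for i, col in enumerate(LABEL_COLUMNS, start=1):
        rows[f"trial_{i}"] = cohort[col].value_counts().reindex(strategies, fill_value=0)
    table = pd.DataFrame(rows).T[strategies].astype(int)
    return AnswerFrequencies(per_trial_counts=table, n_participants=len(cohort))


@dataclass(frozen=True)
class TransitionCounts:
    """Label-to-label transition counts between consecutive trials.

    ``matrices[i]`` counts transitions from trial i+1 to trial i+2 (rows:
    previous label, columns: next label).  ``suppressed[i]`` flags cells
    whose count falls below the display cutoff; the counts themselves are
    always retained.
    """

    matrices: tuple[pd.DataFrame, ...]
    suppressed: tuple[pd.DataFrame, ...]
    min_count: int

    @property
    def pooled(self) -> pd.DataFrame:
        return sum(self.matrices)


def transition_counts(cohort: pd.DataFrame, min_count: int = 5) -> TransitionCounts:
    """4x4 transition counts for each consecutive trial pair."""
    if not set(LABEL_COLUMNS) <= set(cohort.columns):
        cohort = _attach_labels(cohort, DEFAULT_TRIAL_PLAN, threshold=0.75)
    strategies = [s.value for s in Strategy]
    matrices, masks = [], []
    for prev, nxt in zip(LABEL_COLUMNS[:-1], LABEL_COLUMNS[1:]):
        table = (
            pd.crosstab(cohort[prev], cohort[nxt])
            .reindex(index=strategies, columns=strategies, fill_value=0)
            .astype(int)
        )
        table.index.name, table.columns.name = "from", "to"
        matrices.append(table)
        masks.append(table < min_count)
    return TransitionCounts(
        matrices=tuple(matrices), suppressed=tuple(masks), min_count=min_count
    )


def any_label_share(
    cohort: pd.DataFrame,
    label: Strategy | str = Strategy.TURNER,
    classification: str | None = NO_PREFERENCE,
) -> Fraction:
    """Share of participants with at least one trial carrying ``label``.

    Restricted to one classification subgroup when ``classification`` is
    given (default: the no-preference group, whose drift toward turner
    answers is the quantity of interest).
    """
    label = Strategy(label).value
    sub = cohort
    if classification is not None:
        sub = cohort.loc[cohort["classification"] == classification]
    if sub.empty:
        raise EmptyCohortError("subgroup is empty")
    has = (sub[list(LABEL_COLUMNS)] == label).any(axis=1)
    return Fraction(int(has.sum()), len(sub))
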