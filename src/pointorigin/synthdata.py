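"""Synthetic cohort generator with the statistical structure the analysis assumes.

Each participant carries a covariate profile (ethnicity, gender, response
mode) drawn from fixed cell sizes, a latent classification drawn from the
softmax model, and four quadrant answers:

* strategy-class participants answer with their strategy's predicted
  quadrant on every trial, each answer independently replaced by a
  uniformly random *other* quadrant with the lapse probability;
* no-preference participants emit a forced 2-2 split over two distinct
  randomly chosen strategies, which guarantees the 75% criterion fails.

Defaults reproduce the published study conditions: cell sizes summing to
501 participants and the published coefficient table capped at |beta| <= 5
(its -12 / +10.4 entries are quasi-separation artifacts that would empty
cells at realistic sample sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax

from .design import (
    BASELINE_CLASS,
    CLASS_ORDER,
    Covariates,
    CoefficientMatrix,
    STUDY_CELL_SIZES,
    STUDY_COEFFICIENTS,
)
from .errors import EmptyCohortError, InvalidCoefficientError, InvalidParameterError
from .geometry import DEFAULT_TRIAL_PLAN, Quadrant, Strategy, strategy_quadrant_map

__all__ = [
    "GeneratorConfig",
    "strategy_probabilities",
    "cap_coefficients",
    "generate_cohort",
    "study_fixture_cohort",
]

_QUADRANTS = tuple(q.value for q in Quadrant)
_STRATEGIES = tuple(s.value for s in Strategy)


def cap_coefficients(
    coefficients: CoefficientMatrix, bound: float = 5.0
) -> tuple[CoefficientMatrix, list[str]]:
    """Clip coefficient magnitudes to ``bound``; note every replacement."""
    if bound <= 0:
        raise InvalidParameterError("bound must be positive")
    values = coefficients.values.copy()
    notes = []
    for outcome in values.columns:
        for term in values.index:
            v = values.at[term, outcome]
            if abs(v) > bound:
                capped = np.sign(v) * bound
                notes.append(f"{outcome} {term}: {v} -> {capped}")
                values.at[term, outcome] = capped
    return CoefficientMatrix(values), notes


def strategy_probabilities(
    covariates: Covariates | Mapping[str, str],
    coefficients: CoefficientMatrix,
) -> pd.Series:
    """Class probabilities (non-turner, turner, non-mover, no-preference).

    Softmax of the linear predictors with the no-preference predictor
    pinned at zero.
    """
    eta = coefficients.linear_predictors(covariates)
    if not np.all(np.isfinite(eta.to_numpy())):
        raise InvalidCoefficientError("non-finite linear predictor")
    return pd.Series(softmax(eta.to_numpy()), index=list(CLASS_ORDER))


def _default_capped() -> CoefficientMatrix:
    return cap_coefficients(STUDY_COEFFICIENTS)[0]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``cell_sizes`` maps (ethnicity, gender, response_mode) to a participant
    count; gender composition per cell is deterministic, so cohorts are
    exactly sized.  ``lapse_rate`` is the per-trial probability that a
    strategy-class participant answers a uniformly random other quadrant.
    """

    cell_sizes: Mapping[tuple[str, str, str], int] = field(
        default_factory=lambda: dict(STUDY_CELL_SIZES)
    )
    coefficients: CoefficientMatrix = field(default_factory=_default_capped)
    lapse_rate: float = 0.05
    trial_plan: Sequence[float] = DEFAULT_TRIAL_PLAN
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise InvalidParameterError("lapse_rate must lie in [0, 1]")
        if any(n < 0 for n in self.cell_sizes.values()):
            raise InvalidParameterError("cell sizes must be non-negative")


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one cohort table in the classification CSV schema.

    The output has one row per participant with demographics, the four
    quadrant answers, and the latent classification (``latent_class``) that
    produced them; byte-identical across runs with the same config.
    """
    if sum(config.cell_sizes.values()) == 0:
        raise EmptyCohortError("cell sizes sum to zero")
    rng = np.random.default_rng(config.seed)
    n_trials = len(config.trial_plan)
    # quadrant_codes[t, s]: quadrant emitted on trial t by strategy index s
    quadrant_codes = np.array(
        [
            [strategy_quadrant_map(float(a))[Strategy(s)].value for s in _STRATEGIES]
            for a in config.trial_plan
        ]
    )
    frames = []
    pid = 0
    for key in sorted(config.cell_sizes):
        n = config.cell_sizes[key]
        if n == 0:
            continue
        ethnicity, gender, mode = key
        probs = strategy_probabilities(
            Covariates(ethnicity=ethnicity, gender=gender, response_mode=mode),
            config.coefficients,
        ).to_numpy()
        latent_idx = rng.choice(len(CLASS_ORDER), size=n, p=probs)
        class_to_strat = np.array(
            [
                _STRATEGIES.index(c) if c in _STRATEGIES else -1
                for c in CLASS_ORDER
            ]
        )
        # strategy index per (participant, trial); filled below for no-pref
        strat_idx = np.repeat(class_to_strat[latent_idx][:, None], n_trials, axis=1)
        nopref = latent_idx == CLASS_ORDER.index(BASELINE_CLASS)
        m = int(nopref.sum())
        if m:
            first = rng.integers(len(_STRATEGIES), size=m)
            second = (first + 1 + rng.integers(len(_STRATEGIES) - 1, size=m)) % len(
                _STRATEGIES
            )
            split = rng.permuted(np.tile([0, 0, 1, 1], (m, 1)), axis=1)
            strat_idx[nopref] = np.where(
                split == 0, first[:, None], second[:, None]
            )
        answers = quadrant_codes[np.arange(n_trials)[None, :], strat_idx]
        if config.lapse_rate > 0:
            lapse = ~nopref[:, None] & (
                rng.random((n, n_trials)) < config.lapse_rate
            )
            shift = rng.integers(1, 4, size=(n, n_trials))
            if lapse.any():
                quad_index = {q: i for i, q in enumerate(_QUADRANTS)}
                codes = np.vectorize(quad_index.__getitem__)(answers)
                lapsed = (codes + shift) % 4
                answers = np.where(
                    lapse, np.array(_QUADRANTS)[lapsed], answers
                )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [f"P{pid + i + 1:04d}" for i in range(n)],
                    "gender": gender,
                    "ethnicity_raw": ethnicity,
                    "ethnicity_pooled": ethnicity,
                    "response_mode": mode,
                    **{
                        f"answer_t{t + 1}": answers[:, t]
                        for t in range(n_trials)
                    },
                    "latent_class": [CLASS_ORDER[i] for i in latent_idx],
                }
            )
        )
        pid += n
    return pd.concat(frames, ignore_index=True)


def study_fixture_cohort(seed: int = 0) -> pd.DataFrame:
    """A 507-row synthetic stand-in for the study's raw response sheets.

    Built from the default generator (501 complete participants), with
    exactly three participants forced to a consistent spinner pattern and
    six appended rows carrying missing demographics or answers, so that
    preprocessing reproduces the study's published flow: 507 collected,
    6 incomplete, 3 spinners, 498 analysed.
    """
    from .classify import classify_participant, label_answer

    config = GeneratorConfig(seed=seed)
    cohort = generate_cohort(config)
    quadrant_by_trial = [
        {s.value: q.value for s, q in strategy_quadrant_map(float(a)).items()}
        for a in config.trial_plan
    ]

    def _classification(row) -> str:
        labels = [
            label_answer(a, row[f"answer_t{i}"])
            for i, a in enumerate(config.trial_plan, start=1)
        ]
        return classify_participant(labels)

    # lapses can in principle manufacture a spinner classification; rewrite
    # any such participant to their latent strategy's clean pattern so the
    # forced count below is exact
    for idx, row in cohort.iterrows():
        if _classification(row) == Strategy.SPINNER.value:
            latent = row["latent_class"]
            target = latent if latent in _STRATEGIES else Strategy.TURNER.value
            for t in range(4):
                cohort.at[idx, f"answer_t{t + 1}"] = quadrant_by_trial[t][target]

    rng = np.random.default_rng(seed + 1)
    forced = rng.choice(len(cohort), size=3, replace=False)
    for idx in cohort.index[forced]:
        for t in range(4):
            cohort.at[idx, f"answer_t{t + 1}"] = quadrant_by_trial[t][
                Strategy.SPINNER.value
            ]

    incomplete = []
    for j in range(6):
        row = {
            "participant_id": f"X{j + 1:04d}",
            "gender": "female" if j % 2 else np.nan,
            "ethnicity_raw": np.nan if j % 2 else "Caucasian",
            "ethnicity_pooled": np.nan,
            "response_mode": "pictorial",
            "answer_t1": "FL",
            "answer_t2": "FL",
            "answer_t3": np.nan if j == 5 else "FL",
            "answer_t4": "FL",
            "latent_class": np.nan,
        }
        incomplete.append(row)
    return pd.concat(
        [cohort, pd.DataFrame(incomplete)], ignore_index=True
    )
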