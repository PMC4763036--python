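"""Pairwise odds ratios from a multinomial coefficient matrix.

For a softmax model with baseline class b0 and coefficient vectors beta_k,
the odds of class A against class B at covariate profile x are
p_A / p_B = exp(x . (beta_A - beta_B)).  Moving one factor from level
``b`` to level ``a`` while holding the remaining factors at a fixed
profile changes each class's linear predictor by Delta_k = c . beta_k,
where c = x(a) - x(b) is the contrast vector, so

    OR = exp(Delta_target - Delta_baseline).

Refitting under a different choice of dummy-coding reference levels
("baseline rotation") re-parametrises the same model; every pairwise OR is
invariant to it.  The engine therefore computes ORs for all outcome pairs,
factor contrasts and profiles directly from one coefficient matrix, and
keeps the rotation enumeration only as an explicit reporting device.

Wald intervals on the log scale use the full coefficient covariance when a
fitted model supplies one; with only published per-coefficient standard
errors, an independent-SE approximation (sum of squared weighted SEs) is
used and flagged as approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    BASELINE_CLASS,
    CLASS_ORDER,
    CoefficientMatrix,
    FACTORS,
    TERMS,
    design_vector,
)
from .errors import InvalidContrastError
from .glm import ModelFit

__all__ = [
    "ORRecord",
    "odds_ratio",
    "enumerate_rotations",
    "significant_ors",
    "or_table",
]


@dataclass(frozen=True)
class ORRecord:
    """One pairwise-outcome, pairwise-level odds ratio.

    The ratio contrasts ``outcome_pair[0]`` (target) against
    ``outcome_pair[1]`` (baseline outcome) when ``factor`` moves from
    ``level_b`` to ``level_a``, with the remaining factors held at
    ``profile``.  ``approximate_ci`` marks intervals built from
    per-coefficient SEs without covariance terms.
    """

    outcome_pair: tuple[str, str]
    factor: str
    level_a: str
    level_b: str
    profile: tuple[tuple[str, str], ...]
    or_value: float
    log_or: float
    se_log_or: float | None = None
    wald_ci: tuple[float, float] | None = None
    significant: bool | None = None
    approximate_ci: bool = False

    def mirrored(self) -> "ORRecord":
        """The reciprocal record (swapped outcomes, swapped levels)."""
        ci = None
        if self.wald_ci is not None:
            ci = (1.0 / self.wald_ci[1], 1.0 / self.wald_ci[0])
        return ORRecord(
            outcome_pair=(self.outcome_pair[1], self.outcome_pair[0]),
            factor=self.factor,
            level_a=self.level_b,
            level_b=self.level_a,
            profile=self.profile,
            or_value=1.0 / self.or_value,
            log_or=-self.log_or,
            se_log_or=self.se_log_or,
            wald_ci=ci,
            significant=self.significant,
            approximate_ci=self.approximate_ci,
        )


def _contrast_vector(
    factor: str, level_a: str, level_b: str, profile: Mapping[str, str]
) -> np.ndarray:
    if factor not in FACTORS:
        raise InvalidContrastError(f"unknown factor {factor!r}")
    for level in (level_a, level_b):
        if level not in FACTORS[factor]:
            raise InvalidContrastError(
                f"{level!r} is not a level of {factor} {FACTORS[factor]}"
            )
    missing = [f for f in FACTORS if f != factor and f not in profile]
    if missing:
        raise InvalidContrastError(f"profile must fix factors {missing}")
    base = {f: profile[f] for f in FACTORS if f != factor}
    xa = design_vector({**base, factor: level_a})
    xb = design_vector({**base, factor: level_b})
    return xa - xb


def _outcome_delta(
    coefficients: CoefficientMatrix, outcome: str, contrast: np.ndarray
) -> float:
    if outcome == BASELINE_CLASS:
        return 0.0
    if outcome not in coefficients.values.columns:
        raise InvalidContrastError(f"unknown outcome {outcome!r}")
    return float(contrast @ coefficients.values[outcome].to_numpy())


def odds_ratio(
    coefficients: CoefficientMatrix,
    outcome_pair: tuple[str, str],
    factor_contrast: tuple[str, str, str],
    profile: Mapping[str, str],
) -> ORRecord:
    """Point-estimate OR for one outcome pair, factor contrast and profile.

    ``factor_contrast`` is (factor, level_a, level_b); the OR answers "how
    much more likely is the target outcome, rather than the baseline
    outcome, at level_a compared with level_b".
    """
    factor, level_a, level_b = factor_contrast
    c = _contrast_vector(factor, level_a, level_b, profile)
    target, base_outcome = outcome_pair
    log_or = _outcome_delta(coefficients, target, c) - _outcome_delta(
        coefficients, base_outcome, c
    )
    prof = tuple(sorted((k, v) for k, v in profile.items() if k != factor))
    return ORRecord(
        outcome_pair=(target, base_outcome),
        factor=factor,
        level_a=level_a,
        level_b=level_b,
        profile=prof,
        or_value=float(np.exp(log_or)),
        log_or=float(log_or),
    )


def _stacked_weights(
    outcomes: Sequence[str],
    target: str,
    base_outcome: str,
    contrast: np.ndarray,
    terms: Sequence[str],
) -> np.ndarray:
    """Delta-method weight vector over the (outcome, term) parameter stack."""
    w = np.zeros(len(outcomes) * len(terms))
    for sign, outcome in ((1.0, target), (-1.0, base_outcome)):
        if outcome == BASELINE_CLASS:
            continue
        j = list(outcomes).index(outcome)
        w[j * len(terms) : (j + 1) * len(terms)] += sign * contrast
    return w


def _se_log_or(
    record: ORRecord,
    coefficients: CoefficientMatrix,
    cov: pd.DataFrame | None,
    se_table: CoefficientMatrix | None,
) -> tuple[float, bool]:
    c = _contrast_vector(
        record.factor, record.level_a, record.level_b, dict(record.profile)
    )
    outcomes = list(coefficients.values.columns)
    w = _stacked_weights(
        outcomes, record.outcome_pair[0], record.outcome_pair[1], c, list(TERMS)
    )
    if cov is not None:
        var = float(w @ cov.to_numpy() @ w)
        return np.sqrt(max(var, 0.0)), False
    if se_table is None:
        raise InvalidContrastError("need a covariance matrix or an SE table")
    se_stack = np.concatenate(
        [se_table.values[o].to_numpy() for o in outcomes]
    )
    return float(np.sqrt(np.sum((w * se_stack) ** 2))), True


def with_wald_interval(
    record: ORRecord,
    coefficients: CoefficientMatrix,
    cov: pd.DataFrame | None = None,
    se_table: CoefficientMatrix | None = None,
    alpha: float = 0.05,
) -> ORRecord:
    """Attach a Wald interval (log scale) and significance flag to a record."""
    se, approximate = _se_log_or(record, coefficients, cov, se_table)
    if not np.isfinite(se):
        # separated directions carry no usable curvature: infinite interval
        se, approximate = np.inf, True
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo, hi = np.exp(record.log_or - z * se), np.exp(record.log_or + z * se)
    return ORRecord(
        outcome_pair=record.outcome_pair,
        factor=record.factor,
        level_a=record.level_a,
        level_b=record.level_b,
        profile=record.profile,
        or_value=record.or_value,
        log_or=record.log_or,
        se_log_or=se,
        wald_ci=(float(lo), float(hi)),
        significant=bool(not (lo <= 1.0 <= hi)),
        approximate_ci=approximate,
    )


def enumerate_rotations() -> list[dict[str, str]]:
    """All reference-level combinations of the dummy coding (12 profiles).

    Each rotation re-parametrises — never changes — the fitted model, so
    the OR set computed under any rotation is identical.
    """
    return [
        dict(zip(FACTORS, levels))
        for levels in product(*FACTORS.values())
    ]


def _all_records(
    coefficients: CoefficientMatrix,
) -> list[ORRecord]:
    records = []
    for target, base_outcome in combinations(CLASS_ORDER, 2):
        for factor, levels in FACTORS.items():
            others = [f for f in FACTORS if f != factor]
            for level_a, level_b in combinations(levels, 2):
                for profile_levels in product(*(FACTORS[f] for f in others)):
                    profile = dict(zip(others, profile_levels))
                    records.append(
                        odds_ratio(
                            coefficients,
                            (target, base_outcome),
                            (factor, level_a, level_b),
                            profile,
                        )
                    )
    return records


def significant_ors(
    fit: ModelFit | None = None,
    coefficients: CoefficientMatrix | None = None,
    se_table: CoefficientMatrix | None = None,
    alpha: float = 0.05,
    or_window: tuple[float, float] = (0.001, 100.0),
) -> list[ORRecord]:
    """Every significant odds ratio, filtered and reported in >1 orientation.

    Enumerates all outcome pairs, factor-level contrasts and covariate
    profiles; keeps records whose Wald interval excludes 1; drops ORs
    outside ``or_window`` (values beyond it are near-certainly artifacts of
    sparse cells); and reports only the greater-than-one orientation of
    each mirror pair.

    Pass either a fitted model (full-covariance intervals) or a printed
    coefficient matrix with its SE table (approximate intervals).
    """
    if fit is not None:
        coefficients = fit.coefficient_matrix
        cov = fit.cov
    elif coefficients is not None:
        cov = None
        if se_table is None:
            raise InvalidContrastError(
                "printed-coefficient mode needs an SE table"
            )
        warnings.warn(
            "no coefficient covariance available; Wald intervals use the "
            "independent-SE approximation",
            stacklevel=2,
        )
    else:
        raise InvalidContrastError("provide a ModelFit or a CoefficientMatrix")

    kept = []
    for record in _all_records(coefficients):
        record = with_wald_interval(
            record, coefficients, cov=cov, se_table=se_table, alpha=alpha
        )
        if not record.significant:
            continue
        oriented = record if record.or_value > 1.0 else record.mirrored()
        if not or_window[0] <= oriented.or_value <= or_window[1]:
            continue
        kept.append(oriented)
    return kept


def chord_summary(records: Sequence[ORRecord]) -> dict:
    """Group significant ORs by contrast factor (the chord-plot layout).

    Each entry links a baseline side (outcome made less likely at level_a)
    to a target side (outcome made more likely), as a chord diagram draws
    them.
    """
    summary: dict[str, list[dict]] = {}
    for r in records:
        summary.setdefault(r.factor, []).append(
            {
                "more_likely": r.outcome_pair[0],
                "instead_of": r.outcome_pair[1],
                "at_level": r.level_a,
                "vs_level": r.level_b,
                "profile": dict(r.profile),
                "or": round(float(f"{r.or_value:.3g}"), 10),
            }
        )
    return summary


def or_table(records: Sequence[ORRecord]) -> pd.DataFrame:
    """Flatten OR records to a DataFrame (the CSV report layout)."""
    rows = []
    for r in records:
        rows.append(
            {
                "target_outcome": r.outcome_pair[0],
                "baseline_outcome": r.outcome_pair[1],
                "factor": r.factor,
                "level_a": r.level_a,
                "level_b": r.level_b,
                "profile": "; ".join(f"{k}={v}" for k, v in r.profile),
                "or": r.or_value,
                "ci_low": r.wald_ci[0] if r.wald_ci else np.nan,
                "ci_high": r.wald_ci[1] if r.wald_ci else np.nan,
                "significant": r.significant,
                "approximate_ci": r.approximate_ci,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "target_outcome",
            "baseline_outcome",
            "factor",
            "level_a",
            "level_b",
            "profile",
            "or",
            "ci_low",
            "ci_high",
            "significant",
            "approximate_ci",
        ],
    )
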