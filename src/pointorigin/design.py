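"""Factor coding, design vectors, and the multinomial coefficient container.

The classification model regresses a four-level outcome (non-turner,
turner, non-mover, with no-preference as the baseline category) on three
fully crossed categorical factors — ethnicity (Caucasian, Chinese, Other),
response mode (pictorial, text) and gender (female, male) — with all
interaction terms.  Dummy coding uses the first level of each factor as the
reference, yielding 12 design terms per non-baseline outcome.

``STUDY_COEFFICIENTS`` and ``STUDY_STANDARD_ERRORS`` hold the published
estimates from a large classroom study of the task (N = 498 analysed);
``STUDY_CELL_SIZES`` holds that study's subgroup sizes (summing to 501
before spinner exclusion).  They are the default generating model and the
worked-example input for the odds-ratio engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidCoefficientError, InvalidContrastError

__all__ = [
    "FACTORS",
    "TERMS",
    "TERM_GROUPS",
    "OUTCOMES",
    "CLASS_ORDER",
    "BASELINE_CLASS",
    "Covariates",
    "design_vector",
    "CoefficientMatrix",
    "STUDY_COEFFICIENTS",
    "STUDY_STANDARD_ERRORS",
    "STUDY_CELL_SIZES",
]

#: Factor levels; the first level of each factor is the dummy-coding reference.
FACTORS: dict[str, tuple[str, ...]] = {
    "ethnicity": ("Caucasian", "Chinese", "Other"),
    "response_mode": ("pictorial", "text"),
    "gender": ("female", "male"),
}

#: The 12 design terms, in the order used throughout the package.
TERMS: tuple[str, ...] = (
    "Intercept",
    "EthnicityChinese",
    "EthnicityOther",
    "ResponseModeText",
    "GenderMale",
    "EthnicityChinese:ResponseModeText",
    "EthnicityOther:ResponseModeText",
    "EthnicityChinese:GenderMale",
    "EthnicityOther:GenderMale",
    "ResponseModeText:GenderMale",
    "EthnicityChinese:ResponseModeText:GenderMale",
    "EthnicityOther:ResponseModeText:GenderMale",
)

#: Model terms (factors and interactions) -> the design columns they own.
TERM_GROUPS: dict[str, tuple[str, ...]] = {
    "Ethnicity": ("EthnicityChinese", "EthnicityOther"),
    "Response mode": ("ResponseModeText",),
    "Gender": ("GenderMale",),
    "Ethnicity:Response mode": (
        "EthnicityChinese:ResponseModeText",
        "EthnicityOther:ResponseModeText",
    ),
    "Ethnicity:Gender": (
        "EthnicityChinese:GenderMale",
        "EthnicityOther:GenderMale",
    ),
    "Response mode:Gender": ("ResponseModeText:GenderMale",),
    "Ethnicity:Response mode:Gender": (
        "EthnicityChinese:ResponseModeText:GenderMale",
        "EthnicityOther:ResponseModeText:GenderMale",
    ),
}

#: Non-baseline outcomes, in coefficient-table column order.
OUTCOMES: tuple[str, ...] = ("non-turner", "turner", "non-mover")
BASELINE_CLASS = "no-preference"
#: Probability-vector order used by the generator and the bootstrap.
CLASS_ORDER: tuple[str, ...] = ("non-turner", "turner", "non-mover", "no-preference")


@dataclass(frozen=True)
class Covariates:
    """One participant's factor levels."""

    ethnicity: str
    gender: str
    response_mode: str

    def __post_init__(self) -> None:
        for factor in FACTORS:
            level = getattr(self, factor)
            if level not in FACTORS[factor]:
                raise InvalidContrastError(
                    f"{level!r} is not a level of {factor} {FACTORS[factor]}"
                )


def design_vector(covariates: Covariates | Mapping[str, str]) -> np.ndarray:
    """12-element dummy-coded design row for one covariate profile."""
    if not isinstance(covariates, Covariates):
        covariates = Covariates(**dict(covariates))
    chin = float(covariates.ethnicity == "Chinese")
    oth = float(covariates.ethnicity == "Other")
    text = float(covariates.response_mode == "text")
    male = float(covariates.gender == "male")
    return np.array(
        [
            1.0,
            chin,
            oth,
            text,
            male,
            chin * text,
            oth * text,
            chin * male,
            oth * male,
            text * male,
            chin * text * male,
            oth * text * male,
        ]
    )


@dataclass(frozen=True)
class CoefficientMatrix:
    """Multinomial linear-predictor coefficients.

    ``values`` is a (12 terms x 3 outcomes) DataFrame indexed by ``TERMS``
    with columns ``OUTCOMES``; the baseline outcome (no-preference) has an
    implicit all-zero column.
    """

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if list(v.index) != list(TERMS) or list(v.columns) != list(OUTCOMES):
            try:
                v = v.loc[list(TERMS), list(OUTCOMES)]
            except KeyError as exc:
                raise InvalidCoefficientError(
                    "coefficient matrix must cover all design terms and outcomes"
                ) from exc
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidCoefficientError("coefficients must be finite")
        object.__setattr__(self, "values", v.astype(float))

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, float]]) -> "CoefficientMatrix":
        """Build from ``{outcome: {term: value}}``."""
        frame = pd.DataFrame(
            {k: pd.Series(dict(v)) for k, v in data.items()}
        ).reindex(index=list(TERMS), columns=list(OUTCOMES))
        if frame.isna().any().any():
            raise InvalidCoefficientError("missing terms or outcomes in mapping")
        return cls(frame)

    def linear_predictors(self, covariates: Covariates | Mapping[str, str]) -> pd.Series:
        """Linear predictor per class in ``CLASS_ORDER`` (baseline fixed at 0)."""
        x = design_vector(covariates)
        eta = x @ self.values.to_numpy()
        return pd.Series(
            np.append(eta, 0.0), index=list(OUTCOMES) + [BASELINE_CLASS]
        )[list(CLASS_ORDER)]

    def coefficient(self, outcome: str, term: str) -> float:
        if outcome == BASELINE_CLASS:
            return 0.0
        return float(self.values.at[term, outcome])


def _matrix(rows: dict[str, tuple[float, float, float]]) -> CoefficientMatrix:
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(OUTCOMES))
    return CoefficientMatrix(frame.reindex(list(TERMS)))


#: Published multinomial estimates (columns: non-turner, turner, non-mover;
#: baseline no-preference; reference levels Caucasian, pictorial, female).
STUDY_COEFFICIENTS = _matrix(
    {
        "Intercept": (1.15, 0.251, -0.847),
        "EthnicityChinese": (-0.0136, -0.944, 0.847),
        "EthnicityOther": (-0.0469, -1.06, 0.847),
        "ResponseModeText": (-0.452, 0.704, -0.763),
        "GenderMale": (-0.766, 0.516, -1.02),
        "EthnicityChinese:ResponseModeText": (-0.998, 0.156, -0.249),
        "EthnicityOther:ResponseModeText": (0.453, 0.396, -12.0),
        "EthnicityChinese:GenderMale": (1.35, 0.0226, 0.87),
        "EthnicityOther:GenderMale": (1.05, 0.701, 1.31),
        "ResponseModeText:GenderMale": (0.508, -0.824, 1.85),
        "EthnicityChinese:ResponseModeText:GenderMale": (-0.775, 0.119, -1.37),
        "EthnicityOther:ResponseModeText:GenderMale": (-1.08, -0.276, 10.4),
    }
)

#: Published standard errors, same layout as ``STUDY_COEFFICIENTS``.
STUDY_STANDARD_ERRORS = _matrix(
    {
        "Intercept": (0.434, 0.504, 0.69),
        "EthnicityChinese": (0.566, 0.744, 0.822),
        "EthnicityOther": (0.58, 0.784, 0.836),
        "ResponseModeText": (0.699, 0.729, 1.29),
        "GenderMale": (0.564, 0.605, 1.03),
        "EthnicityChinese:ResponseModeText": (0.915, 0.999, 1.49),
        "EthnicityOther:ResponseModeText": (1.04, 1.21, 0.66),
        "EthnicityChinese:GenderMale": (0.787, 0.988, 1.25),
        "EthnicityOther:GenderMale": (0.821, 1.0, 1.25),
        "ResponseModeText:GenderMale": (0.876, 0.884, 1.6),
        "EthnicityChinese:ResponseModeText:GenderMale": (1.24, 1.35, 1.94),
        "EthnicityOther:ResponseModeText:GenderMale": (1.39, 1.56, 0.66),
    }
)

#: Subgroup sizes (ethnicity, gender, response_mode) -> participant count.
STUDY_CELL_SIZES: dict[tuple[str, str, str], int] = {
    ("Caucasian", "male", "pictorial"): 62,
    ("Caucasian", "female", "pictorial"): 41,
    ("Caucasian", "male", "text"): 55,
    ("Caucasian", "female", "text"): 29,
    ("Chinese", "male", "pictorial"): 58,
    ("Chinese", "female", "pictorial"): 56,
    ("Chinese", "male", "text"): 29,
    ("Chinese", "female", "text"): 36,
    ("Other", "male", "pictorial"): 47,
    ("Other", "female", "pictorial"): 49,
    ("Other", "male", "text"): 22,
    ("Other", "female", "text"): 17,
}


def all_profiles() -> list[dict[str, str]]:
    """Every combination of factor levels, in deterministic order."""
    return [
        {"ethnicity": e, "response_mode": m, "gender": g}
        for e, m, g in product(
            FACTORS["ethnicity"], FACTORS["response_mode"], FACTORS["gender"]
        )
    ]
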