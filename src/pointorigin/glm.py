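"""Multinomial and binary logistic models of the participant classification.

The outcome is the four-level classification (baseline: no-preference)
regressed on ethnicity, response mode and gender with all interactions —
12 dummy-coded design terms per non-baseline outcome.  Fitting is
maximum likelihood via Newton iterations from a zero start, so results are
deterministic given the data.  Likelihood-ratio term tests refit the model
with one term's columns removed while every other term is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import (
    BASELINE_CLASS,
    CLASS_ORDER,
    CoefficientMatrix,
    OUTCOMES,
    TERM_GROUPS,
    TERMS,
    design_vector,
)
from .errors import DegenerateOutcomeError, RankDeficiencyError

__all__ = [
    "ModelFit",
    "LRTestRow",
    "build_design_matrix",
    "fit_multinomial",
    "likelihood_ratio_tests",
    "training_accuracy",
    "fit_binary_logistic",
]

#: Fitted |coefficient| and SE beyond which quasi-separation is suspected.
SEPARATION_SE = 10.0


@dataclass(frozen=True)
class ModelFit:
    """A fitted classification model.

    ``coefficients`` and ``standard_errors`` are (terms x outcomes)
    DataFrames; ``cov`` is the full coefficient covariance with a
    (outcome, term) MultiIndex.  ``outcomes`` lists the non-baseline
    outcomes and ``baseline`` the reference class.
    """

    coefficients: pd.DataFrame
    standard_errors: pd.DataFrame
    cov: pd.DataFrame
    log_likelihood: float
    n_obs: int
    converged: bool
    terms: tuple[str, ...]
    outcomes: tuple[str, ...]
    baseline: str

    @property
    def coefficient_matrix(self) -> CoefficientMatrix:
        """The fit as a full-design CoefficientMatrix (multinomial fits only)."""
        if self.terms != tuple(TERMS) or self.outcomes != tuple(OUTCOMES):
            raise RankDeficiencyError(
                "fit does not span the full design; no coefficient matrix"
            )
        return CoefficientMatrix(self.coefficients)

    def predict_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        """Class probabilities per row of a design matrix."""
        eta = X.to_numpy() @ self.coefficients.to_numpy()
        eta = np.column_stack([eta, np.zeros(len(X))])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, columns=list(self.outcomes) + [self.baseline])


@dataclass(frozen=True)
class LRTestRow:
    """One likelihood-ratio term test."""

    term: str
    lr_chi2: float
    df: int
    p: float
    converged: bool = True


def build_design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded design matrix (rows follow the cohort, columns TERMS)."""
    rows = np.stack(
        [
            design_vector(
                {
                    "ethnicity": e,
                    "gender": g,
                    "response_mode": m,
                }
            )
            for e, g, m in zip(
                cohort["ethnicity_pooled"],
                cohort["gender"],
                cohort["response_mode"],
            )
        ]
    )
    return pd.DataFrame(rows, columns=list(TERMS), index=cohort.index)


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name an empty covariate cell if one exists
        counts = X.T @ X
        empty = [c for c in X.columns if counts.at[c, c] == 0]
        detail = f" (empty design cell: {empty})" if empty else ""
        raise RankDeficiencyError(
            f"design matrix has rank {rank} < {X.shape[1]}{detail}"
        )


def _fit_mnlogit(y: np.ndarray, X: pd.DataFrame, maxiter: int = 200):
    model = sm.MNLogit(y, X.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=maxiter, disp=0, tol=1e-10)
        except np.linalg.LinAlgError:
            res = None
        # Newton overflows under (quasi-)separation; a gradient method then
        # still yields finite estimates with the correct predicted classes
        if res is None or not np.all(np.isfinite(res.params)):
            res = model.fit(method="lbfgs", maxiter=5 * maxiter, disp=0)
    return res


def fit_multinomial(
    cohort: pd.DataFrame,
    terms: Sequence[str] | None = None,
    maxiter: int = 200,
) -> ModelFit:
    """ML fit of the softmax classification model on a preprocessed cohort.

    ``cohort`` must carry a ``classification`` column over the four
    analysis classes (spinners already excluded).  ``terms`` restricts the
    design columns (default: the full 12-term design).  Non-convergence is
    flagged on the returned fit, not raised.
    """
    terms = tuple(terms) if terms is not None else tuple(TERMS)
    observed = cohort["classification"]
    present = [c for c in CLASS_ORDER if (observed == c).any()]
    if BASELINE_CLASS not in present or len(present) < 2:
        raise DegenerateOutcomeError(
            f"outcome needs the baseline class and at least one other; saw {present}"
        )
    if set(observed) - set(CLASS_ORDER):
        raise DegenerateOutcomeError(
            f"unexpected classes {sorted(set(observed) - set(CLASS_ORDER))}"
        )
    # code 0 = baseline so the softmax contrasts match the coefficient table
    level_order = [BASELINE_CLASS] + [c for c in OUTCOMES if c in present]
    y = observed.map({c: i for i, c in enumerate(level_order)}).to_numpy()
    X = build_design_matrix(cohort)[list(terms)]
    _check_design(X)
    res = _fit_mnlogit(y, X, maxiter=maxiter)
    outcomes = tuple(level_order[1:])
    coef = pd.DataFrame(res.params, index=list(terms), columns=list(outcomes))
    se = pd.DataFrame(res.bse, index=list(terms), columns=list(outcomes))
    flat_index = pd.MultiIndex.from_product(
        [list(outcomes), list(terms)], names=["outcome", "term"]
    )
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=flat_index, columns=flat_index)
    converged = bool(res.mle_retvals.get("converged", False))
    if converged and (se.to_numpy() > SEPARATION_SE).any():
        warnings.warn(
            "standard errors above %g suggest quasi-separation" % SEPARATION_SE,
            stacklevel=2,
        )
    return ModelFit(
        coefficients=coef,
        standard_errors=se,
        cov=cov,
        log_likelihood=float(res.llf),
        n_obs=len(cohort),
        converged=converged,
        terms=terms,
        outcomes=outcomes,
        baseline=BASELINE_CLASS,
    )


def fit_binary_logistic(cohort: pd.DataFrame, maxiter: int = 200) -> ModelFit:
    """Binary logit of turner vs non-turner with the same design.

    Rows with other classifications must be removed beforehand; the
    baseline (code 0) is non-turner, so coefficients are turner log-odds.
    """
    observed = cohort["classification"]
    classes = sorted(set(observed))
    if set(classes) != {"turner", "non-turner"}:
        raise DegenerateOutcomeError(
            f"binary fit needs exactly the classes turner and non-turner; saw {classes}"
        )
    y = (observed == "turner").to_numpy(dtype=float)
    X = build_design_matrix(cohort)
    _check_design(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X.to_numpy()).fit(
            method="newton", maxiter=maxiter, disp=0, tol=1e-10
        )
    outcomes = ("turner",)
    coef = pd.DataFrame(
        res.params[:, None], index=list(TERMS), columns=list(outcomes)
    )
    se = pd.DataFrame(res.bse[:, None], index=list(TERMS), columns=list(outcomes))
    flat_index = pd.MultiIndex.from_product(
        [list(outcomes), list(TERMS)], names=["outcome", "term"]
    )
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=flat_index, columns=flat_index)
    return ModelFit(
        coefficients=coef,
        standard_errors=se,
        cov=cov,
        log_likelihood=float(res.llf),
        n_obs=len(cohort),
        converged=bool(res.mle_retvals.get("converged", False)),
        terms=tuple(TERMS),
        outcomes=outcomes,
        baseline="non-turner",
    )


def _reduced_loglik(cohort: pd.DataFrame, terms: Sequence[str], binary: bool) -> tuple[float, bool]:
    if binary:
        y = (cohort["classification"] == "turner").to_numpy(dtype=float)
        X = build_design_matrix(cohort)[list(terms)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X.to_numpy()).fit(
                method="newton", maxiter=200, disp=0, tol=1e-10
            )
        return float(res.llf), bool(res.mle_retvals.get("converged", False))
    sub = fit_multinomial(cohort, terms=terms)
    return sub.log_likelihood, sub.converged


def likelihood_ratio_tests(
    fit: ModelFit,
    cohort: pd.DataFrame,
    scheme: str = "drop-one",
) -> list[LRTestRow]:
    """Likelihood-ratio tests of every model term.

    ``scheme='drop-one'`` removes only the tested term's columns, keeping
    all other terms including interactions that contain it (the layout
    matches a term-per-row ANOVA table).  ``scheme='hierarchical'`` also
    removes every higher-order term containing the tested factor(s).

    df per row is (columns removed) x (non-baseline outcome contrasts).
    """
    if scheme not in ("drop-one", "hierarchical"):
        raise ValueError("scheme must be 'drop-one' or 'hierarchical'")
    binary = fit.baseline != BASELINE_CLASS
    n_contrasts = len(fit.outcomes)
    rows = []
    for term, columns in TERM_GROUPS.items():
        drop = set(columns)
        if scheme == "hierarchical":
            factors = set(term.split(":"))
            for other, cols in TERM_GROUPS.items():
                if factors <= set(other.split(":")):
                    drop |= set(cols)
        reduced_terms = [t for t in fit.terms if t not in drop]
        df = (len(fit.terms) - len(reduced_terms)) * n_contrasts
        try:
            ll0, conv = _reduced_loglik(cohort, reduced_terms, binary)
        except (RankDeficiencyError, DegenerateOutcomeError):
            rows.append(LRTestRow(term, np.nan, df, np.nan, converged=False))
            continue
        lr = max(2.0 * (fit.log_likelihood - ll0), 0.0)
        rows.append(
            LRTestRow(
                term=term,
                lr_chi2=lr,
                df=df,
                p=float(stats.chi2.sf(lr, df)),
                converged=conv,
            )
        )
    return rows


def training_accuracy(fit: ModelFit, cohort: pd.DataFrame) -> float:
    """Share of participants whose modal predicted class is their observed one."""
    X = build_design_matrix(cohort)[list(fit.terms)]
    probs = fit.predict_probabilities(X)
    predicted = probs.columns[np.argmax(probs.to_numpy(), axis=1)]
    observed = cohort["classification"].to_numpy()
    return float(np.mean(predicted == observed))
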