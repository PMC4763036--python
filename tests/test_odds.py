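"""Odds-ratio extraction: worked examples, symmetries and filtering."""

import numpy as np
import pytest

from pointorigin.design import (
    CLASS_ORDER,
    Covariates,
    STUDY_COEFFICIENTS,
    STUDY_STANDARD_ERRORS,
)
from pointorigin.errors import InvalidContrastError
from pointorigin.odds import (
    enumerate_rotations,
    odds_ratio,
    or_table,
    significant_ors,
    with_wald_interval,
)
from pointorigin.synthdata import strategy_probabilities

PICT_MALE = {"ethnicity": "Chinese", "response_mode": "pictorial", "gender": "male"}


#: (outcome pair, factor contrast, profile, published value, printed precision)
WORKED_EXAMPLES = [
    (
        ("turner", "non-turner"),
        ("gender", "male", "female"),
        {"ethnicity": "Caucasian", "response_mode": "pictorial"},
        3.6,
        0.05,
    ),
    (
        ("non-turner", "no-preference"),
        ("ethnicity", "Chinese", "Caucasian"),
        {"gender": "male", "response_mode": "pictorial"},
        3.81,
        0.005,
    ),
    (
        ("turner", "non-mover"),
        ("ethnicity", "Caucasian", "Chinese"),
        {"gender": "male", "response_mode": "pictorial"},
        13.99,
        0.005,
    ),
    (
        ("turner", "non-mover"),
        ("ethnicity", "Caucasian", "Chinese"),
        {"gender": "female", "response_mode": "pictorial"},
        6.0,
        0.05,
    ),
    (
        ("non-turner", "turner"),
        ("response_mode", "pictorial", "text"),
        {"ethnicity": "Caucasian", "gender": "female"},
        3.18,
        0.005,
    ),
    (
        ("non-turner", "turner"),
        ("response_mode", "pictorial", "text"),
        {"ethnicity": "Chinese", "gender": "male"},
        6.5,
        0.05,
    ),
    (
        ("non-turner", "turner"),
        ("response_mode", "pictorial", "text"),
        {"ethnicity": "Chinese", "gender": "female"},
        10.07,
        0.005,
    ),
    (
        ("non-turner", "no-preference"),
        ("response_mode", "pictorial", "text"),
        {"ethnicity": "Chinese", "gender": "male"},
        5.57,
        0.005,
    ),
    (
        ("non-turner", "no-preference"),
        ("response_mode", "pictorial", "text"),
        {"ethnicity": "Chinese", "gender": "female"},
        4.26,
        0.005,
    ),
]


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "pair, contrast, profile, expected, tol", WORKED_EXAMPLES
    )
    def test_published_odds_ratios(self, pair, contrast, profile, expected, tol):
        record = odds_ratio(STUDY_COEFFICIENTS, pair, contrast, profile)
        assert record.or_value == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize(
        "pair, contrast, profile, published",
        [
            # published values carry ~1% rounding error from the printed
            # coefficient precision
            (
                ("non-turner", "turner"),
                ("ethnicity", "Chinese", "Caucasian"),
                {"gender": "male", "response_mode": "pictorial"},
                9.58,
            ),
            (
                ("non-turner", "turner"),
                ("ethnicity", "Other", "Caucasian"),
                {"gender": "male", "response_mode": "pictorial"},
                3.93,
            ),
        ],
    )
    def test_rounding_limited_examples_within_one_percent(
        self, pair, contrast, profile, published
    ):
        record = odds_ratio(STUDY_COEFFICIENTS, pair, contrast, profile)
        assert record.or_value == pytest.approx(published, rel=0.01)


class TestSymmetries:
    def test_identical_levels_give_unit_or(self):
        record = odds_ratio(
            STUDY_COEFFICIENTS,
            ("turner", "non-turner"),
            ("gender", "male", "male"),
            {"ethnicity": "Caucasian", "response_mode": "pictorial"},
        )
        assert record.or_value == 1.0

    def test_reciprocal_symmetry(self):
        record = odds_ratio(
            STUDY_COEFFICIENTS,
            ("turner", "non-mover"),
            ("ethnicity", "Caucasian", "Chinese"),
            {"gender": "male", "response_mode": "pictorial"},
        )
        assert record.or_value * record.mirrored().or_value == pytest.approx(
            1.0, abs=1e-12
        )

    def test_or_equals_softmax_odds_ratio(self):
        """Every OR equals the ratio of class-probability odds computed
        directly from the softmax model at the two contrast levels."""
        for pair, contrast, profile, *_ in WORKED_EXAMPLES:
            factor, level_a, level_b = contrast
            record = odds_ratio(STUDY_COEFFICIENTS, pair, contrast, profile)
            p_a = strategy_probabilities(
                Covariates(**{**profile, factor: level_a}), STUDY_COEFFICIENTS
            )
            p_b = strategy_probabilities(
                Covariates(**{**profile, factor: level_b}), STUDY_COEFFICIENTS
            )
            direct = (p_a[pair[0]] / p_a[pair[1]]) / (p_b[pair[0]] / p_b[pair[1]])
            assert record.or_value == pytest.approx(direct, abs=1e-10)

    def test_unknown_level_raises(self):
        with pytest.raises(InvalidContrastError):
            odds_ratio(
                STUDY_COEFFICIENTS,
                ("turner", "non-turner"),
                ("gender", "other", "female"),
                {"ethnicity": "Caucasian", "response_mode": "pictorial"},
            )


class TestRotations:
    def test_twelve_reference_profiles(self):
        rotations = enumerate_rotations()
        assert len(rotations) == 12
        assert len({tuple(sorted(r.items())) for r in rotations}) == 12

    def test_or_is_rotation_invariant(self):
        """The OR for a fixed contrast does not depend on which rotation's
        parametrisation computes it: refitting with relabelled dummy columns
        reproduces the same OR (checked on a well-conditioned cohort where
        the likelihood has no flat directions)."""
        from pointorigin.design import CoefficientMatrix, STUDY_CELL_SIZES
        from pointorigin.glm import fit_multinomial
        from pointorigin.synthdata import GeneratorConfig, generate_cohort

        uniform = CoefficientMatrix(STUDY_COEFFICIENTS.values * 0.0)
        cells = {k: 100 for k in STUDY_CELL_SIZES}
        cohort = generate_cohort(
            GeneratorConfig(cell_sizes=cells, coefficients=uniform, seed=23)
        )
        analysis_cohort = cohort.copy()
        analysis_cohort["classification"] = analysis_cohort["latent_class"]
        fit = fit_multinomial(analysis_cohort)
        base = odds_ratio(
            fit.coefficient_matrix,
            ("turner", "non-turner"),
            ("gender", "male", "female"),
            {"ethnicity": "Chinese", "response_mode": "text"},
        )
        # rotate the coding by relabelling the factor levels, refit, and ask
        # the same scientific question in the rotated parametrisation
        rotated = analysis_cohort.copy()
        swap = {"male": "female", "female": "male"}
        rotated["gender"] = rotated["gender"].map(swap)
        fit_rot = fit_multinomial(rotated)
        mirrored = odds_ratio(
            fit_rot.coefficient_matrix,
            ("turner", "non-turner"),
            ("gender", "female", "male"),
            {"ethnicity": "Chinese", "response_mode": "text"},
        )
        assert base.or_value == pytest.approx(mirrored.or_value, rel=1e-4)


@pytest.fixture(scope="module")
def fitted_records(analysis_cohort):
    import warnings

    from pointorigin.glm import fit_multinomial

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_multinomial(analysis_cohort)
        return significant_ors(fit)


class TestSignificantORs:
    def test_all_reported_above_one(self, fitted_records):
        assert fitted_records
        assert all(r.or_value > 1.0 for r in fitted_records)

    def test_window_filter_applied(self, fitted_records):
        assert all(0.001 <= r.or_value <= 100.0 for r in fitted_records)

    def test_mirror_pairs_deduplicated(self, fitted_records):
        seen = set()
        for r in fitted_records:
            key = (
                frozenset(r.outcome_pair),
                r.factor,
                frozenset((r.level_a, r.level_b)),
                r.profile,
            )
            assert key not in seen
            seen.add(key)

    def test_printed_mode_flags_approximate_intervals(self):
        """Without the coefficient covariance, intervals fall back to the
        independent-SE approximation; the wider bands are flagged."""
        with pytest.warns(UserWarning, match="independent-SE"):
            records = significant_ors(
                coefficients=STUDY_COEFFICIENTS,
                se_table=STUDY_STANDARD_ERRORS,
            )
        assert all(r.approximate_ci for r in records)

    def test_zero_point_estimate_never_significant(self):
        zero = STUDY_COEFFICIENTS.values * 0.0
        from pointorigin.design import CoefficientMatrix

        with pytest.warns(UserWarning):
            records = significant_ors(
                coefficients=CoefficientMatrix(zero),
                se_table=STUDY_STANDARD_ERRORS,
            )
        assert records == []

    def test_separation_artifact_outside_window(self):
        """The -12 interaction for non-movers implies ORs beyond [0.001, 100];
        they are excluded as sparse-data artifacts."""
        record = odds_ratio(
            STUDY_COEFFICIENTS,
            ("non-mover", "no-preference"),
            ("response_mode", "text", "pictorial"),
            {"ethnicity": "Other", "gender": "female"},
        )
        assert record.or_value < 0.001 or record.or_value > 100.0

    def test_table_layout(self, fitted_records):
        table = or_table(fitted_records)
        assert list(table.columns[:6]) == [
            "target_outcome",
            "baseline_outcome",
            "factor",
            "level_a",
            "level_b",
            "profile",
        ]
        assert (table["or"] > 1).all()

    def test_chord_summary_groups_by_factor(self, fitted_records):
        from pointorigin.odds import chord_summary

        summary = chord_summary(fitted_records)
        assert sum(len(v) for v in summary.values()) == len(fitted_records)
        for factor, entries in summary.items():
            assert factor in ("ethnicity", "response_mode", "gender")
            assert all(e["or"] > 1 for e in entries)

    def test_wald_interval_contains_point_estimate(self):
        record = odds_ratio(
            STUDY_COEFFICIENTS,
            ("turner", "non-turner"),
            ("gender", "male", "female"),
            {"ethnicity": "Caucasian", "response_mode": "pictorial"},
        )
        record = with_wald_interval(
            record, STUDY_COEFFICIENTS, se_table=STUDY_STANDARD_ERRORS
        )
        lo, hi = record.wald_ci
        assert lo < record.or_value < hi
        assert record.approximate_ci
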