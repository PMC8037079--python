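"""Dichotomization, odds ratios, logistic IRLS and criterion selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gertality import (
    BODY_REGIONS,
    Cohort,
    ContingencyTable2x2,
    DomainError,
    PatientRecord,
    SeparationError,
    contingency,
    cutoff_search,
    gertality_criteria,
    logistic_fit,
    odds_ratio,
    select_criteria,
    screen_candidates,
    table_from_group_rates,
)
from gertality.development import CandidateCriterion, OddsRatioResult


def toy_record(pid, age, died, gcs=15):
    return PatientRecord(
        patient_id=pid,
        age=age,
        ais_by_region={r: (3 if r == "chest" else 0) for r in BODY_REGIONS},
        gcs=gcs,
        prbc_pre_icu=False,
        icu_admitted=True,
        died_in_hospital=died,
    )


class TestContingency:
    def test_four_record_enumeration(self):
        cohort = Cohort(
            records=[
                toy_record("a", 85, True),
                toy_record("b", 85, False),
                toy_record("c", 70, False),
                toy_record("d", 70, False),
            ]
        )
        table = contingency(cohort, lambda r: r.age >= 80)
        assert (table.a, table.b, table.c, table.d) == (1, 1, 0, 2)
        assert table.n == 4

    def test_unevaluable_records_dropped_and_counted(self):
        cohort = Cohort(
            records=[toy_record("a", 85, True), toy_record("b", 70, False, gcs=None)]
        )
        table = contingency(cohort, lambda r: None if r.gcs is None else r.gcs <= 13)
        assert table.n == 1
        assert table.n_unevaluable == 1

    def test_never_true_predicate(self):
        cohort = Cohort(records=[toy_record("a", 70, False)])
        table = contingency(cohort, lambda r: False)
        assert table.a == table.b == 0


class TestOddsRatio:
    @given(
        st.integers(1, 200),
        st.integers(1, 200),
        st.integers(1, 200),
        st.integers(1, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_equals_odds_form_oracle(self, a, b, c, d):
        # independent oracle: ratio of mortality odds in the two arms
        result = odds_ratio(ContingencyTable2x2(a, b, c, d))
        p1, p2 = a / (a + b), c / (c + d)
        expected = (p1 / (1 - p1)) / (p2 / (1 - p2))
        assert result.or_value == pytest.approx(expected, abs=1e-12)
        assert result.ci_low <= result.or_value <= result.ci_high

    def test_equal_rates_give_unit_odds_ratio(self):
        result = odds_ratio(ContingencyTable2x2(10, 30, 20, 60))
        assert result.or_value == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        result = odds_ratio(ContingencyTable2x2(1, 1, 0, 2), continuity=0.5)
        assert result.or_value == pytest.approx(5.0)  # (1.5*2.5)/(1.5*0.5)
        assert not result.degenerate

    def test_zero_cell_without_correction_is_flagged(self):
        result = odds_ratio(ContingencyTable2x2(1, 1, 0, 2))
        assert result.degenerate
        assert result.or_value == math.inf
        assert math.isnan(result.ci_low) and math.isnan(result.ci_high)

    def test_table_from_group_rates_inverts_printed_rows(self):
        table = table_from_group_rates(4813, 0.434, 53242, 0.204)
        assert table.n_exposed == 4813
        assert table.a == round(0.434 * 4813)
        assert odds_ratio(table).or_value == pytest.approx(2.99, abs=0.05)

    def test_wald_ci_coverage_is_nominal(self):
        # 2,000 simulated tables, 1,000 per arm, known odds ratio
        rng = np.random.default_rng(12345)
        p1, p2, n = 0.30, 0.15, 1000
        true_or = (p1 / (1 - p1)) / (p2 / (1 - p2))
        covered = 0
        for _ in range(2000):
            a = rng.binomial(n, p1)
            c = rng.binomial(n, p2)
            result = odds_ratio(ContingencyTable2x2(a, n - a, c, n - c))
            covered += result.ci_low <= true_or <= result.ci_high
        assert 0.93 <= covered / 2000 <= 0.97


class TestCutoffSearch:
    @pytest.fixture
    def age_graded_cohort(self):
        # mortality 40% above 80, 25% in 75-79, 5% below 75
        records = []
        i = 0
        for age, n, deaths in [(82, 10, 4), (77, 20, 5), (70, 40, 2)]:
            for j in range(n):
                records.append(toy_record(f"p{i}", age, died=j < deaths))
                i += 1
        return Cohort(records=records)

    def test_least_extreme_qualifying_cutoff(self, age_graded_cohort):
        # mortality(>=80) = 0.40, mortality(>=75) = 0.30, mortality(>=65) = 0.157
        found = cutoff_search(
            age_graded_cohort, "age", [65, 70, 75, 80, 85], "ge",
            target_mortality=0.35,
        )
        assert found.cutoff == 80
        found = cutoff_search(
            age_graded_cohort, "age", [65, 70, 75, 80, 85], "ge",
            target_mortality=0.30,
        )
        assert found.cutoff == 75  # exposes more patients, still qualifies

    def test_target_zero_picks_least_extreme_candidate(self, age_graded_cohort):
        found = cutoff_search(
            age_graded_cohort, "age", [70, 75, 80], "ge", target_mortality=0.0
        )
        assert found.cutoff == 70

    def test_unreachable_target_returns_none(self, age_graded_cohort):
        assert (
            cutoff_search(
                age_graded_cohort, "age", [70, 80], "ge", target_mortality=1.0
            )
            is None
        )

    def test_empty_grid_raises(self, age_graded_cohort):
        with pytest.raises(DomainError):
            cutoff_search(age_graded_cohort, "age", [], "ge")


class TestLogisticFit:
    def test_single_binary_predictor_reproduces_table_odds_ratio(self):
        # table with a = 43, b = 57, c = 20, d = 80
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [43, 57, 20, 80])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [43, 57, 20, 80])
        fit = logistic_fit(x, y)
        crude = (43 * 80) / (57 * 20)
        assert fit.odds_ratios[0] == pytest.approx(crude, rel=1e-8)

    def test_null_model_coefficients_near_zero(self):
        rng = np.random.default_rng(99)
        X = rng.integers(0, 2, size=(5000, 3)).astype(float)
        y = rng.integers(0, 2, size=5000).astype(float)
        fit = logistic_fit(X, y)
        assert np.all(np.abs(fit.odds_ratios - 1.0) < 0.15)

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(7)
        n = 50_000
        X = (rng.random((n, 3)) < [0.4, 0.2, 0.5]).astype(float)
        beta = np.array([0.8, 1.5, -0.5])
        p = 1 / (1 + np.exp(-(-2.0 + X @ beta)))
        y = (rng.random(n) < p).astype(float)
        fit = logistic_fit(X, y)
        z = (fit.coef[1:] - beta) / fit.se[1:]
        assert np.all(np.abs(z) < 3)

    def test_perfect_separation_raises(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(SeparationError):
            logistic_fit(x, y)

    def test_constant_predictor_raises(self):
        with pytest.raises(DomainError):
            logistic_fit(np.ones((100, 1)), np.tile([0.0, 1.0], 50))

    def test_insufficient_sample_raises(self):
        with pytest.raises(DomainError):
            logistic_fit(np.tile([0.0, 1.0], 5), np.tile([0.0, 1.0], 5))

    def test_matches_statsmodels_reference(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = (rng.random((2000, 2)) < 0.4).astype(float)
        p = 1 / (1 + np.exp(-(-1.0 + X @ np.array([0.7, -0.4]))))
        y = (rng.random(2000) < p).astype(float)
        fit = logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.coef == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, abs=1e-6)


def candidate(variable, cutoff, direction, or_value):
    odds = OddsRatioResult(
        or_value=or_value,
        ci_low=or_value * 0.9,
        ci_high=or_value * 1.1,
        mortality_exposed=0.3,
        mortality_unexposed=0.1,
        n_exposed=100,
        n_unexposed=100,
    )
    return CandidateCriterion(variable, cutoff, direction, odds)


FIVE_CANDIDATES = [
    candidate("age", 80, "ge", 2.27),
    candidate("max_ais", 4, "ge", 6.25),
    candidate("prbc_pre_icu", 1, "ge", 2.99),
    candidate("asa", 3, "ge", 2.09),
    candidate("gcs", 13, "le", 7.61),
]


class TestSelectCriteria:
    def test_threshold_three_keeps_only_strong_predictors(self):
        definition = select_criteria(FIVE_CANDIDATES, or_threshold=3.0)
        assert [c.name for c in definition.criteria] == [
            "max_ais_ge_4",
            "gcs_le_13",
        ]

    def test_infinite_threshold_gives_empty_score(self):
        definition = select_criteria(FIVE_CANDIDATES, or_threshold=math.inf)
        assert definition.criteria == ()
        assert definition.max_score == 0

    def test_output_order_invariant_to_input_order(self):
        shuffled = FIVE_CANDIDATES[::-1]
        names = [c.name for c in select_criteria(shuffled).criteria]
        assert names == [c.name for c in select_criteria(FIVE_CANDIDATES).criteria]


class TestScreenCandidates:
    def test_synthetic_screen_recovers_score_criteria(self, default_cohort_50k):
        candidates = screen_candidates(default_cohort_50k)
        definition = select_criteria(candidates, or_threshold=2.0)
        expected = [c.name for c in gertality_criteria().criteria]
        assert [c.name for c in definition.criteria] == expected

    def test_multivariable_mode_shrinks_confounded_estimates(
        self, clean_cohort_50k
    ):
        uni = {
            c.name: c.odds.or_value
            for c in screen_candidates(clean_cohort_50k, mode="univariable")
        }
        multi = {
            c.name: c.odds.or_value
            for c in screen_candidates(clean_cohort_50k, mode="multivariable")
        }
        # positive latent dependence inflates crude odds ratios; adjusting
        # for the other components must pull the transfusion OR down
        assert multi["prbc_pre_icu"] < uni["prbc_pre_icu"]
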