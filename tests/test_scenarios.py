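import math

import numpy as np
import pytest

from mammotriage import (
    NOMINAL,
    Band,
    Cohort,
    ReadingMode,
    ScenarioMode,
    ScenarioSpec,
    SpecError,
    evaluate_scenario,
    round_half_up,
    scenario_catalog,
    select_top_fraction,
    volume_reduction,
)

from conftest import random_cohort
from oracle import naive_evaluate

DOUBLE_ALL = ScenarioSpec(
    "all-double",
    ScenarioMode.TRIAGE,
    (Band(0, 10, ReadingMode.DOUBLE),),
)
NEGATIVE_ALL = ScenarioSpec(
    "all-negative",
    ScenarioMode.TRIAGE,
    (Band(0, 10, ReadingMode.NEGATIVE),),
)


class TestCatalog:
    def test_eleven_scenarios_in_order(self):
        catalog = scenario_catalog()
        assert [s.name for s in catalog] == [f"S{i}" for i in range(1, 12)]

    def test_s3_bands(self):
        s3 = scenario_catalog()[2]
        assert s3.bands == (
            Band(0, 5, ReadingMode.NEGATIVE),
            Band(5, 10, ReadingMode.DOUBLE),
        )

    def test_s10_bands(self):
        s10 = scenario_catalog()[9]
        assert s10.bands == (
            Band(0, 5, ReadingMode.NEGATIVE),
            Band(5, 7.5, ReadingMode.DOUBLE),
            Band(7.5, 10, ReadingMode.SINGLE_R1),
        )

    def test_s11_is_standalone_at_recall_rate(self):
        s11 = scenario_catalog()[10]
        assert s11.mode is ScenarioMode.AI_STANDALONE
        assert s11.ai_selection_rate == 0.032

    def test_s2_uses_decile_cutoff(self):
        s2 = scenario_catalog()[1]
        assert s2.mode is ScenarioMode.AI_AS_READER
        assert s2.ai_score_cutoff == 10


class TestSpecValidation:
    def test_gap_in_bands_rejected(self):
        with pytest.raises(SpecError, match="partition"):
            ScenarioSpec(
                "bad",
                ScenarioMode.TRIAGE,
                (
                    Band(0, 4, ReadingMode.NEGATIVE),
                    Band(5, 10, ReadingMode.DOUBLE),
                ),
            )

    def test_bands_must_cover_to_ten(self):
        with pytest.raises(SpecError, match="cover"):
            ScenarioSpec(
                "bad", ScenarioMode.TRIAGE, (Band(0, 9, ReadingMode.DOUBLE),)
            )

    def test_rate_and_cutoff_mutually_exclusive(self):
        with pytest.raises(SpecError):
            ScenarioSpec(
                "bad",
                ScenarioMode.AI_AS_READER,
                ai_selection_rate=0.05,
                ai_score_cutoff=10,
            )


class TestSelectTopFraction:
    def test_rounds_half_up(self, rng):
        cohort = random_cohort(rng, 100)
        assert len(select_top_fraction(cohort, 0.058)) == 6  # round(5.8)

    def test_selects_the_highest_scores(self, rng):
        cohort = random_cohort(rng, 100)
        chosen = select_top_fraction(cohort, 0.1)
        df = cohort.df
        threshold = df.loc[df["exam_id"].isin(chosen), "ai_raw"].min()
        assert (df.loc[~df["exam_id"].isin(chosen), "ai_raw"] <= threshold).all()

    def test_full_selection(self, rng):
        cohort = random_cohort(rng, 25)
        assert len(select_top_fraction(cohort, 1.0)) == 25

    def test_empty_cohort(self):
        assert select_top_fraction(Cohort.from_examinations([]), 0.5) == frozenset()

    def test_tie_break_by_exam_id_is_deterministic(self, ten_exam_cohort):
        df = ten_exam_cohort.df.copy()
        df["ai_raw"] = 5.0
        df["ai_score"] = 5
        tied = Cohort(df)
        first = select_top_fraction(tied, 0.5)
        assert first == select_top_fraction(tied, 0.5)
        assert first == frozenset(sorted(df["exam_id"])[:5])


class TestEvaluate:
    def test_all_double_band_is_identity_with_double_reading(self, ten_exam_cohort):
        result = evaluate_scenario(ten_exam_cohort, DOUBLE_ALL)
        assert result.n_consensus == ten_exam_cohort.n_consensus
        assert result.n_recall == ten_exam_cohort.n_recall
        assert result.n_sdc == ten_exam_cohort.n_sdc

    def test_all_negative_band_detects_nothing(self, ten_exam_cohort):
        result = evaluate_scenario(ten_exam_cohort, NEGATIVE_ALL)
        assert (result.n_consensus, result.n_recall, result.n_sdc) == (0, 0, 0)
        assert result.n_ic_selected == 0

    def test_s3_hand_enumeration(self, ten_exam_cohort):
        """Counts verified by enumerating all ten exams by hand: the SDC at
        raw 9.4 stays recalled; the IC at raw 6.2 is consensus-selected via
        its positive first reader but was never recalled."""
        s3 = scenario_catalog()[2]
        result = evaluate_scenario(ten_exam_cohort, s3)
        assert result.n_consensus == 5  # A04 A05 A06 A08 A10
        assert result.n_recall == 3  # A05 A06 A10
        assert result.n_sdc == 1  # A05
        assert result.n_ic_selected == 1  # A04
        assert result.reader_fraction_r1 == pytest.approx(0.6)
        assert result.reader_fraction_r2 == pytest.approx(0.6)

    def test_s6_single_reading_hand_enumeration(self, ten_exam_cohort):
        s6 = scenario_catalog()[5]
        result = evaluate_scenario(ten_exam_cohort, s6)
        assert result.n_consensus == 3  # A04 A05 A06 (r1 >= 2 in (5,10])
        assert result.n_recall == 2  # A05 A06
        assert result.n_sdc == 1
        assert result.n_ic_selected == 1

    def test_ai_as_reader_union_hand_enumeration(self, ten_exam_cohort):
        spec = ScenarioSpec("ai20", ScenarioMode.AI_AS_READER, ai_selection_rate=0.2)
        result = evaluate_scenario(ten_exam_cohort, spec)
        # AI flags top-2 raw scores (A05, A08); r1-positive: A02 A04 A05 A06.
        assert result.n_consensus == 5
        assert result.n_recall == 2  # A05 A06
        assert result.n_sdc == 1
        assert result.n_ic_selected == 1  # A04 via r1

    def test_standalone_recalls_equal_selection(self, ten_exam_cohort):
        spec = ScenarioSpec("sa20", ScenarioMode.AI_STANDALONE, ai_selection_rate=0.2)
        result = evaluate_scenario(ten_exam_cohort, spec)
        assert result.n_consensus is None
        assert result.n_recall == 2  # A05, A08 regardless of actual recall
        assert result.n_sdc == 1
        assert result.n_ic_selected == 0

    def test_invariant_chain(self, rng):
        cohort = random_cohort(rng, 400)
        for spec in scenario_catalog():
            r = evaluate_scenario(cohort, spec)
            if r.n_consensus is not None:
                assert r.n_recall <= r.n_consensus
            assert r.n_sdc <= r.n_recall
            assert r.n_sdc <= r.n_sdc_total
            assert r.n_ic_selected <= r.n_ic_total

    def test_scenario_recall_subset_of_actual_recall(self, rng):
        cohort = random_cohort(rng, 400)
        actual = cohort.n_recall
        for spec in scenario_catalog()[:10]:  # TRIAGE and AI_AS_READER
            assert evaluate_scenario(cohort, spec).n_recall <= actual

    def test_sdc_conservation(self, rng):
        cohort = random_cohort(rng, 300)
        for spec in scenario_catalog():
            r = evaluate_scenario(cohort, spec)
            assert r.n_sdc + (r.n_sdc_total - r.n_sdc) == cohort.n_sdc


class TestOracleEquivalence:
    def test_matches_naive_evaluator_on_random_cohorts(self, rng):
        for _ in range(60):
            cohort = random_cohort(rng, 50)
            for spec in scenario_catalog():
                got = evaluate_scenario(cohort, spec)
                want = naive_evaluate(cohort, spec)
                assert got.n_consensus == want["n_consensus"], spec.name
                assert got.n_recall == want["n_recall"], spec.name
                assert got.n_sdc == want["n_sdc"], spec.name
                assert got.n_ic_selected == want["n_ic_selected"], spec.name


class TestMonotonicity:
    def test_enlarging_double_band_never_decreases_counts(self, rng):
        """Growing the double-read band (set inclusion) can only add
        consensus selections, recalls and detected cancers."""
        cuts = [1.0, 2.5, 5.0, 7.5, 9.0]
        for _ in range(20):
            cohort = random_cohort(rng, 80)
            results = []
            for cut in cuts:
                spec = ScenarioSpec(
                    f"cut{cut}",
                    ScenarioMode.TRIAGE,
                    (
                        Band(0, cut, ReadingMode.NEGATIVE),
                        Band(cut, 10, ReadingMode.DOUBLE),
                    ),
                )
                results.append(evaluate_scenario(cohort, spec))
            # Lower cut = larger double band; counts must not increase
            # as the cut rises.
            for a, b in zip(results, results[1:]):
                assert a.n_consensus >= b.n_consensus
                assert a.n_recall >= b.n_recall
                assert a.n_sdc >= b.n_sdc

    def test_reading_mode_dominance(self, rng):
        """SINGLE_R1 dominates NEGATIVE and DOUBLE dominates SINGLE_R1 on
        the same band layout."""
        for _ in range(10):
            cohort = random_cohort(rng, 80)
            results = {}
            for mode in ReadingMode:
                spec = ScenarioSpec(
                    f"m-{mode.value}",
                    ScenarioMode.TRIAGE,
                    (
                        Band(0, 5, ReadingMode.NEGATIVE),
                        Band(5, 10, mode),
                    ),
                )
                results[mode] = evaluate_scenario(cohort, spec)
            for low, high in [
                (ReadingMode.NEGATIVE, ReadingMode.SINGLE_R1),
                (ReadingMode.SINGLE_R1, ReadingMode.DOUBLE),
            ]:
                assert results[low].n_consensus <= results[high].n_consensus
                assert results[low].n_recall <= results[high].n_recall
                assert results[low].n_sdc <= results[high].n_sdc


class TestVolumeReduction:
    def test_nominal_table_values(self):
        expected = [50, 50, 50, 70, 90, 75, 25, 35, 63, 63, 100]
        got = [
            round_half_up(volume_reduction(s, NOMINAL))
            for s in scenario_catalog()
        ]
        assert got == expected

    def test_s9_s10_are_exactly_62_5_before_rounding(self):
        catalog = scenario_catalog()
        assert volume_reduction(catalog[8], NOMINAL) == pytest.approx(62.5)
        assert volume_reduction(catalog[9], NOMINAL) == pytest.approx(62.5)

    def test_boundary_cases(self, ten_exam_cohort):
        assert volume_reduction(DOUBLE_ALL, NOMINAL) == 0.0
        assert volume_reduction(scenario_catalog()[10], NOMINAL) == 100.0
        # Empirical: the ten-exam fixture has 6/10 exams above raw score 5.
        s3 = scenario_catalog()[2]
        assert volume_reduction(s3, ten_exam_cohort) == pytest.approx(40.0)
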