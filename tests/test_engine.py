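"""The management rule engine: baseline categories, follow-up growth logic,
new-nodule handling, airway lesions, and participant aggregation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import build_rule_corpus, growth_series, man, run_corpus_case, solid, vol
from nodulekit import (
    Action,
    GrowthAssessment,
    InvalidInputError,
    NoduleContext,
    NoduleRecord,
    Recommendation,
    RiskCategory,
    assess_followup,
    assess_new_nodule,
    classify_airway,
    classify_baseline,
    participant_management,
    size_category,
    substantial_growth,
    vdt_two_point,
)
from nodulekit.engine import ScreenResult
from nodulekit.measurement import Method
from nodulekit.rules import RULES


class TestSizeCategory:
    @pytest.mark.parametrize(
        "volume, expected",
        [
            (99.0, RiskCategory.VERY_LOW),
            (100.0, RiskCategory.LOW),
            (249.0, RiskCategory.LOW),
            (250.0, RiskCategory.INTERMEDIATE),
            (300.0, RiskCategory.INTERMEDIATE),
            (499.0, RiskCategory.INTERMEDIATE),
            (500.0, RiskCategory.HIGH),
        ],
    )
    def test_volumetric_scale(self, volume, expected):
        assert size_category(volume_mm3=volume) is expected

    @pytest.mark.parametrize(
        "diameter, expected",
        [
            (5.9, RiskCategory.VERY_LOW),
            (6.0, RiskCategory.LOW),
            (8.0, RiskCategory.INTERMEDIATE),
            (10.0, RiskCategory.HIGH),
        ],
    )
    def test_manual_scale(self, diameter, expected):
        assert size_category(avg_diameter_mm=diameter) is expected

    def test_exactly_one_size_required(self):
        with pytest.raises(InvalidInputError):
            size_category()
        with pytest.raises(InvalidInputError):
            size_category(volume_mm3=100.0, avg_diameter_mm=6.0)


class TestClassifyBaseline:
    def test_large_solid_nodule_goes_to_workup(self):
        rec = classify_baseline(solid("a", vol(0, 600.0)))
        assert rec.action is Action.WORKUP
        assert rec.screen_result is ScreenResult.POSITIVE

    def test_suspicious_morphology_drops_workup_threshold_to_250(self):
        rec = classify_baseline(
            solid("a", vol(0, 300.0), morphology_suspicious=frozenset({"spiculation"}))
        )
        assert rec.action is Action.WORKUP

    def test_benign_morphology_ends_evaluation(self):
        rec = classify_baseline(
            solid("a", vol(0, 80.0),
                  morphology_benign=frozenset({"calcification_benign_pattern"}))
        )
        assert rec.action is Action.NONE_REGULAR_SCREENING
        assert rec.category is RiskCategory.BENIGN

    def test_benign_morphology_beats_suspicious(self):
        rec = classify_baseline(
            solid("a", vol(0, 300.0),
                  morphology_suspicious=frozenset({"spiculation"}),
                  morphology_benign=frozenset({"calcification_benign_pattern"}))
        )
        assert rec.category is RiskCategory.BENIGN

    def test_very_low_risk_is_negative_annual_screen(self):
        rec = classify_baseline(solid("a", vol(0, 99.0)))
        assert (rec.interval_months, rec.screen_result) == (12, ScreenResult.NEGATIVE)

    def test_upgrade_applies_once(self):
        one = classify_baseline(
            solid("a", vol(0, 150.0), morphology_suspicious=frozenset({"spiculation"}))
        )
        two = classify_baseline(
            solid("b", vol(0, 150.0),
                  morphology_suspicious=frozenset({"spiculation", "concave_sign"}))
        )
        assert one.category is two.category is RiskCategory.INTERMEDIATE

    def test_part_solid_large_core_gets_one_month(self):
        rec = classify_baseline(
            NoduleRecord(id="a", type="part_solid",
                         total_series=(vol(0, 3000.0),),
                         solid_series=(vol(0, 700.0),))  # core 10.9 mm
        )
        assert rec.interval_months == 1

    def test_part_solid_mostly_solid_reclassified(self):
        rec = classify_baseline(
            NoduleRecord(id="a", type="part_solid",
                         total_series=(vol(0, 520.0),),
                         solid_series=(vol(0, 420.0),))  # 93% of diameter
        )
        assert "BASE.RECLASSIFY_SOLID" in rec.rule_trace
        # managed as a solid nodule on the whole-nodule size: 520 mm3 -> workup
        assert rec.action is Action.WORKUP

    def test_part_solid_without_solid_series_rejected(self):
        with pytest.raises(InvalidInputError):
            NoduleRecord(id="a", type="part_solid", total_series=(vol(0, 500.0),))

    def test_nonsolid_without_solid_component_is_very_low(self):
        rec = classify_baseline(
            NoduleRecord(id="a", type="non_solid", total_series=(vol(0, 2000.0),))
        )
        assert rec.category is RiskCategory.VERY_LOW

    def test_nonsolid_with_30mm_gg_component_upgraded_to_low(self):
        rec = classify_baseline(
            NoduleRecord(id="a", type="non_solid", total_series=(vol(0, 15000.0),),
                         morphology_suspicious=frozenset({"gg_component_ge_30mm"}))
        )
        assert rec.category is RiskCategory.LOW
        assert rec.interval_months == 6

    def test_thin_walled_cyst_is_benign(self):
        rec = classify_baseline(
            NoduleRecord(id="a", type="cystic", total_series=(vol(0, 800.0),),
                         morphology_benign=frozenset({"thin_walled_cyst_lt_2mm"}))
        )
        assert rec.category is RiskCategory.BENIGN

    def test_cystic_component_counts_as_suspicious(self):
        # 120 mm3 nodular component would be low; the cystic morphology
        # upgrades it to intermediate (6-month-or-shorter interval)
        rec = classify_baseline(
            NoduleRecord(id="a", type="cystic", total_series=(vol(0, 800.0),),
                         solid_series=(vol(0, 120.0),))
        )
        assert rec.category is RiskCategory.INTERMEDIATE
        assert rec.interval_months <= 6

    def test_infectious_pattern_gets_one_month(self):
        rec = classify_baseline(
            NoduleRecord(id="a", type="non_solid", total_series=(vol(0, 400.0),),
                         context=NoduleContext(infectious_pattern_1mo=True))
        )
        assert rec.interval_months == 1

    def test_monotone_severity_in_size(self):
        volumes = [40.0, 99.0, 150.0, 300.0, 600.0, 2000.0]
        cats = [classify_baseline(solid("a", vol(0, v))).category for v in volumes]
        assert all(a <= b for a, b in zip(cats, cats[1:]))

    @given(st.floats(min_value=10.0, max_value=4000.0))
    def test_every_solid_volume_yields_a_traced_recommendation(self, v):
        rec = classify_baseline(solid("a", vol(0, v)))
        assert isinstance(rec, Recommendation) and rec.rule_trace


class TestSubstantialGrowth:
    @staticmethod
    def _volumetric(vdt_days):
        return GrowthAssessment(
            vdt=vdt_two_point(100.0, 100.0 * 2 ** (91.25 / vdt_days), 91.25),
            delta_avg_diameter_mm=0.0, cumulative_delta_diameter_mm=0.0,
            substantial=False, shrinking=False, method=Method.VOLUMETRY,
        )

    def test_vdt_200_at_3_months_is_substantial(self):
        assert substantial_growth(self._volumetric(200.0), 91.25)

    def test_vdt_300_at_3_months_is_not(self):
        assert not substantial_growth(self._volumetric(300.0), 91.25)

    def test_vdt_450_threshold_depends_on_interval(self):
        a = self._volumetric(450.0)
        assert not substantial_growth(a, 182.5)  # below 400? no -> keep
        assert substantial_growth(a, 365.0)      # 450 < 500 at >= 12 months

    def test_manual_delta_above_1_5_mm(self):
        a = GrowthAssessment(
            vdt=None, delta_avg_diameter_mm=1.6, cumulative_delta_diameter_mm=1.6,
            substantial=False, shrinking=False, method=Method.MANUAL,
        )
        assert substantial_growth(a, 182.0)

    def test_manual_morphology_change_counts(self):
        a = GrowthAssessment(
            vdt=None, delta_avg_diameter_mm=0.0, cumulative_delta_diameter_mm=0.0,
            substantial=False, shrinking=False, method=Method.MANUAL,
            morphology_changed=True,
        )
        assert substantial_growth(a, 182.0)


class TestAssessFollowup:
    def test_intermediate_without_growth_downgrades_to_low(self):
        rec = assess_followup(solid("a", *growth_series(300.0, 600.0, (0.0, 91.25))))
        assert rec.category is RiskCategory.LOW
        assert rec.interval_months == 6

    def test_substantial_growth_at_6_months_triggers_workup(self):
        rec = assess_followup(solid("a", *growth_series(150.0, 350.0, (0.0, 182.5))))
        assert rec.action is Action.WORKUP

    def test_shrinking_nodule_returns_to_annual_screening(self):
        rec = assess_followup(solid("a", vol(0, 300.0), vol(91.25, 240.0)))
        assert rec.category is RiskCategory.VERY_LOW
        assert rec.interval_months == 12

    def test_slow_grower_crossing_5mm_goes_to_mdt(self):
        rec = assess_followup(
            solid("a", *growth_series(300.0, 600.0, (0.0, 365.0, 730.0, 1095.0, 1460.0)))
        )
        assert rec.action is Action.MDT_REFERRAL
        assert "FU.CUMULATIVE_5MM_MDT" in rec.rule_trace

    def test_downgrade_chain_reaches_very_low_and_holds(self):
        times = (0.0, 91.25, 273.75, 638.75, 1003.75)
        full = solid("a", *growth_series(300.0, 600.0, times))
        intervals = [
            assess_followup(full.truncated(k)).interval_months
            for k in range(2, len(times) + 1)
        ]
        assert intervals == [6, 12, 12, 12]

    def test_single_observation_rejected(self):
        with pytest.raises(InvalidInputError):
            assess_followup(solid("a", vol(0, 300.0)))

    def test_one_month_lesion_persistent_goes_to_workup(self):
        rec = assess_followup(
            NoduleRecord(id="a", type="part_solid",
                         total_series=(vol(0, 3000.0), vol(30, 3000.0)),
                         solid_series=(vol(0, 700.0), vol(30, 710.0)))
        )
        assert rec.action is Action.WORKUP

    def test_one_month_lesion_regression_is_benign(self):
        rec = assess_followup(
            NoduleRecord(id="a", type="part_solid",
                         total_series=(vol(0, 3000.0), vol(30, 2000.0)),
                         solid_series=(vol(0, 700.0), vol(30, 400.0)))
        )
        assert rec.action is Action.NONE_REGULAR_SCREENING


class TestAssessNewNodule:
    def test_incident_solid_at_threshold_gets_3_months(self):
        rec = assess_new_nodule(
            solid("a", vol(0, 40.0), context=NoduleContext(is_new=True)), 365.0
        )
        assert rec.interval_months == 3

    def test_incident_solid_below_threshold_stays_annual(self):
        rec = assess_new_nodule(
            solid("a", vol(0, 20.0), context=NoduleContext(is_new=True)), 365.0
        )
        assert rec.interval_months == 12

    def test_incident_nonsolid_stays_annual(self):
        rec = assess_new_nodule(
            NoduleRecord(id="a", type="non_solid", total_series=(vol(0, 300.0),),
                         context=NoduleContext(is_new=True)), 365.0
        )
        assert rec.interval_months == 12

    def test_incident_part_solid_manual_core_4_5mm_gets_3_months(self):
        rec = assess_new_nodule(
            NoduleRecord(id="a", type="part_solid",
                         total_series=(man(0, 9.0),), solid_series=(man(0, 4.5),),
                         context=NoduleContext(is_new=True)), 365.0
        )
        assert rec.interval_months == 3

    def test_prevalent_with_evident_growth_goes_to_workup(self):
        rec = assess_new_nodule(
            solid("a", vol(0, 200.0),
                  context=NoduleContext(is_new=True, visible_in_retrospect=True,
                                        evident_growth=True)), 365.0
        )
        assert rec.action is Action.WORKUP

    def test_prevalent_dubious_without_volumetry_gets_3_months(self):
        rec = assess_new_nodule(
            NoduleRecord(id="a", type="solid", total_series=(man(0, 5.0),),
                         context=NoduleContext(is_new=True, visible_in_retrospect=True)),
            365.0,
        )
        assert rec.interval_months == 3

    def test_prevalent_dubious_vdt_threshold_applies(self):
        grow = assess_new_nodule(
            solid("a", vol(0, 100.0), vol(365.0, 250.0),
                  context=NoduleContext(is_new=True, visible_in_retrospect=True)),
            365.0,
        )
        stable = assess_new_nodule(
            solid("b", vol(0, 100.0), vol(365.0, 105.0),
                  context=NoduleContext(is_new=True, visible_in_retrospect=True)),
            365.0,
        )
        assert grow.action is Action.WORKUP  # VDT 276 d < 500 d
        assert stable.action is Action.FOLLOW_UP

    def test_recheck_outcomes(self):
        grow = assess_new_nodule(
            solid("a", vol(0, 40.0), vol(91.25, 90.0),
                  context=NoduleContext(is_new=True)), 91.25,
        )
        stable = assess_new_nodule(
            solid("b", vol(0, 40.0), vol(91.25, 41.0),
                  context=NoduleContext(is_new=True)), 91.25,
        )
        assert grow.action is Action.WORKUP
        assert stable.interval_months == 12

    def test_requires_is_new(self):
        with pytest.raises(InvalidInputError):
            assess_new_nodule(solid("a", vol(0, 40.0)), 365.0)


class TestAirway:
    def test_small_segmental_lesion_negative_annual(self):
        rec = classify_airway(
            NoduleRecord(id="a", type="airway", total_series=(man(0, 4.0),),
                         context=NoduleContext(bronchus_location="segmental_or_smaller",
                                               bronchus_diameter_mm=4.0))
        )
        assert (rec.interval_months, rec.screen_result) == (12, ScreenResult.NEGATIVE)

    def test_large_bronchus_low_risk_6_months(self):
        rec = classify_airway(
            NoduleRecord(id="a", type="airway", total_series=(man(0, 7.0),),
                         context=NoduleContext(bronchus_location="segmental_or_smaller",
                                               bronchus_diameter_mm=7.0))
        )
        assert (rec.category, rec.interval_months) == (RiskCategory.LOW, 6)

    def test_proximal_lesion_intermediate_3_months(self):
        rec = classify_airway(
            NoduleRecord(id="a", type="airway", total_series=(man(0, 5.0),),
                         context=NoduleContext(bronchus_location="trachea_or_proximal"))
        )
        assert (rec.category, rec.interval_months) == (RiskCategory.INTERMEDIATE, 3)

    def test_persistent_lesion_goes_to_mdt(self):
        rec = classify_airway(
            NoduleRecord(id="a", type="airway",
                         total_series=(man(0, 5.0), man(91, 5.0)),
                         context=NoduleContext(bronchus_location="trachea_or_proximal"))
        )
        assert rec.action is Action.MDT_REFERRAL

    def test_regression_is_negative(self):
        rec = classify_airway(
            NoduleRecord(id="a", type="airway",
                         total_series=(man(0, 5.0), man(91, 3.0)),
                         context=NoduleContext(bronchus_location="trachea_or_proximal"))
        )
        assert rec.screen_result is ScreenResult.NEGATIVE

    def test_benign_signs_end_evaluation(self):
        rec = classify_airway(
            NoduleRecord(id="a", type="airway", total_series=(man(0, 5.0),),
                         morphology_benign=frozenset({"multisegment_mucus"}),
                         context=NoduleContext(bronchus_location="trachea_or_proximal"))
        )
        assert rec.action is Action.NONE_REGULAR_SCREENING

    def test_missing_location_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_airway(
                NoduleRecord(id="a", type="airway", total_series=(man(0, 5.0),))
            )


class TestParticipantManagement:
    def test_shortest_interval_wins(self):
        recs = [
            classify_baseline(solid("a", vol(0, 50.0))),   # 12 months
            classify_baseline(solid("b", vol(0, 300.0))),  # 3 months
        ]
        assert participant_management(recs).interval_months == 3

    def test_benign_nodules_are_ignored(self):
        benign = classify_baseline(
            solid("a", vol(0, 80.0), morphology_benign=frozenset({"fat"}))
        )
        annual = classify_baseline(solid("b", vol(0, 50.0)))
        agg = participant_management([benign, annual])
        assert agg.interval_months == 12
        assert "PARTICIPANT.BENIGN_IGNORED" in agg.rule_trace

    def test_workup_dominates(self):
        recs = [
            classify_baseline(solid("a", vol(0, 600.0))),  # workup
            classify_baseline(solid("b", vol(0, 300.0))),  # 3 months
        ]
        assert participant_management(recs).action is Action.WORKUP

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidInputError):
            participant_management([])


def test_decision_table_exhaustive_and_every_rule_reachable():
    """A generated cross-product of nodule states runs to completion and
    collectively fires every registered rule identifier."""
    corpus = build_rule_corpus()
    fired = set()
    recommendations = []
    for kind, record, kwargs in corpus:
        rec = run_corpus_case(kind, record, kwargs)
        assert isinstance(rec, Recommendation)
        assert rec.rule_trace, f"empty trace for {record.id}"
        fired.update(rec.rule_trace)
        recommendations.append(rec)
    fired.update(participant_management(recommendations).rule_trace)
    unknown = fired - set(RULES)
    missed = set(RULES) - fired
    assert not unknown, f"unregistered rule ids fired: {sorted(unknown)}"
    assert not missed, f"rules never exercised: {sorted(missed)}"
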