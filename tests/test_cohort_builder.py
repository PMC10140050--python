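"""Valid-ACT rules, index selection, and inclusion/exclusion staging."""

import datetime

import pytest

from asthmactl.cohort import build_cohort, is_valid_act, select_index
from asthmactl.data_model import DiagnosisRecord, EncounterRecord

from conftest import INDEX, day, mk_act, mk_rx, single_patient_dataset


class TestValidAct:
    def test_incomplete_act_invalid(self):
        act = mk_act(items=(4, 4, 4, 4, None))
        assert not is_valid_act(act, [act])

    def test_sole_complete_act_valid(self):
        act = mk_act()
        assert is_valid_act(act, [act])

    def test_same_day_duplicates_both_invalid(self):
        a, b = mk_act(items=(4, 4, 4, 4, 4)), mk_act(items=(3, 3, 3, 3, 3))
        assert not is_valid_act(a, [a, b])
        assert not is_valid_act(b, [a, b])

    @pytest.mark.parametrize(
        "gap, first_valid, second_valid",
        [(28, True, False), (29, True, True), (1, True, False)],
    )
    def test_28_day_rule_is_backward_looking(self, gap, first_valid, second_valid):
        """A repeat within 28 days of an earlier ACT is invalid; the earlier
        one stays valid (the rule never acts retroactively)."""
        a, b = mk_act(date=day(0)), mk_act(date=day(gap))
        assert is_valid_act(a, [a, b]) is first_valid
        assert is_valid_act(b, [a, b]) is second_valid

    def test_incomplete_act_still_blocks_the_28_day_window(self):
        broken = mk_act(items=(4, 4, 4, 4, None), date=day(0))
        later = mk_act(date=day(10))
        assert not is_valid_act(later, [broken, later])


class TestSelectIndex:
    def test_no_acts_gives_none(self):
        assert select_index([]) is None

    def test_first_valid_not_first_recorded(self):
        invalid = mk_act(items=(1, 1, 1, 1, None), date=day(0))
        valid = mk_act(date=day(40))
        ip = select_index([invalid, valid])
        assert ip.index_date == day(40)

    def test_first_of_two_valid(self):
        ip = select_index([mk_act(date=day(0)), mk_act(date=day(60))])
        assert ip.index_date == day(0)

    def test_exposure_window_bounds(self):
        ip = select_index([mk_act(date=INDEX)])
        assert ip.window_start == day(-210)
        assert ip.window_end == day(-29)


class TestBuildCohort:
    def test_clean_patient_retained(self):
        cohort, report = build_cohort(single_patient_dataset())
        assert len(cohort) == 1
        assert report.final_n == 1
        assert all(n_after == n_before - n_excl for _, n_before, n_excl, n_after in report.stages)

    @pytest.mark.parametrize(
        "rx_offset, retained",
        [(-20, False), (-29, True), (-210, True), (-211, False)],
    )
    def test_exposure_window_is_closed_at_both_ends(self, rx_offset, retained):
        ds = single_patient_dataset(rxs=[mk_rx(date=day(rx_offset))])
        cohort, report = build_cohort(ds)
        assert (len(cohort) == 1) is retained
        if not retained:
            assert report.excluded_at["P1"] == "treated_in_exposure_window"

    def test_ocs_or_other_rx_does_not_qualify_as_treatment(self):
        ds = single_patient_dataset(
            rxs=[mk_rx(drug_class="OCS", date=day(-60)), mk_rx(drug_class="OTHER", date=day(-70))]
        )
        _, report = build_cohort(ds)
        assert report.excluded_at["P1"] == "treated_in_exposure_window"

    def test_copd_on_day_before_index_excludes(self):
        ds = single_patient_dataset()
        ds.diagnoses.append(DiagnosisRecord("P1", day(-1), "ICD10", "J44.9"))
        _, report = build_cohort(ds)
        assert report.excluded_at["P1"] == "no_copd_diagnosis"

    def test_copd_after_index_does_not_exclude(self):
        ds = single_patient_dataset()
        ds.diagnoses.append(DiagnosisRecord("P1", day(5), "ICD10", "J44.9"))
        cohort, _ = build_cohort(ds)
        assert len(cohort) == 1

    @pytest.mark.parametrize("offset, retained", [(-100, False), (-182, True)])
    def test_activity_requires_encounter_182_days_prior(self, offset, retained):
        ds = single_patient_dataset(
            encounters=[EncounterRecord("P1", day(offset), "Family Medicine")]
        )
        cohort, report = build_cohort(ds)
        assert (len(cohort) == 1) is retained
        if not retained:
            assert report.excluded_at["P1"] == "activity_182d_before_index"

    def test_missing_birth_year_excludes_last(self):
        ds = single_patient_dataset(birth_year=None)
        _, report = build_cohort(ds)
        assert report.excluded_at["P1"] == "birth_year_present"

    def test_no_asthma_diagnosis_excludes_first(self):
        ds = single_patient_dataset(diagnoses=[])
        _, report = build_cohort(ds)
        assert report.excluded_at["P1"] == "asthma_diagnosis"

    def test_asthma_code_prefix_matching_across_systems(self):
        for system, code in [("ICD9", "493.01"), ("ICD10", "J45.21"), ("SNOMED", "H3300")]:
            ds = single_patient_dataset(diagnoses=[DiagnosisRecord("P1", day(-300), system, code)])
            cohort, _ = build_cohort(ds)
            assert len(cohort) == 1, (system, code)

    def test_act_outside_study_window_excluded(self):
        ds = single_patient_dataset(
            acts=[mk_act(date=datetime.date(2014, 6, 1))],
            diagnoses=[DiagnosisRecord("P1", datetime.date(2013, 1, 1), "ICD10", "J45.909")],
        )
        _, report = build_cohort(ds)
        assert report.excluded_at["P1"] == "valid_index_act"

    def test_attrition_is_reproducible(self):
        ds = single_patient_dataset()
        _, r1 = build_cohort(ds)
        _, r2 = build_cohort(ds)
        assert r1.stages == r2.stages
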