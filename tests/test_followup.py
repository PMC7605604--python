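"""Follow-up routing: phases, due actions, referral triggers."""

from __future__ import annotations

import pandas as pd
import pytest

from t2dss.followup import (
    assign_phase,
    due_actions,
    phases_for,
    referral_check,
    route_cohort,
)

from conftest import AS_OF, enrolled_t2d, make_cohort, make_patient, obs


def days_ago(n):
    return (pd.Timestamp(AS_OF) - pd.Timedelta(days=n)).strftime("%Y-%m-%d")


def t2d_cohort(observations=(), conditions_extra=(), prescriptions=(), onset="2015-01-01",
               **patient_kw):
    patient, t2d = enrolled_t2d(onset=onset, **patient_kw)
    return make_cohort([patient], observations, [t2d, *conditions_extra], prescriptions)


class TestPhaseAssignment:
    def test_uncomplicated_enrolled_patient_is_phase_a(self):
        assert assign_phase("P1", t2d_cohort()) == "A"

    def test_insulin_in_window_routes_to_b(self):
        cohort = t2d_cohort(prescriptions=[dict(patient_id="P1", drug_class="INSULIN",
                                                date=days_ago(100))])
        assert assign_phase("P1", cohort) == "B"

    def test_stabilized_complication_routes_to_b(self):
        cohort = t2d_cohort(conditions_extra=[dict(patient_id="P1", condition="CHD",
                                                   onset_date="2017-01-01")])
        assert assign_phase("P1", cohort) == "B"

    def test_inadequate_control_routes_to_b(self):
        cohort = t2d_cohort(observations=[obs("P1", "HBA1C_PCT", 8.6, days_ago(60))])
        assert assign_phase("P1", cohort) == "B"

    def test_recent_onset_is_new_diagnosis(self):
        assert assign_phase("P1", t2d_cohort(onset=days_ago(30))) == "NEW_DIAGNOSIS"

    def test_no_t2d_condition_is_screening(self):
        cohort = make_cohort([make_patient()])
        assert assign_phase("P1", cohort) == "SCREENING"

    def test_enrolled_without_t2d_condition_is_an_error(self):
        cohort = make_cohort([make_patient(enrolled=True)])
        with pytest.raises(ValueError, match="enrolled"):
            assign_phase("P1", cohort)

    def test_batch_phases_match_single_assignment(self, gen_cohort_t2d):
        pids = list(gen_cohort_t2d.patients["patient_id"])[:40]
        batch = phases_for(gen_cohort_t2d, pids)
        for pid in pids:
            assert batch[pid] == assign_phase(pid, gen_cohort_t2d)


class TestDueActions:
    def test_quarterly_visit_overdue_after_100_days(self):
        cohort = t2d_cohort(observations=[obs("P1", "AP_SYS_MMHG", 130, days_ago(100)),
                                          obs("P1", "AP_DIA_MMHG", 80, days_ago(100))])
        actions = dict(due_actions("P1", cohort, "A"))
        assert actions["QUARTERLY_VISIT"] == pd.Timestamp(AS_OF) - pd.Timedelta(days=10)
        assert actions["QUARTERLY_VISIT"] < cohort.as_of  # overdue

    def test_fundus_oculi_at_20_months_is_not_yet_due(self):
        cohort = t2d_cohort(observations=[obs("P1", "FUNDUS_OCULI_DONE", 1,
                                              days_ago(610))])
        actions = dict(due_actions("P1", cohort, "A"))
        assert actions["FUNDUS_OCULI"] > cohort.as_of

    def test_center_review_overdue_at_seven_months_for_phase_b(self):
        cohort = t2d_cohort(observations=[obs("P1", "ECG_DONE", 1, days_ago(213))])
        actions = dict(due_actions("P1", cohort, "B"))
        assert "CENTER_REVIEW" in actions
        assert actions["CENTER_REVIEW"] < cohort.as_of

    def test_phase_a_has_no_center_review_but_annual_screening(self):
        actions = dict(due_actions("P1", t2d_cohort(), "A"))
        assert "CENTER_REVIEW" not in actions
        assert "ANNUAL_CENTER_SCREENING" in actions

    def test_never_recorded_markers_are_due_immediately(self):
        actions = dict(due_actions("P1", t2d_cohort(), "A"))
        assert actions["QUARTERLY_VISIT"] == pd.Timestamp(AS_OF)


class TestReferral:
    def test_repeated_high_fpg_is_programmable(self):
        cohort = t2d_cohort(observations=[obs("P1", "FPG_MGDL", 185, days_ago(90)),
                                          obs("P1", "FPG_MGDL", 190, days_ago(30))])
        level, reasons = referral_check("P1", cohort)
        assert level == "PROGRAMMABLE" and "REPEATED_FPG_GT_180" in reasons

    def test_single_high_fpg_is_not_enough(self):
        cohort = t2d_cohort(observations=[obs("P1", "FPG_MGDL", 190, days_ago(30))])
        assert referral_check("P1", cohort)[0] == "NONE"

    def test_fpg_sweep_boundary_is_exactly_180(self):
        def level(v):
            cohort = t2d_cohort(observations=[obs("P1", "FPG_MGDL", v, days_ago(90)),
                                              obs("P1", "FPG_MGDL", v, days_ago(30))])
            return referral_check("P1", cohort)[0]

        untriggered = [v for v in range(160, 201) if level(v) == "NONE"]
        assert max(untriggered) == 180

    def test_two_consecutive_hba1c_above_6_5(self):
        cohort = t2d_cohort(observations=[obs("P1", "HBA1C_PCT", 6.2, days_ago(300)),
                                          obs("P1", "HBA1C_PCT", 6.7, days_ago(150)),
                                          obs("P1", "HBA1C_PCT", 6.8, days_ago(30))])
        level, reasons = referral_check("P1", cohort)
        assert level == "PROGRAMMABLE" and "HBA1C_GT_6_5_TWICE" in reasons

    def test_latest_pair_not_both_high_does_not_trigger(self):
        cohort = t2d_cohort(observations=[obs("P1", "HBA1C_PCT", 6.8, days_ago(150)),
                                          obs("P1", "HBA1C_PCT", 6.4, days_ago(30))])
        assert referral_check("P1", cohort)[0] == "NONE"

    def test_acute_event_flag_is_urgent_and_dominates(self):
        cohort = t2d_cohort(observations=[obs("P1", "FPG_MGDL", 185, days_ago(90)),
                                          obs("P1", "FPG_MGDL", 190, days_ago(30))],
                            event_flags=frozenset({"FOOT_ULCER"}))
        level, reasons = referral_check("P1", cohort)
        assert level == "URGENT" and reasons == ("FOOT_ULCER",)

    def test_new_complication_onset_in_window_is_programmable(self):
        cohort = t2d_cohort(conditions_extra=[dict(patient_id="P1", condition="CHD",
                                                   onset_date=days_ago(100))])
        level, reasons = referral_check("P1", cohort)
        assert level == "PROGRAMMABLE" and "NEW_COMPLICATION" in reasons

    def test_route_cohort_is_total_and_consistent(self, gen_cohort_small):
        assignments = route_cohort(gen_cohort_small)
        assert len(assignments) == len(gen_cohort_small.patients)
        for a in assignments:
            assert a.phase in {"SCREENING", "NEW_DIAGNOSIS", "A", "B"}
            if a.referral == "URGENT":
                assert a.referral_reasons

    def test_batch_routing_matches_single_patient_functions(self, gen_cohort_small):
        cohort = gen_cohort_small
        batch = {a.patient_id: a for a in route_cohort(cohort)}
        sample = cohort.patients["patient_id"].sample(25, random_state=6)
        for pid in sample:
            phase = assign_phase(pid, cohort)
            assert batch[pid].phase == phase
            assert batch[pid].due_actions == due_actions(pid, cohort, phase)
            assert (batch[pid].referral, batch[pid].referral_reasons) == \
                referral_check(pid, cohort)
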