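"""Consent sections: applicability, validity rules, history, gating."""

import itertools
from datetime import date, datetime, timezone

import pytest

from irdr import (Condition, ConsentQuestion, ConsentSectionDef, ConsentState,
                  UnknownCodeError, consent_status_table, evaluate_applicability,
                  evaluate_validity, gate, record_consent)
from irdr.consent import INVALID, NOT_APPLICABLE, VALID

from conftest import demographics, make_minimal_defn, make_site

AS_OF = date(2018, 1, 1)


class FakePatient:
    def __init__(self, key="p1", registries=("GR",), **demo):
        self.key = key
        self.registries = set(registries)
        self.demographics = demographics(**demo)


class TestApplicability:
    def test_empty_condition_list_applies_to_everyone(self):
        sec = ConsentSectionDef("S", "s", (ConsentQuestion("q", "q"),))
        assert evaluate_applicability(sec, FakePatient())

    def test_minor_fails_adult_condition(self):
        sec = ConsentSectionDef("S", "s", (ConsentQuestion("q", "q"),),
                                applicability=(Condition("age_years", ">=", 18),))
        minor = FakePatient(date_of_birth="2006-06-01")
        adult = FakePatient(date_of_birth="1980-06-01")
        assert not evaluate_applicability(sec, minor, AS_OF)
        assert evaluate_applicability(sec, adult, AS_OF)

    def test_unknown_field_is_an_error(self):
        sec = ConsentSectionDef("S", "s", (ConsentQuestion("q", "q"),),
                                applicability=(Condition("shoe_size", ">", 40),))
        with pytest.raises(UnknownCodeError, match="shoe_size"):
            evaluate_applicability(sec, FakePatient())

    def test_registry_membership_condition(self):
        sec = ConsentSectionDef("S", "s", (ConsentQuestion("q", "q"),),
                                applicability=(Condition("registry", "==", "GR"),))
        assert evaluate_applicability(sec, FakePatient(registries=("GR", "X")))
        assert not evaluate_applicability(sec, FakePatient(registries=("X",)))

    def test_conjunction_matches_brute_force_and(self):
        """For all 2^3 satisfaction patterns of three independent
        conditions, the conjunction equals the AND of the individually
        evaluated conditions."""
        conds = (Condition("age_years", ">=", 18),
                 Condition("sex", "==", "female"),
                 Condition("registry", "==", "GR"))
        choices = {
            0: {"date_of_birth": {True: "1980-01-01", False: "2010-01-01"}},
            1: {"sex": {True: "female", False: "male"}},
        }
        for bits in itertools.product((True, False), repeat=3):
            demo = {}
            demo.update({k: v[bits[0]] for k, v in choices[0].items()})
            demo.update({k: v[bits[1]] for k, v in choices[1].items()})
            patient = FakePatient(registries=("GR",) if bits[2] else ("X",),
                                  **demo)
            sec = ConsentSectionDef("S", "s", (ConsentQuestion("q", "q"),),
                                    applicability=conds)
            individually = [_eval(c, patient) for c in conds]
            assert evaluate_applicability(sec, patient, AS_OF) == all(individually)


def _eval(cond, patient):
    from irdr.consent import evaluate_condition

    return evaluate_condition(cond, patient, AS_OF)


class TestRecordConsent:
    SEC = ConsentSectionDef("S", "s", (ConsentQuestion("q1", "a", True),
                                       ConsentQuestion("q2", "b", False)))

    def test_history_grows_one_snapshot_per_recording(self):
        states = {}
        now = datetime(2018, 1, 1, tzinfo=timezone.utc)
        for i, answers in enumerate([{"q1": True}, {"q1": False},
                                     {"q1": True, "q2": True}], start=1):
            state = record_consent(states, "p1", self.SEC, answers, now)
            assert len(state.history) == i
        assert state.answers == {"q1": True, "q2": True}

    def test_replaying_history_reproduces_current_answers(self):
        states = {}
        now = datetime(2018, 1, 1, tzinfo=timezone.utc)
        for answers in ({"q1": True}, {"q1": False, "q2": True}):
            state = record_consent(states, "p1", self.SEC, answers, now)
        assert state.answers == state.history[-1][1]

    def test_unknown_question_leaves_state_unchanged(self):
        states = {}
        now = datetime(2018, 1, 1, tzinfo=timezone.utc)
        record_consent(states, "p1", self.SEC, {"q1": True}, now)
        before = dict(states[("p1", "S")].answers)
        with pytest.raises(UnknownCodeError, match="q9"):
            record_consent(states, "p1", self.SEC, {"q9": True}, now)
        assert states[("p1", "S")].answers == before


def brute_force_validity(sec, answers):
    """Independent oracle: enumerate the rule definition directly over the
    given (possibly partial) answer assignment, unanswered = False."""
    if sec.validation_rule == "ALL":
        needed = [q.code for q in sec.questions]
    else:
        needed = [q.code for q in sec.questions if q.mandatory]
    return all(answers.get(code) is True for code in needed)


class TestValidity:
    @pytest.mark.parametrize("rule", ["ALL", "MANDATORY_SET"])
    @pytest.mark.parametrize("n_questions", [1, 2, 3, 4])
    def test_truth_table_equivalence(self, rule, n_questions):
        """evaluate_validity agrees with brute-force enumeration over all
        answer assignments (true / false / unanswered) for both rules."""
        questions = tuple(ConsentQuestion(f"q{i}", f"q{i}", mandatory=(i % 2 == 0))
                          for i in range(n_questions))
        if rule == "MANDATORY_SET" and not any(q.mandatory for q in questions):
            questions = (ConsentQuestion("q0", "q0", True),) + questions[1:]
        sec = ConsentSectionDef("S", "s", questions, validation_rule=rule)
        for assignment in itertools.product((True, False, None),
                                            repeat=n_questions):
            answers = {q.code: a for q, a in zip(questions, assignment)
                       if a is not None}
            state = ConsentState("p1", "S", answers=answers)
            assert evaluate_validity(sec, state) == \
                brute_force_validity(sec, answers), (rule, assignment)

    def test_absent_state_is_invalid(self):
        sec = ConsentSectionDef("S", "s", (ConsentQuestion("q", "q"),))
        assert evaluate_validity(sec, None) is False


class TestStatusTable:
    def test_invalid_count_matches_cohort(self):
        defn = make_minimal_defn()
        site = make_site(defn)
        keys = [site.create_patient(demographics(), {"GR"}, {"WA"})
                for _ in range(5)]
        for key in keys[:3]:  # 3 of 5 consent fully on CS_ALL
            site.record_consent(key, "GR", "CS_ALL", {"q1": True, "q2": True})
        table = site.consent_status("GR")
        col = table.header.index("CS_ALL:status")
        statuses = [row[col] for row in table.rows]
        assert statuses.count(VALID) == 3 and statuses.count(INVALID) == 2

    def test_inapplicable_section_reads_not_applicable(self):
        site = make_site()
        minor = site.create_patient(demographics(date_of_birth="2010-01-01"),
                                    {"GR"}, {"WA"})
        table = site.consent_status("GR")
        col = table.header.index("CS_MAND:status")
        row = next(r for r in table.rows if r[0] == minor)
        assert row[col] == NOT_APPLICABLE

    def test_empty_cohort_gives_header_only_table(self):
        table = make_site().consent_status("GR")
        assert table.rows == [] and "CS_ALL:status" in table.header

    def test_filter_status(self):
        site = make_site()
        key = site.create_patient(demographics(), {"GR"}, {"WA"})
        table = site.consent_status("GR").filter_status(INVALID)
        assert [r[0] for r in table.rows] == [key]


class TestGate:
    def test_gate_tracks_section_validity(self):
        site = make_site()
        key = site.create_patient(demographics(), {"GR"}, {"WA"})
        assert site.gate(key, "GR", "include_in_report") is False
        site.record_consent(key, "GR", "CS_ALL", {"q1": True, "q2": True})
        assert site.gate(key, "GR", "include_in_report") is True

    def test_revocation_flips_gate_immediately(self):
        site = make_site()
        key = site.create_patient(demographics(), {"GR"}, {"WA"})
        site.record_consent(key, "GR", "CS_ALL", {"q1": True, "q2": True})
        assert site.gate(key, "GR", "include_in_report") is True
        site.record_consent(key, "GR", "CS_ALL", {"q1": False, "q2": True})
        assert site.gate(key, "GR", "include_in_report") is False

    def test_inapplicable_section_satisfies_the_capability(self):
        defn = make_minimal_defn(capabilities={"include_in_report": ["CS_MAND"]})
        site = make_site(defn)
        minor = site.create_patient(demographics(date_of_birth="2010-01-01"),
                                    {"GR"}, {"WA"})
        assert site.gate(minor, "GR", "include_in_report") is True

    def test_undeclared_capability_is_an_error(self):
        site = make_site()
        key = site.create_patient(demographics(), {"GR"}, {"WA"})
        with pytest.raises(UnknownCodeError, match="export_to_biobank"):
            site.gate(key, "GR", "export_to_biobank")
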