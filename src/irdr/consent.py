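"""Dynamic consent: configurable consent sections, applicability and
validation rules, timestamped modifiable answers, and capability gating.

Consent in a rare-disease registry is not static.  Sections of consent
questions are part of the registry definition, each with

* an *applicability* predicate — a conjunction of field/op/literal
  conditions on the patient's demographics (e.g. ``age_years >= 18``), so a
  section can target adults only, one jurisdiction only, etc.;
* a *validation rule* — ``ALL`` (every question must be agreed) or
  ``MANDATORY_SET`` (only the questions flagged mandatory must be agreed).

Answers are opt-in: an unanswered question counts as *false*.  Every change
of answers appends a timestamped snapshot to an append-only history, so a
curator can always see when consent was given or modified.  Registry
capabilities (e.g. inclusion of a patient in reports) are gated on the
current validity of the consent sections mapped to them; revoking consent
takes effect on the next evaluation, with no caching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Any, Iterable, Mapping, Sequence

from .base import IrdrError, UnknownCodeError, parse_date

RULE_ALL = "ALL"
RULE_MANDATORY_SET = "MANDATORY_SET"
VALIDATION_RULES = (RULE_ALL, RULE_MANDATORY_SET)

CONDITION_OPS = ("==", "!=", "<", "<=", ">", ">=", "in")

VALID = "valid"
INVALID = "invalid"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class Condition:
    """One ``field op value`` clause on patient demographics.

    ``field`` names a demographic field, the derived field ``age_years``
    (computed from ``date_of_birth`` when not stored directly), or the
    special field ``registry`` which resolves to the patient's registry
    memberships (``==``/``!=``/``in`` test membership; ordering operators
    are rejected).
    """

    field: str
    op: str
    value: Any

    def __post_init__(self) -> None:
        if self.op not in CONDITION_OPS:
            raise IrdrError(f"unknown condition operator {self.op!r}")


@dataclass(frozen=True)
class ConsentQuestion:
    code: str
    text: str
    mandatory: bool = False


@dataclass(frozen=True)
class ConsentSectionDef:
    code: str
    name: str
    questions: tuple[ConsentQuestion, ...]
    applicability: tuple[Condition, ...] = ()
    validation_rule: str = RULE_ALL

    def question_codes(self) -> list[str]:
        return [q.code for q in self.questions]

    def mandatory_codes(self) -> list[str]:
        return [q.code for q in self.questions if q.mandatory]


@dataclass
class ConsentState:
    """Current answers plus full history for one (patient, section).

    ``history`` is append-only: one ``(timestamp, answers-snapshot)`` per
    recording, non-decreasing in time; ``answers`` always equals the last
    snapshot.
    """

    patient: str
    section: str
    answers: dict[str, bool] = field(default_factory=dict)
    answered_at: datetime | None = None
    history: list[tuple[datetime, dict[str, bool]]] = field(default_factory=list)


def _resolve_field(cond: Condition, patient: Any, as_of: date | None) -> Any:
    demographics: Mapping[str, Any] = patient.demographics
    if cond.field == "registry":
        return set(patient.registries)
    if cond.field in demographics:
        return demographics[cond.field]
    if cond.field == "age_years" and "date_of_birth" in demographics:
        dob = demographics["date_of_birth"]
        if isinstance(dob, str):
            dob = parse_date(dob)
        ref = as_of or date.today()
        return ref.year - dob.year - ((ref.month, ref.day) < (dob.month, dob.day))
    raise UnknownCodeError(f"condition references unknown field {cond.field!r}")


def _coerce_pair(a: Any, b: Any) -> tuple[Any, Any]:
    # Compare numerically whenever both sides parse as numbers.
    try:
        return float(a), float(b)
    except (TypeError, ValueError):
        return str(a), str(b)


def evaluate_condition(cond: Condition, patient: Any,
                       as_of: date | None = None) -> bool:
    actual = _resolve_field(cond, patient, as_of)
    if isinstance(actual, set):  # registry membership semantics
        if cond.op == "==":
            return cond.value in actual
        if cond.op == "!=":
            return cond.value not in actual
        if cond.op == "in":
            return bool(actual & set(cond.value))
        raise IrdrError(f"operator {cond.op!r} not valid for field 'registry'")
    if cond.op == "in":
        return actual in cond.value
    a, b = _coerce_pair(actual, cond.value)
    if cond.op == "==":
        return a == b
    if cond.op == "!=":
        return a != b
    if cond.op == "<":
        return a < b
    if cond.op == "<=":
        return a <= b
    if cond.op == ">":
        return a > b
    return a >= b


def evaluate_applicability(sec: ConsentSectionDef, patient: Any,
                           as_of: date | None = None) -> bool:
    """True iff every applicability condition holds (empty list → True)."""
    return all(evaluate_condition(c, patient, as_of) for c in sec.applicability)


def record_consent(states: dict[tuple[str, str], ConsentState], patient_key: str,
                   sec: ConsentSectionDef, answers: Mapping[str, bool],
                   now: datetime) -> ConsentState:
    """Record (or modify) a patient's answers for one consent section.

    The state map is only touched when every answer key is a known question
    code; a rejected recording leaves it unchanged.
    """
    known = set(sec.question_codes())
    unknown = sorted(set(answers) - known)
    if unknown:
        raise UnknownCodeError(
            f"unknown consent question(s) {', '.join(unknown)} in section {sec.code}")
    state = states.get((patient_key, sec.code))
    if state is None:
        state = ConsentState(patient=patient_key, section=sec.code)
        states[(patient_key, sec.code)] = state
    snapshot = {code: bool(answers.get(code, False)) for code in sorted(answers)}
    state.answers = dict(snapshot)
    state.answered_at = now
    state.history.append((now, snapshot))
    return state


def evaluate_validity(sec: ConsentSectionDef, state: ConsentState | None) -> bool:
    """Apply the section's validation rule to the current answers.

    Absent state and unanswered questions are treated as *false* answers
    (opt-in semantics), so a patient with no recorded consent is invalid.
    """
    answers = state.answers if state is not None else {}
    if sec.validation_rule == RULE_ALL:
        required = sec.question_codes()
    else:
        required = sec.mandatory_codes()
    return all(answers.get(code, False) for code in required)


def section_status(sec: ConsentSectionDef, patient: Any,
                   state: ConsentState | None,
                   as_of: date | None = None) -> str:
    if not evaluate_applicability(sec, patient, as_of):
        return NOT_APPLICABLE
    return VALID if evaluate_validity(sec, state) else INVALID


def consent_status_table(defn: Any, patients: Sequence[Any],
                         states: Mapping[tuple[str, str], ConsentState],
                         as_of: date | None = None) -> "ConsentStatusTable":
    """One row per patient, one column pair per consent section.

    The table is the curator's view of Fig-2-style consent tracking: each
    cell is ``valid`` / ``invalid`` / ``not_applicable`` plus the timestamp
    of the latest answer, and the whole table filters by status.
    """
    sections: Sequence[ConsentSectionDef] = defn.consent_sections
    header = ["patient"]
    for sec in sections:
        header += [f"{sec.code}:status", f"{sec.code}:answered_at"]
    rows: list[list[Any]] = []
    for patient in patients:
        row: list[Any] = [patient.key]
        for sec in sections:
            state = states.get((patient.key, sec.code))
            row.append(section_status(sec, patient, state, as_of))
            row.append(state.answered_at if state is not None else None)
        rows.append(row)
    return ConsentStatusTable(header=header, rows=rows)


@dataclass
class ConsentStatusTable:
    header: list[str]
    rows: list[list[Any]]

    def filter_status(self, status: str) -> "ConsentStatusTable":
        """Keep rows where at least one section has the given status."""
        status_cols = [i for i, h in enumerate(self.header) if h.endswith(":status")]
        kept = [r for r in self.rows if any(r[i] == status for i in status_cols)]
        return ConsentStatusTable(header=list(self.header), rows=kept)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=self.header)


def gate(defn: Any, patient: Any,
         states: Mapping[tuple[str, str], ConsentState], capability: str,
         as_of: date | None = None) -> bool:
    """True iff every consent section mapped to ``capability`` is either
    inapplicable to the patient or currently valid.

    Memoryless: the answer depends only on the current consent state, so a
    revocation flips the gate immediately.
    """
    if capability not in defn.capabilities:
        raise UnknownCodeError(f"capability {capability!r} not declared in registry "
                               f"{defn.code}")
    by_code = {sec.code: sec for sec in defn.consent_sections}
    for code in defn.capabilities[capability]:
        sec = by_code[code]
        if not evaluate_applicability(sec, patient, as_of):
            continue  # a rule that cannot apply cannot block
        if not evaluate_validity(sec, states.get((patient.key, code))):
            return False
    return True
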