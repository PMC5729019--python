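"""Patients, the demographic/clinical store separation, and longitudinal
assessment contexts.

Two logically distinct stores hold a cohort:

* the **demographic store** holds identifying data (name, date of birth,
  contact, sex), registry enrolments, working-group assignments and the
  consent ledger — everything that can identify a person;
* the **clinical store** holds assessment *contexts* keyed by an opaque
  patient key only.  Its canonical serialization contains no demographic
  field name or value; the opaque key is the only link between the two.

A *context* is one assessment event: it owns a full set of longitudinal
form records for one patient in one registry, keyed by an assessment date.
This gives dual time-stamping — every stored value carries its own entry
timestamp, independent of the assessment date of the context it belongs to
(a value entered in 2018 can legitimately document a 2016 assessment).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Any, Iterable, Mapping

from .base import (Clock, IrdrError, UnknownCodeError, ValueError_,
                   canonical_json, format_timestamp, parse_date)
from .engine import FieldValue, validate_value
from .rml import RegistryDefinition

#: Minimal site-configured identifying fields every patient must provide.
REQUIRED_DEMOGRAPHIC_FIELDS = ("family_name", "given_name", "date_of_birth", "sex")

PatientKey = str


@dataclass
class Patient:
    """Identifying record; lives exclusively in the demographic store.

    ``key`` is an opaque random token that never encodes demographic
    content — it is the only identifier the clinical store ever sees.
    """

    key: PatientKey
    demographics: dict[str, Any]
    registries: set[str]
    working_groups: set[str]
    created_at: datetime


@dataclass
class Context:
    """One assessment event for one patient in one registry.

    ``records`` maps form code → section code → DE code → append-only list
    of :class:`FieldValue` (the last entry is the current value).
    ``created_seq`` is a per-patient monotone counter used to break ties
    between contexts sharing an assessment date.
    """

    id: str
    patient: PatientKey
    registry: str
    assessment_date: date
    created_seq: int
    created_at: datetime | None = None
    records: dict[str, dict[str, dict[str, list[FieldValue]]]] = field(default_factory=dict)

    def current_value(self, de_code: str) -> FieldValue | None:
        """Latest stored value for a DE anywhere in this context (by entry
        timestamp, then write order)."""
        best: FieldValue | None = None
        for by_section in self.records.values():
            for by_de in by_section.values():
                history = by_de.get(de_code)
                if history:
                    fv = history[-1]
                    if best is None or fv.entered_at >= best.entered_at:
                        best = fv
        return best


class DemographicStore:
    """Identifying patient data plus the consent ledger (consent answers
    identify a person's choices, so they live on this side of the split)."""

    def __init__(self, required_fields: tuple[str, ...] = REQUIRED_DEMOGRAPHIC_FIELDS):
        self.required_fields = required_fields
        self.patients: dict[PatientKey, Patient] = {}
        self.consent_states: dict[tuple[PatientKey, str], Any] = {}

    def create_patient(self, demographics: Mapping[str, Any],
                       registries: Iterable[str], working_groups: Iterable[str],
                       clock: Clock, rng: random.Random,
                       known_registries: Iterable[str]) -> Patient:
        registries = set(registries)
        if not registries:
            raise IrdrError("a patient must be enrolled in at least one registry")
        unknown = registries - set(known_registries)
        if unknown:
            raise UnknownCodeError(f"unknown registry code(s): {', '.join(sorted(unknown))}")
        missing = [f for f in self.required_fields if not demographics.get(f)]
        if missing:
            raise IrdrError(f"missing required demographic field(s): "
                            f"{', '.join(missing)}")
        key = f"{rng.getrandbits(64):016x}"
        while key in self.patients:  # vanishing probability; keep keys unique
            key = f"{rng.getrandbits(64):016x}"
        patient = Patient(key=key, demographics=dict(demographics),
                          registries=registries,
                          working_groups=set(working_groups),
                          created_at=clock())
        self.patients[key] = patient
        return patient

    def patients_in_registry(self, registry: str) -> list[Patient]:
        """Stable listing (by creation time, then key)."""
        return sorted((p for p in self.patients.values() if registry in p.registries),
                      key=lambda p: (p.created_at, p.key))

    def to_dict(self) -> dict:
        return {
            "patients": {
                p.key: {"demographics": p.demographics,
                        "registries": sorted(p.registries),
                        "working_groups": sorted(p.working_groups),
                        "created_at": format_timestamp(p.created_at)}
                for p in self.patients.values()},
            "consent": {
                f"{key}:{section}": {
                    "answers": state.answers,
                    "answered_at": format_timestamp(state.answered_at)
                    if state.answered_at else None,
                    "history": [{"at": format_timestamp(ts), "answers": snap}
                                for ts, snap in state.history]}
                for (key, section), state in sorted(self.consent_states.items())},
        }

    def to_canonical_json(self) -> str:
        return canonical_json(self.to_dict())

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DemographicStore":
        from .base import parse_timestamp
        from .consent import ConsentState

        store = cls()
        for key, p in doc.get("patients", {}).items():
            store.patients[key] = Patient(
                key=key, demographics=dict(p["demographics"]),
                registries=set(p["registries"]),
                working_groups=set(p["working_groups"]),
                created_at=parse_timestamp(p["created_at"]))
        for compound, s in doc.get("consent", {}).items():
            key, section = compound.split(":", 1)
            state = ConsentState(
                patient=key, section=section,
                answers={k: bool(v) for k, v in s["answers"].items()},
                answered_at=parse_timestamp(s["answered_at"])
                if s.get("answered_at") else None,
                history=[(parse_timestamp(h["at"]),
                          {k: bool(v) for k, v in h["answers"].items()})
                         for h in s.get("history", [])])
            store.consent_states[(key, section)] = state
        return store


class ClinicalStore:
    """Contexts and their field values, keyed by opaque patient key only.

    The serialized form of this store must never contain a demographic
    field name or value — that separation is the privacy backbone of the
    engine and is asserted by the test suite over generated cohorts.
    """

    def __init__(self) -> None:
        self.contexts: dict[PatientKey, list[Context]] = {}
        self._next_seq: dict[PatientKey, int] = {}

    def add_context(self, defn: RegistryDefinition, patient: Patient,
                    assessment_date: date | str, clock: Clock) -> Context:
        """Open a new, empty assessment for the patient: every longitudinal
        form of the registry is instantiated with no values."""
        if defn.code not in patient.registries:
            raise IrdrError(f"patient is not enrolled in registry {defn.code!r}")
        if isinstance(assessment_date, str):
            assessment_date = parse_date(assessment_date)
        seq = self._next_seq.get(patient.key, 0)
        self._next_seq[patient.key] = seq + 1
        ctx = Context(
            id=f"{patient.key}-{seq}",
            patient=patient.key,
            registry=defn.code,
            assessment_date=assessment_date,
            created_seq=seq,
            created_at=clock(),
            records={f.code: {s.code: {} for s in f.sections}
                     for f in defn.longitudinal_forms()})
        self.contexts.setdefault(patient.key, []).append(ctx)
        return ctx

    def enter_value(self, defn: RegistryDefinition, context: Context,
                    form_code: str, section_code: str, de_code: str,
                    raw: Any, clock: Clock) -> FieldValue:
        """Validate-then-store, atomically: a failing value leaves the
        store untouched; a passing value is appended to the field's
        history (overwrites retain the prior entries)."""
        try:
            by_section = context.records[form_code]
        except KeyError:
            raise UnknownCodeError(
                f"form {form_code!r} is not a longitudinal form of "
                f"{context.registry}") from None
        if section_code not in by_section:
            raise UnknownCodeError(f"unknown section {section_code!r} in form "
                                   f"{form_code!r}")
        section = next(s for s in defn.form(form_code).sections
                       if s.code == section_code)
        if de_code not in section.de_codes:
            raise UnknownCodeError(f"data element {de_code!r} is not in section "
                                   f"{section_code!r}")
        result = validate_value(defn.de(de_code), raw, defn.pv_group_map())
        if not result.ok:
            raise ValueError_(list(result.issues))
        fv = FieldValue(de_code=de_code,
                        raw=raw if isinstance(raw, str) else str(raw),
                        typed=result.typed, entered_at=clock())
        by_section[section_code].setdefault(de_code, []).append(fv)
        return fv

    def list_contexts(self, patient_key: PatientKey,
                      registry: str) -> list[Context]:
        """All contexts for the patient in the registry, ascending by
        (assessment_date, created_seq)."""
        ctxs = [c for c in self.contexts.get(patient_key, [])
                if c.registry == registry]
        return sorted(ctxs, key=lambda c: (c.assessment_date, c.created_seq))

    def current_context(self, patient_key: PatientKey,
                        registry: str) -> Context | None:
        ctxs = self.list_contexts(patient_key, registry)
        return ctxs[-1] if ctxs else None

    def to_dict(self) -> dict:
        return {
            "contexts": {
                key: [{
                    "id": c.id,
                    "registry": c.registry,
                    "assessment_date": c.assessment_date.isoformat(),
                    "created_seq": c.created_seq,
                    "created_at": format_timestamp(c.created_at)
                    if c.created_at else None,
                    "records": {
                        fc: {sc: {dc: [{"raw": fv.raw, "typed": fv.typed,
                                        "entered_at": format_timestamp(fv.entered_at)}
                                       for fv in history]
                                  for dc, history in by_de.items()}
                             for sc, by_de in by_section.items()}
                        for fc, by_section in c.records.items()},
                } for c in ctx_list]
                for key, ctx_list in self.contexts.items()},
        }

    def to_canonical_json(self) -> str:
        return canonical_json(self.to_dict())

    @classmethod
    def from_dict(cls, doc: Mapping,
                  definitions: Mapping[str, RegistryDefinition]) -> "ClinicalStore":
        """Rebuild from the canonical form; typed values are re-coerced
        from their raw text through the (pure) validator."""
        from .base import parse_timestamp

        store = cls()
        for key, ctx_list in doc.get("contexts", {}).items():
            rebuilt: list[Context] = []
            for c in ctx_list:
                defn = definitions[c["registry"]]
                de_map = defn.de_map()
                pvg_map = defn.pv_group_map()
                records: dict[str, dict[str, dict[str, list[FieldValue]]]] = {}
                for fc, by_section in c["records"].items():
                    records[fc] = {}
                    for sc, by_de in by_section.items():
                        records[fc][sc] = {}
                        for dc, history in by_de.items():
                            fvs = []
                            for h in history:
                                result = validate_value(de_map[dc], h["raw"], pvg_map)
                                fvs.append(FieldValue(
                                    de_code=dc, raw=h["raw"], typed=result.typed,
                                    entered_at=parse_timestamp(h["entered_at"])))
                            records[fc][sc][dc] = fvs
                rebuilt.append(Context(
                    id=c["id"], patient=key, registry=c["registry"],
                    assessment_date=parse_date(c["assessment_date"]),
                    created_seq=c["created_seq"],
                    created_at=parse_timestamp(c["created_at"])
                    if c.get("created_at") else None,
                    records=records))
            store.contexts[key] = rebuilt
            store._next_seq[key] = 1 + max(c.created_seq for c in rebuilt)
        return store


def compute_progress(defn: RegistryDefinition, context: Context) -> float:
    """Fraction of the registry's required longitudinal DEs that hold a
    valid value in this context.

    The unit is the distinct required DE (a DE reused in two sections
    counts once).  A definition with no required longitudinal DEs yields
    1.0 — there is nothing left to fill in.  The figure is monotone: each
    additional valid required value can only raise it.
    """
    de_map = defn.de_map()
    required: set[str] = set()
    for form in defn.longitudinal_forms():
        for section in form.sections:
            for de_code in section.de_codes:
                de = de_map.get(de_code)
                if de is not None and de.required:
                    required.add(de_code)
    if not required:
        return 1.0
    filled = sum(1 for code in required if context.current_value(code) is not None)
    return filled / len(required)


def form_progress(defn: RegistryDefinition, context: Context) -> dict[str, float]:
    """Per-form breakdown of the same counts (1.0 for forms with no
    required DEs)."""
    de_map = defn.de_map()
    out: dict[str, float] = {}
    for form in defn.longitudinal_forms():
        required = {c for s in form.sections for c in s.de_codes
                    if de_map.get(c) is not None and de_map[c].required}
        if not required:
            out[form.code] = 1.0
        else:
            filled = sum(1 for c in required
                         if context.current_value(c) is not None)
            out[form.code] = filled / len(required)
    return out
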