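"""Deterministic synthetic registry definitions and cohorts.

Everything the engine needs to be exercised end-to-end is generated here
from an explicit seed: a Gaucher-flavoured registry definition (clinical
forms such as haematology, visceral and skeletal assessments; an enum DE
for the enzyme-replacement product; consent sections under both validation
rules) and a synthetic cohort distributed over working groups, with
partially filled assessments and a mix of consent outcomes.

The flavouring is cosmetic labelling only — no clinical semantics, value
distributions or reference ranges are claimed.  Every generated artifact
passes its module validator, and equal seeds yield byte-equal canonical
serializations.  A single ``random.Random`` stream per call; no global
state.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Mapping

from .access import PermissionMatrix
from .base import IrdrError, StepClock
from .consent import Condition, ConsentQuestion, ConsentSectionDef
from .reporting import ReportTemplate
from .rml import (DataElementDef, FormDef, PermissibleValue,
                  PermissibleValueGroup, RegistryDefinition, SectionDef)
from .site import Site

USER_GROUPS = ("clinical", "genetic", "curator", "admin", "patient")

_FORM_NAMES = ("Haematology", "Visceral", "Skeletal", "Therapy",
               "Quality of Life", "Neurology", "Biochemistry", "Genetics")
_SURNAMES = ("Aalto", "Baker", "Chen", "Duarte", "Ekwueme", "Fischer",
             "Garcia", "Haddad", "Ivanov", "Jensen", "Kaur", "Larsen",
             "Moreau", "Nguyen", "Okafor", "Petrov", "Quinn", "Rossi",
             "Silva", "Tanaka")
_GIVEN = ("Ada", "Bruno", "Clara", "Dawit", "Elena", "Farid", "Greta",
          "Hugo", "Ines", "Jonas", "Kira", "Liam", "Mona", "Nils",
          "Olga", "Pavel", "Rhea", "Sofia", "Tomas", "Uma")

_AS_OF = date(2018, 1, 1)


@dataclass(frozen=True)
class CohortParams:
    """Shape of a generated cohort; rates are per-slot probabilities."""

    n_patients: int = 50
    max_contexts_per_patient: int = 5
    value_fill_rate: float = 0.7
    consent_valid_rate: float = 0.8
    n_working_groups: int = 4
    n_users: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("value_fill_rate", "consent_valid_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise IrdrError(f"{name} must be in [0, 1], got {rate}")
        for name in ("n_patients", "max_contexts_per_patient",
                     "n_working_groups", "n_users"):
            if getattr(self, name) < 0:
                raise IrdrError(f"{name} must be >= 0")


def _pv_groups() -> list[PermissibleValueGroup]:
    return [
        PermissibleValueGroup("PVG_SEX", (
            PermissibleValue("M", "Male"), PermissibleValue("F", "Female"),
            PermissibleValue("U", "Unknown"))),
        PermissibleValueGroup("PVG_PRODUCT", (
            PermissibleValue("IMIGLUCERASE", "Imiglucerase"),
            PermissibleValue("VELAGLUCERASE", "Velaglucerase alfa"),
            PermissibleValue("TALIGLUCERASE", "Taliglucerase alfa"),
            PermissibleValue("UNTREATED", "No current therapy"))),
        PermissibleValueGroup("PVG_SEVERITY", (
            PermissibleValue("MILD", "Mild"), PermissibleValue("MODERATE", "Moderate"),
            PermissibleValue("SEVERE", "Severe"))),
    ]


def _make_de(code: str, idx: int, rng: random.Random) -> DataElementDef:
    kind = ("enum" if idx == 0 else
            rng.choice(("integer", "decimal", "string", "date", "boolean", "enum")))
    required = rng.random() < 0.7
    if kind == "integer":
        lo = rng.choice((0, 0, 1))
        hi = lo + rng.randint(50, 300)
        return DataElementDef(code, f"Count {code}", "integer", min=lo, max=hi,
                              units="count", required=required)
    if kind == "decimal":
        hi = float(rng.randint(10, 50))
        return DataElementDef(code, f"Measure {code}", "decimal", min=0.0,
                              max=hi, units="mL", required=required)
    if kind == "date":
        return DataElementDef(code, f"Date {code}", "date", required=required)
    if kind == "boolean":
        return DataElementDef(code, f"Flag {code}", "boolean", required=required)
    if kind == "enum":
        # PVG_SEX is deliberately never used for clinical DEs: sex lives in
        # demographics, and its value space must stay disjoint from the
        # clinical store (store-separation scan).
        group = "PVG_PRODUCT" if idx == 0 else rng.choice(
            ("PVG_PRODUCT", "PVG_SEVERITY"))
        return DataElementDef(code, f"Choice {code}", "enum", pv_group=group,
                              required=required)
    return DataElementDef(code, f"Note {code}", "string", required=required)


def generate_registry_definition(n_forms: int = 6, n_sections_per_form: int = 2,
                                 n_des_per_section: int = 4,
                                 seed: int = 0) -> RegistryDefinition:
    """A valid Gaucher-like definition with ``n_forms`` longitudinal forms
    and ``n_forms * n_sections_per_form * n_des_per_section`` DEs.

    Always includes at least one enum DE with a PV group, one ``ALL``
    consent section and one ``MANDATORY_SET`` consent section (applicable
    to adults only).  Deterministic in ``seed``.
    """
    if min(n_forms, n_sections_per_form, n_des_per_section) < 1:
        raise IrdrError("all counts must be >= 1")
    rng = random.Random(seed)
    data_elements: list[DataElementDef] = []
    forms: list[FormDef] = []
    de_idx = 0
    for fi in range(n_forms):
        fname = _FORM_NAMES[fi % len(_FORM_NAMES)]
        fcode = f"F{fi + 1}_{fname.upper().replace(' ', '_')[:8]}"
        sections = []
        for si in range(n_sections_per_form):
            scode = f"{fcode}_S{si + 1}"
            de_codes = []
            for di in range(n_des_per_section):
                dcode = f"{scode}_DE{di + 1}"
                data_elements.append(_make_de(dcode, de_idx, rng))
                de_codes.append(dcode)
                de_idx += 1
            sections.append(SectionDef(scode, f"{fname} section {si + 1}",
                                       tuple(de_codes)))
        forms.append(FormDef(fcode, fname, tuple(sections), longitudinal=True))

    consent_sections = [
        ConsentSectionDef(
            code="CS_PART", name="Participation and data storage",
            questions=(ConsentQuestion("q_store", "Store my clinical data", True),
                       ConsentQuestion("q_contact", "Contact me about the registry",
                                       True)),
            validation_rule="ALL"),
        ConsentSectionDef(
            code="CS_SHARE", name="Data sharing with researchers",
            questions=(ConsentQuestion("q_share", "Share de-identified data", True),
                       ConsentQuestion("q_recontact", "Re-contact for studies",
                                       False)),
            applicability=(Condition("age_years", ">=", 18),),
            validation_rule="MANDATORY_SET"),
    ]

    # Role visibility: one genetics-flavoured form is restricted; one DE is
    # curator-only to exercise field-level overrides.
    form_visibility = {}
    for i, form in enumerate(forms):
        if i == min(1, len(forms) - 1) and len(forms) > 1:
            form_visibility[form.code] = {"genetic", "curator"}
        else:
            form_visibility[form.code] = {"clinical", "curator"}
    de_visibility = {data_elements[-1].code: {"curator"}}
    matrix = PermissionMatrix(form_visibility=form_visibility,
                              de_visibility=de_visibility)

    return RegistryDefinition(
        code="GR", name="Gaucher Registry (synthetic)",
        context_label="Assessment date",
        forms=forms, data_elements=data_elements, pv_groups=_pv_groups(),
        consent_sections=consent_sections, permission_matrix=matrix,
        capabilities={"include_in_report": ["CS_PART"]},
        version="1.0")


def random_valid_raw(de: DataElementDef,
                     pv_groups: Mapping[str, PermissibleValueGroup],
                     rng: random.Random) -> str:
    """A raw text value guaranteed to pass validation for ``de``.

    Generated date values stay in 2000-2017 so they can never collide with
    a demographic date of birth (1920-1999) — the store-separation scan
    depends on the two value spaces being disjoint.
    """
    if de.datatype == "integer":
        lo = int(de.min) if de.min is not None else 0
        hi = int(de.max) if de.max is not None else lo + 100
        return str(rng.randint(lo, hi))
    if de.datatype == "decimal":
        lo = de.min if de.min is not None else 0.0
        hi = de.max if de.max is not None else lo + 10.0
        return f"{rng.uniform(lo, hi):.2f}"
    if de.datatype == "date":
        d = date(2000, 1, 1) + timedelta(days=rng.randint(0, 6500))
        return d.isoformat()
    if de.datatype == "boolean":
        return rng.choice(("true", "false"))
    if de.datatype == "enum":
        return rng.choice([v.code for v in pv_groups[de.pv_group].values])
    return f"obs-{rng.getrandbits(32):08x}"


def generate_cohort(defn: RegistryDefinition,
                    params: CohortParams | None = None) -> Site:
    """Populate a :class:`Site` with a synthetic cohort for ``defn``.

    Patients are spread over ``n_working_groups`` jurisdictions; each gets
    0..max contexts with strictly increasing assessment dates; each DE slot
    of each context is filled (with an individually valid value) with
    probability ``value_fill_rate``.  With probability
    ``consent_valid_rate`` a patient answers every applicable consent
    section validly; otherwise they either record a refusal or record
    nothing.  The user roster covers every user group at least once.
    Deterministic in ``params.seed``.
    """
    params = params or CohortParams()
    rng = random.Random(params.seed)
    clock = StepClock(datetime(2018, 1, 1, 9, 0, 0, tzinfo=timezone.utc))
    site = Site(clock=clock, rng=rng, as_of=_AS_OF)
    site.add_registry(defn)
    wgs = [f"WG{i + 1:02d}" for i in range(max(params.n_working_groups, 1))]

    for i in range(params.n_users):
        group = USER_GROUPS[i % len(USER_GROUPS)]
        if group == "admin":
            user_wgs = list(wgs)
        else:
            user_wgs = rng.sample(wgs, rng.randint(1, len(wgs)))
        site.add_user(f"{group}{i + 1:02d}", [group], user_wgs)

    pvg_map = defn.pv_group_map()
    for i in range(params.n_patients):
        # Demographic values occupy value spaces disjoint from anything the
        # clinical store can hold: births pre-2000 (clinical dates are
        # 2000+), spelled-out sex (clinical enums are uppercase codes), so
        # the store-separation scan is meaningful.  Age is derived from the
        # date of birth at the site's as-of date, never stored.
        dob = date(1920, 1, 1) + timedelta(days=rng.randint(0, 365 * 79))
        demographics = {
            "family_name": rng.choice(_SURNAMES),
            "given_name": rng.choice(_GIVEN),
            "date_of_birth": dob.isoformat(),
            "sex": rng.choice(("female", "male", "unknown")),
            "contact": f"participant{i + 1:03d}@registry.example",
        }
        key = site.create_patient(demographics, {defn.code},
                                  {rng.choice(wgs)})
        patient = site.patient(key)

        n_ctx = rng.randint(0, params.max_contexts_per_patient)
        day = date(2015, 1, 1) + timedelta(days=rng.randint(0, 180))
        for _ in range(n_ctx):
            ctx = site.add_context(key, defn.code, day)
            day = day + timedelta(days=rng.randint(30, 400))
            for form in defn.longitudinal_forms():
                for section in form.sections:
                    for de_code in section.de_codes:
                        if rng.random() < params.value_fill_rate:
                            raw = random_valid_raw(defn.de(de_code), pvg_map, rng)
                            site.enter_value(ctx, form.code, section.code,
                                             de_code, raw)

        fully_valid = rng.random() < params.consent_valid_rate
        from .consent import evaluate_applicability

        for sec in defn.consent_sections:
            if not evaluate_applicability(sec, patient, _AS_OF):
                continue
            if fully_valid:
                answers = {q.code: True for q in sec.questions}
                site.record_consent(key, defn.code, sec.code, answers)
            elif rng.random() < 0.5:
                answers = {q.code: False for q in sec.questions}
                site.record_consent(key, defn.code, sec.code, answers)
            # else: no consent recorded at all
    return site


def demo_report_templates(defn: RegistryDefinition) -> list[ReportTemplate]:
    """Two ready-made templates (one per mode) over the first few DEs."""
    selected = [de.code for de in defn.data_elements[:6]]
    demo_cols = ["family_name", "given_name", "sex"]
    return [
        ReportTemplate(name="current_overview", registry=defn.code,
                       selected_des=selected, demographic_columns=demo_cols,
                       mode="current", access_groups={"curator", "clinical"}),
        ReportTemplate(name="longitudinal_overview", registry=defn.code,
                       selected_des=selected, demographic_columns=demo_cols,
                       mode="longitudinal", access_groups={"curator", "clinical"}),
    ]
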