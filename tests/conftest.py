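import random
from datetime import date, datetime, timezone

import pytest

from irdr import (CohortParams, Condition, ConsentQuestion, ConsentSectionDef,
                  DataElementDef, FormDef, PermissibleValue,
                  PermissibleValueGroup, PermissionMatrix, RegistryDefinition,
                  SectionDef, Site, StepClock, generate_cohort,
                  generate_registry_definition)


def make_minimal_defn(**overrides) -> RegistryDefinition:
    """A tiny hand-built registry: one longitudinal form, two sections,
    four DEs (bounded integer, bounded decimal, sex enum, free text), two
    consent sections (one per validation rule)."""
    defn = RegistryDefinition(
        code="GR", name="Gaucher Registry", context_label="Assessment date",
        data_elements=[
            DataElementDef("PLT", "Platelet count", "integer", min=0, max=300,
                           units="10^9/L", required=True),
            DataElementDef("SPLEEN_VOL", "Spleen volume", "decimal", min=0,
                           max=5000, units="mL", required=True),
            DataElementDef("SEX_AT_ASSESS", "Sex", "enum", pv_group="PVG_SEX",
                           required=True),
            DataElementDef("NOTES", "Notes", "string", required=False),
        ],
        pv_groups=[PermissibleValueGroup("PVG_SEX", (
            PermissibleValue("M", "Male"), PermissibleValue("F", "Female"),
            PermissibleValue("U", "Unknown")))],
        forms=[FormDef("CLIN", "Clinical", (
            SectionDef("S1", "Bloods", ("PLT", "SPLEEN_VOL")),
            SectionDef("S2", "Other", ("SEX_AT_ASSESS", "NOTES"))))],
        consent_sections=[
            ConsentSectionDef("CS_ALL", "Participation",
                              (ConsentQuestion("q1", "Store data", True),
                               ConsentQuestion("q2", "Contact me", False)),
                              validation_rule="ALL"),
            ConsentSectionDef("CS_MAND", "Sharing",
                              (ConsentQuestion("m1", "Share data", True),
                               ConsentQuestion("m2", "Optional extra", False)),
                              applicability=(Condition("age_years", ">=", 18),),
                              validation_rule="MANDATORY_SET"),
        ],
        permission_matrix=PermissionMatrix(
            form_visibility={"CLIN": {"clinical", "curator"}}),
        capabilities={"include_in_report": ["CS_ALL"]},
        version="1.0")
    for key, value in overrides.items():
        setattr(defn, key, value)
    return defn


def make_site(defn=None, seed=0) -> Site:
    defn = defn or make_minimal_defn()
    site = Site(clock=StepClock(datetime(2018, 1, 1, tzinfo=timezone.utc)),
                rng=random.Random(seed), as_of=date(2018, 1, 1))
    site.add_registry(defn)
    return site


def demographics(**overrides):
    demo = {"family_name": "Aalto", "given_name": "Ada",
            "date_of_birth": "1970-05-04", "sex": "female"}
    demo.update(overrides)
    return demo


@pytest.fixture(scope="session")
def gr_defn():
    return generate_registry_definition(6, 2, 4, seed=1)


@pytest.fixture(scope="session")
def cohort_site(gr_defn):
    return generate_cohort(gr_defn, CohortParams(n_patients=20, seed=3))
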