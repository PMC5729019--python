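"""Definition language: parsing, canonical serialization, invariant
checking and by-copy DE-library sharing."""

import dataclasses

import pytest

from irdr import (DataElementDef, DefinitionError, DELibrary,
                  MergeConflictError, PermissibleValue, PermissibleValueGroup,
                  SectionDef, check_definition, generate_registry_definition,
                  merge_de_library, parse_library, parse_rml,
                  serialize_library, serialize_rml)
from irdr.rml import FormDef, definition_to_dict

from conftest import make_minimal_defn

MINIMAL_TEXT = """
{
  "code": "GR",
  "name": "Gaucher Registry",
  "context_label": "Assessment date",
  "data_elements": [
    {"code": "PLT", "name": "Platelets", "datatype": "integer",
     "pv_group": null, "min": 0, "max": 300, "units": "", "required": true}
  ],
  "forms": [
    {"code": "CLIN", "name": "Clinical", "longitudinal": true,
     "sections": [{"code": "S1", "name": "Bloods", "de_codes": ["PLT"]}]}
  ]
}
"""


class TestParse:
    def test_minimal_definition_carries_context_label(self):
        defn = parse_rml(MINIMAL_TEXT)
        assert defn.context_label == "Assessment date"
        assert [f.code for f in defn.forms] == ["CLIN"]

    def test_yaml_dialect_accepted(self):
        yaml_text = """
code: GR
name: Gaucher Registry
context_label: Assessment date
data_elements:
  - {code: PLT, name: Platelets, datatype: integer, min: 0, max: 300,
     required: true}
forms:
  - code: CLIN
    name: Clinical
    sections:
      - {code: S1, name: Bloods, de_codes: [PLT]}
"""
        assert parse_rml(yaml_text) == parse_rml(MINIMAL_TEXT)

    def test_dangling_pv_group_reference_named_in_error(self):
        defn = make_minimal_defn()
        defn.data_elements[2] = dataclasses.replace(defn.data_elements[2],
                                                    pv_group="PG9")
        with pytest.raises(DefinitionError, match="PG9"):
            parse_rml(serialize_rml_unchecked(defn))

    def test_garbage_text_is_a_syntax_error(self):
        from irdr import RMLSyntaxError

        with pytest.raises(RMLSyntaxError):
            parse_rml("{not valid json: [nor yaml")


def serialize_rml_unchecked(defn) -> str:
    from irdr.base import canonical_json

    return canonical_json(definition_to_dict(defn))


class TestSerialize:
    def test_byte_determinism(self):
        defn = make_minimal_defn()
        assert serialize_rml(defn) == serialize_rml(defn)

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_identity_over_generated_definitions(self, seed):
        defn = generate_registry_definition(
            n_forms=1 + seed % 4, n_sections_per_form=1 + seed % 3,
            n_des_per_section=1 + seed % 5, seed=seed)
        text = serialize_rml(defn)
        assert parse_rml(text) == defn
        assert serialize_rml(parse_rml(text)) == text

    def test_empty_forms_definition_refused(self):
        defn = make_minimal_defn(forms=[])
        with pytest.raises(DefinitionError, match="at least one form"):
            serialize_rml(defn)


def _replace_de(defn, idx, **kw):
    defn.data_elements[idx] = dataclasses.replace(defn.data_elements[idx], **kw)
    return defn


# Each mutation breaks exactly one documented invariant of the definition.
MUTATIONS = {
    "empty_context_label": lambda d: setattr_(d, "context_label", ""),
    "no_forms": lambda d: setattr_(d, "forms", []),
    "duplicate_form_code": lambda d: setattr_(
        d, "forms", d.forms + [dataclasses.replace(d.forms[0])]),
    "duplicate_de_definition": lambda d: setattr_(
        d, "data_elements",
        d.data_elements + [dataclasses.replace(d.data_elements[0],
                                               datatype="string", min=None,
                                               max=None)]),
    "min_above_max": lambda d: _replace_de(d, 0, min=10, max=2),
    "bounds_on_string": lambda d: _replace_de(d, 3, min=0, max=5),
    "enum_without_pv_group": lambda d: _replace_de(d, 2, pv_group=None),
    "pv_group_on_non_enum": lambda d: _replace_de(d, 0, pv_group="PVG_SEX"),
    "dangling_pv_group": lambda d: _replace_de(d, 2, pv_group="PG9"),
    "unknown_datatype": lambda d: _replace_de(d, 0, datatype="complex",
                                              min=None, max=None),
    "empty_pv_group": lambda d: setattr_(
        d, "pv_groups", [PermissibleValueGroup("PVG_SEX", ())]),
    "duplicate_pv_code": lambda d: setattr_(
        d, "pv_groups", [PermissibleValueGroup("PVG_SEX", (
            PermissibleValue("M", "a"), PermissibleValue("M", "b")))]),
    "sectionless_form": lambda d: setattr_(
        d, "forms", [dataclasses.replace(d.forms[0], sections=())]),
    "empty_section": lambda d: setattr_(
        d, "forms", [dataclasses.replace(d.forms[0], sections=(
            SectionDef("S1", "Bloods", ()),))]),
    "duplicate_de_in_section": lambda d: setattr_(
        d, "forms", [dataclasses.replace(d.forms[0], sections=(
            SectionDef("S1", "Bloods", ("PLT", "PLT")),))]),
    "dangling_de_in_section": lambda d: setattr_(
        d, "forms", [dataclasses.replace(d.forms[0], sections=(
            SectionDef("S1", "Bloods", ("PLT", "NOPE")),))]),
    "mandatory_set_without_mandatory": lambda d: setattr_(
        d, "consent_sections", [dataclasses.replace(
            d.consent_sections[1],
            questions=tuple(dataclasses.replace(q, mandatory=False)
                            for q in d.consent_sections[1].questions))]),
    "unknown_validation_rule": lambda d: setattr_(
        d, "consent_sections", [dataclasses.replace(
            d.consent_sections[0], validation_rule="SOME")]),
    "duplicate_question_code": lambda d: setattr_(
        d, "consent_sections", [dataclasses.replace(
            d.consent_sections[0],
            questions=(d.consent_sections[0].questions[0],) * 2)]),
    "matrix_unknown_form": lambda d: d.permission_matrix.form_visibility
    .__setitem__("NOFORM", {"clinical"}),
    "matrix_unknown_de": lambda d: d.permission_matrix.de_visibility
    .__setitem__("NODE", {"curator"}),
    "capability_unknown_section": lambda d: d.capabilities
    .__setitem__("include_in_report", ["CS_MISSING"]),
}


def setattr_(obj, name, value):
    setattr(obj, name, value)


class TestCheckDefinition:
    def test_valid_fixture_has_no_issues(self, gr_defn):
        assert check_definition(gr_defn) == []

    def test_de_reuse_across_sections_is_legal(self):
        defn = make_minimal_defn()
        defn.forms = [dataclasses.replace(defn.forms[0], sections=(
            SectionDef("S1", "Bloods", ("PLT",)),
            SectionDef("S2", "Again", ("PLT",))))]
        assert check_definition(defn) == []

    @pytest.mark.parametrize("name", sorted(MUTATIONS))
    def test_every_invariant_breaking_mutation_is_detected(self, name):
        defn = make_minimal_defn()
        MUTATIONS[name](defn)
        issues = check_definition(defn)
        assert any(i.severity == "error" for i in issues), name

    def test_min_above_max_error_carries_the_de_path(self):
        defn = _replace_de(make_minimal_defn(), 0, min=10, max=2)
        issues = check_definition(defn)
        assert any("data_elements/PLT" == i.path for i in issues)


class TestMergeDELibrary:
    def lib(self):
        return DELibrary(data_elements=[
            DataElementDef("HB", "Haemoglobin", "integer", min=0, max=250),
            DataElementDef("FERRITIN", "Ferritin", "decimal", min=0, max=10000),
            DataElementDef("GENOTYPE", "Genotype", "string"),
        ])

    def test_union_count(self):
        defn = make_minimal_defn()
        merged = merge_de_library(defn, self.lib())
        assert len(merged.data_elements) == 4 + 3
        assert len(defn.data_elements) == 4  # input untouched

    def test_idempotent(self):
        merged = merge_de_library(make_minimal_defn(), self.lib())
        again = merge_de_library(merged, self.lib())
        assert again == merged

    def test_commutative_for_disjoint_libraries(self):
        other = DELibrary(data_elements=[
            DataElementDef("CHITO", "Chitotriosidase", "decimal", min=0, max=99999)])
        a = merge_de_library(merge_de_library(make_minimal_defn(), self.lib()), other)
        b = merge_de_library(merge_de_library(make_minimal_defn(), other), self.lib())
        assert set(de.code for de in a.data_elements) == \
            set(de.code for de in b.data_elements)

    def test_conflicting_content_is_refused(self):
        lib = DELibrary(data_elements=[
            DataElementDef("SPLEEN_VOL", "Spleen volume", "string")])
        with pytest.raises(MergeConflictError, match="SPLEEN_VOL"):
            merge_de_library(make_minimal_defn(), lib)

    def test_library_round_trip(self):
        lib = self.lib()
        assert parse_library(serialize_library(lib)) == lib
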