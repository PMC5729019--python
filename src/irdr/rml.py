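"""Registry Mark-up Language: parse, validate, serialize and share
declarative registry definitions.

A registry definition is a single self-contained document describing
everything a registry needs: its data elements (DEs — atomic clinical
variables with a datatype, bounds and permissible values), permissible
value groups (controlled vocabularies), sections and forms composing the
case-report screens, consent sections with their validation/applicability
rules, the permission matrix, and the consent-capability map.

The canonical concrete syntax is UTF-8 JSON with lexicographically sorted
object keys and definition-ordered arrays, so serialization is
byte-deterministic and externally diffable; YAML is accepted as an input
convenience and always re-emitted as canonical JSON.  DE sharing between
registries is by-copy with conflict detection: merging a DE library never
silently overwrites an existing definition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

import yaml

from .access import PermissionMatrix
from .base import (ERROR, WARNING, DefinitionError, MergeConflictError,
                   RMLSyntaxError, ValidationIssue, canonical_json, has_errors)
from .consent import (CONDITION_OPS, VALIDATION_RULES, Condition,
                      ConsentQuestion, ConsentSectionDef)

DATATYPES = ("integer", "decimal", "string", "date", "boolean", "enum")
NUMERIC_DATATYPES = ("integer", "decimal")


@dataclass(frozen=True)
class PermissibleValue:
    code: str
    display: str


@dataclass(frozen=True)
class PermissibleValueGroup:
    code: str
    values: tuple[PermissibleValue, ...]


@dataclass(frozen=True)
class DataElementDef:
    """An atomic, reusable clinical variable definition."""

    code: str
    name: str
    datatype: str
    pv_group: str | None = None
    min: float | None = None
    max: float | None = None
    units: str = ""
    required: bool = False


@dataclass(frozen=True)
class SectionDef:
    code: str
    name: str
    de_codes: tuple[str, ...]


@dataclass(frozen=True)
class FormDef:
    """A form groups sections; ``longitudinal=True`` forms are captured per
    assessment context, ``longitudinal=False`` forms are fixed patient-level
    modules (Demographics/Consent style)."""

    code: str
    name: str
    sections: tuple[SectionDef, ...]
    longitudinal: bool = True


@dataclass
class RegistryDefinition:
    code: str
    name: str
    context_label: str
    forms: list[FormDef] = field(default_factory=list)
    data_elements: list[DataElementDef] = field(default_factory=list)
    pv_groups: list[PermissibleValueGroup] = field(default_factory=list)
    consent_sections: list[ConsentSectionDef] = field(default_factory=list)
    permission_matrix: PermissionMatrix = field(default_factory=PermissionMatrix)
    capabilities: dict[str, list[str]] = field(default_factory=dict)
    version: str = "1"

    # -- lookup helpers -------------------------------------------------
    def de(self, code: str) -> DataElementDef:
        for de in self.data_elements:
            if de.code == code:
                return de
        from .base import UnknownCodeError

        raise UnknownCodeError(f"unknown data element {code!r}")

    def de_map(self) -> dict[str, DataElementDef]:
        return {de.code: de for de in self.data_elements}

    def pv_group_map(self) -> dict[str, PermissibleValueGroup]:
        return {g.code: g for g in self.pv_groups}

    def form(self, code: str):
        for f in self.forms:
            if f.code == code:
                return f
        from .base import UnknownCodeError

        raise UnknownCodeError(f"unknown form {code!r}")

    def longitudinal_forms(self) -> list[FormDef]:
        return [f for f in self.forms if f.longitudinal]


@dataclass
class DELibrary:
    """A shareable bundle of DE definitions plus the PV groups they need."""

    data_elements: list[DataElementDef] = field(default_factory=list)
    pv_groups: list[PermissibleValueGroup] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dict <-> dataclass mapping

def _de_to_dict(de: DataElementDef) -> dict:
    return {"code": de.code, "name": de.name, "datatype": de.datatype,
            "pv_group": de.pv_group, "min": de.min, "max": de.max,
            "units": de.units, "required": de.required}


def _pvg_to_dict(g: PermissibleValueGroup) -> dict:
    return {"code": g.code,
            "values": [{"code": v.code, "display": v.display} for v in g.values]}


def definition_to_dict(defn: RegistryDefinition) -> dict:
    m = defn.permission_matrix
    return {
        "code": defn.code,
        "name": defn.name,
        "context_label": defn.context_label,
        "version": defn.version,
        "data_elements": [_de_to_dict(de) for de in defn.data_elements],
        "pv_groups": [_pvg_to_dict(g) for g in defn.pv_groups],
        "forms": [
            {"code": f.code, "name": f.name, "longitudinal": f.longitudinal,
             "sections": [{"code": s.code, "name": s.name,
                           "de_codes": list(s.de_codes)} for s in f.sections]}
            for f in defn.forms
        ],
        "consent_sections": [
            {"code": s.code, "name": s.name,
             "validation_rule": s.validation_rule,
             "questions": [{"code": q.code, "text": q.text,
                            "mandatory": q.mandatory} for q in s.questions],
             "applicability": [{"field": c.field, "op": c.op, "value": c.value}
                               for c in s.applicability]}
            for s in defn.consent_sections
        ],
        "permission_matrix": {
            "form_visibility": {k: sorted(v) for k, v in m.form_visibility.items()},
            "de_visibility": {k: sorted(v) for k, v in m.de_visibility.items()},
            "report_access": {k: sorted(v) for k, v in m.report_access.items()},
        },
        "capabilities": {k: list(v) for k, v in defn.capabilities.items()},
    }


class _Path:
    """Tracks the location inside the document for error messages."""

    def __init__(self, *parts: Any):
        self.parts = parts

    def __truediv__(self, part: Any) -> "_Path":
        return _Path(*self.parts, part)

    def __str__(self) -> str:
        return "/".join(str(p) for p in self.parts) or "<root>"


def _get(d: Mapping, key: str, path: _Path, default: Any = ...) -> Any:
    if not isinstance(d, Mapping):
        raise RMLSyntaxError(f"{path}: expected an object, got {type(d).__name__}")
    if key in d:
        return d[key]
    if default is ...:
        raise RMLSyntaxError(f"{path}: missing required key {key!r}")
    return default


def _de_from_dict(d: Mapping, path: _Path) -> DataElementDef:
    return DataElementDef(
        code=str(_get(d, "code", path)),
        name=str(_get(d, "name", path, "")),
        datatype=str(_get(d, "datatype", path)),
        pv_group=_get(d, "pv_group", path, None),
        min=_get(d, "min", path, None),
        max=_get(d, "max", path, None),
        units=str(_get(d, "units", path, "")),
        required=bool(_get(d, "required", path, False)),
    )


def _pvg_from_dict(d: Mapping, path: _Path) -> PermissibleValueGroup:
    values = tuple(PermissibleValue(code=str(_get(v, "code", path / i)),
                                    display=str(_get(v, "display", path / i, "")))
                   for i, v in enumerate(_get(d, "values", path, [])))
    return PermissibleValueGroup(code=str(_get(d, "code", path)), values=values)


def definition_from_dict(doc: Mapping) -> RegistryDefinition:
    root = _Path()
    forms = []
    for fi, fd in enumerate(_get(doc, "forms", root, [])):
        fpath = root / "forms" / fi
        sections = tuple(
            SectionDef(code=str(_get(sd, "code", fpath / "sections" / si)),
                       name=str(_get(sd, "name", fpath / "sections" / si, "")),
                       de_codes=tuple(str(c) for c in
                                      _get(sd, "de_codes", fpath / "sections" / si, [])))
            for si, sd in enumerate(_get(fd, "sections", fpath, [])))
        forms.append(FormDef(code=str(_get(fd, "code", fpath)),
                             name=str(_get(fd, "name", fpath, "")),
                             longitudinal=bool(_get(fd, "longitudinal", fpath, True)),
                             sections=sections))
    consent_sections = []
    for ci, cd in enumerate(doc.get("consent_sections", [])):
        cpath = root / "consent_sections" / ci
        questions = tuple(
            ConsentQuestion(code=str(_get(q, "code", cpath / "questions" / qi)),
                            text=str(_get(q, "text", cpath / "questions" / qi, "")),
                            mandatory=bool(_get(q, "mandatory",
                                                cpath / "questions" / qi, False)))
            for qi, q in enumerate(_get(cd, "questions", cpath, [])))
        try:
            applicability = tuple(
                Condition(field=str(_get(c, "field", cpath / "applicability" / ai)),
                          op=str(_get(c, "op", cpath / "applicability" / ai)),
                          value=_get(c, "value", cpath / "applicability" / ai))
                for ai, c in enumerate(cd.get("applicability", [])))
        except Exception as exc:  # bad operator, etc.
            raise RMLSyntaxError(f"{cpath}/applicability: {exc}") from exc
        consent_sections.append(ConsentSectionDef(
            code=str(_get(cd, "code", cpath)),
            name=str(_get(cd, "name", cpath, "")),
            questions=questions,
            applicability=applicability,
            validation_rule=str(_get(cd, "validation_rule", cpath, "ALL"))))
    pm = doc.get("permission_matrix", {})
    matrix = PermissionMatrix(
        form_visibility={k: set(v) for k, v in pm.get("form_visibility", {}).items()},
        de_visibility={k: set(v) for k, v in pm.get("de_visibility", {}).items()},
        report_access={k: set(v) for k, v in pm.get("report_access", {}).items()})
    return RegistryDefinition(
        code=str(_get(doc, "code", root)),
        name=str(_get(doc, "name", root, "")),
        context_label=str(_get(doc, "context_label", root, "")),
        version=str(_get(doc, "version", root, "1")),
        data_elements=[_de_from_dict(d, root / "data_elements" / i)
                       for i, d in enumerate(doc.get("data_elements", []))],
        pv_groups=[_pvg_from_dict(d, root / "pv_groups" / i)
                   for i, d in enumerate(doc.get("pv_groups", []))],
        forms=forms,
        consent_sections=consent_sections,
        permission_matrix=matrix,
        capabilities={str(k): [str(c) for c in v]
                      for k, v in doc.get("capabilities", {}).items()})


# ---------------------------------------------------------------------------
# operations

def _load_document(text: str) -> Any:
    try:
        return json.loads(text)
    except json.JSONDecodeError as json_err:
        try:
            return yaml.safe_load(text)
        except yaml.YAMLError as yaml_err:
            raise RMLSyntaxError(
                f"not valid JSON (line {json_err.lineno}: {json_err.msg}) "
                f"nor YAML ({yaml_err})") from yaml_err


def parse_rml(text: str) -> RegistryDefinition:
    """Parse canonical-JSON (or YAML) definition text.

    Raises :class:`RMLSyntaxError` for ill-formed text and
    :class:`DefinitionError` when the document parses but violates a
    definitional invariant (e.g. a dangling permissible-value-group
    reference).
    """
    doc = _load_document(text)
    if not isinstance(doc, Mapping):
        raise RMLSyntaxError("definition document must be a mapping")
    defn = definition_from_dict(doc)
    issues = check_definition(defn)
    if has_errors(issues):
        raise DefinitionError([i for i in issues if i.severity == ERROR])
    return defn


def serialize_rml(defn: RegistryDefinition) -> str:
    """Canonical byte-deterministic text; refuses invalid definitions."""
    issues = check_definition(defn)
    if has_errors(issues):
        raise DefinitionError([i for i in issues if i.severity == ERROR])
    return canonical_json(definition_to_dict(defn))


def _err(path: str, message: str) -> ValidationIssue:
    return ValidationIssue(ERROR, path, message)


def check_definition(defn: RegistryDefinition) -> list[ValidationIssue]:
    """Check every definitional invariant; empty list iff all hold.

    Sound and complete with respect to the documented invariants: each
    violated invariant yields at least one ``error`` issue whose path
    locates the offending element.
    """
    issues: list[ValidationIssue] = []
    if not defn.code:
        issues.append(_err("code", "registry code must be non-empty"))
    if not defn.context_label:
        issues.append(_err("context_label", "context label must be non-empty"))
    if not defn.forms:
        issues.append(_err("forms", "a registry must define at least one form"))

    def check_unique(codes: Iterable[str], kind: str, path_fn) -> None:
        seen: set[str] = set()
        for code in codes:
            if code in seen:
                issues.append(_err(path_fn(code), f"duplicate {kind} code {code!r}"))
            seen.add(code)

    check_unique((f.code for f in defn.forms), "form", lambda c: f"forms/{c}")
    check_unique((s.code for f in defn.forms for s in f.sections), "section",
                 lambda c: f"sections/{c}")
    check_unique((de.code for de in defn.data_elements), "data element",
                 lambda c: f"data_elements/{c}")
    check_unique((g.code for g in defn.pv_groups), "permissible value group",
                 lambda c: f"pv_groups/{c}")
    check_unique((s.code for s in defn.consent_sections), "consent section",
                 lambda c: f"consent_sections/{c}")

    de_codes = {de.code for de in defn.data_elements}
    pvg_codes = {g.code for g in defn.pv_groups}

    for de in defn.data_elements:
        path = f"data_elements/{de.code}"
        if de.datatype not in DATATYPES:
            issues.append(_err(path, f"unknown datatype {de.datatype!r}"))
        if de.min is not None and de.max is not None and de.min > de.max:
            issues.append(_err(path, f"min {de.min} exceeds max {de.max}"))
        if (de.min is not None or de.max is not None) \
                and de.datatype not in NUMERIC_DATATYPES:
            issues.append(_err(path, "bounds are only valid for numeric datatypes"))
        if de.datatype == "enum" and not de.pv_group:
            issues.append(_err(path, "enum data element requires a pv_group"))
        if de.datatype != "enum" and de.pv_group:
            issues.append(_err(path, "pv_group is only valid for enum datatype"))
        if de.pv_group and de.pv_group not in pvg_codes:
            issues.append(_err(path, f"dangling permissible value group "
                                     f"reference {de.pv_group!r}"))

    for g in defn.pv_groups:
        path = f"pv_groups/{g.code}"
        if not g.values:
            issues.append(_err(path, "permissible value group has no values"))
        check_unique((v.code for v in g.values), "permissible value",
                     lambda c, p=path: f"{p}/values/{c}")

    for f in defn.forms:
        fpath = f"forms/{f.code}"
        if not f.sections:
            issues.append(_err(fpath, "form must contain at least one section"))
        for s in f.sections:
            spath = f"{fpath}/sections/{s.code}"
            if not s.de_codes:
                issues.append(_err(spath, "section must list at least one data element"))
            seen: set[str] = set()
            for code in s.de_codes:
                if code in seen:
                    issues.append(_err(f"{spath}/de_codes/{code}",
                                       f"duplicate data element {code!r} in section"))
                seen.add(code)
                if code not in de_codes:
                    issues.append(_err(f"{spath}/de_codes/{code}",
                                       f"dangling data element reference {code!r}"))

    for cs in defn.consent_sections:
        cpath = f"consent_sections/{cs.code}"
        check_unique((q.code for q in cs.questions), "consent question",
                     lambda c, p=cpath: f"{p}/questions/{c}")
        if cs.validation_rule not in VALIDATION_RULES:
            issues.append(_err(cpath, f"unknown validation rule "
                                      f"{cs.validation_rule!r}"))
        elif cs.validation_rule == "MANDATORY_SET" and not cs.mandatory_codes():
            issues.append(_err(cpath, "MANDATORY_SET rule requires at least one "
                                      "mandatory question"))

    form_codes = {f.code for f in defn.forms}
    m = defn.permission_matrix
    for code in m.form_visibility:
        if code not in form_codes:
            issues.append(_err(f"permission_matrix/form_visibility/{code}",
                               f"unknown form {code!r}"))
    for code in m.de_visibility:
        if code not in de_codes:
            issues.append(_err(f"permission_matrix/de_visibility/{code}",
                               f"unknown data element {code!r}"))

    cs_codes = {s.code for s in defn.consent_sections}
    for cap, mapped in defn.capabilities.items():
        for code in mapped:
            if code not in cs_codes:
                issues.append(_err(f"capabilities/{cap}",
                                   f"unknown consent section {code!r}"))
    return issues


def merge_de_library(target: RegistryDefinition,
                     lib: DELibrary) -> RegistryDefinition:
    """Copy the library's DEs and PV groups into ``target``.

    Sharing is by-copy: a code already present with identical content is a
    no-op; a code present with *different* content is a conflict and nothing
    is merged (no silent overwrite).  Returns a new definition; the input is
    untouched.  Idempotent, and commutative for disjoint libraries.
    """
    conflicts: list[tuple[str, Any, Any]] = []
    de_map = target.de_map()
    new_des: list[DataElementDef] = []
    for de in lib.data_elements:
        existing = de_map.get(de.code)
        if existing is None:
            if de.code not in {d.code for d in new_des}:
                new_des.append(de)
        elif existing != de:
            conflicts.append((de.code, existing, de))
    pvg_map = target.pv_group_map()
    new_pvgs: list[PermissibleValueGroup] = []
    for g in lib.pv_groups:
        existing_g = pvg_map.get(g.code)
        if existing_g is None:
            if g.code not in {x.code for x in new_pvgs}:
                new_pvgs.append(g)
        elif existing_g != g:
            conflicts.append((g.code, existing_g, g))
    if conflicts:
        raise MergeConflictError(conflicts)
    merged = replace(target)
    merged.data_elements = list(target.data_elements) + new_des
    merged.pv_groups = list(target.pv_groups) + new_pvgs
    return merged


def library_to_dict(lib: DELibrary) -> dict:
    return {"data_elements": [_de_to_dict(de) for de in lib.data_elements],
            "pv_groups": [_pvg_to_dict(g) for g in lib.pv_groups]}


def serialize_library(lib: DELibrary) -> str:
    return canonical_json(library_to_dict(lib))


def parse_library(text: str) -> DELibrary:
    doc = _load_document(text)
    if not isinstance(doc, Mapping):
        raise RMLSyntaxError("library document must be a mapping")
    root = _Path()
    return DELibrary(
        data_elements=[_de_from_dict(d, root / "data_elements" / i)
                       for i, d in enumerate(doc.get("data_elements", []))],
        pv_groups=[_pvg_from_dict(d, root / "pv_groups" / i)
                   for i, d in enumerate(doc.get("pv_groups", []))])
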