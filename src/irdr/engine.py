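"""Value validation against the registry definition.

Every clinical value passes through here before it may be persisted:
nothing invalid is ever stored.  Validation is pure — the same inputs
always produce the same result and no store is touched.

Conventions (stated so the behaviour is exact):

* numeric bounds are inclusive on both ends;
* the empty string means "no value" and is never a stored value;
* *entry* mode does not enforce required-ness (incremental capture of an
  assessment is legal and drives the progress figure); *finalisation* mode
  additionally requires every required DE to hold a value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, datetime
from typing import Any, Mapping, Sequence

from .base import ERROR, ValidationIssue
from .rml import (NUMERIC_DATATYPES, DataElementDef, PermissibleValueGroup,
                  RegistryDefinition)

MODE_ENTRY = "entry"
MODE_FINAL = "final"

_INT_RE = re.compile(r"[+-]?\d+\Z")
_DECIMAL_RE = re.compile(r"[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?\Z")
_TRUE = {"true", "yes", "1"}
_FALSE = {"false", "no", "0"}


@dataclass(frozen=True)
class FieldValue:
    """One stored clinical value: the raw entered text, its typed
    coercion, and the field-level entry timestamp (independent of the
    owning context's assessment date)."""

    de_code: str
    raw: str
    typed: Any
    entered_at: datetime


@dataclass(frozen=True)
class ValueResult:
    """Outcome of :func:`validate_value`: either a typed value or a
    non-empty issue list, never both."""

    typed: Any
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not self.issues


def _issue(de: DataElementDef, message: str) -> ValueResult:
    return ValueResult(None, (ValidationIssue(ERROR, f"de/{de.code}", message),))


def _coerce(de: DataElementDef, raw: str,
            pv_groups: Mapping[str, PermissibleValueGroup]) -> ValueResult:
    if de.datatype == "integer":
        if not _INT_RE.match(raw):
            return _issue(de, f"{raw!r} is not an integer")
        return ValueResult(int(raw), ())
    if de.datatype == "decimal":
        if not _DECIMAL_RE.match(raw):
            return _issue(de, f"{raw!r} is not a decimal number")
        return ValueResult(float(raw), ())
    if de.datatype == "date":
        try:
            return ValueResult(date.fromisoformat(raw), ())
        except ValueError:
            return _issue(de, f"{raw!r} is not an ISO date (YYYY-MM-DD)")
    if de.datatype == "boolean":
        low = raw.strip().lower()
        if low in _TRUE:
            return ValueResult(True, ())
        if low in _FALSE:
            return ValueResult(False, ())
        return _issue(de, f"{raw!r} is not a boolean")
    if de.datatype == "enum":
        group = pv_groups.get(de.pv_group or "")
        if group is None:
            return _issue(de, f"permissible value group {de.pv_group!r} not found")
        if raw not in {v.code for v in group.values}:
            return _issue(de, f"{raw!r} is not a permissible value of {group.code}")
        return ValueResult(raw, ())
    return ValueResult(raw, ())  # string


def validate_value(de: DataElementDef, raw: Any,
                   pv_groups: Sequence[PermissibleValueGroup] | Mapping[str, PermissibleValueGroup]) -> ValueResult:
    """Coerce ``raw`` to the DE's datatype and check its constraints.

    Returns the typed value when datatype, bounds and permissible values
    all pass, otherwise the issues.  Bounds are inclusive: for a numeric DE
    exactly the values in ``[min, max]`` are accepted.
    """
    if not isinstance(pv_groups, Mapping):
        pv_groups = {g.code: g for g in pv_groups}
    raw = raw if isinstance(raw, str) else str(raw)
    if raw == "":
        return _issue(de, "empty string is not a value")
    result = _coerce(de, raw, pv_groups)
    if not result.ok:
        return result
    if de.datatype in NUMERIC_DATATYPES:
        v = result.typed
        if de.min is not None and v < de.min:
            return _issue(de, f"{v} is below the minimum {de.min}")
        if de.max is not None and v > de.max:
            return _issue(de, f"{v} is above the maximum {de.max}")
    return result


def validate_context_data(defn: RegistryDefinition,
                          records: Mapping[str, Mapping[str, Mapping[str, Any]]],
                          mode: str = MODE_ENTRY) -> list[ValidationIssue]:
    """Validate a whole assessment's worth of raw values.

    ``records`` maps form code → section code → DE code → raw value.  The
    result concatenates structural issues (unknown or non-longitudinal
    form, unknown section/DE addresses) with per-value issues; in
    finalisation mode, missing required DEs are issues too.  Empty list iff
    everything is valid.
    """
    issues: list[ValidationIssue] = []
    de_map = defn.de_map()
    pvg_map = defn.pv_group_map()
    form_map = {f.code: f for f in defn.forms}

    for form_code, by_section in records.items():
        form = form_map.get(form_code)
        if form is None:
            issues.append(ValidationIssue(ERROR, f"forms/{form_code}",
                                          f"unknown form {form_code!r}"))
            continue
        if not form.longitudinal:
            issues.append(ValidationIssue(
                ERROR, f"forms/{form_code}",
                f"form {form_code!r} is not longitudinal; it cannot hold "
                f"per-assessment values"))
            continue
        section_map = {s.code: s for s in form.sections}
        for section_code, by_de in by_section.items():
            section = section_map.get(section_code)
            spath = f"forms/{form_code}/sections/{section_code}"
            if section is None:
                issues.append(ValidationIssue(ERROR, spath,
                                              f"unknown section {section_code!r}"))
                continue
            for de_code, raw in by_de.items():
                if de_code not in section.de_codes or de_code not in de_map:
                    issues.append(ValidationIssue(
                        ERROR, f"{spath}/{de_code}",
                        f"unknown data element {de_code!r} at this address"))
                    continue
                result = validate_value(de_map[de_code], raw, pvg_map)
                issues.extend(result.issues)

    if mode == MODE_FINAL:
        for form in defn.longitudinal_forms():
            for section in form.sections:
                for de_code in section.de_codes:
                    de = de_map.get(de_code)
                    if de is None or not de.required:
                        continue
                    raw = (records.get(form.code, {})
                           .get(section.code, {}).get(de_code, ""))
                    if raw in ("", None):
                        issues.append(ValidationIssue(
                            ERROR,
                            f"forms/{form.code}/sections/{section.code}/{de_code}",
                            f"required data element {de_code!r} has no value"))
    return issues
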