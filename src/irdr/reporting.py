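"""Report templates and access-scoped report execution.

A report template is a saved *query*, not saved results: a check-box
selection of DEs plus demographic columns, a mode, and optional
demographic filters.  Execution always reads the live stores, so a report
built after a data edit reflects the edit.

Two modes:

* ``current`` — one row per included patient, clinical cells taken from
  the patient's latest assessment context (blank when the patient has no
  context yet, so curators still see the whole cohort);
* ``longitudinal`` — one row per (patient, context) pair, sorted by
  patient then (assessment date, creation order).

Inclusion composes every access layer: the acting user's working groups
scope the patient set, the permission matrix scopes the visible DE
columns, and patients failing the consent gate for the
``include_in_report`` capability (when the registry declares it) are
dropped.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Any, Sequence

from .access import (AccessDeniedError, PermissionMatrix, User,
                     accessible_patients, authorize_report, visible_des,
                     visible_forms)
from .base import IrdrError, UnknownCodeError, canonical_json, format_timestamp
from .cohort import ClinicalStore, DemographicStore
from .consent import Condition, evaluate_condition, gate
from .rml import RegistryDefinition

MODE_CURRENT = "current"
MODE_LONGITUDINAL = "longitudinal"

INCLUDE_IN_REPORT = "include_in_report"


@dataclass
class ReportTemplate:
    name: str
    registry: str
    selected_des: list[str]
    demographic_columns: list[str] = field(default_factory=list)
    mode: str = MODE_CURRENT
    filters: list[Condition] = field(default_factory=list)
    access_groups: set[str] = field(default_factory=set)


@dataclass
class ReportTable:
    header: list[str]
    rows: list[list[Any]]
    generated_at: datetime | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=self.header)


class TemplateStore:
    """Named, reusable report templates; saving registers the template's
    user-group access in the permission matrix (deny-by-default)."""

    def __init__(self) -> None:
        self.templates: dict[str, ReportTemplate] = {}

    def store_template(self, tpl: ReportTemplate, matrix: PermissionMatrix,
                       defn: RegistryDefinition, overwrite: bool = False) -> str:
        if tpl.mode not in (MODE_CURRENT, MODE_LONGITUDINAL):
            raise IrdrError(f"unknown report mode {tpl.mode!r}")
        known = {de.code for de in defn.data_elements}
        unknown = [c for c in tpl.selected_des if c not in known]
        if unknown:
            raise UnknownCodeError(
                f"template selects unknown data element(s): {', '.join(unknown)}")
        if tpl.name in self.templates and not overwrite:
            raise IrdrError(f"template {tpl.name!r} already exists "
                            f"(pass overwrite to replace it)")
        self.templates[tpl.name] = tpl
        matrix.report_access[tpl.name] = set(tpl.access_groups)
        return tpl.name

    def get(self, name: str) -> ReportTemplate:
        if name not in self.templates:
            raise UnknownCodeError(f"unknown report template {name!r}")
        return self.templates[name]


def _cell(value: Any) -> Any:
    return "" if value is None else value


def build_report(tpl: ReportTemplate, defn: RegistryDefinition,
                 demographic_store: DemographicStore,
                 clinical_store: ClinicalStore, user: User,
                 now: datetime | None = None,
                 as_of: date | None = None) -> ReportTable:
    """Execute a template for a user against the live stores.

    Raises :class:`AccessDeniedError` when the user is not authorized for
    the template.  ``as_of`` anchors age-derived consent/filter conditions.
    """
    matrix = defn.permission_matrix
    if not authorize_report(user, tpl.name, matrix):
        raise AccessDeniedError(
            f"user {user.username!r} is not authorized for report {tpl.name!r}")

    patients = demographic_store.patients_in_registry(tpl.registry)
    patients = accessible_patients(user, patients)
    patients = [p for p in patients
                if all(evaluate_condition(c, p, as_of) for c in tpl.filters)]
    if INCLUDE_IN_REPORT in defn.capabilities:
        patients = [p for p in patients
                    if gate(defn, p, demographic_store.consent_states,
                            INCLUDE_IN_REPORT, as_of)]

    # DE columns the acting user may see, in template order.
    visible: set[str] = set()
    for form in visible_forms(user, defn):
        visible.update(visible_des(user, form, matrix))
    de_columns = [c for c in tpl.selected_des if c in visible]

    header = list(tpl.demographic_columns) + ["assessment_date"] + de_columns
    rows: list[list[Any]] = []
    for patient in patients:
        demo_cells = [_cell(patient.demographics.get(c))
                      for c in tpl.demographic_columns]
        if tpl.mode == MODE_CURRENT:
            ctx = clinical_store.current_context(patient.key, tpl.registry)
            contexts = [ctx] if ctx is not None else [None]
            include_empty = True
        else:
            contexts = clinical_store.list_contexts(patient.key, tpl.registry)
            include_empty = False
            if not contexts:
                continue
        for ctx in contexts:
            if ctx is None:
                rows.append(demo_cells + [""] + ["" for _ in de_columns])
                continue
            cells: list[Any] = [ctx.assessment_date]
            for de_code in de_columns:
                fv = ctx.current_value(de_code)
                cells.append(_cell(fv.typed if fv is not None else None))
            rows.append(demo_cells + cells)
    return ReportTable(header=header, rows=rows,
                       generated_at=now or datetime.now())


def _stringify(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, date) and not isinstance(value, datetime):
        return value.isoformat()
    if isinstance(value, datetime):
        return format_timestamp(value)
    return str(value)


def export_table(tbl: ReportTable, format: str = "csv") -> bytes:
    """Lossless machine-readable export.

    ``csv`` follows RFC 4180 (CRLF line endings, quoting where needed),
    UTF-8 encoded; ``json`` is the canonical dialect with sorted keys.
    Export is deterministic: the same table always yields the same bytes.
    """
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\r\n", quoting=csv.QUOTE_MINIMAL)
        writer.writerow(tbl.header)
        for row in tbl.rows:
            writer.writerow([_stringify(v) for v in row])
        return buf.getvalue().encode("utf-8")
    if format in ("json", "canonical-json"):
        doc = {"header": tbl.header,
               "rows": [[_stringify(v) for v in row] for row in tbl.rows],
               "generated_at": format_timestamp(tbl.generated_at)
               if tbl.generated_at else None}
        return canonical_json(doc).encode("utf-8")
    raise IrdrError(f"unknown export format {format!r}")


def parse_csv_table(data: bytes) -> ReportTable:
    """Inverse of the CSV export (all cells come back as strings)."""
    rows = list(csv.reader(io.StringIO(data.decode("utf-8"))))
    if not rows:
        return ReportTable(header=[], rows=[])
    return ReportTable(header=rows[0], rows=[list(r) for r in rows[1:]])
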