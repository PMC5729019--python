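"""A deployed site: registries, the two stores, users and templates.

``Site`` is the facade the CLI (and most library users) talk to.  It wires
the registry definitions to the demographic and clinical stores, the
consent ledger, the user roster and the saved report templates, threading
the injected clock and random stream through every operation so a whole
session is reproducible.

Persistence keeps the demographic store and the clinical store in two
separate canonical-JSON files — never one — so the identifying and the
clinical halves of the data can live under different custody.
"""

from __future__ import annotations

import random
from datetime import date, datetime
from pathlib import Path
from typing import Any, Iterable, Mapping

from . import consent as consent_mod
from .access import User, make_user
from .base import (Clock, IrdrError, StepClock, UnknownCodeError,
                   canonical_json, parse_date, system_clock)
from .cohort import (ClinicalStore, Context, DemographicStore, Patient,
                     PatientKey, compute_progress)
from .consent import ConsentState, consent_status_table
from .reporting import (ReportTable, ReportTemplate, TemplateStore,
                        build_report)
from .rml import RegistryDefinition, definition_from_dict, definition_to_dict
import json


class Site:
    def __init__(self, clock: Clock | None = None,
                 rng: random.Random | None = None,
                 as_of: date | None = None):
        self.clock: Clock = clock or system_clock
        self.rng = rng or random.Random()
        #: reference date for age-derived consent/filter conditions
        self.as_of = as_of
        self.definitions: dict[str, RegistryDefinition] = {}
        self.demographic_store = DemographicStore()
        self.clinical_store = ClinicalStore()
        self.template_store = TemplateStore()
        self.users: dict[str, User] = {}

    # -- configuration --------------------------------------------------
    def add_registry(self, defn: RegistryDefinition) -> None:
        self.definitions[defn.code] = defn

    def definition(self, registry: str) -> RegistryDefinition:
        if registry not in self.definitions:
            raise UnknownCodeError(f"unknown registry {registry!r}")
        return self.definitions[registry]

    def add_user(self, username: str, user_groups: Iterable[str],
                 working_groups: Iterable[str] = ()) -> User:
        user = make_user(username, user_groups, working_groups)
        self.users[username] = user
        return user

    def user(self, username: str) -> User:
        if username not in self.users:
            raise UnknownCodeError(f"unknown user {username!r}")
        return self.users[username]

    # -- cohort ---------------------------------------------------------
    def create_patient(self, demographics: Mapping[str, Any],
                       registries: Iterable[str],
                       working_groups: Iterable[str] = ()) -> PatientKey:
        patient = self.demographic_store.create_patient(
            demographics, registries, working_groups, self.clock, self.rng,
            self.definitions)
        return patient.key

    def patient(self, key: PatientKey) -> Patient:
        if key not in self.demographic_store.patients:
            raise UnknownCodeError(f"unknown patient {key!r}")
        return self.demographic_store.patients[key]

    def add_context(self, key: PatientKey, registry: str,
                    assessment_date: date | str) -> Context:
        return self.clinical_store.add_context(
            self.definition(registry), self.patient(key), assessment_date,
            self.clock)

    def enter_value(self, context: Context, form: str, section: str,
                    de: str, raw: Any):
        return self.clinical_store.enter_value(
            self.definition(context.registry), context, form, section, de,
            raw, self.clock)

    def list_contexts(self, key: PatientKey, registry: str) -> list[Context]:
        self.patient(key)
        self.definition(registry)
        return self.clinical_store.list_contexts(key, registry)

    def current_context(self, key: PatientKey, registry: str) -> Context | None:
        self.patient(key)
        self.definition(registry)
        return self.clinical_store.current_context(key, registry)

    def progress(self, context: Context) -> float:
        return compute_progress(self.definition(context.registry), context)

    # -- consent --------------------------------------------------------
    def record_consent(self, key: PatientKey, registry: str,
                       section_code: str, answers: Mapping[str, bool]) -> ConsentState:
        defn = self.definition(registry)
        sec = next((s for s in defn.consent_sections if s.code == section_code),
                   None)
        if sec is None:
            raise UnknownCodeError(f"unknown consent section {section_code!r}")
        self.patient(key)
        return consent_mod.record_consent(
            self.demographic_store.consent_states, key, sec, answers,
            self.clock())

    def consent_status(self, registry: str):
        defn = self.definition(registry)
        patients = self.demographic_store.patients_in_registry(registry)
        return consent_status_table(defn, patients,
                                    self.demographic_store.consent_states,
                                    self.as_of)

    def gate(self, key: PatientKey, registry: str, capability: str) -> bool:
        return consent_mod.gate(self.definition(registry), self.patient(key),
                                self.demographic_store.consent_states,
                                capability, self.as_of)

    # -- reporting ------------------------------------------------------
    def save_template(self, tpl: ReportTemplate, overwrite: bool = False) -> str:
        defn = self.definition(tpl.registry)
        return self.template_store.store_template(
            tpl, defn.permission_matrix, defn, overwrite=overwrite)

    def run_report(self, name: str, username: str) -> ReportTable:
        tpl = self.template_store.get(name)
        return build_report(tpl, self.definition(tpl.registry),
                            self.demographic_store, self.clinical_store,
                            self.user(username), now=self.clock(),
                            as_of=self.as_of)

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write the site as canonical-JSON files; the demographic and the
        clinical stores go to two separate files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        regs = {code: definition_to_dict(d) for code, d in self.definitions.items()}
        (directory / "registries.json").write_text(canonical_json(regs))
        (directory / "demographics.json").write_text(
            self.demographic_store.to_canonical_json())
        (directory / "clinical.json").write_text(
            self.clinical_store.to_canonical_json())
        (directory / "users.json").write_text(canonical_json({
            u.username: {"user_groups": sorted(u.user_groups),
                         "working_groups": sorted(u.working_groups)}
            for u in self.users.values()}))
        (directory / "templates.json").write_text(canonical_json({
            t.name: {"registry": t.registry,
                     "selected_des": list(t.selected_des),
                     "demographic_columns": list(t.demographic_columns),
                     "mode": t.mode,
                     "filters": [{"field": c.field, "op": c.op, "value": c.value}
                                 for c in t.filters],
                     "access_groups": sorted(t.access_groups)}
            for t in self.template_store.templates.values()}))
        (directory / "site.json").write_text(canonical_json({
            "as_of": self.as_of.isoformat() if self.as_of else None}))

    @classmethod
    def load(cls, directory: str | Path, clock: Clock | None = None,
             rng: random.Random | None = None) -> "Site":
        directory = Path(directory)
        meta = json.loads((directory / "site.json").read_text()) \
            if (directory / "site.json").exists() else {}
        site = cls(clock=clock, rng=rng,
                   as_of=parse_date(meta["as_of"]) if meta.get("as_of") else None)
        regs = json.loads((directory / "registries.json").read_text())
        for doc in regs.values():
            site.add_registry(definition_from_dict(doc))
        site.demographic_store = DemographicStore.from_dict(
            json.loads((directory / "demographics.json").read_text()))
        site.clinical_store = ClinicalStore.from_dict(
            json.loads((directory / "clinical.json").read_text()),
            site.definitions)
        if (directory / "users.json").exists():
            for name, u in json.loads((directory / "users.json").read_text()).items():
                site.add_user(name, u["user_groups"], u["working_groups"])
        if (directory / "templates.json").exists():
            tdocs = json.loads((directory / "templates.json").read_text())
            for name, t in tdocs.items():
                tpl = ReportTemplate(
                    name=name, registry=t["registry"],
                    selected_des=list(t["selected_des"]),
                    demographic_columns=list(t["demographic_columns"]),
                    mode=t["mode"],
                    filters=[consent_mod.Condition(c["field"], c["op"], c["value"])
                             for c in t.get("filters", [])],
                    access_groups=set(t.get("access_groups", [])))
                site.save_template(tpl, overwrite=True)
        return site
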