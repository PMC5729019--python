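# irdr — an independent rare-disease registry engine

Rare-disease registries for post-market drug surveillance need to be
*independent* of any single drug company, yet cheap to stand up and to
change: the case-report forms, the consent wording and the access rules
all evolve after deployment.  `irdr` is an embeddable Python engine for
such registries, modelled on the data-management core of disease-centric
registry platforms (the worked fixture is a Gaucher-disease registry, a
condition with several competing enzyme-replacement therapies).

The engine provides:

* **A declarative registry definition language.**  A single canonical-JSON
  (or YAML) document defines a complete registry: reusable *data elements*
  (DEs — code, datatype, bounds, units, required flag), *permissible value
  groups* (controlled vocabularies), *sections* and *forms*, consent
  sections, the permission matrix and capability map.  Serialization is
  byte-deterministic, so definitions can be versioned and diffed; DE
  libraries merge by copy with conflict detection, never silent overwrite.
* **Validation as a gate.**  Every value is coerced to its DE's datatype
  and checked against bounds (inclusive) and permissible values before it
  may be stored; nothing invalid is ever persisted, and a rejected write
  leaves the store byte-identical.
* **A longitudinal "context" model.**  Data are captured per *assessment
  context* — one assessment date owning a full set of longitudinal form
  records — with field-level entry timestamps kept independently, so a
  value entered in 2018 can document a 2016 assessment.  Demographics and
  consent are fixed patient-level modules.  Per-assessment progress is the
  fraction of required DEs holding a valid value.
* **Strict store separation.**  Identifying demographics (and the consent
  ledger) live in a demographic store; clinical data live in a clinical
  store keyed only by an opaque random patient key.  The clinical store's
  serialization contains no demographic field name or value.
* **Dynamic consent.**  Consent sections carry applicability conditions
  (e.g. adults only) and a validation rule — `ALL` questions agreed, or
  only the `MANDATORY_SET` — with an append-only timestamped answer
  history.  Registry capabilities (such as inclusion in reports) are gated
  on current consent validity; revocation takes effect immediately.
* **Multi-level access.**  Working groups (clinic/state/country) scope
  which patients a user can reach — with no admin bypass — while user
  groups (clinical, genetic, curator, admin, patient) scope which forms,
  fields and report templates they may see, deny-by-default.
* **A reporting engine.**  Saved, reusable templates select DEs by code
  and run in `current` (one row per patient, latest context) or
  `longitudinal` (one row per patient-context) mode, always against the
  live stores, exporting RFC 4180 CSV or canonical JSON.

## Worked example

Everything below is generated from a seed — no external data needed.

```python
from irdr import (CohortParams, demo_report_templates, export_table,
                  generate_cohort, generate_registry_definition)

defn = generate_registry_definition(n_forms=6, n_sections_per_form=2,
                                    n_des_per_section=4, seed=1)
site = generate_cohort(defn, CohortParams(n_patients=50, seed=1))
for tpl in demo_report_templates(defn):
    site.save_template(tpl)
site.add_user("root", ["admin"], ["WG01", "WG02", "WG03", "WG04"])

status = site.consent_status("GR")
invalid = status.filter_status("invalid")
print(f"patients: {len(status.rows)}, lacking valid consent: {len(invalid.rows)}")

current = site.run_report("current_overview", "root")
longitudinal = site.run_report("longitudinal_overview", "root")
print(f"current report: {len(current.rows)} rows, "
      f"longitudinal report: {len(longitudinal.rows)} rows")
print(export_table(current, "csv").decode()[:199])
```

prints

```
patients: 50, lacking valid consent: 6
current report: 44 rows, longitudinal report: 122 rows
family_name,given_name,sex,assessment_date,F1_HAEMATOL_S1_DE1,F1_HAEMATOL_S1_DE2,F1_HAEMATOL_S1_DE3,F1_HAEMATOL_S1_DE4,F1_HAEMATOL_S2_DE1,F1_HAEMATOL_S2_DE2
Rossi,Ada,male,2017-06-30,TALIGLUCERASE,2
```

Fifty synthetic patients enrol in the Gaucher-like registry `GR` (6
longitudinal forms, 48 DEs); 6 of them lack valid consent on some section,
and the `include_in_report` capability gate excludes those from reports —
hence 44 current rows (one per consented patient) while the longitudinal
report has one row per assessment context of the same patients.  The CSV
header shows the template's demographic columns, the assessment date, and
the selected DE codes; the first data cell of the clinical block is the
enum DE for the enzyme-replacement product.

The same workflow is available from the shell:

```sh
irdr fixtures make-registry -o gr.json --seed 1
irdr rml check gr.json
irdr fixtures make-cohort gr.json -o site/ --patients 50 --seed 1
irdr consent status --site site/ --registry GR --missing-only
irdr report run --site site/ current_overview --as curator03 -o report.csv
```

Site state persists as canonical-JSON files, with the demographic and the
clinical store always in two separate files.

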