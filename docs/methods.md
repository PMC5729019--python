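# Methods

This note documents the data model, the conventions the engine commits
to where a registry platform could reasonably choose otherwise, the
synthetic-data generator, and known limitations.

## The registry model

A registry is described entirely by one declarative document.  Its
entities form a small hierarchy:

* **Data element (DE)** — an atomic clinical variable: code, display
  name, datatype (one of `integer`, `decimal`, `string`, `date`,
  `boolean`, `enum`), optional numeric bounds with units, an optional
  permissible-value-group reference (required exactly for `enum`), and a
  `required` flag.  DEs are standalone and reusable: a section references
  them by code, and the same DE may appear in several sections or be
  copied between registries.
* **Permissible value group** — a named controlled vocabulary of
  (code, display) pairs.
* **Section / form** — ordered groupings; a form is `longitudinal`
  (captured per assessment) or fixed (patient-level, Demographics/Consent
  style).  Demographics themselves are site configuration, not part of
  the definition; the minimal required set is family name, given name,
  date of birth and sex.
* **Consent section, permission matrix, capability map** — described
  below.

The six datatypes are a deliberate minimum: they cover counts, measures,
free text, calendar dates, checkboxes and coded choices, which is what a
clinical case-report screen needs; derived/calculated DEs are out of
scope.

### Concrete syntax and canonicalisation

The canonical form is UTF-8 JSON with lexicographically sorted object
keys, two-space indent, definition-ordered arrays and a trailing newline.
YAML input is accepted and always re-emitted as canonical JSON.  This
buys three properties the tests rely on: serialization is
byte-deterministic; `parse ∘ serialize` is identity on valid definitions
and `serialize ∘ parse` is byte-identity on canonical text; and version
control diffs are meaningful, which is the whole of the engine's
"versioning" story (a free-text version tag plus diffable canonical
text — no built-in diff engine).

Dates are ISO 8601 `YYYY-MM-DD`, timestamps ISO 8601 UTC with `Z`.
Nothing else is accepted: ambiguous date formats are a classic registry
data-quality failure.

### DE sharing

`merge_de_library` copies DEs and PV groups from a library into a
definition.  Sharing is by copy, not by live reference, so each registry
document stays self-contained and versionable.  A code collision with
identical content is a no-op (merging is idempotent and, for disjoint
libraries, commutative); a collision with different content aborts the
whole merge listing both versions — silent overwrite of a clinical
variable definition is never acceptable.

## Validation

`check_definition` enforces every structural invariant (unique codes,
resolvable references, `min ≤ max`, bounds only on numerics, enum iff PV
group, non-empty forms/sections, consent-rule consistency, permission
matrix referencing real codes) and returns issues with paths; an
error-free result is a precondition for serialization and parsing alike,
so an invalid definition can never circulate.

Value validation is pure and total: it returns either a typed value or a
non-empty issue list, never both.  Conventions chosen and frozen:

* numeric bounds are **inclusive** on both ends (least surprise; the
  property tests scan `[min−2, max+2]` and demand acceptance exactly on
  `[min, max]`);
* the empty string is "no value", never a stored value — this keeps
  progress counting unambiguous;
* whole-context validation has two modes: *entry* (required-ness not
  enforced, since assessments are filled incrementally and partial data
  is legal) and *finalisation* (every required DE must hold a value).

## Cohorts, contexts and time

A patient is created once, with demographics, registry enrolments and
working-group assignments, and receives an opaque 64-bit random hex key.
That key is the only identifier the clinical store ever contains: the
demographic store (plus the consent ledger, which also identifies a
person's choices) and the clinical store are two logically distinct
collections, persisted to two separate files.  The suite asserts, over
generated cohorts, that the clinical store's canonical serialization
contains zero occurrences of any demographic field name or quoted value.

Time is stamped twice, independently: each *context* (assessment event)
carries an assessment date, and each stored value carries its own entry
timestamp from an injected clock.  Contexts are ordered by
`(assessment_date, created_seq)`; the creation counter breaks ties
deterministically, and "current" means maximal under that order.  All
clocks are injectable; the deterministic `StepClock` drives tests and
fixtures.

**Progress** of an assessment is the fraction of the registry's distinct
required longitudinal DEs holding a valid value (a DE reused in two
sections counts once); a definition with no required DEs reads 1.0.  The
metric is simple, monotone under additional valid entries, and computed
identically at per-form granularity (`form_progress`), with the
per-assessment figure treated as canonical.

Field histories are append-only: an overwrite appends, and the history
length equals the number of successful writes.  A rejected write is
atomic — the store is byte-identical before and after.

## Consent

Consent is configuration, not code.  A section has ordered questions
(each optionally `mandatory`), an applicability predicate, and one of two
validation rules: `ALL` (every question must be agreed; mandatory flags
ignored) or `MANDATORY_SET` (exactly the mandatory questions must be
agreed, of which there must be at least one).

Choices made where the behaviour was genuinely open:

* **Unanswered = false.**  Opt-in semantics: a question never answered,
  or a patient with no recorded state, is treated as not consented.
* **Full history.**  Modifying consent appends a timestamped snapshot;
  nothing is overwritten, and replaying the history reproduces the
  current answers.
* **Applicability grammar** is a conjunction of `field op literal`
  clauses over demographics (`==, !=, <, <=, >, >=, in`), plus two
  conveniences: `age_years` is derived from the date of birth at an
  injectable reference date when not stored directly, and the special
  field `registry` tests enrolment membership (ordering operators are
  rejected for it).  Disjunction and negation are deliberately absent —
  unspecified requirements are not guessed at.
* **Capability gating**: a capability (e.g. `include_in_report`) maps to
  consent sections; it is granted iff every mapped section is either
  inapplicable to the patient (a rule that cannot apply cannot block) or
  currently valid.  Gating is memoryless, so revocation is immediate.

The validity evaluator is verified against a brute-force oracle
enumerating all `{true, false, unanswered}` assignments for sections of
up to four questions under both rules.

## Access control

Patient reach and data visibility are orthogonal:

* `accessible_patients` intersects working groups — **no admin bypass**,
  because jurisdictional patient scoping is stated as an unconditional
  privacy rule, not a convenience;
* `visible_forms` / `visible_des` / `authorize_report` intersect user
  groups with the permission matrix, deny-by-default for anything absent
  from the matrix, with the `admin` role bypassing form/field/report
  restrictions only.  DE-level entries override; other DEs inherit their
  form's visibility, preserving order.

All four operations are property-tested against brute-force enumeration
on seeded cohorts (50 patients, 10 users, 4 working groups) and are
monotone under group enlargement.  Authentication itself (passwords,
sessions, transport security) is out of scope: the engine trusts an
injected authenticated user.

## Reporting

A template stores the query (DE selection, demographic columns, mode,
optional demographic filters, access groups), never results, so every
run reflects the live stores.  Column order is demographic columns, then
the assessment date, then the selected DEs restricted to the acting
user's visible set.  `current` yields one row per included patient from
the latest context — patients with no context appear with blank clinical
cells, because curator workflows need full-cohort visibility;
`longitudinal` yields one row per (patient, context), sorted by patient
then context order.  Row-count identities (current rows = included
patients; longitudinal rows = Σ contexts over included patients) are
property-tested over seeded cohorts.  Demographic filtering uses the same
condition grammar as consent applicability rather than free-form SQL —
safer and portable.  When a DE holds several values across sections, a
report cell shows the latest entry by timestamp.

Exports are RFC 4180 CSV (CRLF, minimal quoting, UTF-8) and canonical
JSON; CSV export–parse–export is byte-identical.

## The synthetic-data generator

`generate_registry_definition` emulates the *shape* of a Gaucher-disease
registry: longitudinal clinical forms labelled haematology, visceral,
skeletal, therapy and so on; an enum DE for the enzyme-replacement
product (imiglucerase / velaglucerase alfa / taliglucerase alfa /
untreated); bounded counts and measures; one `ALL` consent section and
one adults-only `MANDATORY_SET` section; a role-restricted form and one
curator-only DE.  The default demo scale is 6 forms × 2 sections × 4 DEs
(48 DEs), with roughly 70 % of DEs flagged required.

`generate_cohort` distributes `n_patients` (default 50) over 4 working
groups, gives each 0–5 assessments with strictly increasing dates from
2015, fills each DE slot with probability `value_fill_rate` (default
0.7) with an individually valid random value, and makes each patient
fully consent with probability `consent_valid_rate` (default 0.8),
otherwise recording either a refusal or nothing.  The user roster covers
every user group.  Each call uses a single explicit `random.Random`
stream and a deterministic step clock, so equal seeds give byte-equal
canonical stores.

Two value-space conventions keep the store-separation scan meaningful
rather than vacuous: dates of birth fall before 2000 while all clinical
and assessment dates fall after, and demographic sex is spelled out
(`female`/`male`/`unknown`) while clinical enum codes are uppercase
tokens — so any demographic value appearing in the clinical store would
be a genuine leak, not a coincidence.

What the generator does **not** emulate: realistic clinical
distributions, reference ranges, correlated measurements, genotypes,
missing-not-at-random patterns, or entry errors.  Passing tests
therefore demonstrate the engine's structural guarantees (validation,
separation, ordering, counting, access composition) on data of the right
shape — they say nothing about clinical plausibility.

## Problem sizes

The default suite and the acceptance script run at desk scale: 100
generated definitions for round-trip checks, 25–100 seeded cohorts of
15–50 patients for the access and reporting oracles, and one 50-patient
end-to-end demo — a few seconds on one CPU.  All sizes are parameters;
nothing in the engine assumes them.

## Known limitations

* No cross-field validation rules, computed DEs or unit conversion.
* Consent applicability supports conjunction only.
* 'Current' reports use latest-context semantics, not latest-per-field.
* No HTTP transport, record linkage, charting or scheduled delivery;
  the library API and canonical import/export are the interoperability
  surface.
* Operational security (encryption at rest, TLS, CSRF, workstation
  policy) is a deployment concern outside the engine.
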