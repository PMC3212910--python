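# Methods

## The two-level model

`tisskit` keeps information and knowledge apart. The information level is a
fixed reference model (RM): a record is a `COMPOSITION` whose content is a
list of `ENTRY` objects (optionally grouped in `SECTION`s); entries are
clinical (`OBSERVATION`, `EVALUATION`, `INSTRUCTION`, `ACTION`) or
administrative (`ADMIN_ENTRY`); entry data is an item structure
(`ITEM_TREE`, `ITEM_LIST`, `ITEM_TABLE`, `ITEM_SINGLE`) whose leaves are
`ELEMENT`s holding typed data values. The knowledge level is a set of
archetypes — constraint trees over the RM, one per domain concept — and
templates that compose archetypes into concrete forms.

The kernel deliberately covers only what claim and authorization documents
need. Versioning, folders, EVENT/HISTORY structures and contribution/audit
metadata are out of scope; `ITEM_TABLE` is kept for RM completeness even
though no shipped archetype uses it.

Demographic references use `PARTY_IDENTIFIED` wherever an entity must be
resolvable in a *different* system: it carries external identifiers such as
the national provider registry number, the health-plan number, or the
patient's number in the plan. The `subject`, `provider` and
`other_participations` attributes of `ENTRY` carry the patient, the acting
professional, and everyone else in the billing process (the payer, the
billing manager, hospital staff).

Associations that cross the entry hierarchy — a performed service relating
to two diagnoses, a response relating to its request — are `LINK` objects
(meaning, type, target path), never duplicated content.

## The extended reference model

The administrative branch of the RM is a single generic class, so a claim's
fixed attributes (submission id and date, who submitted to whom, billing
date, status) exist only as archetype-defined elements. The extension gives
billing the same treatment the RM gives clinical care: an abstract
`SUBMISSION` entry with `submission_id`, `submission_date`, `submitter`
(provider), `submittee` (payer) and `original_submission`; `CLAIM`
(adds `billing_date`) specialized into `PROFESSIONAL_CLAIM` (a `performer`)
and `INSTITUTIONAL_CLAIM` (a list of `participants`); `AUTHORIZATION`
(`requester`, and — on responses — `authorization_id` plus a validity
period); and `ANNEX`, a supplement to another submission. The composition
itself gains an `ISM_TRANSITION` attribute carrying the submission status.

Both representations carry the same information, and
`convert_base_to_extended` / `convert_extended_to_base` are exact inverses
on documents conforming to the shipped plain-RM archetypes. The mapping
lifts elements by label (submission ID, original submission, submission
date, billing date, validity, authorization number, status) into RM
attributes and re-materializes them with the archetype's own node ids and
labels on the way down, merging with residual elements in node-id order —
the canonical document order of the shipped archetypes. Two asymmetries are
deliberate:

* The plain-RM professional claim and authorization archetypes carry a
  "validity" element, but in the extended RM only `AUTHORIZATION` has a
  validity attribute; on claims the element stays where it is. Likewise
  "authorization date" stays an element: mapping it onto
  `submission_date` would collide with the "submission date" element and
  break the round-trip identity.
* Status values form an internal code set (`tiss_status`:
  `submitted | pending | denied | returned_for_correction | completed`) —
  the printed TISS forms never show them. A plain `DV_TEXT` status is accepted on
  lifting, but lowering always emits the canonical coded form, so a
  free-text status round-trips only up to that canonicalization. The
  synthetic generator emits the canonical form.

Moving `other_participations` down to `CARE_ENTRY` (so administrative
subtypes would be free to model their parties without the clinical-oriented
attribute) is discussed in the field but not implemented here; the
extended subtypes simply add their own party attributes alongside it.

## The claim lifecycle

The billing cycle is *request → authorization → claim → denied or
completed*, with five statuses and the rule that a refused submission may be
resubmitted and reanalyzed. The transition relation shipped as default is
the minimal one consistent with those constraints:

| from | to |
| --- | --- |
| submitted | pending, denied, returned_for_correction, completed |
| pending | denied, returned_for_correction, completed |
| denied | submitted |
| returned_for_correction | submitted |
| completed | — |

`completed` is the unique terminal state and every state is reachable from
`submitted`. Payers with richer workflows can export the table
(`transitions_to_config`), edit it, and pass their own relation to every
lifecycle function; histories are immutable, append-only and validated
(initial state `submitted`, each step in the relation, timestamps
non-decreasing).

## The ADL dialect

The parser covers exactly the constructs the shipped archetypes use:
complex object constraints with `occurrences matches {I}`, attribute
constraints with `cardinality matches {I; unordered}`, DV leaf constraints
(`DV_TEXT matches {*}` — the ANY pattern is the only value pattern),
`allow_archetype` slots with `|`-separated include lists, and trailing `--`
comments, which carry the node labels (term texts). An optional `archetype`
header and a small `ontology` section support fixture authoring;
descriptions default to the term text when absent. Full ADL 1.4
(specialization, assumed values, bindings sections) is out of scope.
Unstated occurrences default to `{1..1}`, the openEHR convention.

Parsing validates node-id uniqueness and registered RM type names; the
default registry accepts both the plain and the extended RM, so
`INSTITUTIONAL_CLAIM`-rooted definitions parse out of the box (a
core-only registry is available to reject them). Serialization is
canonical: `parse ∘ serialize` is the identity on definitions, and
`serialize ∘ parse` is a fixed point after one canonicalization.

## Fixtures

The three archetype sets and the eleven templates are built from in-memory
tables and emitted as `.adl` / `.tpl.yaml` files plus a manifest, so fixture
files are reproducible byte-for-byte. Choices a fixture reader should know:

* **Value types default to text**, dates included — the claim-header
  definitions type even "submission Date" and "billing date" as `DV_TEXT`,
  and the fixtures reproduce that; `DateValue` exists in the kernel and is
  the preferred type for new archetypes. Only "date of encounter"
  (`DV_DATE_TIME`), the day counts (`DV_COUNT`) and monetary elements
  (`DV_MONEY`) deviate; every deviation is listed in the manifest.
* The institutional claim archetypes (plain and extended) reproduce their
  reference definition sections token for token, including the `{0..*}`
  occurrences on submission ID / original submission, the at-code gaps
  before the slots (`at0015`, `at0010`), the "submission Date"
  capitalization, and the `openEHR-EHR-CLUSTER.costs.v1` include spelling.
  That spelling is treated as an **alias** of
  `openEHR-EHR-CLUSTER.total_costs.v1` in the repository — resolved, not
  silently merged. The extended institutional claim also keeps its `status`
  element as printed, even though the composition's `ISM_TRANSITION`
  carries the status too; the other extended archetypes drop it.
* The obstetrics "number of living births" breakdown is a nested cluster of
  five count elements with items cardinality `{0..5}` (the one bounded
  cardinality in the set, which also gives the mutant generator a
  cardinality-violation site).
* The composition archetype's content slot includes the ENTRY-rooted
  archetypes of its approach; cluster archetypes enter through the
  administrative archetypes' own slots.
* The template-to-archetype assignments reconstruct the eleven forms from
  their names and the form descriptions (a consultation form carries
  diagnosis/accident/encounter-type data; admission forms carry the
  admission cluster; claim forms carry services and cost summaries); they
  are a design choice of this package, documented in
  `fixtures.template_specs()`.

## Validation

Validation is two-level conformance: the archetype constrains, it does not
enumerate, so instance content in unconstrained attributes is always
permitted, while within a constrained attribute every child must match a
constraint by node id (and, at slot positions, by archetype id — aliases
honored, with fillers recursively validated against their own archetypes
from the repository). All problems are findings `(path, rule, detail,
severity)` — validation never throws on bad data, because payer-side
adjudication needs the complete report. Findings are emitted in canonical
path order; two runs are byte-identical. Node-id matching is exact (no
specialization semantics): the fixture set is flat.

The rule set is `RM_TYPE_MISMATCH`, `NODE_ID_UNKNOWN`,
`OCCURRENCES_EXCEEDED`, `OCCURRENCES_UNMET`, `CARDINALITY_VIOLATION`,
`VALUE_TYPE_MISMATCH`, `SLOT_INCLUDE_VIOLATION`, `SLOT_FILLER_INVALID`,
plus `CODE_BINDING_VIOLATION` for template code bindings (a distinct rule
rather than an overload of the value-type rule, so reports separate
structural from terminology problems) and three lifecycle rules for status
histories. RM-subtype substitutability holds throughout: an
`INSTITUTIONAL_CLAIM` instance satisfies an `ADMIN_ENTRY` constraint, and a
`DV_CODED_TEXT` value satisfies a `DV_TEXT` leaf.

Terminology-binding content is out of scope: ICD-10 and procedure codes are
opaque strings, and template bindings accept any terminology identifier.

## Templates and flattening

A template names a root archetype and is keyed restriction: slot fills,
exclusions, occurrence overrides (narrowing only — widening is a load
error) and code bindings, each addressed as
`<host-archetype-id>#<path-within-host>` (host defaults to the root
archetype; the prefix disambiguates equally-named nested slots in sibling
fillers). Loading validates everything and reports *all* offenders at once.

Flattening replaces each filled slot with a deep copy of the filler's
constraint tree, re-rooted at the slot's node id and tagged with the filler
archetype (`archetype_ref`), then applies the restrictions. Exclusion sets
occurrences to `{0..0}` instead of deleting the node, so the provenance map
(flattened path → source archetype and node) stays total. Cyclic fills are
detected and refused. Form schemas are derived from the flattened tree: one
field per visible element, document order, required iff the occurrences
lower bound is ≥ 1.

## Synthetic data

The generator is valid-by-construction: it walks a flattened template and
emits one instance per constraint, so validator tests have a guaranteed
green baseline and the mutant generator can promise exactly one violation.
Parameters that define the emitted population (chosen once, as what a claims
dataset plausibly looks like; they are not statistical models of Brazilian
claim volumes or costs):

* identifiers are opaque with issuer labels (`PAT-…`/health plan,
  `CNES-…`/national registry, `ANS-…`/regulator, `CRM-…`/professional
  council, `SUB-…`, `AUT-…`);
* dates are drawn from a 180-day window in 2026 and kept coherent
  (admission ≤ discharge, requested days ≤ authorized days, validity =
  submission date + 30 days);
* costs are `BRL` amounts in [10, 5000) with two decimals; counts are
  small integers;
* elements that the conversion or adjudication relies on (submission id and
  date, billing date, status, authorization number, validity, encounter
  fields) are always emitted; other optional elements appear with
  probability 0.85, optional clusters 0.9, and "original submission" only
  on request (it marks resubmissions);
* one RNG stream per composition, seeded from `(seed, template, index)`, so
  adding templates never shifts existing outputs; organizations derive from
  the seed alone so a scenario's compositions share one provider/payer
  pair.

Because the generator emulates *form-complete, internally coherent*
documents, passing tests demonstrate the machinery (validation, conversion,
exchange) — they say nothing about real-world TISS data quality, coding
practice, or volume distributions.

`mutate_for_violation` deep-copies the composition and applies the minimal
edit for the requested rule (duplicate a `{0..1}` element, drop a mandated
one, overfill the bounded cluster, swap a timestamp value for a count,
retarget a node id to `at9999`, replace the item tree with a list, swap a
filler's archetype id, blank it, or push a bound code out of its value set),
returning the expected finding; rules with no site on the given composition
raise an explicit `MutationNotApplicable`.

## Exchange

Extracts group compositions by record subject and travel through an
in-process resource store with REST verb semantics
(`/{organization_id}/{resource_id}`; POST creates with a server-assigned
id, PUT upserts idempotently, GET/DELETE answer not-found as data, every
operation is logged). An HTTP binding would be a thin adapter over the same
contract; tests need no network.

Adjudication is policy-driven because the payer's decision logic is not
part of the architecture: a policy maps submission concepts to
approve/deny/return-for-correction/pend, with an optional cost ceiling and
a configurable validity length (default 30 days) for approved
authorizations. Invalid compositions are always returned for correction
with the validation report attached as an `ANNEX`. Responses reference
their request via `original_submission` and a `LINK`, swap
source and target organizations, and are one-to-one with requests.
Lifecycle histories are tracked per submission id and only ever extended by
legal transitions; `run_roundtrip` accepts a list of policies to model the
deny → resubmit → reanalyze cycle. Ids come from per-kind monotone
counters and time from a fixed stepping clock, so whole runs are
byte-reproducible.

## Numerical and encoding choices

* Monetary amounts parse tolerantly ("1,200.00" ≡ "1200.00"), compare
  numerically, and serialize with banker's rounding to two decimals.
* Timestamps and dates are ISO-8601, canonicalized at construction, so
  structural equality is insensitive to formatting variants.
* All files are UTF-8; XML and JSON serializations are bespoke (element
  name = RM attribute, node id in `archetype_node_id`) and documented in
  `docs/formats.md` — they are *not* the official TISS message schemas,
  which are out of scope along with the TISS terminology and security
  standards.

## Problem sizes

The shipped checks run the parser round-trip on 500 random archetypes,
validate 200 generated compositions per template (2 200 total), round-trip
200 extracts through both serializations, exercise every applicable
mutation rule on every template, and run the exchange simulation with six
submissions twice; the whole suite completes in a few seconds on one CPU.

## Known limitations

* The archetypes model the TISS data structures, not the terminologies or
  the official XSDs; codes are opaque.
* Node-id matching has no specialization semantics, and slot include lists
  are exact-id (plus alias) matches, not patterns.
* The exchange is single-threaded and unauthenticated by design; the
  security standard is out of scope.
* The extended-RM representation, being non-standard, trades
  interoperability with existing openEHR tooling for semantic directness;
  the package keeps both representations and a lossless bridge precisely so
  that choice stays reversible.
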