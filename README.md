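# tisskit

An archetype-based (dual-model) data architecture for **TISS** — Brazil's
mandatory standard for exchanging healthcare authorization and claim data
between health plans (payers) and providers.

TISS defines forms and XML messages but no underlying information model, so
every revision of the standard ripples through every system that speaks it.
`tisskit` re-founds the standard on two-level modeling as used in openEHR
and ISO 13606: a small, stable **reference model** (RM) of generic record
structures — `COMPOSITION → SECTION → ENTRY → ITEM_TREE → ELEMENT`, with
entries split into clinical (`CARE_ENTRY`: observation, evaluation,
instruction, action) and administrative (`ADMIN_ENTRY`) branches — plus
**archetypes**: constraint definitions, written in an ADL dialect, that
restrict the RM to one domain concept each (a claim header, an admission
cluster, a cost summary). **Templates** combine archetypes into the eleven
TISS forms, narrowing what each form shows and binding coded fields to local
terminologies. Evolving the standard then means publishing new archetypes,
never touching the model or the systems built on it.

The package implements this architecture three ways, matching three modeling
approaches for the same content:

1. **Plain RM** — ten archetypes rooted in the clinical entry subtypes plus
   generic `ADMIN_ENTRY` claim/authorization headers;
2. **ADMIN_ENTRY + clusters** — the clinical content re-rooted in `CLUSTER`
   archetypes pluggable into the administrative headers' slots;
3. **Extended RM** — new administrative entry subtypes
   (`SUBMISSION` → `CLAIM` → `PROFESSIONAL_CLAIM`/`INSTITUTIONAL_CLAIM`,
   `AUTHORIZATION`, `ANNEX`) that absorb the fixed billing attributes
   (submission id/date, submitter = provider, submittee = payer, billing
   date), plus an `ISM_TRANSITION` status attribute on `COMPOSITION`
   carrying the claim lifecycle: *submitted → pending / denied / returned
   for correction / completed*, with resubmission after a refusal.

Around the models sit: an ADL parser/printer, an archetype validator whose
findings are citable instance paths, a lossless converter between the
plain-RM and extended-RM representations, a seedable synthetic-claim
generator (with a single-violation mutant mode for validator testing), and a
simulated provider↔payer exchange that packages compositions into EXTRACTs,
moves them through REST-style `/{organization}/{resource}` transports, and
adjudicates them under a configurable payer policy.

## Worked example

Generate the archetype fixture set and look at one form's flattened schema:

```sh
tisskit fixtures --approach 1 --outdir archetypes/approach1 --templates
tisskit flatten --template consultation_claim
```

The schema lists one field per element constraint, in document order, e.g.:

```json
{
  "label": "type of encounter",
  "path": "/content[at0001]/data[at0001]/items[at0008]",
  "kind": "DV_TEXT",
  "required": true,
  "allowed_codes": ["first_visit", "follow_up", "prenatal", "emergency"]
}
```

`required: true` because the consultation template narrows this element's
occurrences from the archetype's `{0..1}` to `{1..1}`, and the four codes
are the template's local terminology binding — templates only ever restrict,
never widen, what an archetype allows.

Generate a claim, validate it, then run the seeded exchange simulation:

```sh
tisskit gen --template admission_claim --seed 4 > claim.json
tisskit validate claim.json --template admission_claim   # exit 0, report on stdout
tisskit exchange --seed 1
```

The exchange prints a deterministic JSON-lines log — the provider POSTs the
request extract to the payer's resource space, the payer adjudicates and
POSTs back a response extract (here under the default approve-all policy),
and every submission's lifecycle history is recorded:

```
{"actor": "provider", "extract": "s1-EXT-000001", "op": "submit", "org": "ANS-42002", "resource": "r000001", "round": 0}
{"actor": "payer", "extract": "EXT-000001", "op": "respond", "org": "CNES-005678", "resource": "r000001", "round": 0}
{"history": ["submitted", "completed"], "submission": "SUB-000-898533"}
```

`ANS-42002` is the payer organization's identifier, `CNES-005678` the
provider's; the history line shows the authorization request entering the
state machine as *submitted* and ending in the unique terminal state
*completed*, with an `authorization_id` and a validity period granted in the
response. A deny policy (`tisskit exchange --policy deny.yaml`) ends
histories in *denied* instead, from which only resubmission is legal.

## Layout

| Module | Role |
| --- | --- |
| `tisskit.rm_core` | RM kernel: compositions, entries, item structures, data values, paths, links |
| `tisskit.rm_extension` | SUBMISSION hierarchy, claim lifecycle state machine, plain↔extended conversion |
| `tisskit.adl` | ADL-dialect parser/printer, archetype identifiers |
| `tisskit.validator` | instance-vs-archetype validation with slot resolution |
| `tisskit.templates` | template loading, flattening, form schemas |
| `tisskit.fixtures` | programmatic builder for the three archetype sets and eleven templates |
| `tisskit.synth` | synthetic claim generator, mutants, scenarios |
| `tisskit.exchange`, `tisskit.serialize` | extracts, transports, adjudication; XML/JSON forms |
| `tisskit.cli` | `tisskit` command (fixtures, parse, validate, flatten, gen, exchange, lifecycle) |

Design notes, parameter choices and limitations are in
[`docs/methods.md`](docs/methods.md); the serialization and config formats
are documented in [`docs/formats.md`](docs/formats.md).
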