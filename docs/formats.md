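# File and wire formats

All formats are UTF-8 text. The XML/JSON document forms are bespoke to this
package (deliberately *not* the official TISS message XSDs).

## ADL dialect (`*.adl`)

One archetype per file:

```
archetype (adl_version=1.4)
    openEHR-EHR-ADMIN_ENTRY.institutional_claim.v1

definition
    ADMIN_ENTRY[at0000] matches {    -- claim header
        data matches {
            ITEM_TREE[at0001] matches {    -- components
                items cardinality matches {0..*; unordered} matches {
                    ELEMENT[at0002] occurrences matches {0..*} matches {    -- submission ID
                        value matches {
                            DV_TEXT matches {*}
                        }
                    }
                    allow_archetype CLUSTER[at0015] occurrences matches {0..*} matches {
                        include archetype_id/value matches {
                            openEHR-EHR-CLUSTER.admission.v1 |
                            openEHR-EHR-CLUSTER.costs.v1
                        }
                    }
                }
            }
        }
    }

ontology
    term_definitions
        ["at0002"] = <text = "submission ID"; description = "...">
```

* `archetype` header and `ontology` section are optional; a bare definition
  section parses (`--` comments supply the term texts).
* Grammar: complex objects `RM_TYPE[atNNNN] [occurrences matches {I}]
  matches { attributes… | * }`; attributes `name [cardinality matches
  {I[; ordered|unordered]}] matches { objects… }`; leaf values
  `DV_* matches {*}`; slots `allow_archetype RM_TYPE[atNNNN] occurrences
  matches {I} matches { include archetype_id/value matches { id | id } }`.
* Intervals: `lo..hi` or `lo..*`; unstated occurrences mean `{1..1}`.
* Value types: `DV_TEXT`, `DV_CODED_TEXT`, `DV_DATE_TIME`, `DV_DATE`,
  `DV_COUNT`, `DV_QUANTITY`, `DV_MONEY`, `DV_IDENTIFIER`.

## Template config (`*.tpl.yaml`)

```yaml
name: admission_claim
root_archetype: openEHR-EHR-COMPOSITION.tiss_claim.v1
slot_fills:
  /content[at0001]:                       # path within the root archetype
    - openEHR-EHR-ADMIN_ENTRY.institutional_claim.v1
    - openEHR-EHR-EVALUATION.patient_evaluation.v1
  openEHR-EHR-ADMIN_ENTRY.institutional_claim.v1#/data[at0001]/items[at0015]:
    - openEHR-EHR-CLUSTER.admission.v1    # host-prefixed nested slot
exclusions:
  - openEHR-EHR-EVALUATION.patient_evaluation.v1#/data[at0001]/items[at0010]
occurrence_overrides:
  openEHR-EHR-ADMIN_ENTRY.professional_claim.v1#/data[at0001]/items[at0008]: 1..1
code_bindings:
  openEHR-EHR-ADMIN_ENTRY.professional_claim.v1#/data[at0001]/items[at0008]:
    - tiss_local
    - [first_visit, follow_up, prenatal, emergency]
```

Keys are `<host-archetype-id>#<path>`; without the prefix the path is
relative to the root archetype. Overrides may only narrow; exclusions
require a lower bound of 0 in the source archetype.

## Instance documents

JSON: every node carries `_rm` (RM type name), `name`,
`archetype_node_id`, optional `archetype_id` (archetype roots and slot
fillers) and `links`; children under the RM attribute names (`content`,
`data`, `items`, `rows`, `item`); data values are tagged objects
(`{"_dv": "DV_MONEY", "amount": "123.45", "currency": "BRL"}`); parties are
`{"_party": "PARTY_IDENTIFIED", "name": …, "identifiers": […]}` or
`{"_party": "PARTY_SELF"}`. Extended-RM entries add their attributes
(`submission_id`, `submission_date`, `original_submission`, `submitter`,
`submittee`, `billing_date`, `performer`, `participants`, `requester`,
`authorization_id`, `validity` as `"start/end"`, `is_response`,
`complements`); compositions add `composer`, `context_start_time` and
`ism_transition`.

XML mirrors the same structure: element name = RM attribute
(`<composition>`, `<content>`, `<data>`, `<items>`…), RM type in `rm`,
node id in `archetype_node_id`; scalar extended-RM attributes are XML
attributes, parties and participations are child elements, values are
`<value dv="DV_TEXT">…</value>`. Monetary amounts serialize with banker's
rounding to two decimals in both forms, so XML↔JSON round-trips are
structurally exact.

## Extracts

```json
{"extract_id": "EXT-000001",
 "source_org": {"_party": "PARTY_IDENTIFIED", "...": "..."},
 "target_org": {"_party": "PARTY_IDENTIFIED", "...": "..."},
 "created_at": "2026-01-05T08:00:00",
 "items": [{"subject": {"_party": "..."}, "compositions": ["..."]}]}
```

XML: `<extract extract_id=… created_at=…>` with `<source_org>`,
`<target_org>` and `<item><subject/><composition/>…</item>` children.

## Adjudication policy (YAML)

```yaml
default: approve          # approve | deny | return_for_correction | pend
rules:
  authorization_request: approve
  institutional_claim: pend
validity_days: 30         # validity period granted with approvals
max_total: 10000.0        # optional cost ceiling; above it claims are denied
```

## Lifecycle transition table (YAML)

```yaml
submitted: [completed, denied, pending, returned_for_correction]
pending: [completed, denied, returned_for_correction]
denied: [submitted]
returned_for_correction: [submitted]
completed: []
```

Exported by `tisskit lifecycle`; any edited table can be passed to the
lifecycle functions for payer-specific workflows.

## Validation report (JSON)

```json
{"valid": false,
 "findings": [{"path": "/content[at0001]/data[at0001]/items[at0006]",
               "rule": "VALUE_TYPE_MISMATCH",
               "detail": "expected DV_DATE_TIME, got CountValue",
               "severity": "ERROR"}]}
```

Findings are sorted by (path, rule); the CLI exits 0 iff `valid`.

## Exchange log (JSON lines)

One JSON object per transport event (`round`, `actor`, `op`, `org`,
`resource`, `extract`) followed by one per submission
(`{"submission": …, "history": ["submitted", "completed"]}`).
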