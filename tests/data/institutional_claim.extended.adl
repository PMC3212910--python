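INSTITUTIONAL_CLAIM[at0000] matches { -- claim header
data matches {
ITEM_TREE[at0001] matches { -- components
items cardinality matches {0..*; unordered} matches {
ELEMENT[at0002] occurrences matches {0..1} matches { -- type of encounter
value matches { DV_TEXT matches {*} } }
ELEMENT[at0003] occurrences matches {0..1} matches { -- date of encounter
value matches {DV_DATE_TIME matches {*} } }
ELEMENT[at0004] occurrences matches {0..1} matches { -- type of claim
value matches { DV_TEXT matches {*} } }
ELEMENT[at0005] occurrences matches {0..1} matches { -- status
value matches { DV_TEXT matches {*} } }
ELEMENT[at0006] occurrences matches {0..1} matches { -- discharge reason
value matches { DV_TEXT matches {*} } }
ELEMENT[at0007] occurrences matches {0..1} matches { -- further action
value matches { DV_TEXT matches {*} } }
ELEMENT[at0008] occurrences matches {0..1} matches { -- comments
value matches { DV_TEXT matches {*} } }
allow_archetype CLUSTER[at0010] occurrences matches {0..*} matches {
include archetype_id/value matches {
openEHR-EHR-CLUSTER.admission.v1 |
openEHR-EHR-CLUSTER.costs.v1 } } } } } }
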