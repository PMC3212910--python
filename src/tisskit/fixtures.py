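"""Programmatic builder for the TISS archetype sets and form templates.

Three archetype sets model the same claim/authorization content:

* **approach 1** — rooted in the clinical ENTRY subtypes (EVALUATION, ACTION)
  plus generic ADMIN_ENTRY archetypes for the administrative headers, and a
  COMPOSITION archetype whose content slot accepts them all;
* **approach 2** — the clinical content re-rooted in CLUSTER archetypes, with
  the ADMIN_ENTRY archetypes gaining a slot that accepts them;
* **approach 3** — the administrative archetypes re-rooted in the extended
  reference model (PROFESSIONAL_CLAIM / INSTITUTIONAL_CLAIM / AUTHORIZATION),
  where submission id/date, original submission and billing date live in the
  model itself and disappear from the archetypes.

Eleven templates combine the archetypes into the TISS forms: individual
claim, consultation claim, admission request/authorization/claim, tests and
procedures request/authorization/claim, dental evaluation, dental claim and
other charges.

Everything is emitted from in-memory tables, so the ADL files and template
configs are reproducible byte-for-byte.  Element value types default to text
(dates included — only "date of encounter" is a DV_DATE_TIME); costs and
counts deviate and are listed in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .adl import (
    ArchetypeDefinition,
    AttributeConstraint,
    ComplexObjectConstraint,
    Interval,
    PrimitiveConstraint,
    SlotConstraint,
    parse_archetype_id,
    serialize_archetype,
)
from .rm_core import NodeId
from .validator import ArchetypeRepository

__all__ = [
    "El", "Cl", "Sl", "ArchSpec", "FixtureInventory",
    "build_definition", "build_fixtures", "build_templates",
    "default_repository", "template_specs", "inventory",
    "admin_label_codes", "element_code",
    "APPROACH_SPECS", "TEMPLATE_NAMES", "ALIASES",
]


# ---------------------------------------------------------------------------
# Spec mini-language
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class El:
    label: str
    dv: str = "DV_TEXT"
    occ: tuple[int, Optional[int]] = (0, 1)
    code: Optional[str] = None


@dataclass(frozen=True)
class Cl:
    label: str
    items: tuple
    occ: tuple[int, Optional[int]] = (0, 1)
    card: Optional[tuple[int, Optional[int]]] = None  # None -> {0..*}
    code: Optional[str] = None


@dataclass(frozen=True)
class Sl:
    includes: tuple[str, ...]
    occ: tuple[int, Optional[int]] = (0, None)
    rm: str = "CLUSTER"
    code: Optional[str] = None


@dataclass(frozen=True)
class ArchSpec:
    id: str
    root_label: str
    items: tuple
    kind: str = "entry"  # entry | cluster | composition


# ---------------------------------------------------------------------------
# Archetype ids
# ---------------------------------------------------------------------------

PATIENT_EVALUATION = "openEHR-EHR-EVALUATION.patient_evaluation.v1"
ODONTO_EVALUATION = "openEHR-EHR-EVALUATION.odontologic_evaluation.v1"
CLAIM_SERVICES = "openEHR-EHR-ACTION.claim_services.v1"
ADMISSION = "openEHR-EHR-CLUSTER.admission.v1"
TOTAL_COSTS = "openEHR-EHR-CLUSTER.total_costs.v1"
COSTS_ALIAS = "openEHR-EHR-CLUSTER.costs.v1"  # spelling used in slot includes
PROFESSIONAL_CLAIM = "openEHR-EHR-ADMIN_ENTRY.professional_claim.v1"
INSTITUTIONAL_CLAIM = "openEHR-EHR-ADMIN_ENTRY.institutional_claim.v1"
AUTHORIZATION = "openEHR-EHR-ADMIN_ENTRY.authorization.v1"
AUTHORIZATION_REQUEST = "openEHR-EHR-ADMIN_ENTRY.authorization_request.v1"
TISS_CLAIM = "openEHR-EHR-COMPOSITION.tiss_claim.v1"

C_PATIENT_EVALUATION = "openEHR-EHR-CLUSTER.patient_evaluation.v1"
C_ODONTO_EVALUATION = "openEHR-EHR-CLUSTER.odontologic_evaluation.v1"
C_CLAIM_SERVICES = "openEHR-EHR-CLUSTER.claim_services.v1"

X_PROFESSIONAL_CLAIM = "openEHR-EHR-PROFESSIONAL_CLAIM.professional_claim.v1"
X_INSTITUTIONAL_CLAIM = "openEHR-EHR-INSTITUTIONAL_CLAIM.institutional_claim.v1"
X_AUTHORIZATION = "openEHR-EHR-AUTHORIZATION.authorization.v1"
X_AUTHORIZATION_REQUEST = "openEHR-EHR-AUTHORIZATION.authorization_request.v1"

#: The "costs" spelling in slot includes names the total_costs archetype.
ALIASES = {COSTS_ALIAS: TOTAL_COSTS}


# ---------------------------------------------------------------------------
# Content tables
# ---------------------------------------------------------------------------

_OBSTETRICS = Cl("obstetrics", (
    El("gestation"), El("abortion"), El("pregnancy-related problems"),
    El("puerperium complications"), El("neonatal assistance"),
    El("neonatal complication"), El("low birthweight"),
    El("cesarean section"), El("normal delivery"), El("maternal death"),
    Cl("number of living births", (
        El("living term births", dv="DV_COUNT"),
        El("premature living births", dv="DV_COUNT"),
        El("still births", dv="DV_COUNT"),
        El("early neonatal deaths", dv="DV_COUNT"),
        El("late neonatal deaths", dv="DV_COUNT"),
    ), card=(0, 5)),
))

_PLANNED_SERVICES = Cl("planned services", (
    El("type of procedure"), El("procedure"),
    El("quantity requested", dv="DV_COUNT"),
    El("quantity authorized", dv="DV_COUNT"),
    Cl("orthoses and prostheses", (
        El("vendor"), El("unit cost", dv="DV_MONEY"),
    )),
))

_PATIENT_EVALUATION_ITEMS = (
    El("clinical indication"), El("type of disease"),
    El("duration of disease"), El("accident indication"),
    El("main diagnosis"), El("secondary diagnoses"),
    El("cause of death"), El("death certificate number"),
    _OBSTETRICS, _PLANNED_SERVICES,
)

_ODONTO_ITEMS = (
    El("periodontal disease"), El("alterations in soft tissues"),
    Cl("initial status", (El("tooth"), El("status"))),
)

_CLAIM_SERVICES_ITEMS = (
    El("type of procedure"), El("procedure"),
    El("quantity authorized", dv="DV_COUNT"),
    El("quantity performed", dv="DV_COUNT"),
    El("access"), El("technique"), El("vendor"),
    El("unit cost", dv="DV_MONEY"), El("total cost", dv="DV_MONEY"),
    El("percent of reduction/addition"), El("deduction", dv="DV_MONEY"),
    El("tooth"), El("face"),
)

_ADMISSION_ITEMS = (
    El("type of admission"), El("probable date of admission"),
    El("hospital service"), El("admission regime"),
    El("requested number of days", dv="DV_COUNT"),
    El("authorized number of days", dv="DV_COUNT"),
    El("type of accommodation"), El("date of admission"),
    El("discharge date"),
)

_TOTAL_COSTS_ITEMS = tuple(
    El(label, dv="DV_MONEY") for label in (
        "total costs", "total rent", "total drugs", "total materials",
        "total hospital stay", "total gases", "total other rates",
        "total procedures", "total medicinal gases", "Total deduction",
    ))

_PROFESSIONAL_ITEMS = (
    El("original submission", occ=(0, None)),
    El("submission ID", occ=(0, None)),
    El("submission date"), El("validity"), El("billing date"),
    El("type of claim"), El("type of encounter"),
    El("date of encounter", dv="DV_DATE_TIME"),
    El("discharge reason"), El("further action"),
    El("status"), El("comments"),
    Sl((COSTS_ALIAS,), code="at0015"),
)

# Matches the reference definition section for this concept exactly
# (element order, occurrences, the "submission Date" capitalization, the
# at0015 slot and its "costs" include spelling).
_INSTITUTIONAL_ITEMS = (
    El("submission ID", occ=(0, None), code="at0002"),
    El("original submission", occ=(0, None), code="at0003"),
    El("submission Date", code="at0004"),
    El("type of encounter", code="at0005"),
    El("date of encounter", dv="DV_DATE_TIME", code="at0006"),
    El("type of claim", code="at0007"),
    El("billing date", code="at0008"),
    El("status", code="at0009"),
    El("discharge reason", code="at0010"),
    El("further action", code="at0011"),
    El("comments", code="at0012"),
    Sl((ADMISSION, COSTS_ALIAS), code="at0015"),
)

_AUTHORIZATION_ITEMS = (
    El("original submission", occ=(0, None)),
    El("submission ID", occ=(0, None)),
    El("submission date"), El("validity"),
    El("authorization date"), El("authorization number"),
    El("type of encounter"),
    El("date of encounter", dv="DV_DATE_TIME"),
    El("status"), El("comments"),
    Sl((ADMISSION,), code="at0015"),
)

_AUTH_REQUEST_ITEMS = (
    El("submission ID", occ=(0, None)),
    El("submission date"), El("status"),
    El("type of encounter"),
    El("date of encounter", dv="DV_DATE_TIME"),
    El("comments"),
    Sl((ADMISSION,), code="at0015"),
)

# extended RM: submission id/date, original submission and billing date moved
# into the reference model.
_X_PROFESSIONAL_ITEMS = (
    El("type of encounter", code="at0002"),
    El("date of encounter", dv="DV_DATE_TIME", code="at0003"),
    El("discharge reason", code="at0004"),
    El("further action", code="at0005"),
    El("comments", code="at0006"),
    Sl((COSTS_ALIAS,), code="at0010"),
)

# Matches the reference extended-RM definition section (which keeps a status
# element even though the composition's ISM_TRANSITION also carries it).
_X_INSTITUTIONAL_ITEMS = (
    El("type of encounter", code="at0002"),
    El("date of encounter", dv="DV_DATE_TIME", code="at0003"),
    El("type of claim", code="at0004"),
    El("status", code="at0005"),
    El("discharge reason", code="at0006"),
    El("further action", code="at0007"),
    El("comments", code="at0008"),
    Sl((ADMISSION, COSTS_ALIAS), code="at0010"),
)

_X_AUTHORIZATION_ITEMS = (
    El("type of encounter", code="at0002"),
    El("date of encounter", dv="DV_DATE_TIME", code="at0003"),
    El("comments", code="at0004"),
    Sl((ADMISSION,), code="at0010"),
)

_A1_ENTRY_IDS = (
    PATIENT_EVALUATION, ODONTO_EVALUATION, CLAIM_SERVICES,
    PROFESSIONAL_CLAIM, INSTITUTIONAL_CLAIM, AUTHORIZATION,
    AUTHORIZATION_REQUEST,
)
_A2_CLUSTER_IDS = (
    C_PATIENT_EVALUATION, C_ODONTO_EVALUATION, C_CLAIM_SERVICES,
    ADMISSION, TOTAL_COSTS,
)
_A3_ENTRY_IDS = (
    PATIENT_EVALUATION, ODONTO_EVALUATION, CLAIM_SERVICES,
    X_PROFESSIONAL_CLAIM, X_INSTITUTIONAL_CLAIM, X_AUTHORIZATION,
    X_AUTHORIZATION_REQUEST,
)


def _admin(archetype_id: str, items: tuple, label: str = "claim header") -> ArchSpec:
    return ArchSpec(archetype_id, label, items)


def _with_cluster_slot(items: tuple) -> tuple:
    """Approach-2 variant: widen the trailing slot to all cluster archetypes."""
    slot = items[-1]
    assert isinstance(slot, Sl)
    return items[:-1] + (Sl(_A2_CLUSTER_IDS, code=slot.code),)


APPROACH_SPECS: dict[int, tuple[ArchSpec, ...]] = {
    1: (
        ArchSpec(PATIENT_EVALUATION, "patient evaluation", _PATIENT_EVALUATION_ITEMS),
        ArchSpec(ODONTO_EVALUATION, "odontologic evaluation", _ODONTO_ITEMS),
        ArchSpec(CLAIM_SERVICES, "claim services", _CLAIM_SERVICES_ITEMS),
        ArchSpec(ADMISSION, "admission", _ADMISSION_ITEMS, kind="cluster"),
        ArchSpec(TOTAL_COSTS, "total costs", _TOTAL_COSTS_ITEMS, kind="cluster"),
        _admin(PROFESSIONAL_CLAIM, _PROFESSIONAL_ITEMS),
        _admin(INSTITUTIONAL_CLAIM, _INSTITUTIONAL_ITEMS),
        _admin(AUTHORIZATION, _AUTHORIZATION_ITEMS, "authorization"),
        _admin(AUTHORIZATION_REQUEST, _AUTH_REQUEST_ITEMS, "authorization request"),
        ArchSpec(TISS_CLAIM, "TISS claim", (Sl(_A1_ENTRY_IDS, rm="ENTRY", code="at0001"),),
                 kind="composition"),
    ),
    2: (
        ArchSpec(C_PATIENT_EVALUATION, "patient evaluation",
                 _PATIENT_EVALUATION_ITEMS, kind="cluster"),
        ArchSpec(C_ODONTO_EVALUATION, "odontologic evaluation",
                 _ODONTO_ITEMS, kind="cluster"),
        ArchSpec(C_CLAIM_SERVICES, "claim services",
                 _CLAIM_SERVICES_ITEMS, kind="cluster"),
        ArchSpec(ADMISSION, "admission", _ADMISSION_ITEMS, kind="cluster"),
        ArchSpec(TOTAL_COSTS, "total costs", _TOTAL_COSTS_ITEMS, kind="cluster"),
        _admin(PROFESSIONAL_CLAIM, _with_cluster_slot(_PROFESSIONAL_ITEMS)),
        _admin(INSTITUTIONAL_CLAIM, _with_cluster_slot(_INSTITUTIONAL_ITEMS)),
        _admin(AUTHORIZATION, _with_cluster_slot(_AUTHORIZATION_ITEMS), "authorization"),
        _admin(AUTHORIZATION_REQUEST, _with_cluster_slot(_AUTH_REQUEST_ITEMS),
               "authorization request"),
        ArchSpec(TISS_CLAIM, "TISS claim",
                 (Sl((PROFESSIONAL_CLAIM, INSTITUTIONAL_CLAIM, AUTHORIZATION,
                      AUTHORIZATION_REQUEST), rm="ENTRY", code="at0001"),),
                 kind="composition"),
    ),
    3: (
        ArchSpec(PATIENT_EVALUATION, "patient evaluation", _PATIENT_EVALUATION_ITEMS),
        ArchSpec(ODONTO_EVALUATION, "odontologic evaluation", _ODONTO_ITEMS),
        ArchSpec(CLAIM_SERVICES, "claim services", _CLAIM_SERVICES_ITEMS),
        ArchSpec(ADMISSION, "admission", _ADMISSION_ITEMS, kind="cluster"),
        ArchSpec(TOTAL_COSTS, "total costs", _TOTAL_COSTS_ITEMS, kind="cluster"),
        _admin(X_PROFESSIONAL_CLAIM, _X_PROFESSIONAL_ITEMS),
        _admin(X_INSTITUTIONAL_CLAIM, _X_INSTITUTIONAL_ITEMS),
        _admin(X_AUTHORIZATION, _X_AUTHORIZATION_ITEMS, "authorization"),
        _admin(X_AUTHORIZATION_REQUEST, _X_AUTHORIZATION_ITEMS, "authorization request"),
        ArchSpec(TISS_CLAIM, "TISS claim", (Sl(_A3_ENTRY_IDS, rm="ENTRY", code="at0001"),),
                 kind="composition"),
    ),
}


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

class _Codes:
    def __init__(self, start: int = 2):
        self.next = start

    def take(self, explicit: Optional[str]) -> NodeId:
        if explicit is not None:
            n = int(explicit[2:])
            self.next = max(self.next, n + 1)
            return NodeId(explicit)
        nid = NodeId(f"at{self.next:04d}")
        self.next += 1
        return nid


def _interval(t: tuple[int, Optional[int]], ordered: Optional[bool] = None) -> Interval:
    return Interval(lower=t[0], upper=t[1], ordered=ordered)


def _build_item(item: Union[El, Cl, Sl], codes: _Codes):
    if isinstance(item, El):
        return ComplexObjectConstraint(
            rm_type="ELEMENT", node_id=codes.take(item.code),
            occurrences=_interval(item.occ), label=item.label,
            attributes=[AttributeConstraint(
                name="value",
                children=[PrimitiveConstraint(rm_type=item.dv)])])
    if isinstance(item, Cl):
        nid = codes.take(item.code)
        card = _interval(item.card, ordered=False) if item.card else \
            Interval(0, None, ordered=False)
        node = ComplexObjectConstraint(
            rm_type="CLUSTER", node_id=nid,
            occurrences=_interval(item.occ), label=item.label)
        attr = AttributeConstraint(name="items", cardinality=card)
        for sub in item.items:
            attr.children.append(_build_item(sub, codes))
        node.attributes.append(attr)
        return node
    if isinstance(item, Sl):
        return SlotConstraint(
            rm_type=item.rm, node_id=codes.take(item.code),
            occurrences=_interval(item.occ), includes=list(item.includes))
    raise TypeError(type(item))


def build_definition(spec: ArchSpec) -> ArchetypeDefinition:
    aid = parse_archetype_id(spec.id)
    codes = _Codes()
    if spec.kind == "composition":
        attr = AttributeConstraint(name="content",
                                   cardinality=Interval(0, None, ordered=False))
        for item in spec.items:
            attr.children.append(_build_item(item, codes))
        root = ComplexObjectConstraint(
            rm_type=aid.rm_entity, node_id=NodeId("at0000"),
            label=spec.root_label, attributes=[attr])
    elif spec.kind == "cluster":
        attr = AttributeConstraint(name="items",
                                   cardinality=Interval(0, None, ordered=False))
        for item in spec.items:
            attr.children.append(_build_item(item, codes))
        root = ComplexObjectConstraint(
            rm_type=aid.rm_entity, node_id=NodeId("at0000"),
            label=spec.root_label, attributes=[attr])
    else:  # entry
        items_attr = AttributeConstraint(name="items",
                                         cardinality=Interval(0, None, ordered=False))
        codes.take("at0001")  # reserved for the item tree
        for item in spec.items:
            items_attr.children.append(_build_item(item, codes))
        tree = ComplexObjectConstraint(
            rm_type="ITEM_TREE", node_id=NodeId("at0001"),
            label="components", attributes=[items_attr])
        root = ComplexObjectConstraint(
            rm_type=aid.rm_entity, node_id=NodeId("at0000"),
            label=spec.root_label,
            attributes=[AttributeConstraint(name="data", children=[tree])])
    return ArchetypeDefinition(id=aid, root=root)


def default_repository(approach: int = 1) -> ArchetypeRepository:
    """In-memory repository with every archetype of one approach (+ aliases)."""
    repo = ArchetypeRepository()
    for spec in APPROACH_SPECS[approach]:
        repo.add(build_definition(spec))
    for alias, target in ALIASES.items():
        repo.add_alias(alias, target)
    return repo


def build_fixtures(approach: int, outdir: Union[str, Path]) -> list[Path]:
    """Write one ``.adl`` file per archetype plus a manifest; returns paths."""
    if approach not in APPROACH_SPECS:
        raise ValueError(f"unknown approach {approach!r}; expected 1, 2 or 3")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, dict] = {}
    for spec in APPROACH_SPECS[approach]:
        defn = build_definition(spec)
        aid = parse_archetype_id(spec.id)
        path = outdir / f"{aid.rm_entity}.{aid.concept}.v{aid.version}.adl"
        path.write_text(serialize_archetype(defn), encoding="utf-8")
        written.append(path)
        deviations = {e.label: e.dv for e in _iter_elements(spec.items)
                      if e.dv != "DV_TEXT"}
        manifest[spec.id] = {
            "approach": approach,
            "concept": aid.concept,
            "file": path.name,
            "elements": [e.label for e in _top_elements(spec.items)],
            "value_type_deviations": deviations,
        }
    mpath = outdir / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")
    return written


def _top_elements(items: tuple) -> list[El]:
    return [i for i in items if isinstance(i, El)]


def _iter_elements(items: tuple):
    for i in items:
        if isinstance(i, El):
            yield i
        elif isinstance(i, Cl):
            yield from _iter_elements(i.items)


@dataclass(frozen=True)
class FixtureInventory:
    approach: int
    entries: tuple = ()

    def __getattr__(self, concept: str):
        for e in self.entries:
            if e["concept"] == concept:
                return e
        raise AttributeError(concept)


def inventory(approach: int) -> FixtureInventory:
    """Per-archetype inventory: top-level element labels, cluster labels and
    slot includes."""
    entries = []
    for spec in APPROACH_SPECS[approach]:
        aid = parse_archetype_id(spec.id)
        entries.append({
            "id": str(aid),
            "concept": aid.concept,
            "elements": [i.label for i in spec.items if isinstance(i, El)],
            "clusters": [i.label for i in spec.items if isinstance(i, Cl)],
            "slot_includes": [inc for i in spec.items if isinstance(i, Sl)
                              for inc in i.includes],
        })
    return FixtureInventory(approach=approach, entries=tuple(entries))


def element_code(archetype_id: str, label: str, approach: int = 1) -> str:
    """at-code of a (possibly nested) element or cluster, by label."""
    for spec in APPROACH_SPECS[approach]:
        if spec.id != archetype_id:
            continue
        defn = build_definition(spec)
        want = " ".join(label.lower().split())
        from .adl import iter_objects
        for node in iter_objects(defn.root):
            node_label = getattr(node, "label", None)
            if node_label and " ".join(node_label.lower().split()) == want \
                    and node.node_id is not None:
                return node.node_id.code
        raise KeyError(f"no node labelled {label!r} in {archetype_id}")
    raise KeyError(f"unknown archetype {archetype_id!r} in approach {approach}")


def admin_label_codes(concept: str) -> dict[str, tuple[str, str]]:
    """normalized label -> (at-code, canonical label) for a plain-RM admin
    archetype's top-level elements (used by the RM-extension conversion)."""
    by_concept = {
        "professional_claim": PROFESSIONAL_CLAIM,
        "institutional_claim": INSTITUTIONAL_CLAIM,
        "authorization": AUTHORIZATION,
        "authorization_request": AUTHORIZATION_REQUEST,
    }
    spec = next(s for s in APPROACH_SPECS[1] if s.id == by_concept[concept])
    codes = _Codes()
    out: dict[str, tuple[str, str]] = {}
    codes.take("at0001")
    for item in spec.items:
        if isinstance(item, El):
            nid = codes.take(item.code)
            out[" ".join(item.label.lower().split())] = (nid.code, item.label)
        else:
            _build_item(item, codes)  # advance the counter consistently
    return out


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

TEMPLATE_NAMES = (
    "individual_claim", "consultation_claim",
    "admission_request", "admission_authorization", "admission_claim",
    "tests_procedures_request", "tests_procedures_authorization",
    "tests_procedures_claim",
    "dental_evaluation", "dental_claim", "other_charges",
)

_ENCOUNTER_CODES = ["first_visit", "follow_up", "prenatal", "emergency"]
_FACE_CODES = ["M", "D", "V", "L", "O"]


def _slot_path(host: str, label_or_code: str = "at0015") -> str:
    return f"{host}#/data[at0001]/items[{label_or_code}]"


def _el_path(host: str, label: str) -> str:
    return f"{host}#/data[at0001]/items[{element_code(host, label)}]"


def template_specs() -> dict[str, dict]:
    """The eleven form templates as plain config dictionaries (approach 1)."""
    content = "/content[at0001]"

    def t(name: str, entries: list[str], fills: Optional[dict] = None,
          exclusions: Optional[list] = None, bindings: Optional[dict] = None,
          overrides: Optional[dict] = None) -> dict:
        slot_fills = {content: list(entries)}
        slot_fills.update(fills or {})
        return {
            "name": name,
            "root_archetype": TISS_CLAIM,
            "slot_fills": slot_fills,
            "exclusions": exclusions or [],
            "code_bindings": bindings or {},
            "occurrence_overrides": overrides or {},
        }

    prof_slot = _slot_path(PROFESSIONAL_CLAIM)
    inst_slot = _slot_path(INSTITUTIONAL_CLAIM)
    auth_slot = _slot_path(AUTHORIZATION)
    req_slot = _slot_path(AUTHORIZATION_REQUEST)

    specs = [
        t("individual_claim",
          [PROFESSIONAL_CLAIM, PATIENT_EVALUATION, CLAIM_SERVICES],
          fills={prof_slot: [TOTAL_COSTS]}),
        t("consultation_claim",
          [PROFESSIONAL_CLAIM, PATIENT_EVALUATION],
          fills={prof_slot: [TOTAL_COSTS]},
          exclusions=[f"{PATIENT_EVALUATION}#/data[at0001]/items"
                      f"[{element_code(PATIENT_EVALUATION, 'obstetrics')}]"],
          bindings={_el_path(PROFESSIONAL_CLAIM, "type of encounter"):
                    ["tiss_local", _ENCOUNTER_CODES]},
          overrides={_el_path(PROFESSIONAL_CLAIM, "type of encounter"): "1..1"}),
        t("admission_request",
          [AUTHORIZATION_REQUEST, PATIENT_EVALUATION],
          fills={req_slot: [ADMISSION]}),
        t("admission_authorization",
          [AUTHORIZATION],
          fills={auth_slot: [ADMISSION]}),
        t("admission_claim",
          [INSTITUTIONAL_CLAIM, PATIENT_EVALUATION, CLAIM_SERVICES],
          fills={inst_slot: [ADMISSION, TOTAL_COSTS]}),
        t("tests_procedures_request",
          [AUTHORIZATION_REQUEST, PATIENT_EVALUATION]),
        t("tests_procedures_authorization",
          [AUTHORIZATION]),
        t("tests_procedures_claim",
          [PROFESSIONAL_CLAIM, CLAIM_SERVICES],
          fills={prof_slot: [TOTAL_COSTS]}),
        t("dental_evaluation",
          [AUTHORIZATION_REQUEST, ODONTO_EVALUATION]),
        t("dental_claim",
          [PROFESSIONAL_CLAIM, ODONTO_EVALUATION, CLAIM_SERVICES],
          fills={prof_slot: [TOTAL_COSTS]},
          bindings={_el_path(CLAIM_SERVICES, "face"):
                    ["tiss_dental", _FACE_CODES]}),
        t("other_charges",
          [INSTITUTIONAL_CLAIM, CLAIM_SERVICES],
          fills={inst_slot: [TOTAL_COSTS]}),
    ]
    return {s["name"]: s for s in specs}


def build_templates(outdir: Union[str, Path]) -> list[Path]:
    """Write the eleven template configs as ``*.tpl.yaml`` files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, spec in template_specs().items():
        path = outdir / f"{name}.tpl.yaml"
        path.write_text(yaml.safe_dump(spec, sort_keys=True), encoding="utf-8")
        written.append(path)
    return written
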