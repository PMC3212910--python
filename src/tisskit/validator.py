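"""Two-level conformance checking: instance trees against archetypes.

An archetype constrains the reference model; it does not enumerate it, so
instance content in unconstrained attributes (links, parties...) is always
permitted.  Validation never raises on bad data — every violated constraint
becomes a finding with a citable instance path — and slot fillers are
recursively validated against their own archetypes, resolved through an
:class:`ArchetypeRepository` (the in-process stand-in for a public archetype
repository).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from . import rm_core, rm_extension  # noqa: F401  (registers extended RM types)
from .adl import (
    ArchetypeDefinition,
    AttributeConstraint,
    ComplexObjectConstraint,
    PrimitiveConstraint,
    SlotConstraint,
    parse_archetype_id,
)
from .report import Rule, Severity, ValidationFinding, ValidationReport
from .rm_core import (
    CodedTextValue,
    CountValue,
    DataValue,
    DateTimeValue,
    DateValue,
    Element,
    IdentifierValue,
    InstancePath,
    Locatable,
    MoneyValue,
    QuantityValue,
    TextValue,
    children,
)

__all__ = [
    "ArchetypeRepository",
    "validate_instance",
    "check_value_constraint",
    "VALUE_CLASS_REGISTRY",
    "ValidationFinding",
    "ValidationReport",
    "Rule",
    "Severity",
]


VALUE_CLASS_REGISTRY: dict[str, type] = {
    "DV_TEXT": TextValue,
    "DV_CODED_TEXT": CodedTextValue,
    "DV_DATE_TIME": DateTimeValue,
    "DV_DATE": DateValue,
    "DV_COUNT": CountValue,
    "DV_QUANTITY": QuantityValue,
    "DV_MONEY": MoneyValue,
    "DV_IDENTIFIER": IdentifierValue,
}


def _canon_id(archetype_id: str) -> str:
    """Normalize an archetype id string (short form → full form)."""
    try:
        return str(parse_archetype_id(archetype_id))
    except ValueError:
        return archetype_id


@dataclass
class ArchetypeRepository:
    """Id → definition lookup with alias support.

    Aliases resolve alternative spellings of the same concept (e.g. a slot
    include naming ``...CLUSTER.costs.v1`` for the ``total_costs`` archetype)
    without silently merging them.
    """

    definitions: dict[str, ArchetypeDefinition] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)

    def add(self, defn: ArchetypeDefinition) -> None:
        if defn.id is None:
            raise ValueError("cannot register an archetype without an id")
        key = str(defn.id)
        if key in self.definitions:
            raise ValueError(f"duplicate archetype id {key}")
        self.definitions[key] = defn

    def add_alias(self, alias: str, target: str) -> None:
        self.aliases[_canon_id(alias)] = _canon_id(target)

    def canonical(self, archetype_id: str) -> str:
        cid = _canon_id(archetype_id)
        return self.aliases.get(cid, cid)

    def get(self, archetype_id: str) -> Optional[ArchetypeDefinition]:
        return self.definitions.get(self.canonical(archetype_id))

    def __contains__(self, archetype_id: str) -> bool:
        return self.canonical(archetype_id) in self.definitions

    def ids(self) -> list[str]:
        return sorted(self.definitions)


def check_value_constraint(
    value: Optional[DataValue],
    constraint: PrimitiveConstraint,
    path: str = "/",
) -> Optional[ValidationFinding]:
    """ANY pattern accepts every value of the constrained DV type; a value of
    the wrong variant is a VALUE_TYPE_MISMATCH.  A None value (explicitly
    unknown) is always accepted."""
    if value is None:
        return None
    expected = VALUE_CLASS_REGISTRY.get(constraint.rm_type)
    if expected is None:
        return ValidationFinding(path, Rule.VALUE_TYPE_MISMATCH,
                                 f"unknown value type {constraint.rm_type!r}")
    if not isinstance(value, expected):
        return ValidationFinding(
            path, Rule.VALUE_TYPE_MISMATCH,
            f"expected {constraint.rm_type}, got {type(value).__name__}")
    return None


def validate_instance(
    node: Locatable,
    archetype: Union[ArchetypeDefinition, ComplexObjectConstraint],
    repo: Optional[ArchetypeRepository] = None,
    bindings: Optional[dict[str, tuple[str, list[str]]]] = None,
) -> ValidationReport:
    """Validate an instance tree against an archetype constraint tree.

    ``bindings`` maps instance paths to (terminology_id, allowed codes); used
    by the template engine for local code bindings.
    """
    root = archetype.root if isinstance(archetype, ArchetypeDefinition) else archetype
    repo = repo or ArchetypeRepository()
    report = ValidationReport()
    # the root pairing is the caller's choice; a slot filler legitimately
    # carries the slot's node id rather than at0000, so only subtree node ids
    # are checked
    _validate_object(node, root, "/", report, repo, skip_node_id=True)
    if bindings:
        _check_bindings(node, bindings, report)
    return report.sorted()


def _rm_class(rm_type: str) -> Optional[type]:
    return rm_core.RM_CLASS_REGISTRY.get(rm_type)


def _validate_object(
    inst: Locatable,
    constraint: ComplexObjectConstraint,
    path: str,
    report: ValidationReport,
    repo: ArchetypeRepository,
    skip_node_id: bool,
) -> None:
    cls = _rm_class(constraint.rm_type)
    if cls is None or not isinstance(inst, cls):
        report.add(path, Rule.RM_TYPE_MISMATCH,
                   f"expected {constraint.rm_type}, got "
                   f"{type(inst).__name__}")
        return
    if (not skip_node_id and constraint.node_id is not None
            and inst.archetype_node_id != constraint.node_id):
        report.add(path, Rule.NODE_ID_UNKNOWN,
                   f"node id {inst.archetype_node_id} does not match "
                   f"constraint {constraint.node_id}")
        return
    if constraint.any_allowed:
        return

    inst_children: dict[str, list[Locatable]] = {}
    for attr, _i, child in children(inst):
        inst_children.setdefault(attr, []).append(child)

    if isinstance(inst, Element):
        for attr in constraint.attributes:
            if attr.name == "value":
                for prim in attr.children:
                    if isinstance(prim, PrimitiveConstraint):
                        finding = check_value_constraint(inst.value, prim, path)
                        if finding:
                            report.findings.append(finding)
        return

    for attr in constraint.attributes:
        present = inst_children.get(attr.name, [])
        if attr.cardinality is not None and not attr.cardinality.contains(len(present)):
            report.add(path, Rule.CARDINALITY_VIOLATION,
                       f"attribute {attr.name!r} has {len(present)} children, "
                       f"cardinality allows {{{attr.cardinality.render()}}}")
        _validate_attribute(present, attr, path, report, repo)
    # instance attributes with no constraint are permitted (the archetype
    # constrains, it does not enumerate)


def _validate_attribute(
    present: list[Locatable],
    attr: AttributeConstraint,
    parent_path: str,
    report: ValidationReport,
    repo: ArchetypeRepository,
) -> None:
    complex_by_nid: dict[str, list[ComplexObjectConstraint]] = {}
    slots_by_nid: dict[str, SlotConstraint] = {}
    for c in attr.children:
        if isinstance(c, ComplexObjectConstraint) and c.node_id is not None:
            complex_by_nid.setdefault(c.node_id.code, []).append(c)
        elif isinstance(c, SlotConstraint) and c.node_id is not None:
            slots_by_nid[c.node_id.code] = c

    matched: dict[int, list[Locatable]] = {id(c): [] for c in attr.children}
    slot_matched: dict[str, list[Locatable]] = {k: [] for k in slots_by_nid}

    for child in present:
        nid = child.archetype_node_id.code
        cpath = f"{parent_path.rstrip('/')}/{attr.name}[{nid}]"
        candidates = complex_by_nid.get(nid, [])
        chosen: Optional[ComplexObjectConstraint] = None
        for c in candidates:
            if c.archetype_ref is None:
                chosen = c
                break
            if child.archetype_id is not None and \
                    repo.canonical(child.archetype_id) == repo.canonical(c.archetype_ref):
                chosen = c
                break
        if chosen is not None:
            matched[id(chosen)].append(child)
            _validate_object(child, chosen, cpath, report, repo, skip_node_id=True)
            continue
        if candidates:
            # a slot position (flattened fillers) with a foreign archetype
            if child.archetype_id is None:
                report.add(cpath, Rule.SLOT_FILLER_INVALID,
                           "node at a slot position carries no archetype id")
            else:
                allowed = sorted({repo.canonical(c.archetype_ref)
                                  for c in candidates if c.archetype_ref})
                report.add(cpath, Rule.SLOT_INCLUDE_VIOLATION,
                           f"archetype {child.archetype_id!r} is not among the "
                           f"slot fillers {allowed}")
            continue
        if nid in slots_by_nid:
            slot = slots_by_nid[nid]
            slot_matched[nid].append(child)
            _validate_slot_filler(child, slot, cpath, report, repo)
            continue
        report.add(cpath, Rule.NODE_ID_UNKNOWN,
                   f"no constraint for node id {nid} under attribute "
                   f"{attr.name!r}")

    for c in attr.children:
        if isinstance(c, ComplexObjectConstraint) and c.node_id is not None:
            n = len(matched[id(c)])
            cpath = f"{parent_path.rstrip('/')}/{attr.name}[{c.node_id.code}]"
            if not c.occurrences.contains(n):
                rule = (Rule.OCCURRENCES_UNMET if n < c.occurrences.lower
                        else Rule.OCCURRENCES_EXCEEDED)
                report.add(cpath, rule,
                           f"{n} occurrence(s) of {c.label or c.rm_type}, allowed "
                           f"{{{c.occurrences.render()}}}")
        elif isinstance(c, SlotConstraint) and c.node_id is not None:
            n = len(slot_matched[c.node_id.code])
            cpath = f"{parent_path.rstrip('/')}/{attr.name}[{c.node_id.code}]"
            if not c.occurrences.contains(n):
                rule = (Rule.OCCURRENCES_UNMET if n < c.occurrences.lower
                        else Rule.OCCURRENCES_EXCEEDED)
                report.add(cpath, rule,
                           f"{n} filler(s) in slot, allowed "
                           f"{{{c.occurrences.render()}}}")


def _validate_slot_filler(
    child: Locatable,
    slot: SlotConstraint,
    path: str,
    report: ValidationReport,
    repo: ArchetypeRepository,
) -> None:
    cls = _rm_class(slot.rm_type)
    if cls is not None and not isinstance(child, cls):
        report.add(path, Rule.RM_TYPE_MISMATCH,
                   f"slot expects {slot.rm_type}, got {type(child).__name__}")
        return
    if child.archetype_id is None:
        report.add(path, Rule.SLOT_FILLER_INVALID,
                   "slot filler carries no archetype id")
        return
    allowed = {repo.canonical(i) for i in slot.includes}
    if repo.canonical(child.archetype_id) not in allowed:
        report.add(path, Rule.SLOT_INCLUDE_VIOLATION,
                   f"archetype {child.archetype_id!r} not in slot includes "
                   f"{sorted(allowed)}")
        return
    defn = repo.get(child.archetype_id)
    if defn is None:
        report.add(path, Rule.SLOT_FILLER_INVALID,
                   f"archetype {child.archetype_id!r} is absent from the repository")
        return
    _validate_object(child, defn.root, path, report, repo, skip_node_id=True)


def _check_bindings(
    root: Locatable,
    bindings: dict[str, tuple[str, list[str]]],
    report: ValidationReport,
) -> None:
    for path_str, (terminology, codes) in sorted(bindings.items()):
        for node in rm_core.resolve_path(root, InstancePath.parse(path_str)):
            if isinstance(node, Element) and isinstance(node.value, CodedTextValue):
                v = node.value
                if v.code not in codes:
                    report.add(path_str, Rule.CODE_BINDING_VIOLATION,
                               f"code {v.code!r} not in binding "
                               f"{terminology}:{codes}")
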