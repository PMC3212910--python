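"""Minimal openEHR-style reference-model kernel for claim/authorization documents.

The kernel implements the class subset a two-level (reference model +
archetype) claims architecture needs: COMPOSITION / SECTION / ENTRY (split
into CARE_ENTRY and ADMIN_ENTRY), the item structures (ITEM_TREE, ITEM_LIST,
ITEM_TABLE, ITEM_SINGLE), ELEMENT leaves holding typed data values, party
references, participations and LINKs.  Versioning, folders, EVENT/HISTORY and
audit are deliberately out of scope: billing documents do not need them.

Every instance node is a :class:`Locatable` carrying exactly one archetype
node id (``atNNNN``); nodes are addressed by :class:`InstancePath`, rendered
in the familiar ``/attribute[atNNNN]`` syntax so that validation findings are
citable.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from typing import Iterator, Optional, Union

__all__ = [
    "NodeId",
    "Link",
    "DataValue",
    "TextValue",
    "CodedTextValue",
    "DateTimeValue",
    "DateValue",
    "CountValue",
    "QuantityValue",
    "MoneyValue",
    "IdentifierValue",
    "PartyProxy",
    "PartySelf",
    "PartyIdentified",
    "Participation",
    "Locatable",
    "Element",
    "Cluster",
    "ItemStructure",
    "ItemTree",
    "ItemList",
    "ItemTable",
    "ItemSingle",
    "Entry",
    "CareEntry",
    "AdminEntry",
    "Observation",
    "Evaluation",
    "Instruction",
    "Action",
    "Section",
    "Composition",
    "PathSegment",
    "InstancePath",
    "PathError",
    "resolve_path",
    "structural_equals",
    "collect_links",
    "children",
    "walk",
    "RM_CLASS_REGISTRY",
    "rm_type_name",
]


_NODE_ID_RE = re.compile(r"^at\d{4,}$")


@dataclass(frozen=True)
class NodeId:
    """An ``atNNNN`` archetype node identifier (at least four digits)."""

    code: str

    def __post_init__(self) -> None:
        if not _NODE_ID_RE.match(self.code):
            raise ValueError(f"invalid node id {self.code!r}: must match 'at' + 4+ digits")

    @property
    def is_root(self) -> bool:
        return self.code == "at0000"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.code


# ---------------------------------------------------------------------------
# Data values
# ---------------------------------------------------------------------------

class DataValue:
    """Abstract base of the closed set of leaf value variants."""

    __slots__ = ()


def _canon_decimal(value: Union[str, int, float, Decimal], what: str) -> Decimal:
    """Parse a decimal, tolerating thousands separators ("1,200.00")."""
    if isinstance(value, Decimal):
        return value
    if isinstance(value, (int,)):
        return Decimal(value)
    if isinstance(value, float):
        return Decimal(str(value))
    try:
        return Decimal(str(value).replace(",", ""))
    except InvalidOperation as exc:
        raise ValueError(f"invalid {what} {value!r}") from exc


@dataclass(frozen=True)
class TextValue(DataValue):
    value: str


@dataclass(frozen=True)
class CodedTextValue(TextValue):
    # DV_CODED_TEXT specialises DV_TEXT: `value` carries the display text.
    code: str = ""
    terminology_id: str = ""

    @property
    def display(self) -> str:
        return self.value


@dataclass(frozen=True)
class DateTimeValue(DataValue):
    """ISO-8601 timestamp, canonicalized at construction."""

    value: str

    def __post_init__(self) -> None:
        try:
            canon = _dt.datetime.fromisoformat(self.value).isoformat()
        except ValueError as exc:
            raise ValueError(f"invalid ISO timestamp {self.value!r}") from exc
        object.__setattr__(self, "value", canon)


@dataclass(frozen=True)
class DateValue(DataValue):
    """ISO-8601 calendar date."""

    value: str

    def __post_init__(self) -> None:
        try:
            canon = _dt.date.fromisoformat(self.value).isoformat()
        except ValueError as exc:
            raise ValueError(f"invalid ISO date {self.value!r}") from exc
        object.__setattr__(self, "value", canon)


@dataclass(frozen=True)
class CountValue(DataValue):
    value: int

    def __post_init__(self) -> None:
        if not isinstance(self.value, int) or isinstance(self.value, bool) or self.value < 0:
            raise ValueError(f"count must be a non-negative integer, got {self.value!r}")


@dataclass(frozen=True)
class QuantityValue(DataValue):
    magnitude: Decimal
    units: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "magnitude", _canon_decimal(self.magnitude, "magnitude"))


_CURRENCY_RE = re.compile(r"^[A-Z]{3}$")


@dataclass(frozen=True)
class MoneyValue(DataValue):
    """Monetary amount; serialized with banker's rounding to 2 decimals."""

    amount: Decimal
    currency: str = "BRL"

    def __post_init__(self) -> None:
        object.__setattr__(self, "amount", _canon_decimal(self.amount, "amount"))
        if not _CURRENCY_RE.match(self.currency):
            raise ValueError(f"currency must be a 3-letter code, got {self.currency!r}")


@dataclass(frozen=True)
class IdentifierValue(DataValue):
    id: str
    issuer: str = ""
    type: str = ""


# ---------------------------------------------------------------------------
# Parties, participations and links
# ---------------------------------------------------------------------------

class PartyProxy:
    """Abstract reference to a demographic entity."""

    __slots__ = ()


@dataclass(frozen=True)
class PartySelf(PartyProxy):
    """The subject of the record itself (no external identifier needed)."""


@dataclass(frozen=True)
class PartyIdentified(PartyProxy):
    """A party resolvable in a target system through its identifiers.

    Cross-organization exchange (provider ↔ payer) always uses this form,
    carrying e.g. the national provider identifier, the health-plan number or
    the patient number in the plan.
    """

    name: str
    identifiers: tuple[IdentifierValue, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "identifiers", tuple(self.identifiers))


@dataclass(frozen=True)
class Participation:
    performer: PartyProxy
    function: str
    mode: Optional[str] = None


@dataclass(frozen=True)
class Link:
    """Typed association from one node to another (e.g. service → diagnosis)."""

    meaning: str
    type: str
    target: str  # composition id + path, e.g. "comp-1#/content[at0001]/..."


# ---------------------------------------------------------------------------
# Instance nodes
# ---------------------------------------------------------------------------

@dataclass(kw_only=True)
class Locatable:
    """Base of every instance node.

    ``archetype_id`` is set only on archetype roots (document roots and slot
    fillers); for those nodes a root node id ``at0000`` is legal.
    """

    name: str
    archetype_node_id: NodeId
    links: list[Link] = field(default_factory=list)
    archetype_id: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.archetype_node_id, str):  # convenience coercion
            self.archetype_node_id = NodeId(self.archetype_node_id)
        if self.archetype_node_id.is_root and self.archetype_id is None:
            raise ValueError("node id at0000 is only permitted at an archetype root "
                             "(archetype_id must be set)")


@dataclass(kw_only=True)
class Element(Locatable):
    """Leaf node; ``value`` of None means explicitly unknown."""

    value: Optional[DataValue] = None


@dataclass(kw_only=True)
class Cluster(Locatable):
    items: list[Union[Element, "Cluster"]] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.items:
            raise ValueError(f"cluster {self.name!r} must contain at least one item")


@dataclass(kw_only=True)
class ItemStructure(Locatable):
    """Abstract base of the four item-structure variants."""


@dataclass(kw_only=True)
class ItemTree(ItemStructure):
    items: list[Union[Element, Cluster]] = field(default_factory=list)


@dataclass(kw_only=True)
class ItemList(ItemStructure):
    items: list[Element] = field(default_factory=list)


@dataclass(kw_only=True)
class ItemTable(ItemStructure):
    rows: list[Cluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        shapes = {tuple(e.name for e in row.items) for row in self.rows}
        if len(shapes) > 1:
            raise ValueError("ITEM_TABLE rows must all contain the same element "
                             f"names in the same order; got {sorted(shapes)}")


@dataclass(kw_only=True)
class ItemSingle(ItemStructure):
    item: Element = None  # type: ignore[assignment]


@dataclass(kw_only=True)
class Entry(Locatable):
    subject: PartyProxy = field(default_factory=PartySelf)
    provider: Optional[PartyProxy] = None
    other_participations: list[Participation] = field(default_factory=list)
    data: Optional[ItemStructure] = None


class CareEntry(Entry):
    """Clinical branch of ENTRY (OBSERVATION/EVALUATION/INSTRUCTION/ACTION)."""


@dataclass(kw_only=True)
class AdminEntry(Entry):
    """Administrative data (admission, scheduling, billing headers...)."""


@dataclass(kw_only=True)
class Observation(CareEntry):
    pass


@dataclass(kw_only=True)
class Evaluation(CareEntry):
    pass


@dataclass(kw_only=True)
class Instruction(CareEntry):
    pass


@dataclass(kw_only=True)
class Action(CareEntry):
    pass


@dataclass(kw_only=True)
class Section(Locatable):
    items: list[Union["Section", Entry]] = field(default_factory=list)


@dataclass(kw_only=True)
class Composition(Locatable):
    composer: PartyProxy = field(default_factory=PartySelf)
    context_start_time: Optional[DateTimeValue] = None
    content: list[Union[Section, Entry]] = field(default_factory=list)
    # Extended-mode claim status; populated only by rm_extension.
    ism_transition: Optional[object] = None


# Names used by archetypes (and serializations) for each instance class.
# rm_extension registers its subclasses here at import time.
RM_CLASS_REGISTRY: dict[str, type] = {
    "COMPOSITION": Composition,
    "SECTION": Section,
    "ENTRY": Entry,
    "CARE_ENTRY": CareEntry,
    "ADMIN_ENTRY": AdminEntry,
    "OBSERVATION": Observation,
    "EVALUATION": Evaluation,
    "INSTRUCTION": Instruction,
    "ACTION": Action,
    "CLUSTER": Cluster,
    "ELEMENT": Element,
    "ITEM_STRUCTURE": ItemStructure,
    "ITEM_TREE": ItemTree,
    "ITEM_LIST": ItemList,
    "ITEM_TABLE": ItemTable,
    "ITEM_SINGLE": ItemSingle,
}


def rm_type_name(node: Locatable) -> str:
    """The reference-model type name of an instance node (e.g. "ADMIN_ENTRY")."""
    for name, cls in RM_CLASS_REGISTRY.items():
        if type(node) is cls:
            return name
    raise TypeError(f"unregistered instance class {type(node).__name__}")


# ---------------------------------------------------------------------------
# Tree access
# ---------------------------------------------------------------------------

def children(node: Locatable) -> Iterator[tuple[str, Optional[int], Locatable]]:
    """Yield ``(attribute_name, index, child)`` for every Locatable child.

    ``index`` is the position within the attribute's collection, or None for
    single-valued attributes.  Document order is the declaration order below.
    """
    if isinstance(node, Cluster):
        for i, item in enumerate(node.items):
            yield "items", i, item
    elif isinstance(node, (ItemTree, ItemList)):
        for i, item in enumerate(node.items):
            yield "items", i, item
    elif isinstance(node, ItemTable):
        for i, row in enumerate(node.rows):
            yield "rows", i, row
    elif isinstance(node, ItemSingle):
        if node.item is not None:
            yield "item", None, node.item
    elif isinstance(node, Entry):
        if node.data is not None:
            yield "data", None, node.data
    elif isinstance(node, Section):
        for i, item in enumerate(node.items):
            yield "items", i, item
    elif isinstance(node, Composition):
        for i, item in enumerate(node.content):
            yield "content", i, item


def walk(node: Locatable, _path: str = "") -> Iterator[tuple[str, Locatable]]:
    """Depth-first document-order walk yielding (canonical path, node)."""
    yield (_path or "/", node)
    per_attr: dict[str, int] = {}
    for attr, _idx, child in children(node):
        n = per_attr.get(attr, 0)
        per_attr[attr] = n + 1
        seg = f"{_path}/{attr}[{child.archetype_node_id}]"
        yield from walk(child, seg)


# ---------------------------------------------------------------------------
# Paths
# ---------------------------------------------------------------------------

class PathError(ValueError):
    """Raised for malformed instance path strings."""


_SEGMENT_RE = re.compile(
    r"/(?P<attr>[A-Za-z_][A-Za-z0-9_]*)"
    r"(?:\[(?P<nid>at\d{4,})\])?"
    r"(?:\[(?P<idx>\d+)\])?"
)


@dataclass(frozen=True)
class PathSegment:
    attribute: str
    node_id: Optional[NodeId] = None
    index: Optional[int] = None

    def __str__(self) -> str:
        s = f"/{self.attribute}"
        if self.node_id is not None:
            s += f"[{self.node_id}]"
        if self.index is not None:
            s += f"[{self.index}]"
        return s


@dataclass(frozen=True)
class InstancePath:
    segments: tuple[PathSegment, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "InstancePath":
        if text in ("", "/"):
            return cls(())
        pos = 0
        segments = []
        while pos < len(text):
            m = _SEGMENT_RE.match(text, pos)
            if not m or m.start() != pos:
                raise PathError(
                    f"malformed path {text!r}: cannot parse segment at {text[pos:]!r}")
            nid = m.group("nid")
            idx = m.group("idx")
            segments.append(PathSegment(
                attribute=m.group("attr"),
                node_id=NodeId(nid) if nid else None,
                index=int(idx) if idx is not None else None,
            ))
            pos = m.end()
        return cls(tuple(segments))

    def __str__(self) -> str:
        if not self.segments:
            return "/"
        return "".join(str(s) for s in self.segments)

    def child(self, attribute: str, node_id: Optional[NodeId] = None,
              index: Optional[int] = None) -> "InstancePath":
        return InstancePath(self.segments + (PathSegment(attribute, node_id, index),))


def resolve_path(root: Locatable, path: Union[InstancePath, str]) -> list[Locatable]:
    """All instance nodes matching ``path`` from ``root`` (may be empty).

    A node-id segment must match the child's ``archetype_node_id``; an index
    segment selects within the per-parent list of node-id matches.
    """
    if isinstance(path, str):
        path = InstancePath.parse(path)
    current = [root]
    for seg in path.segments:
        nxt: list[Locatable] = []
        for node in current:
            matches = [child for attr, _i, child in children(node)
                       if attr == seg.attribute
                       and (seg.node_id is None
                            or child.archetype_node_id == seg.node_id)]
            if seg.index is not None:
                if seg.index < len(matches):
                    nxt.append(matches[seg.index])
            else:
                nxt.extend(matches)
        current = nxt
        if not current:
            break
    return current


def structural_equals(a: Locatable, b: Locatable) -> bool:
    """Deep structural identity: same types, node ids, names, order and values.

    Timestamps and decimals are canonicalized at construction, so "1,200.00"
    and "1200.00" money values compare equal.
    """
    if type(a) is not type(b):
        return False
    return a == b


def collect_links(root: Locatable) -> list[tuple[str, Link]]:
    """Every link in the tree with the canonical path of its owner, in
    document order."""
    out: list[tuple[str, Link]] = []
    for path, node in walk(root):
        for link in node.links:
            out.append((path, link))
    return out
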