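"""Parser and printer for the ADL dialect used by the shipped archetypes.

The dialect covers exactly the constructs the TISS archetypes need:

* complex object constraints — ``RM_TYPE[atNNNN] occurrences matches {I}
  matches { ... }`` (or ``matches {*}`` for an ANY constraint);
* attribute constraints — ``name cardinality matches {I; unordered}
  matches { ... }``;
* primitive data-value constraints — ``DV_TEXT matches {*}``;
* archetype slots — ``allow_archetype CLUSTER[atNNNN] occurrences matches {I}
  matches { include archetype_id/value matches { id | id } }``;
* ``--`` trailing comments, which carry the node labels (term texts);
* an optional ``archetype`` header and ``ontology`` section for fixture
  authoring.

Full ADL 1.4 (specialization, assumed values, bindings) is out of scope.
Occurrences default to ``{1..1}`` when unstated, per openEHR convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .rm_core import NodeId

__all__ = [
    "ArchetypeId",
    "Interval",
    "ComplexObjectConstraint",
    "AttributeConstraint",
    "PrimitiveConstraint",
    "SlotConstraint",
    "ConstraintNode",
    "ArchetypeDefinition",
    "AdlParseError",
    "parse_archetype",
    "serialize_archetype",
    "serialize_definition",
    "parse_archetype_id",
    "tokenize",
    "RmTypeRegistry",
    "DEFAULT_REGISTRY",
    "UNBOUNDED",
]


# ---------------------------------------------------------------------------
# Archetype identifiers
# ---------------------------------------------------------------------------

_AID_RE = re.compile(
    r"^(?P<orig>openEHR)(?P<ehr>-EHR)?-(?P<rm>[A-Z][A-Z_]*)"
    r"\.(?P<concept>[a-z][a-z0-9_]*)\.v(?P<version>\d+)$")


@dataclass(frozen=True)
class ArchetypeId:
    """``openEHR-EHR-<RM_ENTITY>.<concept>.v<N>`` identifier.

    Short-form ids (``openEHR-CLUSTER.admission.v1``) normalize to the full
    form with ``normalized`` flagged; the flag does not affect equality.
    """

    originator: str
    rm_entity: str
    concept: str
    version: int
    normalized: bool = field(default=False, compare=False)

    def __str__(self) -> str:
        return f"{self.originator}-EHR-{self.rm_entity}.{self.concept}.v{self.version}"


def parse_archetype_id(s: str) -> ArchetypeId:
    m = _AID_RE.match(s.strip())
    if not m:
        raise ValueError(
            f"invalid archetype id {s!r}: expected "
            "'openEHR-EHR-<RM_ENTITY>.<concept>.v<N>'")
    return ArchetypeId(
        originator=m.group("orig"),
        rm_entity=m.group("rm"),
        concept=m.group("concept"),
        version=int(m.group("version")),
        normalized=m.group("ehr") is None,
    )


# ---------------------------------------------------------------------------
# Constraint model
# ---------------------------------------------------------------------------

UNBOUNDED = None  # upper bound marker


@dataclass(frozen=True)
class Interval:
    """Occurrences / cardinality interval; ``upper`` None means unbounded.

    ``ordered`` is meaningful only for cardinality (None for occurrences).
    """

    lower: int = 1
    upper: Optional[int] = 1
    ordered: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"interval lower bound {self.lower} < 0")
        if self.upper is not None and self.lower > self.upper:
            raise ValueError(f"interval {self.lower}..{self.upper} is empty")

    def contains(self, n: int) -> bool:
        return n >= self.lower and (self.upper is None or n <= self.upper)

    def within(self, other: "Interval") -> bool:
        """True iff every count allowed here is allowed by ``other``."""
        if self.lower < other.lower:
            return False
        if other.upper is None:
            return True
        return self.upper is not None and self.upper <= other.upper

    def render(self) -> str:
        upper = "*" if self.upper is None else str(self.upper)
        s = f"{self.lower}..{upper}"
        if self.ordered is not None:
            s += "; ordered" if self.ordered else "; unordered"
        return s


@dataclass
class AttributeConstraint:
    name: str
    cardinality: Optional[Interval] = None
    children: list["ConstraintNode"] = field(default_factory=list)


@dataclass
class ComplexObjectConstraint:
    rm_type: str
    node_id: Optional[NodeId] = None
    occurrences: Interval = field(default_factory=Interval)
    label: Optional[str] = None
    attributes: list[AttributeConstraint] = field(default_factory=list)
    any_allowed: bool = False
    # Set by template flattening when this subtree came from a slot filler.
    archetype_ref: Optional[str] = None


@dataclass
class PrimitiveConstraint:
    rm_type: str  # a DV_* name
    pattern: str = "*"  # the dialect supports the ANY pattern only


@dataclass
class SlotConstraint:
    rm_type: str
    node_id: Optional[NodeId] = None
    occurrences: Interval = field(default_factory=Interval)
    includes: list[str] = field(default_factory=list)
    label: Optional[str] = None


ConstraintNode = Union[ComplexObjectConstraint, PrimitiveConstraint, SlotConstraint]


@dataclass
class ArchetypeDefinition:
    """A parsed archetype: identifier, constraint tree and term definitions.

    When no ontology section is present, term definitions are derived from
    the ``--`` comment labels (description defaulting to the term text).
    """

    id: Optional[ArchetypeId]
    root: ComplexObjectConstraint
    term_definitions: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.term_definitions:
            terms: dict[str, tuple[str, str]] = {}
            for node in iter_objects(self.root):
                if isinstance(node, (ComplexObjectConstraint, SlotConstraint)) \
                        and node.node_id is not None and node.label:
                    terms[node.node_id.code] = (node.label, node.label)
            self.term_definitions = terms


def iter_objects(node: ConstraintNode):
    """Document-order walk over all object constraints in a tree."""
    yield node
    if isinstance(node, ComplexObjectConstraint):
        for attr in node.attributes:
            for child in attr.children:
                yield from iter_objects(child)


# ---------------------------------------------------------------------------
# RM type registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmTypeRegistry:
    complex_types: frozenset[str]
    value_types: frozenset[str]

    def extended(self, *names: str) -> "RmTypeRegistry":
        return replace(self, complex_types=self.complex_types | frozenset(names))


_CORE_COMPLEX = frozenset({
    "COMPOSITION", "SECTION", "ENTRY", "CARE_ENTRY", "ADMIN_ENTRY",
    "OBSERVATION", "EVALUATION", "INSTRUCTION", "ACTION",
    "CLUSTER", "ELEMENT", "ITEM_STRUCTURE", "ITEM_TREE", "ITEM_LIST",
    "ITEM_TABLE", "ITEM_SINGLE",
})
_EXTENDED_COMPLEX = frozenset({
    "SUBMISSION", "CLAIM", "PROFESSIONAL_CLAIM", "INSTITUTIONAL_CLAIM",
    "AUTHORIZATION", "ANNEX",
})
_VALUE_TYPES = frozenset({
    "DV_TEXT", "DV_CODED_TEXT", "DV_DATE_TIME", "DV_DATE", "DV_COUNT",
    "DV_QUANTITY", "DV_MONEY", "DV_IDENTIFIER",
})

CORE_REGISTRY = RmTypeRegistry(_CORE_COMPLEX, _VALUE_TYPES)
#: Default registry accepts both the plain and the extended reference model.
DEFAULT_REGISTRY = RmTypeRegistry(_CORE_COMPLEX | _EXTENDED_COMPLEX, _VALUE_TYPES)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

class AdlParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class _Token:
    kind: str  # WORD NUM LBRACE RBRACE LBRACKET RBRACKET PIPE SEMI DOTDOT STAR COMMENT
    text: str
    line: int


_TOKEN_RE = re.compile(r"""
    (?P<comment>--[^\n]*)
  | (?P<word>[A-Za-z][A-Za-z0-9_./\-]*)
  | (?P<num>\d+)
  | (?P<dotdot>\.\.)
  | (?P<lbrace>\{) | (?P<rbrace>\})
  | (?P<lbracket>\[) | (?P<rbracket>\])
  | (?P<pipe>\|) | (?P<semi>;) | (?P<star>\*)
  | (?P<ws>[\s,]+)
""", re.VERBOSE)


def tokenize(text: str) -> list[_Token]:
    """Whitespace-insensitive token stream (comments are tokens: they carry
    the node labels)."""
    tokens: list[_Token] = []
    pos, line = 0, 1
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise AdlParseError(f"unexpected character {text[pos]!r}", line)
        kind = m.lastgroup
        raw = m.group()
        if kind == "ws":
            line += raw.count("\n")
        elif kind == "comment":
            tokens.append(_Token("COMMENT", raw[2:].strip(), line))
        else:
            tokens.append(_Token(kind.upper(), raw, line))
        pos = m.end()
    return tokens


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, tokens: list[_Token], registry: RmTypeRegistry):
        self.tokens = tokens
        self.pos = 0
        self.registry = registry

    # -- token helpers -----------------------------------------------------
    def peek(self, offset: int = 0) -> Optional[_Token]:
        # comments are skipped except where explicitly read as labels
        i, seen = self.pos, 0
        while i < len(self.tokens):
            if self.tokens[i].kind != "COMMENT":
                if seen == offset:
                    return self.tokens[i]
                seen += 1
            i += 1
        return None

    def next(self) -> _Token:
        while self.pos < len(self.tokens) and self.tokens[self.pos].kind == "COMMENT":
            self.pos += 1
        if self.pos >= len(self.tokens):
            last = self.tokens[-1].line if self.tokens else 0
            raise AdlParseError("unexpected end of input (unbalanced braces?)", last)
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind: str, text: Optional[str] = None) -> _Token:
        tok = self.next()
        if tok.kind != kind or (text is not None and tok.text != text):
            want = text or kind
            raise AdlParseError(f"expected {want!r}, got {tok.text!r}", tok.line)
        return tok

    def take_label(self) -> Optional[str]:
        """Consume an immediately-following comment token, if any."""
        while self.pos < len(self.tokens) and self.tokens[self.pos].kind == "COMMENT":
            label = self.tokens[self.pos].text
            self.pos += 1
            return label or None
        return None

    def at_end(self) -> bool:
        return self.peek() is None

    # -- grammar -----------------------------------------------------------
    def parse_object(self) -> ConstraintNode:
        tok = self.peek()
        assert tok is not None
        if tok.kind == "WORD" and tok.text == "allow_archetype":
            return self.parse_slot()
        rm_tok = self.expect("WORD")
        rm_type = rm_tok.text
        if rm_type in self.registry.value_types:
            return self.parse_primitive(rm_type)
        if rm_type not in self.registry.complex_types:
            raise AdlParseError(f"unregistered rm_type {rm_type!r}", rm_tok.line)
        node_id = self.maybe_node_id()
        occurrences = self.maybe_occurrences()
        self.expect("WORD", "matches")
        self.expect("LBRACE")
        label = self.take_label()
        node = ComplexObjectConstraint(rm_type=rm_type, node_id=node_id,
                                       occurrences=occurrences, label=label)
        if self.peek() and self.peek().kind == "STAR":
            self.next()
            node.any_allowed = True
            self.expect("RBRACE")
            return node
        while self.peek() and self.peek().kind != "RBRACE":
            node.attributes.append(self.parse_attribute())
        self.expect("RBRACE")
        return node

    def parse_primitive(self, rm_type: str) -> PrimitiveConstraint:
        self.expect("WORD", "matches")
        self.expect("LBRACE")
        self.expect("STAR")
        self.expect("RBRACE")
        return PrimitiveConstraint(rm_type=rm_type, pattern="*")

    def parse_slot(self) -> SlotConstraint:
        self.expect("WORD", "allow_archetype")
        rm_tok = self.expect("WORD")
        if rm_tok.text not in self.registry.complex_types:
            raise AdlParseError(f"unregistered rm_type {rm_tok.text!r}", rm_tok.line)
        node_id = self.maybe_node_id()
        occurrences = self.maybe_occurrences()
        self.expect("WORD", "matches")
        self.expect("LBRACE")
        label = self.take_label()
        self.expect("WORD", "include")
        self.expect("WORD", "archetype_id/value")
        self.expect("WORD", "matches")
        self.expect("LBRACE")
        includes = [self.expect("WORD").text]
        while self.peek() and self.peek().kind == "PIPE":
            self.next()
            includes.append(self.expect("WORD").text)
        self.expect("RBRACE")
        self.expect("RBRACE")
        return SlotConstraint(rm_type=rm_tok.text, node_id=node_id,
                              occurrences=occurrences, includes=includes,
                              label=label)

    def parse_attribute(self) -> AttributeConstraint:
        name_tok = self.expect("WORD")
        cardinality = None
        nxt = self.peek()
        if nxt and nxt.kind == "WORD" and nxt.text == "cardinality":
            self.next()
            self.expect("WORD", "matches")
            self.expect("LBRACE")
            cardinality = self.parse_interval(allow_order=True)
            self.expect("RBRACE")
        self.expect("WORD", "matches")
        self.expect("LBRACE")
        attr = AttributeConstraint(name=name_tok.text, cardinality=cardinality)
        while self.peek() and self.peek().kind != "RBRACE":
            attr.children.append(self.parse_object())
        self.expect("RBRACE")
        return attr

    def maybe_node_id(self) -> Optional[NodeId]:
        nxt = self.peek()
        if nxt and nxt.kind == "LBRACKET":
            self.next()
            tok = self.expect("WORD")
            try:
                nid = NodeId(tok.text)
            except ValueError as exc:
                raise AdlParseError(str(exc), tok.line) from exc
            self.expect("RBRACKET")
            return nid
        return None

    def maybe_occurrences(self) -> Interval:
        nxt = self.peek()
        if nxt and nxt.kind == "WORD" and nxt.text == "occurrences":
            self.next()
            self.expect("WORD", "matches")
            self.expect("LBRACE")
            interval = self.parse_interval(allow_order=False)
            self.expect("RBRACE")
            return interval
        return Interval()

    def parse_interval(self, allow_order: bool) -> Interval:
        lo_tok = self.expect("NUM")
        self.expect("DOTDOT")
        up_tok = self.next()
        if up_tok.kind == "NUM":
            upper: Optional[int] = int(up_tok.text)
        elif up_tok.kind == "STAR":
            upper = None
        else:
            raise AdlParseError(
                f"malformed interval: expected number or '*', got {up_tok.text!r}",
                up_tok.line)
        ordered = None
        nxt = self.peek()
        if nxt and nxt.kind == "SEMI":
            if not allow_order:
                raise AdlParseError("ordering flag only allowed on cardinality",
                                    nxt.line)
            self.next()
            flag = self.expect("WORD")
            if flag.text not in ("ordered", "unordered"):
                raise AdlParseError(
                    f"expected 'ordered' or 'unordered', got {flag.text!r}", flag.line)
            ordered = flag.text == "ordered"
        try:
            return Interval(lower=int(lo_tok.text), upper=upper, ordered=ordered)
        except ValueError as exc:
            raise AdlParseError(str(exc), lo_tok.line) from exc


# ---------------------------------------------------------------------------
# Sections
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(
    r"^(archetype|concept|definition|ontology)(?:\s*\(adl_version=[^)\n]*\))?\s*$",
    re.M)
_TERM_RE = re.compile(
    r'\[\s*"(at\d{4,})"\s*\]\s*=\s*<\s*text\s*=\s*"([^"]*)"\s*'
    r'(?:;\s*description\s*=\s*"([^"]*)"\s*)?>')


def _split_sections(text: str) -> dict[str, str]:
    marks = [(m.group(1), m.start(), m.end()) for m in _SECTION_RE.finditer(text)]
    if not marks:
        return {"definition": text}
    sections: dict[str, str] = {}
    for i, (name, _start, end) in enumerate(marks):
        stop = marks[i + 1][1] if i + 1 < len(marks) else len(text)
        sections[name] = text[end:stop]
    return sections


def parse_archetype(
    text: str,
    archetype_id: Optional[Union[str, ArchetypeId]] = None,
    registry: RmTypeRegistry = DEFAULT_REGISTRY,
) -> ArchetypeDefinition:
    """Parse one archetype (a bare definition section, or a full file with
    optional ``archetype`` / ``concept`` / ``ontology`` sections).

    ``archetype_id`` overrides any id found in the header; with neither, the
    definition parses with ``id=None``.
    """
    sections = _split_sections(text)
    if "definition" not in sections:
        raise AdlParseError("no definition section found")
    aid: Optional[ArchetypeId] = None
    if archetype_id is not None:
        aid = (archetype_id if isinstance(archetype_id, ArchetypeId)
               else parse_archetype_id(archetype_id))
    elif "archetype" in sections:
        header = sections["archetype"].strip().splitlines()
        for ln in header:
            ln = ln.strip()
            if ln and not ln.startswith("(") and not ln.startswith("--"):
                aid = parse_archetype_id(ln)
                break

    parser = _Parser(tokenize(sections["definition"]), registry)
    root = parser.parse_object()
    if not parser.at_end():
        tok = parser.peek()
        raise AdlParseError(f"trailing content after definition: {tok.text!r}",
                            tok.line)
    if not isinstance(root, ComplexObjectConstraint):
        raise AdlParseError("definition root must be a complex object constraint")
    if root.node_id is None or not root.node_id.is_root:
        raise AdlParseError("definition root must carry node id at0000")

    seen: set[str] = set()
    for node in iter_objects(root):
        if isinstance(node, (ComplexObjectConstraint, SlotConstraint)) and node.node_id:
            if node.node_id.code in seen:
                raise AdlParseError(
                    f"duplicate node id {node.node_id.code} within archetype")
            seen.add(node.node_id.code)

    terms: dict[str, tuple[str, str]] = {}
    if "ontology" in sections:
        for code, txt, desc in _TERM_RE.findall(sections["ontology"]):
            terms[code] = (txt, desc or txt)
    return ArchetypeDefinition(id=aid, root=root, term_definitions=terms)


# ---------------------------------------------------------------------------
# Serializer
# ---------------------------------------------------------------------------

_INDENT = "    "


def _fmt_object(node: ConstraintNode, depth: int, out: list[str]) -> None:
    pad = _INDENT * depth
    if isinstance(node, PrimitiveConstraint):
        out.append(f"{pad}{node.rm_type} matches {{*}}")
        return
    if isinstance(node, SlotConstraint):
        head = f"{pad}allow_archetype {node.rm_type}"
        if node.node_id:
            head += f"[{node.node_id}]"
        head += f" occurrences matches {{{node.occurrences.render()}}} matches {{"
        if node.label:
            head += f"    -- {node.label}"
        out.append(head)
        out.append(f"{pad}{_INDENT}include archetype_id/value matches {{")
        for i, inc in enumerate(node.includes):
            sep = " |" if i + 1 < len(node.includes) else ""
            out.append(f"{pad}{_INDENT * 2}{inc}{sep}")
        out.append(f"{pad}{_INDENT}}}")
        out.append(f"{pad}}}")
        return

    head = f"{pad}{node.rm_type}"
    if node.node_id:
        head += f"[{node.node_id}]"
    occ = node.occurrences
    if not (occ.lower == 1 and occ.upper == 1 and occ.ordered is None):
        head += f" occurrences matches {{{occ.render()}}}"
    if node.any_allowed:
        head += " matches {*}"
        if node.label:
            head += f"    -- {node.label}"
        out.append(head)
        return
    head += " matches {"
    if node.label:
        head += f"    -- {node.label}"
    out.append(head)
    for attr in node.attributes:
        a = f"{pad}{_INDENT}{attr.name}"
        if attr.cardinality is not None:
            a += f" cardinality matches {{{attr.cardinality.render()}}}"
        a += " matches {"
        out.append(a)
        for child in attr.children:
            _fmt_object(child, depth + 2, out)
        out.append(f"{pad}{_INDENT}}}")
    out.append(f"{pad}}}")


def serialize_definition(root: ConstraintNode) -> str:
    """Canonical pretty-printed definition section."""
    out: list[str] = []
    _fmt_object(root, 0, out)
    return "\n".join(out) + "\n"


def serialize_archetype(defn: ArchetypeDefinition) -> str:
    """Canonical file form; ``parse_archetype(serialize_archetype(d))``
    structurally equals ``d``."""
    parts: list[str] = []
    if defn.id is not None:
        parts.append("archetype (adl_version=1.4)")
        parts.append(f"{_INDENT}{defn.id}")
        parts.append("")
    parts.append("definition")
    body = serialize_definition(defn.root).rstrip("\n").splitlines()
    parts.extend(_INDENT + ln if ln else ln for ln in body)

    # emit ontology only when it adds information beyond the comment labels
    derived = ArchetypeDefinition(id=None, root=defn.root).term_definitions
    if defn.term_definitions and defn.term_definitions != derived:
        parts.append("")
        parts.append("ontology")
        parts.append(f"{_INDENT}term_definitions")
        for code in sorted(defn.term_definitions):
            text, desc = defn.term_definitions[code]
            parts.append(f'{_INDENT * 2}["{code}"] = <text = "{text}"; '
                         f'description = "{desc}">')
    return "\n".join(parts) + "\n"
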