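"""Templates: combining archetypes into concrete forms.

A template names a root (composition) archetype, fills its slots with other
archetypes, and further *restricts* the result: excluding optional elements
that are not on the form, narrowing occurrences, and binding coded elements
to local terminologies.  Restriction is one-way — a template can never widen
what an archetype allows.

Flattening produces an operational template: a single constraint tree with
every filled slot replaced by the filler archetype's constraints, plus a
total provenance map back to the source archetypes.  Exclusion is modelled
as occurrences ``{0..0}`` rather than node deletion so provenance stays
total over the flattened tree.

Because two fillers of one slot may each contain an equally-named nested
slot, template paths are keyed ``<host-archetype-id>#<path-within-host>``;
the host prefix defaults to the root archetype.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .adl import (
    ArchetypeDefinition,
    ComplexObjectConstraint,
    Interval,
    PrimitiveConstraint,
    SlotConstraint,
)
from .report import ValidationReport
from .rm_core import Composition, Locatable
from .validator import ArchetypeRepository, validate_instance

__all__ = [
    "TemplateDefinition",
    "OperationalTemplate",
    "FormField",
    "FormSchema",
    "TemplateError",
    "load_template",
    "template_from_dict",
    "flatten",
    "validate_against_template",
    "form_schema",
]


class TemplateError(ValueError):
    """Unresolvable ids/paths, widening restrictions, or slot-fill cycles.

    Collects *all* offenders found during loading, not just the first."""

    def __init__(self, errors: Union[str, list[str]]):
        self.errors = [errors] if isinstance(errors, str) else list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class TemplateDefinition:
    name: str
    root_archetype: str
    slot_fills: dict[str, list[str]] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)
    code_bindings: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    occurrence_overrides: dict[str, Interval] = field(default_factory=dict)


@dataclass
class OperationalTemplate:
    name: str
    root: ComplexObjectConstraint
    #: flattened absolute path -> (source archetype id, source node id)
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: flattened absolute path -> (terminology id, allowed codes)
    bindings: dict[str, tuple[str, list[str]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _parse_interval_str(s: str) -> Interval:
    lo, _, up = s.partition("..")
    return Interval(lower=int(lo), upper=None if up == "*" else int(up))


def template_from_dict(data: dict) -> TemplateDefinition:
    bindings = {}
    for path, val in (data.get("code_bindings") or {}).items():
        term, codes = val
        bindings[path] = (term, list(codes))
    overrides = {}
    for path, val in (data.get("occurrence_overrides") or {}).items():
        overrides[path] = val if isinstance(val, Interval) else _parse_interval_str(val)
    return TemplateDefinition(
        name=data["name"],
        root_archetype=data["root_archetype"],
        slot_fills={k: list(v) for k, v in (data.get("slot_fills") or {}).items()},
        exclusions=list(data.get("exclusions") or []),
        code_bindings=bindings,
        occurrence_overrides=overrides,
    )


def load_template(
    source: Union[str, Path, dict],
    repo: ArchetypeRepository,
) -> TemplateDefinition:
    """Load and fully validate a template config (YAML file or dict).

    Every unresolvable archetype id or path, every exclusion of a mandatory
    node and every widening override is reported, together, as a
    :class:`TemplateError`.
    """
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    else:
        data = source
    tdef = template_from_dict(data)
    errors = _check_template(tdef, repo)
    if errors:
        raise TemplateError(errors)
    return tdef


def _split_key(key: str, root_id: str) -> tuple[str, str]:
    if "#" in key:
        host, _, path = key.partition("#")
        return host, path
    return root_id, key


def _resolve_constraint_path(root: ComplexObjectConstraint, path: str):
    """Node in a constraint tree addressed by /attr[atNNNN] segments."""
    node: Union[ComplexObjectConstraint, SlotConstraint] = root
    if path in ("", "/"):
        return node
    for seg in path.strip("/").split("/"):
        if not isinstance(node, ComplexObjectConstraint):
            return None
        attr_name, _, rest = seg.partition("[")
        nid = rest.rstrip("]")
        attr = next((a for a in node.attributes if a.name == attr_name), None)
        if attr is None:
            return None
        node = next(
            (c for c in attr.children
             if isinstance(c, (ComplexObjectConstraint, SlotConstraint))
             and c.node_id is not None and c.node_id.code == nid), None)
        if node is None:
            return None
    return node


def _check_template(tdef: TemplateDefinition, repo: ArchetypeRepository) -> list[str]:
    errors: list[str] = []
    if tdef.root_archetype not in repo:
        errors.append(f"root archetype {tdef.root_archetype!r} not in repository")
        return errors

    def host_root(host: str) -> Optional[ComplexObjectConstraint]:
        defn = repo.get(host)
        if defn is None:
            errors.append(f"archetype {host!r} not in repository")
            return None
        return defn.root

    for key, fillers in tdef.slot_fills.items():
        host, path = _split_key(key, tdef.root_archetype)
        root = host_root(host)
        if root is None:
            continue
        node = _resolve_constraint_path(root, path)
        if not isinstance(node, SlotConstraint):
            errors.append(f"slot fill {key!r} does not address a slot")
            continue
        allowed = {repo.canonical(i) for i in node.includes}
        for f in fillers:
            if f not in repo:
                errors.append(f"slot filler {f!r} (at {key!r}) not in repository")
            elif repo.canonical(f) not in allowed:
                errors.append(f"slot filler {f!r} not allowed by slot {key!r} "
                              f"includes")
    for key in tdef.exclusions:
        host, path = _split_key(key, tdef.root_archetype)
        root = host_root(host)
        if root is None:
            continue
        node = _resolve_constraint_path(root, path)
        if node is None:
            errors.append(f"exclusion path {key!r} does not resolve")
        elif node.occurrences.lower > 0:
            errors.append(f"cannot exclude mandatory node at {key!r} "
                          f"(occurrences {{{node.occurrences.render()}}})")
    for key, interval in tdef.occurrence_overrides.items():
        host, path = _split_key(key, tdef.root_archetype)
        root = host_root(host)
        if root is None:
            continue
        node = _resolve_constraint_path(root, path)
        if node is None:
            errors.append(f"override path {key!r} does not resolve")
        elif not interval.within(node.occurrences):
            errors.append(
                f"override {{{interval.render()}}} at {key!r} widens the "
                f"archetype's {{{node.occurrences.render()}}}")
    for key in tdef.code_bindings:
        host, path = _split_key(key, tdef.root_archetype)
        root = host_root(host)
        if root is None:
            continue
        node = _resolve_constraint_path(root, path)
        if not isinstance(node, ComplexObjectConstraint) or node.rm_type != "ELEMENT":
            errors.append(f"code binding path {key!r} does not address an element")
    return errors


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def flatten(tdef: TemplateDefinition, repo: ArchetypeRepository) -> OperationalTemplate:
    """Replace filled slots by their filler archetypes' constraint trees and
    apply the template's restrictions; provenance is total over all nodes."""
    root_defn = repo.get(tdef.root_archetype)
    if root_defn is None:
        raise TemplateError(f"root archetype {tdef.root_archetype!r} not in repository")
    root = copy.deepcopy(root_defn.root)
    root.archetype_ref = repo.canonical(tdef.root_archetype)
    opt = OperationalTemplate(name=tdef.name, root=root)
    host = repo.canonical(tdef.root_archetype)
    opt.provenance["/"] = (host, "at0000")
    _flatten_into(root, tdef, repo, opt, host, "", "", (host,))
    return opt


def _apply_restrictions(node, tdef: TemplateDefinition, host: str,
                        host_path: str, abs_path: str, opt: OperationalTemplate) -> None:
    key_full = f"{host}#{host_path}"
    keys = {key_full}
    if host == tdef.root_archetype:
        keys.add(host_path)
    if keys & set(tdef.exclusions):
        node.occurrences = Interval(0, 0)
    for k in keys:
        if k in tdef.occurrence_overrides:
            node.occurrences = tdef.occurrence_overrides[k]
        if k in tdef.code_bindings:
            opt.bindings[abs_path] = tdef.code_bindings[k]


def _flatten_into(
    node: ComplexObjectConstraint,
    tdef: TemplateDefinition,
    repo: ArchetypeRepository,
    opt: OperationalTemplate,
    host: str,
    host_path: str,
    abs_path: str,
    stack: tuple[str, ...],
) -> None:
    for attr in node.attributes:
        new_children = []
        for child in attr.children:
            if isinstance(child, PrimitiveConstraint):
                new_children.append(child)
                continue
            nid = child.node_id.code if child.node_id is not None else "?"
            child_hpath = f"{host_path}/{attr.name}[{nid}]"
            child_abs = f"{abs_path}/{attr.name}[{nid}]"
            if isinstance(child, SlotConstraint):
                fillers = _fills_for(tdef, host, child_hpath)
                if fillers is None:
                    opt.provenance[child_abs] = (host, nid)
                    _apply_restrictions(child, tdef, host, child_hpath,
                                        child_abs, opt)
                    new_children.append(child)
                    continue
                for filler_id in fillers:
                    fid = repo.canonical(filler_id)
                    if fid in stack:
                        raise TemplateError(
                            f"circular slot fill: {' -> '.join(stack + (fid,))}")
                    fdefn = repo.get(filler_id)
                    if fdefn is None:
                        raise TemplateError(
                            f"slot filler {filler_id!r} not in repository")
                    clone = copy.deepcopy(fdefn.root)
                    clone.node_id = child.node_id
                    clone.occurrences = Interval(0, child.occurrences.upper)
                    clone.archetype_ref = fid
                    opt.provenance[child_abs] = (fid, "at0000")
                    _apply_restrictions(clone, tdef, host, child_hpath,
                                        child_abs, opt)
                    _flatten_into(clone, tdef, repo, opt, fid, "",
                                  child_abs, stack + (fid,))
                    new_children.append(clone)
                continue
            # complex object within the host archetype
            opt.provenance[child_abs] = (host, nid)
            _apply_restrictions(child, tdef, host, child_hpath, child_abs, opt)
            _flatten_into(child, tdef, repo, opt, host, child_hpath,
                          child_abs, stack)
            new_children.append(child)
        attr.children = new_children


def _fills_for(tdef: TemplateDefinition, host: str, host_path: str) -> Optional[list[str]]:
    for key, fillers in tdef.slot_fills.items():
        k_host, k_path = _split_key(key, tdef.root_archetype)
        if k_host == host and k_path == host_path:
            return fillers
    return None


# ---------------------------------------------------------------------------
# Validation & forms
# ---------------------------------------------------------------------------

def validate_against_template(
    comp: Composition,
    opt: OperationalTemplate,
    repo: ArchetypeRepository,
) -> ValidationReport:
    """Validate a composition against a flattened template: archetype
    conformance plus the template's exclusions, narrowed occurrences and
    code bindings."""
    return validate_instance(comp, opt.root, repo, bindings=opt.bindings)


@dataclass(frozen=True)
class FormField:
    label: str
    path: str
    kind: str  # the DV type name of the element's value constraint
    required: bool
    allowed_codes: tuple[str, ...] = ()


@dataclass(frozen=True)
class FormSchema:
    name: str
    fields: tuple[FormField, ...]

    def to_json(self, indent: Optional[int] = 2) -> str:
        return json.dumps(
            {"name": self.name,
             "fields": [{"label": f.label, "path": f.path, "kind": f.kind,
                         "required": f.required,
                         "allowed_codes": list(f.allowed_codes)}
                        for f in self.fields]},
            indent=indent)


def form_schema(opt: OperationalTemplate) -> FormSchema:
    """One field per visible ELEMENT constraint, in document order; a field
    is required iff its occurrences lower bound is at least 1."""
    fields: list[FormField] = []

    def visit(node: ComplexObjectConstraint, abs_path: str) -> None:
        if node.occurrences.upper == 0:
            return  # excluded from the form
        for attr in node.attributes:
            for child in attr.children:
                if isinstance(child, ComplexObjectConstraint):
                    nid = child.node_id.code if child.node_id else "?"
                    child_abs = f"{abs_path}/{attr.name}[{nid}]"
                    if child.rm_type == "ELEMENT":
                        if child.occurrences.upper == 0:
                            continue
                        kind = "DV_TEXT"
                        for a in child.attributes:
                            if a.name == "value":
                                for p in a.children:
                                    if isinstance(p, PrimitiveConstraint):
                                        kind = p.rm_type
                        term = opt.bindings.get(child_abs)
                        fields.append(FormField(
                            label=child.label or nid,
                            path=child_abs,
                            kind=kind,
                            required=child.occurrences.lower >= 1,
                            allowed_codes=tuple(term[1]) if term else ()))
                    else:
                        visit(child, child_abs)

    visit(opt.root, "")
    return FormSchema(name=opt.name, fields=tuple(fields))
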