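"""Seedable generator of valid claim/authorization compositions, plus a
single-violation mutant generator for validator testing.

The generator is valid-by-construction: it walks a flattened template and
emits one instance node per constraint (honouring occurrences), drawing
values from label-aware pools — opaque Brazilian-style identifiers (provider
registry, health-plan and patient numbers), procedure and diagnosis codes as
opaque strings, coherent dates (admission ≤ discharge, requested days ≤
authorized days) and non-negative costs.  One RNG stream is derived per
composition from ``(seed, template, index)``, so adding templates never
shifts existing outputs and equal configs yield byte-identical documents.

No statistical realism of claim volumes or cost distributions is attempted.
"""

from __future__ import annotations

import copy
import datetime as _dt
import random
from dataclasses import dataclass, field, replace
from decimal import Decimal
from typing import Optional

from . import fixtures
from .exchange import Clock, IdSource, package_extract
from .exchange_types import Extract
from .report import Rule, ValidationFinding
from .rm_core import (
    AdminEntry,
    Cluster,
    CodedTextValue,
    Composition,
    CountValue,
    DateTimeValue,
    Element,
    Entry,
    IdentifierValue,
    ItemList,
    ItemTree,
    Link,
    Locatable,
    MoneyValue,
    NodeId,
    Participation,
    PartyIdentified,
    TextValue,
    children,
    walk,
)
from .rm_extension import ClaimStatus, STATUS_TERMINOLOGY
from .templates import (
    OperationalTemplate,
    flatten,
    load_template,
)
from .adl import ComplexObjectConstraint, PrimitiveConstraint, SlotConstraint
from .validator import ArchetypeRepository

__all__ = [
    "GeneratorConfig",
    "MutationNotApplicable",
    "default_context",
    "generate_composition",
    "mutate_for_violation",
    "generate_scenario",
]


# value pools: abstract stand-ins for Brazilian billing identifiers/codes
PATIENTS = ("Ana Souza", "Bruno Lima", "Carla Mendes", "Diego Santos",
            "Elisa Ferreira", "Fabio Alves", "Gloria Pinto", "Hugo Ramos")
PROFESSIONALS = ("Helena Castro", "Igor Nunes", "Julia Prado", "Marcos Reis")
PROVIDERS = (("Hospital Santa Clara", "CNES-001234"),
             ("Clinica Vida", "CNES-005678"),
             ("Laboratorio Lumen", "CNES-009012"))
PAYERS = (("Plano Saude Total", "ANS-41001"),
          ("Unimed Horizonte", "ANS-42002"))
PROCEDURE_CODES = ("10101012", "20103044", "30204010", "40304361", "50000470")
DIAGNOSIS_CODES = ("A09", "E11.9", "I10", "J18.9", "S42.2", "Z34.0")
GENERIC_TEXTS = ("not applicable", "routine", "chronic condition",
                 "acute episode", "see attached report")
ENCOUNTER_TYPES = ("consultation", "exam", "hospitalization", "dental care")
CLAIM_TYPES = ("consultation", "exam", "hospitalization", "dental")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    template: str = "admission_claim"
    index: int = 0
    n_requests: int = 1
    n_claims: int = 0
    with_original_submission: bool = False
    invalid_mutation: Optional[str] = None  # a Rule name, applied post-generation

    def stream(self) -> random.Random:
        return random.Random(f"{self.seed}:{self.template}:{self.index}")


class MutationNotApplicable(Exception):
    """The requested violation cannot be produced on this composition."""


_CONTEXT_CACHE: dict[int, tuple[ArchetypeRepository, dict[str, OperationalTemplate]]] = {}


def default_context(approach: int = 1):
    """(repository, flattened templates) for one approach's fixture set."""
    if approach not in _CONTEXT_CACHE:
        repo = fixtures.default_repository(approach)
        opts = {}
        if approach == 1:
            for name, spec in fixtures.template_specs().items():
                opts[name] = flatten(load_template(spec, repo), repo)
        _CONTEXT_CACHE[approach] = (repo, opts)
    return _CONTEXT_CACHE[approach]


# ---------------------------------------------------------------------------
# Value synthesis
# ---------------------------------------------------------------------------

class _Ctx:
    """Per-composition state keeping dates and counts coherent."""

    def __init__(self, rng: random.Random, cfg: GeneratorConfig):
        self.rng = rng
        self.cfg = cfg
        self.base_date = _dt.date(2026, 1, 5) + _dt.timedelta(days=rng.randrange(180))
        self.stay_days = rng.randrange(1, 11)
        self.requested_days = rng.randrange(1, 8)
        self.patient = PartyIdentified(
            name=rng.choice(PATIENTS),
            identifiers=(IdentifierValue(f"PAT-{rng.randrange(10**6):06d}",
                                         "health plan", "patient number"),))
        # organizations depend on the seed only, so every composition of one
        # scenario shares a provider/payer pair
        org_rng = random.Random(f"{cfg.seed}:orgs")
        pname, pid = org_rng.choice(PROVIDERS)
        self.provider_org = PartyIdentified(
            name=pname, identifiers=(IdentifierValue(pid, "national registry",
                                                     "provider id"),))
        yname, yid = org_rng.choice(PAYERS)
        self.payer_org = PartyIdentified(
            name=yname, identifiers=(IdentifierValue(yid, "regulator",
                                                     "payer id"),))
        self.professional = PartyIdentified(
            name=rng.choice(PROFESSIONALS),
            identifiers=(IdentifierValue(f"CRM-{rng.randrange(10**5):05d}",
                                         "professional council", "license"),))

    def date(self, offset: int = 0) -> str:
        return (self.base_date + _dt.timedelta(days=offset)).isoformat()

    def timestamp(self) -> str:
        return f"{self.date()}T{8 + self.rng.randrange(9):02d}:00:00"


def _value_for(label: str, dv: str, ctx: _Ctx,
               binding: Optional[tuple[str, list[str]]]):
    rng = ctx.rng
    key = " ".join(label.lower().split())
    if binding is not None:
        code = rng.choice(binding[1])
        return CodedTextValue(value=code, code=code, terminology_id=binding[0])
    if dv == "DV_DATE_TIME":
        return DateTimeValue(ctx.timestamp())
    if dv == "DV_COUNT":
        if key == "requested number of days":
            return CountValue(ctx.requested_days)
        if key == "authorized number of days":
            return CountValue(ctx.requested_days + rng.randrange(0, 4))
        if "quantity" in key:
            q = rng.randrange(1, 6)
            return CountValue(q)
        return CountValue(rng.randrange(0, 5))
    if dv == "DV_MONEY":
        return MoneyValue(Decimal(rng.randrange(1000, 500000)) / 100, "BRL")
    # DV_TEXT family, label-driven
    if key == "submission id":
        return TextValue(f"SUB-{ctx.cfg.index:03d}-{rng.randrange(10**6):06d}")
    if key == "original submission":
        return TextValue(f"SUB-{rng.randrange(10**6):06d}")
    if key == "authorization number":
        return TextValue(f"AUT-{rng.randrange(10**6):06d}")
    if key == "status":
        s = ClaimStatus.SUBMITTED
        return CodedTextValue(value=s.display, code=s.value,
                              terminology_id=STATUS_TERMINOLOGY)
    if key == "validity":
        start = ctx.date()
        end = (ctx.base_date + _dt.timedelta(days=30)).isoformat()
        return TextValue(f"{start}/{end}")
    if key == "submission date":
        return TextValue(ctx.date())
    if key in ("billing date", "authorization date"):
        return TextValue(ctx.date(1))
    if key in ("date of admission", "probable date of admission"):
        return TextValue(ctx.date())
    if key == "discharge date":
        return TextValue(ctx.date(ctx.stay_days))
    if "date" in key:
        return TextValue(ctx.date())
    if key == "type of encounter":
        return TextValue(rng.choice(ENCOUNTER_TYPES))
    if key == "type of claim":
        return TextValue(rng.choice(CLAIM_TYPES))
    if key in ("procedure", "type of procedure"):
        return TextValue(rng.choice(PROCEDURE_CODES))
    if key in ("main diagnosis", "secondary diagnoses", "clinical indication"):
        return TextValue(rng.choice(DIAGNOSIS_CODES))
    if key == "tooth":
        return TextValue(str(rng.choice((11, 12, 21, 26, 36, 48))))
    if key == "face":
        return TextValue(rng.choice(("M", "D", "V", "L", "O")))
    if key == "vendor":
        return TextValue(rng.choice(("OrtoMed", "ProteseLab", "BioSupply")))
    return TextValue(rng.choice(GENERIC_TEXTS))


_ALWAYS_INCLUDE = {
    "submission id", "submission date", "billing date", "status",
    "authorization number", "validity", "date of encounter",
    "type of encounter", "authorization date",
}


def _include_element(c: ComplexObjectConstraint, ctx: _Ctx) -> bool:
    if c.occurrences.upper == 0:
        return False
    if c.occurrences.lower >= 1:
        return True
    key = " ".join((c.label or "").lower().split())
    if key == "original submission":
        return ctx.cfg.with_original_submission
    if key in _ALWAYS_INCLUDE:
        return True
    return ctx.rng.random() < 0.85


# ---------------------------------------------------------------------------
# Instance building
# ---------------------------------------------------------------------------

def _element_kind(c: ComplexObjectConstraint) -> str:
    for a in c.attributes:
        if a.name == "value":
            for p in a.children:
                if isinstance(p, PrimitiveConstraint):
                    return p.rm_type
    return "DV_TEXT"


def _build_items(attr_children, ctx: _Ctx, opt: OperationalTemplate,
                 abs_path: str, attr_name: str) -> list:
    items = []
    for c in attr_children:
        if isinstance(c, SlotConstraint):
            continue  # unfilled slot: nothing to instantiate
        if not isinstance(c, ComplexObjectConstraint):
            continue
        nid = c.node_id.code if c.node_id else "?"
        child_abs = f"{abs_path}/{attr_name}[{nid}]"
        if c.rm_type == "ELEMENT":
            if not _include_element(c, ctx):
                continue
            items.append(Element(
                name=c.label or nid,
                archetype_node_id=NodeId(nid),
                value=_value_for(c.label or "", _element_kind(c), ctx,
                                 opt.bindings.get(child_abs))))
        elif c.rm_type == "CLUSTER":
            if c.occurrences.upper == 0:
                continue
            if c.occurrences.lower < 1 and ctx.rng.random() > 0.9:
                continue
            sub_attr = next((a for a in c.attributes if a.name == "items"), None)
            sub = _build_items(sub_attr.children if sub_attr else [], ctx, opt,
                               child_abs, "items")
            if not sub:
                continue  # a cluster must carry at least one item
            items.append(Cluster(
                name=c.label or nid, archetype_node_id=NodeId(nid),
                archetype_id=c.archetype_ref, items=sub))
    return items


def _build_entry(c: ComplexObjectConstraint, ctx: _Ctx,
                 opt: OperationalTemplate, abs_path: str) -> Entry:
    import tisskit.rm_core as rm
    cls = rm.RM_CLASS_REGISTRY[c.rm_type]
    nid = c.node_id.code if c.node_id else "at0001"
    data_attr = next((a for a in c.attributes if a.name == "data"), None)
    tree = None
    if data_attr:
        tree_c = next((t for t in data_attr.children
                       if isinstance(t, ComplexObjectConstraint)), None)
        if tree_c is not None:
            t_nid = tree_c.node_id.code if tree_c.node_id else "at0001"
            t_abs = f"{abs_path}/data[{t_nid}]"
            items_attr = next((a for a in tree_c.attributes
                               if a.name == "items"), None)
            tree = ItemTree(
                name=tree_c.label or "components",
                archetype_node_id=NodeId(t_nid),
                items=_build_items(items_attr.children if items_attr else [],
                                   ctx, opt, t_abs, "items"))

    kwargs = dict(
        name=c.label or nid,
        archetype_node_id=NodeId(nid),
        archetype_id=c.archetype_ref,
        subject=ctx.patient,
        data=tree,
    )
    if issubclass(cls, AdminEntry):
        participations = [Participation(ctx.provider_org, "submitter"),
                          Participation(ctx.payer_org, "submittee")]
        concept = (c.archetype_ref or "").rsplit(".", 2)[-2] \
            if c.archetype_ref else ""
        if concept == "institutional_claim":
            participations.append(Participation(ctx.professional, "participant"))
            kwargs.update(provider=None)
        else:
            kwargs.update(provider=ctx.professional)
        kwargs.update(other_participations=participations)
    else:
        kwargs.update(provider=ctx.professional)
    return cls(**kwargs)


def generate_composition(
    cfg: GeneratorConfig,
    repo: Optional[ArchetypeRepository] = None,
    templates: Optional[dict[str, OperationalTemplate]] = None,
) -> Composition:
    """A composition valid against the named template, deterministic in the
    config."""
    if repo is None or templates is None:
        repo, templates = default_context()
    if cfg.template not in templates:
        raise KeyError(f"unknown template {cfg.template!r}; "
                       f"known: {sorted(templates)}")
    opt = templates[cfg.template]
    rng = cfg.stream()
    ctx = _Ctx(rng, cfg)

    content = []
    content_attr = next((a for a in opt.root.attributes if a.name == "content"),
                        None)
    for c in (content_attr.children if content_attr else []):
        if isinstance(c, ComplexObjectConstraint) and c.archetype_ref:
            nid = c.node_id.code if c.node_id else "?"
            content.append(_build_entry(c, ctx, opt, f"/content[{nid}]"))

    _link_services_to_diagnoses(content)

    comp = Composition(
        name=cfg.template,
        archetype_node_id=NodeId("at0000"),
        archetype_id=opt.root.archetype_ref or "openEHR-EHR-COMPOSITION.tiss_claim.v1",
        composer=ctx.provider_org,
        context_start_time=DateTimeValue(ctx.timestamp()),
        content=content,
    )
    if cfg.invalid_mutation:
        comp, _finding = mutate_for_violation(comp, Rule(cfg.invalid_mutation),
                                              rng, opt)
    return comp


def _link_services_to_diagnoses(content: list) -> None:
    """Tie a services entry to the evaluation's diagnosis elements with LINKs
    (a performed service may relate to several diagnoses)."""
    action = next((e for e in content
                   if (e.archetype_id or "").endswith("claim_services.v1")), None)
    evaluation = next((e for e in content
                       if (e.archetype_id or "").endswith("patient_evaluation.v1")),
                      None)
    if action is None or evaluation is None:
        return
    for path, node in walk(evaluation):
        if isinstance(node, Element) and node.name in (
                "main diagnosis", "secondary diagnoses"):
            action.links.append(Link(
                meaning="service relates to diagnosis", type="diagnosis",
                target=f"{evaluation.archetype_id}#{path}"))


# ---------------------------------------------------------------------------
# Mutants
# ---------------------------------------------------------------------------

def _paired_walk(inst: Locatable, constraint: ComplexObjectConstraint,
                 path: str = ""):
    """Walk instance and constraint trees together, disambiguating sibling
    slot fillers (which share a node id) by archetype reference."""
    yield (path or "/", inst, constraint)
    for attr_c in constraint.attributes:
        for attr_name, _i, child in children(inst):
            if attr_name != attr_c.name:
                continue
            match = None
            for c in attr_c.children:
                if not isinstance(c, ComplexObjectConstraint) or c.node_id is None:
                    continue
                if c.node_id != child.archetype_node_id:
                    continue
                if c.archetype_ref is not None and child.archetype_id is not None \
                        and c.archetype_ref != child.archetype_id:
                    continue
                match = c
                break
            if match is not None:
                cpath = f"{path}/{attr_name}[{child.archetype_node_id.code}]"
                yield from _paired_walk(child, match, cpath)


def _find_parent(root: Locatable, target: Locatable):
    for _path, node in walk(root):
        for attr, _i, child in children(node):
            if child is target:
                return node, attr
    return None, None


def _instance_at(comp: Composition, want_path: str) -> Optional[Locatable]:
    for path, node in walk(comp):
        if path == want_path:
            return node
    return None


def mutate_for_violation(
    comp: Composition,
    rule: Rule,
    rng: random.Random,
    opt: OperationalTemplate,
) -> tuple[Composition, ValidationFinding]:
    """A minimally mutated deep copy guaranteed to trigger ``rule`` at the
    returned finding's path; the original is untouched.  Raises
    :class:`MutationNotApplicable` when the composition offers no site for
    the rule (e.g. no bound coded element for a binding violation)."""
    rule = Rule(rule)
    mutant = copy.deepcopy(comp)

    def sites(pred) -> list[tuple[str, Locatable]]:
        return [(path, node)
                for path, node, c in _paired_walk(mutant, opt.root)
                if path != "/" and pred(path, node, c)]

    if rule is Rule.OCCURRENCES_EXCEEDED:
        cands = sites(lambda p, n, c: isinstance(n, Element)
                      and isinstance(c, ComplexObjectConstraint)
                      and c.occurrences.upper == 1)
        if not cands:
            raise MutationNotApplicable("no single-occurrence element present")
        path, node = rng.choice(cands)
        parent, _attr = _find_parent(mutant, node)
        parent.items.append(copy.deepcopy(node))
        return mutant, ValidationFinding(path, rule, "duplicated element")

    if rule is Rule.OCCURRENCES_UNMET:
        cands = sites(lambda p, n, c: isinstance(n, Element)
                      and c.occurrences.lower >= 1)
        if not cands:
            raise MutationNotApplicable("template mandates no element")
        path, node = rng.choice(cands)
        parent, _attr = _find_parent(mutant, node)
        parent.items.remove(node)
        return mutant, ValidationFinding(path, rule, "removed mandatory element")

    if rule is Rule.CARDINALITY_VIOLATION:
        cands = []
        for path, node, c in _paired_walk(mutant, opt.root):
            if isinstance(node, Cluster):
                attr = next((a for a in c.attributes if a.name == "items"), None)
                if attr is not None and attr.cardinality is not None \
                        and attr.cardinality.upper is not None:
                    cands.append((path, node, attr.cardinality.upper))
        if not cands:
            raise MutationNotApplicable("no bounded-cardinality cluster present")
        path, node, upper = cands[0]
        while len(node.items) <= upper:
            node.items.append(copy.deepcopy(node.items[0]))
        return mutant, ValidationFinding(path, rule, "overfilled cluster")

    if rule is Rule.VALUE_TYPE_MISMATCH:
        cands = sites(lambda p, n, c: isinstance(n, Element)
                      and isinstance(c, ComplexObjectConstraint)
                      and _element_kind(c) == "DV_DATE_TIME")
        if not cands:
            raise MutationNotApplicable("no timestamp-typed element present")
        path, node = rng.choice(cands)
        node.value = CountValue(1)
        return mutant, ValidationFinding(path, rule, "wrong value variant")

    if rule is Rule.NODE_ID_UNKNOWN:
        cands = sites(lambda p, n, c: isinstance(n, Element))
        if not cands:
            raise MutationNotApplicable("no element present")
        path, node = rng.choice(cands)
        node.archetype_node_id = NodeId("at9999")
        new_path = path.rsplit("[", 1)[0] + "[at9999]"
        return mutant, ValidationFinding(new_path, rule, "foreign node id")

    if rule is Rule.RM_TYPE_MISMATCH:
        for path, node in walk(mutant):
            if isinstance(node, ItemTree):
                parent, _attr = _find_parent(mutant, node)
                replacement = ItemList(
                    name=node.name, archetype_node_id=node.archetype_node_id,
                    items=[i for i in node.items if isinstance(i, Element)])
                parent.data = replacement
                return mutant, ValidationFinding(path, rule,
                                                 "item tree replaced by list")
        raise MutationNotApplicable("no item tree present")

    if rule is Rule.SLOT_INCLUDE_VIOLATION:
        entry = next((e for e in mutant.content), None)
        if entry is None:
            raise MutationNotApplicable("empty composition")
        entry.archetype_id = "openEHR-EHR-SECTION.unrelated.v1"
        return mutant, ValidationFinding(
            f"/content[{entry.archetype_node_id.code}]", rule,
            "foreign archetype at slot position")

    if rule is Rule.SLOT_FILLER_INVALID:
        entry = next((e for e in mutant.content), None)
        if entry is None:
            raise MutationNotApplicable("empty composition")
        entry.archetype_id = None
        return mutant, ValidationFinding(
            f"/content[{entry.archetype_node_id.code}]", rule,
            "filler without archetype id")

    if rule is Rule.CODE_BINDING_VIOLATION:
        for bpath in sorted(opt.bindings):
            for path, node in walk(mutant):
                if path == bpath and isinstance(node, Element) \
                        and isinstance(node.value, CodedTextValue):
                    node.value = replace(node.value, code="__OUT_OF_BINDING__")
                    return mutant, ValidationFinding(bpath, rule,
                                                     "code outside binding")
        raise MutationNotApplicable("no bound coded element present")

    raise MutationNotApplicable(f"no mutation strategy for rule {rule.value}")


# ---------------------------------------------------------------------------
# Random constraint trees (for parser round-trip property testing)
# ---------------------------------------------------------------------------

_RAND_RM = ("ADMIN_ENTRY", "EVALUATION", "ACTION", "OBSERVATION")
_RAND_DV = ("DV_TEXT", "DV_DATE_TIME", "DV_COUNT", "DV_MONEY")
_RAND_WORDS = ("alpha", "beta", "gamma", "delta", "cost", "date", "status",
               "procedure", "quantity", "reason")


def random_archetype(rng: random.Random, max_depth: int = 3):
    """A random archetype definition in the supported ADL dialect; used to
    property-test the parse ∘ serialize identity."""
    from .adl import (ArchetypeDefinition, AttributeConstraint,
                      ComplexObjectConstraint, Interval, PrimitiveConstraint,
                      SlotConstraint, parse_archetype_id)
    counter = [2]

    def nid() -> NodeId:
        n = NodeId(f"at{counter[0]:04d}")
        counter[0] += 1
        return n

    def interval(ordered: Optional[bool] = None) -> Interval:
        lo = rng.choice((0, 0, 1))
        up = rng.choice((lo or 1, None))
        return Interval(lo, up, ordered)

    def label() -> Optional[str]:
        if rng.random() < 0.2:
            return None
        return " ".join(rng.sample(_RAND_WORDS, rng.randrange(1, 3)))

    def element() -> ComplexObjectConstraint:
        return ComplexObjectConstraint(
            rm_type="ELEMENT", node_id=nid(), occurrences=interval(),
            label=label(),
            attributes=[AttributeConstraint("value", children=[
                PrimitiveConstraint(rng.choice(_RAND_DV))])])

    def slot() -> SlotConstraint:
        return SlotConstraint(
            rm_type="CLUSTER", node_id=nid(), occurrences=interval(),
            includes=[f"openEHR-EHR-CLUSTER.{w}.v1"
                      for w in rng.sample(_RAND_WORDS, rng.randrange(1, 3))])

    def cluster(depth: int) -> ComplexObjectConstraint:
        n = ComplexObjectConstraint(
            rm_type="CLUSTER", node_id=nid(), occurrences=interval(),
            label=label())
        n.attributes.append(AttributeConstraint(
            "items", cardinality=interval(ordered=rng.random() < 0.5),
            children=items(depth - 1)))
        return n

    def items(depth: int) -> list:
        out = []
        for _ in range(rng.randrange(1, 5)):
            r = rng.random()
            if r < 0.6 or depth <= 0:
                out.append(element())
            elif r < 0.8:
                out.append(cluster(depth))
            else:
                out.append(slot())
        return out

    tree = ComplexObjectConstraint(
        rm_type="ITEM_TREE", node_id=NodeId("at0001"), label="components",
        attributes=[AttributeConstraint(
            "items", cardinality=Interval(0, None, ordered=False),
            children=items(max_depth))])
    root = ComplexObjectConstraint(
        rm_type=rng.choice(_RAND_RM), node_id=NodeId("at0000"),
        label=label(),
        attributes=[AttributeConstraint("data", children=[tree])])
    concept = f"{rng.choice(_RAND_WORDS)}_{rng.randrange(100)}"
    aid = parse_archetype_id(
        f"openEHR-EHR-{root.rm_type}.{concept}.v{rng.randrange(1, 4)}")
    return ArchetypeDefinition(id=aid, root=root)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def generate_scenario(
    cfg: GeneratorConfig,
    repo: Optional[ArchetypeRepository] = None,
    templates: Optional[dict[str, OperationalTemplate]] = None,
) -> list[tuple[str, Extract]]:
    """Provider → payer extracts: authorization requests, then (optionally)
    claims.  Deterministic under the config's seed."""
    if repo is None or templates is None:
        repo, templates = default_context()
    id_source = IdSource(namespace=f"s{cfg.seed}")
    clock = Clock()
    comps: list[Composition] = []
    for i in range(cfg.n_requests):
        comps.append(generate_composition(
            replace(cfg, template="admission_request", index=i),
            repo, templates))
    claim_comps: list[Composition] = []
    for i in range(cfg.n_claims):
        claim_comps.append(generate_composition(
            replace(cfg, template="admission_claim", index=cfg.n_requests + i),
            repo, templates))

    first = comps[0].content[0] if comps else claim_comps[0].content[0]
    provider = next(p.performer for p in first.other_participations
                    if p.function == "submitter")
    payer = next(p.performer for p in first.other_participations
                 if p.function == "submittee")
    scenario: list[tuple[str, Extract]] = []
    if comps:
        scenario.append(("provider", package_extract(
            comps, provider, payer, id_source, created_at=clock.tick())))
    if claim_comps:
        scenario.append(("provider", package_extract(
            claim_comps, provider, payer, id_source, created_at=clock.tick())))
    return scenario
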