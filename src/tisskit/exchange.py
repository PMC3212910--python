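"""Simulated provider ↔ payer exchange of claim/authorization extracts.

Compositions are grouped into an :class:`~tisskit.exchange_types.Extract`,
stored by a REST-style in-process transport (``/{organization_id}/{resource_id}``
resources with GET/POST/PUT/DELETE semantics), adjudicated by the payer under
a user-supplied policy, and answered with a response extract whose
source/target organizations are swapped.  The transport is an in-process
contract so simulations need no network; every identifier and timestamp
comes from seedable counters and a fixed clock, making whole runs
byte-reproducible.

The payer's decision logic is not fixed: an :class:`AdjudicationPolicy` maps
submission types (and an optional cost ceiling) to approve / deny /
return-for-correction / pend.  A structurally invalid composition is always
returned for correction, with the validation report attached as an ANNEX.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from .exchange_types import Extract, ExtractItem
from .report import ValidationReport
from .rm_core import (
    AdminEntry,
    Composition,
    Element,
    ItemTree,
    Link,
    MoneyValue,
    NodeId,
    PartyIdentified,
    TextValue,
    walk,
)
from .rm_extension import (
    Annex,
    Authorization,
    ClaimStatus,
    ConversionError,
    DateInterval,
    IsmTransition,
    LifecycleHistory,
    Submission,
    apply_transition,
    convert_base_to_extended,
)
from .templates import OperationalTemplate, validate_against_template
from .validator import ArchetypeRepository

__all__ = [
    "Extract", "ExtractItem", "IdSource", "Clock", "Response",
    "ResourceStore", "AdjudicationPolicy", "ExchangeLog",
    "package_extract", "adjudicate", "run_roundtrip",
    "transport_get", "transport_post", "transport_put", "transport_delete",
]


class IdSource:
    """Deterministic monotonically-increasing id generator, per kind."""

    def __init__(self, namespace: str = ""):
        self.namespace = namespace
        self._counters: dict[str, int] = {}

    def next(self, kind: str) -> str:
        n = self._counters.get(kind, 0) + 1
        self._counters[kind] = n
        prefix = f"{self.namespace}-" if self.namespace else ""
        return f"{prefix}{kind}-{n:06d}"


@dataclass
class Clock:
    """Fixed, stepping clock: every tick advances by a constant interval."""

    start: str = "2026-01-05T08:00:00"
    step_seconds: int = 60
    _ticks: int = 0

    def now(self) -> str:
        t = _dt.datetime.fromisoformat(self.start) + \
            _dt.timedelta(seconds=self.step_seconds * self._ticks)
        return t.isoformat()

    def tick(self) -> str:
        out = self.now()
        self._ticks += 1
        return out

    def today(self) -> str:
        return _dt.datetime.fromisoformat(self.now()).date().isoformat()


# ---------------------------------------------------------------------------
# Extract packaging
# ---------------------------------------------------------------------------

def _submission_entry(comp: Composition) -> Optional[AdminEntry]:
    for entry in comp.content:
        if isinstance(entry, AdminEntry):
            return entry
    return None


def package_extract(
    comps: list[Composition],
    source: PartyIdentified,
    target: PartyIdentified,
    id_source: IdSource,
    created_at: str = "2026-01-05T08:00:00",
) -> Extract:
    """Group compositions by record subject into one outbound extract."""
    if not comps:
        raise ValueError("cannot package an empty list of compositions")
    items: list[ExtractItem] = []
    index: dict[tuple, ExtractItem] = {}
    for comp in comps:
        entry = _submission_entry(comp)
        if entry is None:
            raise ValueError(
                f"composition {comp.name!r} carries no administrative entry")
        subject = entry.subject
        if not isinstance(subject, PartyIdentified):
            raise ValueError(
                f"composition {comp.name!r} subject is not an identified party")
        key = (subject.name, subject.identifiers)
        if key not in index:
            item = ExtractItem(subject=subject)
            index[key] = item
            items.append(item)
        index[key].compositions.append(comp)
    return Extract(
        extract_id=id_source.next("EXT"),
        source_org=source,
        target_org=target,
        created_at=created_at,
        items=items,
    )


# ---------------------------------------------------------------------------
# Transport
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Response:
    status: int
    resource_id: Optional[str] = None
    payload: Optional[str] = None


class ResourceStore:
    """In-process resource store: ``/{organization_id}/{resource_id}``."""

    def __init__(self):
        self._orgs: set[str] = set()
        self._data: dict[tuple[str, str], str] = {}
        self._counters: dict[str, int] = {}
        self.log: list[dict] = []

    def register(self, org_id: str) -> None:
        self._orgs.add(org_id)

    def _check_org(self, org_id: str) -> None:
        if org_id not in self._orgs:
            raise KeyError(f"organization {org_id!r} is not registered")

    def _log(self, op: str, org: str, rid: Optional[str], status: int) -> None:
        self.log.append({"op": op, "org": org, "resource": rid, "status": status})

    def _new_id(self, org: str) -> str:
        n = self._counters.get(org, 0) + 1
        self._counters[org] = n
        return f"r{n:06d}"

    def resources(self, org_id: str) -> list[str]:
        return sorted(rid for (o, rid) in self._data if o == org_id)


def transport_post(store: ResourceStore, org_id: str, payload: str) -> Response:
    """Create a resource with a server-assigned id."""
    store._check_org(org_id)
    rid = store._new_id(org_id)
    store._data[(org_id, rid)] = payload
    store._log("POST", org_id, rid, 201)
    return Response(201, resource_id=rid)


def transport_put(store: ResourceStore, org_id: str, resource_id: str,
                  payload: str) -> Response:
    """Idempotent upsert at a client-chosen id."""
    store._check_org(org_id)
    created = (org_id, resource_id) not in store._data
    store._data[(org_id, resource_id)] = payload
    status = 201 if created else 200
    store._log("PUT", org_id, resource_id, status)
    return Response(status, resource_id=resource_id)


def transport_get(store: ResourceStore, org_id: str, resource_id: str) -> Response:
    store._check_org(org_id)
    payload = store._data.get((org_id, resource_id))
    status = 200 if payload is not None else 404
    store._log("GET", org_id, resource_id, status)
    return Response(status, resource_id=resource_id, payload=payload)


def transport_delete(store: ResourceStore, org_id: str, resource_id: str) -> Response:
    store._check_org(org_id)
    existed = store._data.pop((org_id, resource_id), None) is not None
    status = 204 if existed else 404
    store._log("DELETE", org_id, resource_id, status)
    return Response(status, resource_id=resource_id)


# ---------------------------------------------------------------------------
# Adjudication
# ---------------------------------------------------------------------------

_DECISIONS = ("approve", "deny", "return_for_correction", "pend")
_DECISION_STATE = {
    "approve": ClaimStatus.COMPLETED,
    "deny": ClaimStatus.DENIED,
    "return_for_correction": ClaimStatus.RETURNED_FOR_CORRECTION,
    "pend": ClaimStatus.PENDING,
}


@dataclass
class AdjudicationPolicy:
    """Payer decision rules.

    ``rules`` maps a submission concept (``authorization_request``,
    ``professional_claim``, ...) to a decision; unmatched submissions get
    ``default``.  ``max_total`` (optional) denies any claim whose summed
    monetary elements exceed it.  ``validity_days`` sizes the validity
    period granted with approved authorizations.
    """

    default: str = "approve"
    rules: dict[str, str] = field(default_factory=dict)
    validity_days: int = 30
    max_total: Optional[float] = None

    def __post_init__(self) -> None:
        for d in [self.default, *self.rules.values()]:
            if d not in _DECISIONS:
                raise ValueError(f"unknown decision {d!r}; expected one of {_DECISIONS}")

    @classmethod
    def approve_all(cls, validity_days: int = 30) -> "AdjudicationPolicy":
        return cls(default="approve", validity_days=validity_days)

    @classmethod
    def deny_all(cls) -> "AdjudicationPolicy":
        return cls(default="deny")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AdjudicationPolicy":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(default=data.get("default", "approve"),
                   rules=dict(data.get("rules", {})),
                   validity_days=int(data.get("validity_days", 30)),
                   max_total=data.get("max_total"))

    def decide(self, sub: Submission) -> str:
        concept = (sub.archetype_id or "").rsplit(".", 2)[-2] \
            if sub.archetype_id else ""
        decision = self.rules.get(concept, self.default)
        if decision == "approve" and self.max_total is not None:
            total = sum(
                n.value.amount for _p, n in walk(sub)
                if isinstance(n, Element) and isinstance(n.value, MoneyValue))
            if float(total) > self.max_total:
                return "deny"
        return decision


def _report_annex(sub_id: str, report: ValidationReport, id_source: IdSource,
                  submitter: PartyIdentified, submittee: PartyIdentified,
                  subject, when: str) -> Annex:
    items = [Element(
        name="finding",
        archetype_node_id=NodeId(f"at{2 + i:04d}"),
        value=TextValue(f"{f.rule.value} at {f.path}: {f.detail}"))
        for i, f in enumerate(report.sorted().findings)]
    if not items:
        items = [Element(name="finding", archetype_node_id=NodeId("at0002"),
                         value=TextValue("no findings"))]
    return Annex(
        name="validation report",
        archetype_node_id=NodeId("at0000"),
        archetype_id="openEHR-EHR-ANNEX.validation_report.v1",
        subject=subject,
        submission_id=id_source.next("ANX"),
        submission_date=when[:10],
        submitter=submitter,
        submittee=submittee,
        complements=sub_id,
        data=ItemTree(name="findings", archetype_node_id=NodeId("at0001"),
                      items=items),
    )


def adjudicate(
    extract: Extract,
    policy: AdjudicationPolicy,
    clock: Clock,
    id_source: IdSource,
    repo: Optional[ArchetypeRepository] = None,
    templates: Optional[dict[str, OperationalTemplate]] = None,
    histories: Optional[dict[str, LifecycleHistory]] = None,
) -> Extract:
    """Process one inbound extract and produce the payer's response extract.

    Emits exactly one response composition per request composition.  Each
    request's lifecycle history (keyed by submission id, tracked in
    ``histories``) is extended only through legal transitions: SUBMITTED on
    receipt (initial or resubmission), then the decision's state.  A
    composition that fails template validation is returned for correction
    with the report attached as an annex.
    """
    histories = histories if histories is not None else {}
    response_items: list[ExtractItem] = []
    for item in extract.items:
        responses: list[Composition] = []
        for comp in item.compositions:
            responses.append(_adjudicate_one(
                comp, policy, clock, id_source, repo, templates, histories,
                extract))
        response_items.append(ExtractItem(subject=item.subject,
                                          compositions=responses))
    return Extract(
        extract_id=id_source.next("EXT"),
        source_org=extract.target_org,
        target_org=extract.source_org,
        created_at=clock.tick(),
        items=response_items,
    )


def _adjudicate_one(comp, policy, clock, id_source, repo, templates,
                    histories, extract) -> Composition:
    report: Optional[ValidationReport] = None
    if repo is not None and templates and comp.name in templates:
        report = validate_against_template(comp, templates[comp.name], repo)

    xcomp = comp
    if not any(isinstance(e, Submission) for e in comp.content):
        try:
            xcomp = convert_base_to_extended(comp)
        except ConversionError:
            xcomp = None
    sub = next((e for e in (xcomp.content if xcomp else [])
                if isinstance(e, Submission)), None)

    if sub is None or (report is not None and not report.valid):
        decision = "return_for_correction"
    else:
        decision = policy.decide(sub)

    sub_id = sub.submission_id if sub else id_source.next("UNK")
    received = clock.tick()
    history = histories.get(sub_id, LifecycleHistory())
    if history.last is None or history.last.current_state in (
            ClaimStatus.DENIED, ClaimStatus.RETURNED_FOR_CORRECTION):
        history = apply_transition(history, ClaimStatus.SUBMITTED, received)
    decided = clock.tick()
    state = _DECISION_STATE[decision]
    history = apply_transition(history, state, decided)
    histories[sub_id] = history

    payer, provider = extract.target_org, extract.source_org
    subject = sub.subject if sub else comp.content[0].subject

    entry: Submission
    if decision == "approve" and isinstance(sub, Authorization) and not sub.is_response:
        start = clock.today()
        end = (_dt.date.fromisoformat(start)
               + _dt.timedelta(days=policy.validity_days)).isoformat()
        entry = Authorization(
            name="authorization response",
            archetype_node_id=NodeId("at0000"),
            archetype_id="openEHR-EHR-AUTHORIZATION.authorization.v1",
            subject=subject,
            submission_id=id_source.next("SUB"),
            submission_date=decided[:10],
            original_submission=sub_id,
            submitter=payer,
            submittee=provider,
            requester=sub.requester,
            authorization_id=id_source.next("AUT"),
            validity=DateInterval(start, end),
            is_response=True,
            data=ItemTree(name="components", archetype_node_id=NodeId("at0001"),
                          items=[]),
        )
    else:
        entry = _report_annex(
            sub_id, report or ValidationReport(), id_source,
            payer, provider, subject, decided)
        entry.original_submission = sub_id

    response = Composition(
        name=f"response:{comp.name}",
        archetype_node_id=NodeId("at0000"),
        archetype_id="openEHR-EHR-COMPOSITION.tiss_claim.v1",
        composer=payer,
        context_start_time=None,
        content=[entry],
        ism_transition=IsmTransition(current_state=state, timestamp=decided),
        links=[Link(meaning="responds to", type="submission",
                    target=f"{sub_id}#/")],
    )
    return response


# ---------------------------------------------------------------------------
# Round-trip simulation
# ---------------------------------------------------------------------------

@dataclass
class ExchangeLog:
    events: list[dict] = field(default_factory=list)
    histories: dict[str, LifecycleHistory] = field(default_factory=dict)
    responses: list[Extract] = field(default_factory=list)

    def final_states(self) -> dict[str, ClaimStatus]:
        return {sid: h.last.current_state
                for sid, h in sorted(self.histories.items()) if h.last}

    def to_jsonl(self) -> str:
        lines = [json.dumps(e, sort_keys=True) for e in self.events]
        for sid, h in sorted(self.histories.items()):
            lines.append(json.dumps(
                {"submission": sid,
                 "history": [t.current_state.value for t in h.transitions]},
                sort_keys=True))
        return "\n".join(lines) + ("\n" if lines else "")


def _org_id(org: PartyIdentified) -> str:
    return org.identifiers[0].id if org.identifiers else org.name


def run_roundtrip(
    scenario: list[tuple[str, Extract]],
    policy: Union[AdjudicationPolicy, list[AdjudicationPolicy]],
    repo: Optional[ArchetypeRepository] = None,
    templates: Optional[dict[str, OperationalTemplate]] = None,
    clock: Optional[Clock] = None,
    store: Optional[ResourceStore] = None,
) -> ExchangeLog:
    """Full provider → payer → provider loop over a scenario.

    ``policy`` may be a list: non-terminal submissions (denied / returned for
    correction) are resubmitted and re-adjudicated under the next policy in
    the list, modelling the resubmit-and-reanalyze cycle.
    """
    from . import serialize  # deferred: serialize imports exchange_types only

    policies = policy if isinstance(policy, list) else [policy]
    clock = clock or Clock()
    store = store or ResourceStore()
    id_source = IdSource()
    log = ExchangeLog()

    for _actor, extract in scenario:
        store.register(_org_id(extract.source_org))
        store.register(_org_id(extract.target_org))

    pending: list[Extract] = [ex for _actor, ex in scenario]
    for round_no, pol in enumerate(policies):
        if not pending:
            break
        next_round: list[Extract] = []
        for extract in pending:
            payer_org = _org_id(extract.target_org)
            provider_org = _org_id(extract.source_org)
            posted = transport_post(store, payer_org,
                                    serialize.extract_to_json(extract))
            log.events.append({"round": round_no, "actor": "provider",
                               "op": "submit", "org": payer_org,
                               "resource": posted.resource_id,
                               "extract": extract.extract_id})
            fetched = transport_get(store, payer_org, posted.resource_id)
            inbound = serialize.extract_from_json(fetched.payload)
            response = adjudicate(inbound, pol, clock, id_source,
                                  repo=repo, templates=templates,
                                  histories=log.histories)
            rput = transport_post(store, provider_org,
                                  serialize.extract_to_json(response))
            log.events.append({"round": round_no, "actor": "payer",
                               "op": "respond", "org": provider_org,
                               "resource": rput.resource_id,
                               "extract": response.extract_id})
            got = transport_get(store, provider_org, rput.resource_id)
            log.responses.append(serialize.extract_from_json(got.payload))

            # provider-side resubmission of non-terminal submissions
            retry: list[Composition] = []
            for comp in extract.compositions():
                entry = _submission_entry(comp)
                if entry is None:
                    continue
                sid = _request_submission_id(comp)
                h = log.histories.get(sid)
                if h and h.last and h.last.current_state in (
                        ClaimStatus.DENIED, ClaimStatus.RETURNED_FOR_CORRECTION):
                    retry.append(comp)
            if retry and round_no + 1 < len(policies):
                next_round.append(replace(
                    extract,
                    extract_id=id_source.next("EXT"),
                    created_at=clock.tick(),
                    items=_regroup(retry),
                ))
        pending = next_round
    return log


def _request_submission_id(comp: Composition) -> str:
    entry = _submission_entry(comp)
    if isinstance(entry, Submission):
        return entry.submission_id
    if isinstance(entry, AdminEntry) and isinstance(entry.data, ItemTree):
        for item in entry.data.items:
            if isinstance(item, Element) and \
                    " ".join(item.name.lower().split()) == "submission id" and \
                    isinstance(item.value, TextValue):
                return item.value.value
    return ""


def _regroup(comps: list[Composition]) -> list[ExtractItem]:
    items: list[ExtractItem] = []
    index: dict[tuple, ExtractItem] = {}
    for comp in comps:
        entry = _submission_entry(comp)
        subject = entry.subject
        key = (subject.name, getattr(subject, "identifiers", ()))
        if key not in index:
            item = ExtractItem(subject=subject)
            index[key] = item
            items.append(item)
        index[key].compositions.append(comp)
    return items
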