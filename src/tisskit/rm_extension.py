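"""Extended reference model for authorization and claim submissions.

The plain reference model can carry a claim only as a generic ADMIN_ENTRY
whose meaning lives entirely in the archetype.  This module adds the
administrative counterpart of the clinical entry subtypes: an abstract
SUBMISSION entry (fixed attributes common to every authorization and claim —
submission id/date, submitter = provider, submittee = payer), specialized
into CLAIM (professional / institutional), AUTHORIZATION and ANNEX, plus an
ISM_TRANSITION attribute on COMPOSITION carrying the submission status.

The claim lifecycle is the traditional billing cycle — request,
authorization, claim, denied or completed — with resubmission after a
refusal.  The transition relation here is the minimal one consistent with
that cycle and the five status values (submitted, pending, denied, returned
for correction, completed); payers with different workflows can export it,
edit it, and pass their own table to every lifecycle function.

Conversion between the two representations is lossless: elements whose
meaning moved into the extended RM (submission ID, submission date, original
submission, billing date, validity, authorization number, status) are lifted
to attributes on the way up and re-materialized — same node ids, same labels
— on the way down.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Union

from . import rm_core
from .rm_core import (
    AdminEntry,
    CodedTextValue,
    Composition,
    DateTimeValue,
    Element,
    ItemTree,
    Participation,
    PartyIdentified,
    TextValue,
)
from .report import Rule, ValidationReport

__all__ = [
    "ClaimStatus",
    "IsmTransition",
    "LifecycleHistory",
    "LifecycleError",
    "ConversionError",
    "DateInterval",
    "Submission",
    "Claim",
    "ProfessionalClaim",
    "InstitutionalClaim",
    "Authorization",
    "Annex",
    "DEFAULT_TRANSITIONS",
    "allowed_transitions",
    "apply_transition",
    "validate_history",
    "transitions_to_config",
    "transitions_from_config",
    "convert_base_to_extended",
    "convert_extended_to_base",
    "BASE_ARCHETYPE_IDS",
    "EXTENDED_ARCHETYPE_IDS",
    "STATUS_TERMINOLOGY",
]


class ClaimStatus(str, Enum):
    SUBMITTED = "submitted"
    PENDING = "pending"
    DENIED = "denied"
    RETURNED_FOR_CORRECTION = "returned_for_correction"
    COMPLETED = "completed"

    @property
    def display(self) -> str:
        return self.value.replace("_", " ")


#: Internal code set for status values (the printed TISS forms never show
#: them; they are codified only in the message layer).
STATUS_TERMINOLOGY = "tiss_status"

DEFAULT_TRANSITIONS: dict[ClaimStatus, frozenset[ClaimStatus]] = {
    ClaimStatus.SUBMITTED: frozenset({
        ClaimStatus.PENDING, ClaimStatus.DENIED,
        ClaimStatus.RETURNED_FOR_CORRECTION, ClaimStatus.COMPLETED}),
    ClaimStatus.PENDING: frozenset({
        ClaimStatus.DENIED, ClaimStatus.RETURNED_FOR_CORRECTION,
        ClaimStatus.COMPLETED}),
    ClaimStatus.DENIED: frozenset({ClaimStatus.SUBMITTED}),
    ClaimStatus.RETURNED_FOR_CORRECTION: frozenset({ClaimStatus.SUBMITTED}),
    ClaimStatus.COMPLETED: frozenset(),
}


def allowed_transitions(
    state: ClaimStatus,
    table: Optional[dict[ClaimStatus, frozenset[ClaimStatus]]] = None,
) -> frozenset[ClaimStatus]:
    """The set of statuses reachable from ``state`` in one step."""
    return (table or DEFAULT_TRANSITIONS)[ClaimStatus(state)]


def transitions_to_config(
    table: Optional[dict[ClaimStatus, frozenset[ClaimStatus]]] = None,
) -> dict[str, list[str]]:
    """Export a transition table as a plain (YAML/JSON-friendly) mapping."""
    table = table or DEFAULT_TRANSITIONS
    return {s.value: sorted(t.value for t in table[s]) for s in ClaimStatus}


def transitions_from_config(cfg: dict[str, list[str]]) -> dict[ClaimStatus, frozenset[ClaimStatus]]:
    table = {ClaimStatus(k): frozenset(ClaimStatus(v) for v in vs)
             for k, vs in cfg.items()}
    for s in ClaimStatus:
        table.setdefault(s, frozenset())
    return table


@dataclass(frozen=True)
class IsmTransition:
    """Current point in the submission state machine, stamped on a composition."""

    current_state: ClaimStatus
    timestamp: str
    careflow_step: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "current_state", ClaimStatus(self.current_state))
        canon = _dt.datetime.fromisoformat(self.timestamp).isoformat()
        object.__setattr__(self, "timestamp", canon)


class LifecycleError(ValueError):
    """Illegal lifecycle transition or timestamp regression."""


@dataclass(frozen=True)
class LifecycleHistory:
    """Immutable ordered status history (timestamps non-decreasing)."""

    transitions: tuple[IsmTransition, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(self.transitions))

    @property
    def last(self) -> Optional[IsmTransition]:
        return self.transitions[-1] if self.transitions else None

    def states(self) -> list[ClaimStatus]:
        return [t.current_state for t in self.transitions]

    def __len__(self) -> int:
        return len(self.transitions)


def apply_transition(
    history: LifecycleHistory,
    next_state: ClaimStatus,
    at: str,
    table: Optional[dict[ClaimStatus, frozenset[ClaimStatus]]] = None,
) -> LifecycleHistory:
    """Return a new history with ``next_state`` appended (never mutates).

    An empty history may only start with SUBMITTED; otherwise the step must be
    in the transition relation and ``at`` must not precede the last timestamp.
    """
    next_state = ClaimStatus(next_state)
    step = IsmTransition(current_state=next_state, timestamp=at)
    last = history.last
    if last is None:
        if next_state is not ClaimStatus.SUBMITTED:
            raise LifecycleError(
                f"a lifecycle must start with {ClaimStatus.SUBMITTED.value!r}, "
                f"not {next_state.value!r}")
        return LifecycleHistory((step,))
    if next_state not in allowed_transitions(last.current_state, table):
        raise LifecycleError(
            f"illegal transition {last.current_state.value!r} -> {next_state.value!r}")
    if step.timestamp < last.timestamp:
        raise LifecycleError(
            f"time regression: {step.timestamp} precedes {last.timestamp}")
    return LifecycleHistory(history.transitions + (step,))


def validate_history(
    history: LifecycleHistory,
    table: Optional[dict[ClaimStatus, frozenset[ClaimStatus]]] = None,
) -> ValidationReport:
    """Check a full history; problems are findings, never exceptions."""
    report = ValidationReport()
    ts = history.transitions
    if ts and ts[0].current_state is not ClaimStatus.SUBMITTED:
        report.add("/transitions[0]", Rule.LIFECYCLE_BAD_INITIAL_STATE,
                   f"history starts with {ts[0].current_state.value!r}, "
                   f"expected 'submitted'")
    for i in range(1, len(ts)):
        prev, cur = ts[i - 1], ts[i]
        if cur.current_state not in allowed_transitions(prev.current_state, table):
            report.add(f"/transitions[{i}]", Rule.LIFECYCLE_ILLEGAL_TRANSITION,
                       f"{prev.current_state.value!r} -> {cur.current_state.value!r} "
                       f"is not allowed")
        if cur.timestamp < prev.timestamp:
            report.add(f"/transitions[{i}]", Rule.LIFECYCLE_TIME_REGRESSION,
                       f"{cur.timestamp} precedes {prev.timestamp}")
    return report


# ---------------------------------------------------------------------------
# Submission hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DateInterval:
    """Closed calendar-date interval (e.g. an authorization validity period)."""

    start: str
    end: str

    def __post_init__(self) -> None:
        s = _dt.date.fromisoformat(self.start).isoformat()
        e = _dt.date.fromisoformat(self.end).isoformat()
        if s > e:
            raise ValueError(f"interval start {s} after end {e}")
        object.__setattr__(self, "start", s)
        object.__setattr__(self, "end", e)

    def __str__(self) -> str:
        return f"{self.start}/{self.end}"

    @classmethod
    def parse(cls, text: str) -> "DateInterval":
        try:
            start, end = text.split("/")
        except ValueError as exc:
            raise ValueError(f"invalid date interval {text!r}; expected "
                             f"'YYYY-MM-DD/YYYY-MM-DD'") from exc
        return cls(start, end)


@dataclass(kw_only=True)
class Submission(AdminEntry):
    """Abstract administrative entry shared by every authorization and claim."""

    submission_id: str = ""
    submission_date: Optional[str] = None  # ISO date
    submitter: Optional[PartyIdentified] = None  # provider organization
    submittee: Optional[PartyIdentified] = None  # payer organization
    original_submission: Optional[str] = None  # prior submission_id

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.submission_id:
            raise ValueError("submission_id must be non-empty")
        for role, party in (("submitter", self.submitter), ("submittee", self.submittee)):
            if party is not None and not party.identifiers:
                raise ValueError(f"{role} must carry at least one identifier")
        if self.submission_date is not None:
            self.submission_date = _dt.date.fromisoformat(self.submission_date).isoformat()


@dataclass(kw_only=True)
class Claim(Submission):
    billing_date: Optional[str] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.billing_date is not None:
            self.billing_date = _dt.date.fromisoformat(self.billing_date).isoformat()


@dataclass(kw_only=True)
class ProfessionalClaim(Claim):
    """Claim by an individual professional (physician, dentist, ...)."""

    performer: Optional[PartyIdentified] = None


@dataclass(kw_only=True)
class InstitutionalClaim(Claim):
    """Claim by a hospital, laboratory or clinic; lists the staff involved."""

    participants: list[PartyIdentified] = field(default_factory=list)


@dataclass(kw_only=True)
class Authorization(Submission):
    """Authorization request, or its response when ``is_response`` is set."""

    requester: Optional[PartyIdentified] = None
    authorization_id: Optional[str] = None
    validity: Optional[DateInterval] = None
    is_response: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.is_response and not self.authorization_id:
            raise ValueError("an authorization response must carry an authorization_id")


@dataclass(kw_only=True)
class Annex(Submission):
    """Supplement to another submission (e.g. a clinical report the payer
    requested before authorizing a procedure)."""

    complements: str = ""


rm_core.RM_CLASS_REGISTRY.update({
    "SUBMISSION": Submission,
    "CLAIM": Claim,
    "PROFESSIONAL_CLAIM": ProfessionalClaim,
    "INSTITUTIONAL_CLAIM": InstitutionalClaim,
    "AUTHORIZATION": Authorization,
    "ANNEX": Annex,
})


# ---------------------------------------------------------------------------
# Plain-RM <-> extended-RM conversion
# ---------------------------------------------------------------------------

class ConversionError(ValueError):
    """Raised when a plain-RM entry cannot be lifted to the extended RM."""


#: Plain-RM (ADMIN_ENTRY) archetypes convertible to extended entries.
BASE_ARCHETYPE_IDS: dict[str, str] = {
    "openEHR-EHR-ADMIN_ENTRY.professional_claim.v1": "professional_claim",
    "openEHR-EHR-ADMIN_ENTRY.institutional_claim.v1": "institutional_claim",
    "openEHR-EHR-ADMIN_ENTRY.authorization.v1": "authorization",
    "openEHR-EHR-ADMIN_ENTRY.authorization_request.v1": "authorization_request",
}

#: Extended-RM archetype id for each concept (and back).
EXTENDED_ARCHETYPE_IDS: dict[str, str] = {
    "professional_claim": "openEHR-EHR-PROFESSIONAL_CLAIM.professional_claim.v1",
    "institutional_claim": "openEHR-EHR-INSTITUTIONAL_CLAIM.institutional_claim.v1",
    "authorization": "openEHR-EHR-AUTHORIZATION.authorization.v1",
    "authorization_request": "openEHR-EHR-AUTHORIZATION.authorization_request.v1",
}
_BASE_ID_BY_CONCEPT = {v: k for k, v in BASE_ARCHETYPE_IDS.items()}
_EXTENDED_TO_BASE = {ext_id: _BASE_ID_BY_CONCEPT[concept]
                     for concept, ext_id in EXTENDED_ARCHETYPE_IDS.items()}


def _norm_label(label: str) -> str:
    return " ".join(label.lower().split())


def _value_text(element: Element) -> str:
    v = element.value
    if isinstance(v, CodedTextValue):
        return v.code or v.value
    if isinstance(v, TextValue):
        return v.value
    raise ConversionError(
        f"element {element.name!r} holds a {type(v).__name__}, expected a text value")


def _status_from_text(text: str) -> ClaimStatus:
    key = _norm_label(text).replace(" ", "_")
    try:
        return ClaimStatus(key)
    except ValueError as exc:
        raise ConversionError(f"unknown status value {text!r}") from exc


def _status_value(state: ClaimStatus) -> CodedTextValue:
    return CodedTextValue(value=state.display, code=state.value,
                          terminology_id=STATUS_TERMINOLOGY)


def _find_participation(entry: AdminEntry, function: str) -> Optional[PartyIdentified]:
    for p in entry.other_participations:
        if p.function == function and isinstance(p.performer, PartyIdentified):
            return p.performer
    return None


def _label_codes(concept: str) -> dict[str, tuple[str, str]]:
    """normalized element label -> (at-code, canonical label) for a plain-RM
    admin archetype (taken from the shipped fixture inventory)."""
    from . import fixtures  # local import: fixtures depends on adl, not on us
    return fixtures.admin_label_codes(concept)


def convert_base_to_extended(comp: Composition) -> Composition:
    """Lift every convertible ADMIN_ENTRY in ``comp`` to its extended type.

    Element values whose meaning lives in the extended RM are moved to
    attributes; the status element becomes the composition's ISM_TRANSITION;
    all remaining elements are preserved verbatim.  The input is not mutated.
    """
    new_content = []
    ism: Optional[IsmTransition] = None
    converted = 0
    for entry in comp.content:
        if isinstance(entry, AdminEntry) and not isinstance(entry, Submission) \
                and entry.archetype_id in BASE_ARCHETYPE_IDS:
            entry, status = _lift_entry(entry, comp)
            converted += 1
            if status is not None:
                ism = status
        new_content.append(entry)
    if not converted:
        raise ConversionError(
            "composition contains no ADMIN_ENTRY with a convertible archetype id "
            f"(known: {sorted(BASE_ARCHETYPE_IDS)})")
    return replace(comp, content=new_content, ism_transition=ism)


def _lift_entry(entry: AdminEntry, comp: Composition) -> tuple[Submission, Optional[IsmTransition]]:
    concept = BASE_ARCHETYPE_IDS[entry.archetype_id]  # type: ignore[index]
    if not isinstance(entry.data, ItemTree):
        raise ConversionError(
            f"entry {entry.name!r} has no ITEM_TREE data to convert")

    lifted: dict[str, Element] = {}
    residual = []
    # Elements whose meaning lives in the extended RM, per concept.  The
    # professional claim's "validity" element has no extended-RM attribute on
    # claims (only authorizations carry a validity period), so it stays put.
    common_lift = {"submission id", "original submission", "submission date", "status"}
    liftable = {
        "professional_claim": common_lift | {"billing date"},
        "institutional_claim": common_lift | {"billing date"},
        "authorization": common_lift | {"validity", "authorization number"},
        "authorization_request": common_lift,
    }[concept]
    for item in entry.data.items:
        key = _norm_label(item.name) if isinstance(item, Element) else None
        if key in liftable and key not in lifted:
            lifted[key] = item  # type: ignore[assignment]
        else:
            residual.append(item)

    gaps = []
    if "submission id" not in lifted:
        gaps.append("submission ID")
    submitter = _find_participation(entry, "submitter")
    submittee = _find_participation(entry, "submittee")
    if submitter is None:
        gaps.append("submitter participation")
    if submittee is None:
        gaps.append("submittee participation")
    if gaps:
        raise ConversionError(
            f"cannot convert {concept} entry {entry.name!r}: missing " + ", ".join(gaps))

    participations = [p for p in entry.other_participations
                      if p.function not in ("submitter", "submittee", "participant")]
    participants = [p.performer for p in entry.other_participations
                    if p.function == "participant"
                    and isinstance(p.performer, PartyIdentified)]

    common = dict(
        name=entry.name,
        archetype_node_id=entry.archetype_node_id,
        links=list(entry.links),
        archetype_id=EXTENDED_ARCHETYPE_IDS[concept],
        subject=entry.subject,
        other_participations=participations,
        data=replace(entry.data, items=residual),
        submission_id=_value_text(lifted["submission id"]),
        submission_date=(_value_text(lifted["submission date"])
                         if "submission date" in lifted else None),
        original_submission=(_value_text(lifted["original submission"])
                             if "original submission" in lifted else None),
        submitter=submitter,
        submittee=submittee,
    )

    new: Submission
    if concept == "professional_claim":
        new = ProfessionalClaim(
            **common,
            billing_date=(_value_text(lifted["billing date"])
                          if "billing date" in lifted else None),
            performer=entry.provider if isinstance(entry.provider, PartyIdentified) else None,
        )
    elif concept == "institutional_claim":
        new = InstitutionalClaim(
            **common,
            provider=entry.provider,
            billing_date=(_value_text(lifted["billing date"])
                          if "billing date" in lifted else None),
            participants=participants,
        )
    else:
        auth_id = (_value_text(lifted["authorization number"])
                   if "authorization number" in lifted else None)
        if concept == "authorization" and auth_id is None:
            raise ConversionError(
                f"cannot convert authorization entry {entry.name!r}: "
                "missing authorization number")
        new = Authorization(
            **common,
            requester=entry.provider if isinstance(entry.provider, PartyIdentified) else None,
            authorization_id=auth_id,
            validity=(DateInterval.parse(_value_text(lifted["validity"]))
                      if "validity" in lifted else None),
            is_response=(concept == "authorization"),
        )

    ism = None
    if "status" in lifted:
        when = comp.context_start_time.value if comp.context_start_time else "1970-01-01T00:00:00"
        ism = IsmTransition(current_state=_status_from_text(_value_text(lifted["status"])),
                            timestamp=when)
    return new, ism


def convert_extended_to_base(comp: Composition) -> Composition:
    """Exact inverse of :func:`convert_base_to_extended`.

    Attribute values are re-materialized as elements with the archetype's own
    node ids and labels, merged with the residual elements in node-id order
    (the canonical document order of the shipped archetypes).
    """
    new_content = []
    lowered = 0
    for entry in comp.content:
        if isinstance(entry, Submission):
            new_content.append(_lower_entry(entry, comp))
            lowered += 1
        else:
            new_content.append(entry)
    if not lowered:
        raise ConversionError("composition contains no extended-RM Submission entry")
    return replace(comp, content=new_content, ism_transition=None)


def _lower_entry(entry: Submission, comp: Composition) -> AdminEntry:
    base_archetype_id = _EXTENDED_TO_BASE.get(entry.archetype_id or "")
    if base_archetype_id is None:
        raise ConversionError(
            f"unknown extended archetype id {entry.archetype_id!r}")
    concept = BASE_ARCHETYPE_IDS[base_archetype_id]
    codes = _label_codes(concept)

    def make(label_key: str, value: rm_core.DataValue) -> Element:
        code, label = codes[label_key]
        return Element(name=label, archetype_node_id=rm_core.NodeId(code), value=value)

    elements: list[Element] = [make("submission id", TextValue(entry.submission_id))]
    if entry.original_submission is not None:
        elements.append(make("original submission", TextValue(entry.original_submission)))
    if entry.submission_date is not None:
        elements.append(make("submission date", TextValue(entry.submission_date)))
    if isinstance(entry, Claim) and entry.billing_date is not None:
        elements.append(make("billing date", TextValue(entry.billing_date)))
    if isinstance(entry, Authorization):
        if entry.validity is not None:
            elements.append(make("validity", TextValue(str(entry.validity))))
        if entry.authorization_id is not None:
            elements.append(make("authorization number", TextValue(entry.authorization_id)))
    if comp.ism_transition is not None:
        elements.append(make("status", _status_value(comp.ism_transition.current_state)))

    assert isinstance(entry.data, ItemTree)
    items = sorted(
        list(entry.data.items) + list(elements),
        key=lambda it: int(it.archetype_node_id.code[2:]))

    participations = [Participation(entry.submitter, "submitter"),
                      Participation(entry.submittee, "submittee")]
    if isinstance(entry, InstitutionalClaim):
        participations += [Participation(p, "participant") for p in entry.participants]
    participations += entry.other_participations

    provider = entry.provider
    if isinstance(entry, ProfessionalClaim):
        provider = entry.performer
    elif isinstance(entry, Authorization):
        provider = entry.requester

    return AdminEntry(
        name=entry.name,
        archetype_node_id=entry.archetype_node_id,
        links=list(entry.links),
        archetype_id=base_archetype_id,
        subject=entry.subject,
        provider=provider,
        other_participations=participations,
        data=replace(entry.data, items=items),
    )
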