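"""Extended RM: lifecycle state machine and lossless conversions."""

import random
from collections import Counter, deque

import pytest

from tisskit.rm_core import (
    Element,
    NodeId,
    PartyIdentified,
    IdentifierValue,
    TextValue,
    structural_equals,
    walk,
)
from tisskit.rm_extension import (
    Authorization,
    ClaimStatus,
    ConversionError,
    InstitutionalClaim,
    LifecycleError,
    LifecycleHistory,
    ProfessionalClaim,
    Submission,
    allowed_transitions,
    apply_transition,
    convert_base_to_extended,
    convert_extended_to_base,
    transitions_from_config,
    transitions_to_config,
    validate_history,
)
from tests.conftest import make_composition

ALL = list(ClaimStatus)


class TestTransitionRelation:
    def test_completed_is_terminal(self):
        assert allowed_transitions(ClaimStatus.COMPLETED) == frozenset()

    def test_denied_allows_resubmission(self):
        assert allowed_transitions(ClaimStatus.DENIED) == {ClaimStatus.SUBMITTED}

    def test_all_states_reachable_from_submitted(self):
        seen, queue = {ClaimStatus.SUBMITTED}, deque([ClaimStatus.SUBMITTED])
        while queue:
            for nxt in allowed_transitions(queue.popleft()):
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        assert seen == set(ALL)

    def test_unique_terminal_state(self):
        terminals = [s for s in ALL if not allowed_transitions(s)]
        assert terminals == [ClaimStatus.COMPLETED]

    def test_config_round_trip(self):
        cfg = transitions_to_config()
        assert transitions_from_config(cfg) is not None
        assert transitions_to_config(transitions_from_config(cfg)) == cfg


class TestApplyTransition:
    def test_initial_state_must_be_submitted(self):
        h = apply_transition(LifecycleHistory(), ClaimStatus.SUBMITTED,
                             "2026-01-01T08:00:00")
        assert h.states() == [ClaimStatus.SUBMITTED]
        with pytest.raises(LifecycleError, match="submitted"):
            apply_transition(LifecycleHistory(), ClaimStatus.PENDING,
                             "2026-01-01T08:00:00")

    def test_terminal_state_rejects_continuation(self):
        h = LifecycleHistory()
        h = apply_transition(h, ClaimStatus.SUBMITTED, "2026-01-01T08:00:00")
        h = apply_transition(h, ClaimStatus.COMPLETED, "2026-01-01T09:00:00")
        with pytest.raises(LifecycleError, match="completed.*pending"):
            apply_transition(h, ClaimStatus.PENDING, "2026-01-01T10:00:00")

    def test_time_regression_rejected(self):
        h = apply_transition(LifecycleHistory(), ClaimStatus.SUBMITTED,
                             "2026-01-01T08:00:00")
        with pytest.raises(LifecycleError, match="regression"):
            apply_transition(h, ClaimStatus.PENDING, "2026-01-01T07:00:00")

    def test_never_mutates_input(self):
        h0 = apply_transition(LifecycleHistory(), ClaimStatus.SUBMITTED,
                              "2026-01-01T08:00:00")
        apply_transition(h0, ClaimStatus.DENIED, "2026-01-01T09:00:00")
        assert len(h0) == 1

    def test_random_legal_walks_always_validate(self):
        rng = random.Random(99)
        for _ in range(25):
            h = apply_transition(LifecycleHistory(), ClaimStatus.SUBMITTED,
                                 "2026-01-01T08:00:00")
            t = 0
            for _step in range(20):
                nxt = allowed_transitions(h.last.current_state)
                if not nxt:
                    break
                t += 1
                h = apply_transition(h, rng.choice(sorted(nxt)),
                                     f"2026-01-01T{8:02d}:{t:02d}:00")
            assert validate_history(h).valid


class TestValidateHistory:
    def _history(self, *states):
        ts = [f"2026-01-01T08:{i:02d}:00" for i in range(len(states))]
        from tisskit.rm_extension import IsmTransition
        return LifecycleHistory(tuple(
            IsmTransition(current_state=s, timestamp=t)
            for s, t in zip(states, ts)))

    def test_legal_history_is_clean(self):
        h = self._history(ClaimStatus.SUBMITTED, ClaimStatus.PENDING,
                          ClaimStatus.COMPLETED)
        assert validate_history(h).valid

    def test_bad_initial_state_is_one_finding(self):
        rep = validate_history(self._history(ClaimStatus.PENDING))
        assert len(rep.findings) == 1 and not rep.valid

    def test_resubmission_path_is_legal(self):
        h = self._history(ClaimStatus.SUBMITTED, ClaimStatus.DENIED,
                          ClaimStatus.SUBMITTED, ClaimStatus.COMPLETED)
        assert validate_history(h).valid


def _pairs(comp):
    """Multiset of (normalized element name, text) pairs plus lifted
    attributes — the conversion conservation currency."""
    out = Counter()
    for _p, node in walk(comp):
        if isinstance(node, Element) and isinstance(node.value, TextValue):
            out[(" ".join(node.name.lower().split()), node.value.value)] += 1
    for entry in comp.content:
        if isinstance(entry, Submission):
            out[("submission id", entry.submission_id)] += 1
            if entry.submission_date:
                out[("submission date", entry.submission_date)] += 1
            if entry.original_submission:
                out[("original submission", entry.original_submission)] += 1
            if getattr(entry, "billing_date", None):
                out[("billing date", entry.billing_date)] += 1
            if getattr(entry, "authorization_id", None):
                out[("authorization number", entry.authorization_id)] += 1
            if getattr(entry, "validity", None):
                out[("validity", str(entry.validity))] += 1
    if comp.ism_transition is not None:
        out[("status", comp.ism_transition.current_state.value)] += 1
    return out


ADMIN_TEMPLATES = ["admission_claim", "individual_claim",
                   "tests_procedures_authorization", "admission_request"]


class TestConversion:
    def test_institutional_claim_lifts_five_elements(self, admission_claim):
        base_entry = admission_claim.content[0]
        n_before = len(base_entry.data.items)
        ext = convert_base_to_extended(admission_claim)
        entry = next(e for e in ext.content if isinstance(e, Submission))
        assert isinstance(entry, InstitutionalClaim)
        # submission ID, original submission, submission Date, billing date
        # and status move into the model; the rest stay put
        assert len(entry.data.items) == n_before - 5
        assert entry.submission_id.startswith("SUB-")
        assert entry.billing_date is not None
        assert ext.ism_transition is not None
        assert ext.ism_transition.current_state is ClaimStatus.SUBMITTED

    def test_authorization_response_fields(self, authorization_comp):
        ext = convert_base_to_extended(authorization_comp)
        entry = next(e for e in ext.content if isinstance(e, Submission))
        assert isinstance(entry, Authorization)
        assert entry.is_response
        assert entry.authorization_id.startswith("AUT-")
        assert entry.validity is not None
        assert entry.validity.start <= entry.validity.end

    def test_missing_status_leaves_ism_absent(self, admission_claim):
        entry = admission_claim.content[0]
        entry.data.items = [i for i in entry.data.items
                            if i.name.lower() != "status"]
        ext = convert_base_to_extended(admission_claim)
        assert ext.ism_transition is None

    def test_missing_submission_id_is_an_error_naming_the_gap(self, admission_claim):
        entry = admission_claim.content[0]
        entry.data.items = [i for i in entry.data.items
                            if " ".join(i.name.lower().split()) != "submission id"]
        with pytest.raises(ConversionError, match="submission ID"):
            convert_base_to_extended(admission_claim)

    @pytest.mark.parametrize("template", ADMIN_TEMPLATES)
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_round_trip_is_identity(self, template, seed):
        comp = make_composition(template, seed=seed,
                                with_original_submission=(seed % 2 == 0))
        back = convert_extended_to_base(convert_base_to_extended(comp))
        assert structural_equals(comp, back)

    @pytest.mark.parametrize("template", ADMIN_TEMPLATES)
    def test_no_populated_value_is_dropped(self, template):
        comp = make_composition(template, seed=5, with_original_submission=True)
        ext = convert_base_to_extended(comp)
        assert _pairs(comp) == _pairs(ext)

    def test_professional_performer_maps_to_provider(self):
        comp = make_composition("individual_claim", seed=4)
        professional = comp.content[0].provider
        ext = convert_base_to_extended(comp)
        entry = next(e for e in ext.content if isinstance(e, Submission))
        assert isinstance(entry, ProfessionalClaim)
        assert entry.performer == professional
        back = convert_extended_to_base(ext)
        assert back.content[0].provider == professional

    def test_institutional_participants_map_to_participations(self):
        comp = make_composition("admission_claim", seed=6)
        ext = convert_base_to_extended(comp)
        entry = next(e for e in ext.content if isinstance(e, Submission))
        extra = PartyIdentified(name="Extra Staff", identifiers=(
            IdentifierValue("CRM-00001", "professional council", "license"),))
        entry.participants.append(extra)
        back = convert_extended_to_base(ext)
        parts = [p for p in back.content[0].other_participations
                 if p.function == "participant"]
        assert len(parts) == len(entry.participants) == 2

    def test_unknown_archetype_id_is_an_error(self, admission_claim):
        admission_claim.content[0].archetype_id = \
            "openEHR-EHR-ADMIN_ENTRY.someting_else.v1"
        with pytest.raises(ConversionError, match="no ADMIN_ENTRY"):
            convert_base_to_extended(admission_claim)


class TestSubmissionInvariants:
    def _party(self):
        return PartyIdentified(name="Org", identifiers=(
            IdentifierValue("X-1", "reg", "id"),))

    def test_submission_id_required(self):
        with pytest.raises(ValueError, match="submission_id"):
            InstitutionalClaim(name="c", archetype_node_id=NodeId("at0000"),
                               archetype_id="x.v1", submission_id="")

    def test_parties_need_identifiers(self):
        with pytest.raises(ValueError, match="identifier"):
            InstitutionalClaim(
                name="c", archetype_node_id=NodeId("at0000"),
                archetype_id="x.v1", submission_id="S-1",
                submitter=PartyIdentified(name="NoIds"))

    def test_response_needs_authorization_id(self):
        with pytest.raises(ValueError, match="authorization_id"):
            Authorization(name="a", archetype_node_id=NodeId("at0000"),
                          archetype_id="x.v1", submission_id="S-1",
                          is_response=True)
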