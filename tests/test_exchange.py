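"""Provider↔payer exchange: packaging, transport, adjudication, round-trips."""

import pytest

from tests.conftest import make_composition
from tisskit import synth
from tisskit.exchange import (
    AdjudicationPolicy,
    Clock,
    IdSource,
    ResourceStore,
    adjudicate,
    package_extract,
    run_roundtrip,
    transport_delete,
    transport_get,
    transport_post,
    transport_put,
)
from tisskit.report import Rule
from tisskit.rm_core import PartyIdentified, IdentifierValue
from tisskit.rm_extension import (
    Annex,
    Authorization,
    ClaimStatus,
    validate_history,
)


def _org(name, oid):
    return PartyIdentified(name=name,
                           identifiers=(IdentifierValue(oid, "registry", "org"),))


PROVIDER = _org("Hospital Santa Clara", "CNES-001234")
PAYER = _org("Plano Saude Total", "ANS-41001")


class TestPackaging:
    def test_same_subject_groups_into_one_item(self):
        a = make_composition("admission_claim", seed=30)
        b = make_composition("individual_claim", seed=31)
        subj = a.content[0].subject
        for e in b.content:
            e.subject = subj
        ex = package_extract([a, b], PROVIDER, PAYER, IdSource())
        assert len(ex.items) == 1 and len(ex.items[0].compositions) == 2

    def test_two_subjects_give_two_items(self):
        a = make_composition("admission_claim", seed=30)
        b = make_composition("admission_claim", seed=32)
        assert a.content[0].subject != b.content[0].subject
        ex = package_extract([a, b], PROVIDER, PAYER, IdSource())
        assert len(ex.items) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            package_extract([], PROVIDER, PAYER, IdSource())

    def test_inputs_not_mutated(self):
        from tisskit import serialize
        a = make_composition("admission_claim", seed=33)
        before = serialize.composition_to_json(a)
        package_extract([a], PROVIDER, PAYER, IdSource())
        assert serialize.composition_to_json(a) == before


class TestTransport:
    @pytest.fixture()
    def store(self):
        s = ResourceStore()
        s.register("ANS-41001")
        return s

    def test_post_then_get_round_trips_payload(self, store):
        r = transport_post(store, "ANS-41001", "payload-1")
        assert r.status == 201
        got = transport_get(store, "ANS-41001", r.resource_id)
        assert (got.status, got.payload) == (200, "payload-1")

    def test_put_is_idempotent_but_logged_each_time(self, store):
        transport_put(store, "ANS-41001", "r1", "p")
        transport_put(store, "ANS-41001", "r1", "p")
        assert store.resources("ANS-41001") == ["r1"]
        assert [e["op"] for e in store.log] == ["PUT", "PUT"]

    def test_delete_then_get_is_not_found(self, store):
        r = transport_post(store, "ANS-41001", "p")
        assert transport_delete(store, "ANS-41001", r.resource_id).status == 204
        assert transport_get(store, "ANS-41001", r.resource_id).status == 404
        assert transport_delete(store, "ANS-41001", r.resource_id).status == 404

    def test_unregistered_org_rejected(self, store):
        with pytest.raises(KeyError, match="not registered"):
            transport_get(store, "ANS-99999", "r1")


class TestAdjudication:
    def _scenario(self, context, **kw):
        repo, opts = context
        cfg = synth.GeneratorConfig(seed=50, **kw)
        return synth.generate_scenario(cfg, repo, opts)

    def test_approved_authorization_gets_id_and_validity(self, context):
        repo, opts = context
        (_a, extract), = self._scenario(context)
        policy = AdjudicationPolicy.approve_all(validity_days=45)
        response = adjudicate(extract, policy, Clock(), IdSource(),
                              repo=repo, templates=opts, histories={})
        (auth,) = [e for c in response.compositions() for e in c.content]
        assert isinstance(auth, Authorization) and auth.is_response
        assert auth.authorization_id
        import datetime as dt
        got = (dt.date.fromisoformat(auth.validity.end)
               - dt.date.fromisoformat(auth.validity.start)).days
        assert got == 45

    def test_histories_submitted_to_completed(self, context):
        repo, opts = context
        (_a, extract), = self._scenario(context)
        histories = {}
        adjudicate(extract, AdjudicationPolicy.approve_all(), Clock(),
                   IdSource(), repo=repo, templates=opts, histories=histories)
        (h,) = histories.values()
        assert h.states() == [ClaimStatus.SUBMITTED, ClaimStatus.COMPLETED]
        assert validate_history(h).valid

    def test_deny_all_yields_denied_without_authorization(self, context):
        repo, opts = context
        (_a, extract), = self._scenario(context)
        histories = {}
        response = adjudicate(extract, AdjudicationPolicy.deny_all(), Clock(),
                              IdSource(), repo=repo, templates=opts,
                              histories=histories)
        (h,) = histories.values()
        assert h.states()[-1] is ClaimStatus.DENIED
        assert not any(isinstance(e, Authorization)
                       for c in response.compositions() for e in c.content)

    def test_invalid_composition_returned_for_correction_with_annex(self, context, rng):
        repo, opts = context
        (_a, extract), = self._scenario(context)
        comp = extract.items[0].compositions[0]
        mutant, _exp = synth.mutate_for_violation(
            comp, Rule.VALUE_TYPE_MISMATCH, rng, opts["admission_request"])
        extract.items[0].compositions[0] = mutant
        histories = {}
        response = adjudicate(extract, AdjudicationPolicy.approve_all(), Clock(),
                              IdSource(), repo=repo, templates=opts,
                              histories=histories)
        (h,) = histories.values()
        assert h.states()[-1] is ClaimStatus.RETURNED_FOR_CORRECTION
        (entry,) = [e for c in response.compositions() for e in c.content]
        assert isinstance(entry, Annex)
        texts = [i.value.value for i in entry.data.items]
        assert any("VALUE_TYPE_MISMATCH" in t for t in texts)

    def test_one_response_per_request(self, context):
        repo, opts = context
        (_a, extract), = self._scenario(context, n_requests=3)
        response = adjudicate(extract, AdjudicationPolicy.approve_all(), Clock(),
                              IdSource(), repo=repo, templates=opts, histories={})
        assert len(response.compositions()) == len(extract.compositions())
        assert response.source_org == extract.target_org
        assert response.target_org == extract.source_org

    def test_cost_ceiling_denies_expensive_claims(self, context):
        repo, opts = context
        (_a, extract), = self._scenario(context, n_requests=0, n_claims=1)
        histories = {}
        adjudicate(extract, AdjudicationPolicy(default="approve", max_total=0.01),
                   Clock(), IdSource(), repo=repo, templates=opts,
                   histories=histories)
        (h,) = histories.values()
        assert h.states()[-1] is ClaimStatus.DENIED


class TestRoundtrip:
    def test_approve_all_ends_terminal_and_legal(self, context):
        repo, opts = context
        sc = synth.generate_scenario(
            synth.GeneratorConfig(seed=51, n_requests=2, n_claims=2), repo, opts)
        log = run_roundtrip(sc, AdjudicationPolicy.approve_all(),
                            repo=repo, templates=opts)
        assert len(log.histories) == 4
        for h in log.histories.values():
            assert validate_history(h).valid
            assert h.last.current_state is ClaimStatus.COMPLETED

    def test_byte_reproducible(self, context):
        repo, opts = context
        cfg = synth.GeneratorConfig(seed=51, n_requests=2, n_claims=1)
        a = run_roundtrip(synth.generate_scenario(cfg, repo, opts),
                          AdjudicationPolicy.approve_all(), repo=repo,
                          templates=opts)
        b = run_roundtrip(synth.generate_scenario(cfg, repo, opts),
                          AdjudicationPolicy.approve_all(), repo=repo,
                          templates=opts)
        assert a.to_jsonl() == b.to_jsonl() != ""

    def test_deny_then_resubmit_then_complete(self, context):
        repo, opts = context
        sc = synth.generate_scenario(synth.GeneratorConfig(seed=52), repo, opts)
        log = run_roundtrip(sc, [AdjudicationPolicy.deny_all(),
                                 AdjudicationPolicy.approve_all()],
                            repo=repo, templates=opts)
        (h,) = log.histories.values()
        assert h.states() == [ClaimStatus.SUBMITTED, ClaimStatus.DENIED,
                              ClaimStatus.SUBMITTED, ClaimStatus.COMPLETED]
        assert validate_history(h).valid

    def test_empty_scenario_leaves_no_trace(self):
        store = ResourceStore()
        log = run_roundtrip([], AdjudicationPolicy.approve_all(), store=store)
        assert log.events == [] and log.histories == {} and store.log == []
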