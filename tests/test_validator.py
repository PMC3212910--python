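"""Archetype validation: findings, slots, determinism, monotonicity."""

import copy
import random

import pytest

from tests.conftest import make_composition
from tisskit import fixtures
from tisskit.adl import PrimitiveConstraint
from tisskit.report import Rule
from tisskit.rm_core import (
    AdminEntry,
    Cluster,
    CodedTextValue,
    CountValue,
    DateTimeValue,
    Element,
    ItemTree,
    NodeId,
    TextValue,
    children,
    walk,
)
from tisskit.rm_extension import convert_base_to_extended
from tisskit.templates import validate_against_template
from tisskit.validator import (
    ArchetypeRepository,
    check_value_constraint,
    validate_instance,
)


@pytest.fixture(scope="module")
def institutional(repo_module):
    return repo_module.get(fixtures.INSTITUTIONAL_CLAIM)


@pytest.fixture(scope="module")
def repo_module():
    return fixtures.default_repository(1)


def _entry(items, archetype_id=fixtures.INSTITUTIONAL_CLAIM):
    return AdminEntry(
        name="claim header", archetype_node_id=NodeId("at0000"),
        archetype_id=archetype_id,
        data=ItemTree(name="components", archetype_node_id=NodeId("at0001"),
                      items=items))


def _el(code, name, value):
    return Element(name=name, archetype_node_id=NodeId(code), value=value)


class TestValidateInstance:
    def test_all_optional_elements_absent_is_valid(self, institutional, repo_module):
        rep = validate_instance(_entry([]), institutional, repo_module)
        assert rep.valid and rep.findings == []

    def test_duplicate_singleton_element_is_one_finding(self, institutional,
                                                        repo_module):
        items = [_el("at0004", "submission Date", TextValue("2026-01-01")),
                 _el("at0004", "submission Date", TextValue("2026-01-02"))]
        rep = validate_instance(_entry(items), institutional, repo_module)
        assert not rep.valid
        assert [(f.rule, f.path) for f in rep.findings] == \
            [(Rule.OCCURRENCES_EXCEEDED, "/data[at0001]/items[at0004]")]

    def test_repeatable_element_may_repeat(self, institutional, repo_module):
        items = [_el("at0002", "submission ID", TextValue("SUB-1")),
                 _el("at0002", "submission ID", TextValue("SUB-2"))]
        assert validate_instance(_entry(items), institutional, repo_module).valid

    def test_unknown_node_id_is_reported_at_its_path(self, institutional,
                                                     repo_module):
        rep = validate_instance(
            _entry([_el("at9999", "mystery", TextValue("?"))]),
            institutional, repo_module)
        assert [(f.rule, f.path) for f in rep.findings] == \
            [(Rule.NODE_ID_UNKNOWN, "/data[at0001]/items[at9999]")]

    def test_slot_accepts_included_archetype(self, institutional, repo_module):
        admission = Cluster(
            name="admission", archetype_node_id=NodeId("at0015"),
            archetype_id=fixtures.ADMISSION,
            items=[Element(name="type of admission",
                           archetype_node_id=NodeId("at0002"),
                           value=TextValue("elective"))])
        rep = validate_instance(_entry([admission]), institutional, repo_module)
        assert rep.valid

    def test_slot_alias_resolves_costs_to_total_costs(self, institutional,
                                                      repo_module):
        costs = Cluster(
            name="total costs", archetype_node_id=NodeId("at0015"),
            archetype_id=fixtures.COSTS_ALIAS,
            items=[Element(name="total costs",
                           archetype_node_id=NodeId("at0002"),
                           value=None)])
        rep = validate_instance(_entry([costs]), institutional, repo_module)
        assert rep.valid

    def test_slot_rejects_non_included_archetype(self, institutional, repo_module):
        wrong = Cluster(
            name="x", archetype_node_id=NodeId("at0015"),
            archetype_id=fixtures.PATIENT_EVALUATION,
            items=[Element(name="y", archetype_node_id=NodeId("at0002"),
                           value=None)])
        rep = validate_instance(_entry([wrong]), institutional, repo_module)
        assert [f.rule for f in rep.findings] == [Rule.SLOT_INCLUDE_VIOLATION]

    def test_slot_filler_missing_from_repo(self, institutional):
        bare = ArchetypeRepository()
        bare.add_alias(fixtures.COSTS_ALIAS, fixtures.TOTAL_COSTS)
        admission = Cluster(
            name="admission", archetype_node_id=NodeId("at0015"),
            archetype_id=fixtures.ADMISSION,
            items=[Element(name="z", archetype_node_id=NodeId("at0002"),
                           value=None)])
        rep = validate_instance(_entry([admission]), institutional, bare)
        assert [f.rule for f in rep.findings] == [Rule.SLOT_FILLER_INVALID]

    def test_slot_filler_content_recursively_validated(self, institutional,
                                                       repo_module):
        admission = Cluster(
            name="admission", archetype_node_id=NodeId("at0015"),
            archetype_id=fixtures.ADMISSION,
            items=[_el("at9998", "bogus", TextValue("?"))])
        rep = validate_instance(_entry([admission]), institutional, repo_module)
        assert [f.rule for f in rep.findings] == [Rule.NODE_ID_UNKNOWN]
        assert rep.findings[0].path == \
            "/data[at0001]/items[at0015]/items[at9998]"

    def test_extended_entry_satisfies_admin_entry_constraint(self, institutional,
                                                             repo_module):
        comp = make_composition("admission_claim", seed=9)
        ext = convert_base_to_extended(comp)
        entry = ext.content[0]
        assert validate_instance(entry, institutional, repo_module).valid

    def test_unconstrained_attributes_are_permitted(self, institutional,
                                                    repo_module):
        entry = _entry([])
        entry.other_participations = []  # unconstrained but present attrs ok
        assert validate_instance(entry, institutional, repo_module).valid


class TestCheckValueConstraint:
    def test_text_matches_any_text(self):
        assert check_value_constraint(TextValue("x"),
                                      PrimitiveConstraint("DV_TEXT")) is None

    def test_coded_text_is_substitutable_for_text(self):
        v = CodedTextValue(value="a", code="a", terminology_id="t")
        assert check_value_constraint(v, PrimitiveConstraint("DV_TEXT")) is None

    def test_text_against_timestamp_is_a_mismatch(self):
        f = check_value_constraint(TextValue("2026"),
                                   PrimitiveConstraint("DV_DATE_TIME"))
        assert f is not None and f.rule is Rule.VALUE_TYPE_MISMATCH

    def test_timestamp_matches(self):
        assert check_value_constraint(DateTimeValue("2011-10-12T00:00:00"),
                                      PrimitiveConstraint("DV_DATE_TIME")) is None

    def test_null_value_means_explicitly_unknown(self):
        assert check_value_constraint(None, PrimitiveConstraint("DV_COUNT")) is None

    def test_count_against_text_is_a_mismatch(self):
        f = check_value_constraint(CountValue(1), PrimitiveConstraint("DV_TEXT"))
        assert f is not None and f.rule is Rule.VALUE_TYPE_MISMATCH


class TestReportProperties:
    def test_determinism_byte_identical(self, repo_module):
        comp = make_composition("admission_claim", seed=3)
        from tisskit.synth import default_context
        _repo, opts = default_context()
        r1 = validate_against_template(comp, opts["admission_claim"], repo_module)
        r2 = validate_against_template(comp, opts["admission_claim"], repo_module)
        assert r1.to_json() == r2.to_json()

    def test_findings_sorted_by_path(self, institutional, repo_module):
        items = [_el("at9999", "a", TextValue("x")),
                 _el("at0004", "submission Date", TextValue("2026-01-01")),
                 _el("at0004", "submission Date", TextValue("2026-01-02")),
                 _el("at8888", "b", TextValue("y"))]
        rep = validate_instance(_entry(items), institutional, repo_module)
        paths = [f.path for f in rep.findings]
        assert paths == sorted(paths)

    def test_removing_optional_subtree_keeps_validity(self, repo_module):
        """Monotonicity: dropping lower-bound-0 nodes never adds an ERROR."""
        from tisskit.synth import default_context
        _repo, opts = default_context()
        rng = random.Random(17)
        comp = make_composition("admission_claim", seed=13)
        opt = opts["admission_claim"]
        assert validate_against_template(comp, opt, repo_module).valid
        for _ in range(10):
            mutant = copy.deepcopy(comp)
            nodes = [n for _p, n in walk(mutant)]
            target = rng.choice(nodes)
            parent = next((n for _p, n in walk(mutant)
                           for _a, _i, c in children(n) if c is target), None)
            if parent is None or not hasattr(parent, "items") \
                    or len(getattr(parent, "items", [])) <= 1:
                continue
            parent.items.remove(target)
            assert validate_against_template(mutant, opt, repo_module).valid
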