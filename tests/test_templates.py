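"""Template engine: loading, flattening, restriction and form schemas."""

import copy

import pytest

from tests.conftest import make_composition
from tisskit import fixtures
from tisskit.adl import ArchetypeDefinition, ComplexObjectConstraint, Interval, iter_objects
from tisskit.report import Rule
from tisskit.rm_core import Cluster, Element, NodeId, TextValue
from tisskit.templates import (
    TemplateError,
    flatten,
    form_schema,
    load_template,
    validate_against_template,
)


@pytest.fixture(scope="module")
def repo():
    return fixtures.default_repository(1)


@pytest.fixture(scope="module")
def specs():
    return fixtures.template_specs()


class TestLoad:
    def test_consultation_template_loads(self, repo, specs):
        t = load_template(specs["consultation_claim"], repo)
        assert t.root_archetype == fixtures.TISS_CLAIM

    def test_template_files_round_trip(self, repo, specs, tmp_path):
        fixtures.build_templates(tmp_path)
        for name in specs:
            t = load_template(tmp_path / f"{name}.tpl.yaml", repo)
            assert t.name == name

    def test_excluding_mandatory_path_is_an_error(self, repo, specs):
        bad = copy.deepcopy(specs["admission_claim"])
        # the entry's item tree is a {1..1} node
        bad["exclusions"] = [f"{fixtures.INSTITUTIONAL_CLAIM}#/data[at0001]"]
        with pytest.raises(TemplateError, match="mandatory"):
            load_template(bad, repo)

    def test_widening_override_is_an_error(self, repo, specs):
        bad = copy.deepcopy(specs["consultation_claim"])
        key = next(iter(bad["occurrence_overrides"]))
        bad["occurrence_overrides"][key] = "0..*"  # source allows {0..1}
        with pytest.raises(TemplateError, match="widens"):
            load_template(bad, repo)

    def test_all_offenders_reported_together(self, repo, specs):
        bad = copy.deepcopy(specs["admission_claim"])
        bad["slot_fills"]["/content[at0001]"] = ["openEHR-EHR-SECTION.nope.v1"]
        bad["exclusions"] = ["/content[at0001]/data[at9999]"]
        with pytest.raises(TemplateError) as exc:
            load_template(bad, repo)
        assert len(exc.value.errors) >= 2

    def test_filler_outside_slot_includes_is_an_error(self, repo, specs):
        bad = copy.deepcopy(specs["admission_claim"])
        key = f"{fixtures.INSTITUTIONAL_CLAIM}#/data[at0001]/items[at0015]"
        bad["slot_fills"][key] = [fixtures.PATIENT_EVALUATION]
        with pytest.raises(TemplateError, match="not allowed by slot"):
            load_template(bad, repo)


class TestFlatten:
    def test_cluster_fillers_appear_under_the_claim_entry(self, repo, specs):
        opt = flatten(load_template(specs["admission_claim"], repo), repo)
        refs = {n.archetype_ref for n in iter_objects(opt.root)
                if isinstance(n, ComplexObjectConstraint) and n.archetype_ref}
        assert fixtures.ADMISSION in refs and fixtures.TOTAL_COSTS in refs

    def test_provenance_total_over_flattened_paths(self, repo, specs):
        opt = flatten(load_template(specs["admission_claim"], repo), repo)

        paths = set()

        def visit(node, path):
            paths.add(path or "/")
            for attr in getattr(node, "attributes", []):
                for c in attr.children:
                    nid = getattr(c, "node_id", None)
                    if nid is not None:
                        visit(c, f"{path}/{attr.name}[{nid.code}]")

        visit(opt.root, "")
        assert paths == set(opt.provenance)

    def test_no_restrictions_yields_slot_substitution_only(self, repo, specs):
        opt = flatten(load_template(specs["admission_authorization"], repo), repo)
        auth = repo.get(fixtures.AUTHORIZATION)
        flat_entry = opt.root.attributes[0].children[0]
        assert flat_entry.rm_type == "ADMIN_ENTRY"
        assert flat_entry.archetype_ref == fixtures.AUTHORIZATION
        def own_element_labels(node, is_root=True):
            if not is_root and node.archetype_ref is not None:
                return  # a filler subtree, not host content
            if node.rm_type == "ELEMENT":
                yield node.label
            for attr in node.attributes:
                for c in attr.children:
                    if isinstance(c, ComplexObjectConstraint):
                        yield from own_element_labels(c, is_root=False)

        src_labels = [n.label for n in iter_objects(auth.root)
                      if isinstance(n, ComplexObjectConstraint)
                      and n.rm_type == "ELEMENT"]
        assert list(own_element_labels(flat_entry)) == src_labels

    def test_flattening_without_slots_is_identity(self, repo):
        costs = repo.get(fixtures.TOTAL_COSTS)
        sub = fixtures.ArchetypeRepository()
        sub.add(costs)
        tdef = load_template({"name": "just_costs",
                              "root_archetype": fixtures.TOTAL_COSTS}, sub)
        opt = flatten(tdef, sub)
        stripped = copy.deepcopy(opt.root)
        for n in iter_objects(stripped):
            if isinstance(n, ComplexObjectConstraint):
                n.archetype_ref = None
        assert stripped == costs.root

    def test_circular_slot_fill_detected(self):
        repo = fixtures.ArchetypeRepository()
        text = ("CLUSTER[at0000] matches { items matches { "
                "allow_archetype CLUSTER[at0002] occurrences matches {0..*} "
                "matches { include archetype_id/value matches { "
                "openEHR-EHR-CLUSTER.loop.v1 } } } }")
        from tisskit.adl import parse_archetype
        repo.add(parse_archetype(text, archetype_id="openEHR-EHR-CLUSTER.loop.v1"))
        tdef = load_template(
            {"name": "loopy", "root_archetype": "openEHR-EHR-CLUSTER.loop.v1",
             "slot_fills": {"/items[at0002]": ["openEHR-EHR-CLUSTER.loop.v1"]}},
            repo)
        with pytest.raises(TemplateError, match="circular"):
            flatten(tdef, repo)

    def test_exclusion_narrows_to_zero_occurrences(self, repo, specs):
        opt = flatten(load_template(specs["consultation_claim"], repo), repo)
        obst = fixtures.element_code(fixtures.PATIENT_EVALUATION, "obstetrics")
        excluded = [n for n in iter_objects(opt.root)
                    if getattr(n, "node_id", None) is not None
                    and n.node_id.code == obst and n.rm_type == "CLUSTER"]
        assert excluded and all(n.occurrences == Interval(0, 0)
                                for n in excluded)


class TestValidateAgainstTemplate:
    def test_generated_claim_is_valid(self, repo, specs):
        from tisskit.synth import default_context
        _r, opts = default_context()
        comp = make_composition("dental_claim", seed=21)
        assert validate_against_template(comp, opts["dental_claim"], repo).valid

    def test_excluded_element_present_is_a_finding(self, repo, specs):
        from tisskit.synth import default_context
        _r, opts = default_context()
        comp = make_composition("consultation_claim", seed=22)
        evaluation = next(e for e in comp.content
                          if (e.archetype_id or "").endswith(
                              "patient_evaluation.v1"))
        obst_code = fixtures.element_code(fixtures.PATIENT_EVALUATION,
                                          "obstetrics")
        evaluation.data.items.append(Cluster(
            name="obstetrics", archetype_node_id=NodeId(obst_code),
            items=[Element(name="gestation",
                           archetype_node_id=NodeId("at0011"),
                           value=TextValue("yes"))]))
        rep = validate_against_template(comp, opts["consultation_claim"], repo)
        assert any(f.rule is Rule.OCCURRENCES_EXCEEDED
                   and f.path.endswith(f"items[{obst_code}]")
                   for f in rep.findings)

    def test_code_outside_binding_is_a_finding(self, repo):
        from tisskit.synth import default_context
        from tisskit.rm_core import CodedTextValue, walk
        _r, opts = default_context()
        comp = make_composition("consultation_claim", seed=23)
        for _p, n in walk(comp):
            if isinstance(n, Element) and isinstance(n.value, CodedTextValue) \
                    and n.value.terminology_id == "tiss_local":
                n.value = CodedTextValue(value="zzz", code="zzz",
                                         terminology_id="tiss_local")
        rep = validate_against_template(comp, opts["consultation_claim"], repo)
        assert any(f.rule is Rule.CODE_BINDING_VIOLATION for f in rep.findings)

    def test_template_is_at_least_as_strict_as_root_archetype(self, repo, specs):
        """Finding sets against the flattened template are supersets of those
        against the composition archetype alone."""
        import random
        from tisskit.synth import (GeneratorConfig, default_context,
                                   generate_composition, mutate_for_violation)
        _r, opts = default_context()
        rng = random.Random(5)
        tiss = repo.get(fixtures.TISS_CLAIM)
        from tisskit.validator import validate_instance
        for rule in (Rule.OCCURRENCES_EXCEEDED, Rule.VALUE_TYPE_MISMATCH,
                     Rule.NODE_ID_UNKNOWN):
            comp = generate_composition(
                GeneratorConfig(seed=31, template="admission_claim"))
            mut, _exp = mutate_for_violation(comp, rule, rng,
                                            opts["admission_claim"])
            root_findings = {(f.rule, f.path) for f in
                             validate_instance(mut, tiss, repo).findings}
            tpl_findings = {(f.rule, f.path) for f in validate_against_template(
                mut, opts["admission_claim"], repo).findings}
            assert root_findings <= tpl_findings


class TestFormSchema:
    def test_eleven_templates_ship(self, specs):
        assert set(specs) == set(fixtures.TEMPLATE_NAMES)
        assert len(specs) == 11

    def test_consultation_form_has_encounter_field(self, repo, specs):
        opt = flatten(load_template(specs["consultation_claim"], repo), repo)
        schema = form_schema(opt)
        field = next(f for f in schema.fields if f.label == "type of encounter")
        assert field.required  # narrowed to {1..1} by the template
        assert field.allowed_codes == ("first_visit", "follow_up",
                                       "prenatal", "emergency")

    def test_excluded_cluster_drops_its_leaf_fields(self, repo, specs):
        with_excl = flatten(load_template(specs["consultation_claim"], repo), repo)
        spec2 = copy.deepcopy(specs["consultation_claim"])
        spec2["exclusions"] = []
        without = flatten(load_template(spec2, repo), repo)
        # oracle: leaf elements inside the obstetrics cluster (10 direct +
        # 5 in the nested living-births breakdown)
        drop = len(form_schema(without).fields) - len(form_schema(with_excl).fields)
        assert drop == 15

    def test_all_optional_template_has_no_required_fields(self, repo, specs):
        opt = flatten(load_template(specs["tests_procedures_authorization"],
                                    repo), repo)
        assert all(not f.required for f in form_schema(opt).fields)

    def test_schema_is_byte_stable(self, repo, specs):
        opt1 = flatten(load_template(specs["dental_claim"], repo), repo)
        opt2 = flatten(load_template(specs["dental_claim"], repo), repo)
        assert form_schema(opt1).to_json() == form_schema(opt2).to_json()
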