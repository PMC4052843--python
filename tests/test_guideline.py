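import pytest

from strokeaudit import knowledge
from strokeaudit.guideline import (
    ArchetypeBinding, Guideline, GuidelineFormatError, Rule, parse_guideline,
    serialize_guideline, validate_guideline, guideline_from_dict,
    guideline_to_dict,
)
from strokeaudit.expr import parse_expression
from strokeaudit.terminology import TermGroup
from strokeaudit.knowledge import criteria as C

BUILDERS = {
    "thrombolysis_contraindications": knowledge.build_thrombolysis_guideline,
    "nihss_score": knowledge.build_nihss_guideline,
    "euro_stroke_criteria": knowledge.build_euro_criteria_guideline,
}


@pytest.mark.parametrize("gid", sorted(BUILDERS))
def test_shipped_files_match_programmatic_builders(gid):
    assert knowledge.load_guideline(gid) == BUILDERS[gid]()


@pytest.mark.parametrize("gid", sorted(BUILDERS))
def test_shipped_guidelines_roundtrip_through_text(gid):
    g = knowledge.load_guideline(gid)
    assert parse_guideline(serialize_guideline(g)) == g


@pytest.mark.parametrize("gid", sorted(BUILDERS))
def test_shipped_guidelines_roundtrip_through_dict(gid):
    g = knowledge.load_guideline(gid)
    assert guideline_from_dict(guideline_to_dict(g)) == g


@pytest.mark.parametrize("gid", sorted(BUILDERS))
def test_shipped_guidelines_validate_cleanly(gid, registry, store):
    assert validate_guideline(knowledge.load_guideline(gid), registry, store) == []


def _minimal(rules=(), bindings=None, groups=None):
    return Guideline("g", "", bindings or {}, groups or {}, tuple(rules))


def test_unbound_gt_code_is_a_violation(registry, store):
    rule = Rule("r1", (parse_expression("$gt9999 > 1"),),
                (parse_expression("$gt9998=true"),), 0)
    violations = validate_guideline(_minimal([rule]), registry, store)
    assert any(v.kind == "gt_ref" for v in violations)


def test_binding_to_nonexistent_path_is_a_violation(registry, store):
    bad = ArchetypeBinding("gt0001", C.DIAGNOSIS, "/data[at0001]/items[at9999]",
                           "input")
    violations = validate_guideline(_minimal(bindings={"gt0001": bad}),
                                    registry, store)
    assert any(v.kind == "binding" for v in violations)


def test_is_a_against_unresolved_group_is_a_violation(registry, store):
    bindings = {
        "gt0003": ArchetypeBinding("gt0003", C.DIAGNOSIS, C.DIAG_CODE, "input"),
        "gt0015": ArchetypeBinding(
            "gt0015", C.THROMB_EVAL, "/data[at0001]/items[at0002]", "output"),
    }
    rule = Rule("r1", (parse_expression("$gt0003 is_a local::gt0999|x|"),),
                (parse_expression("$gt0015=true"),), 0)
    violations = validate_guideline(_minimal([rule], bindings), registry, store)
    assert any(v.kind == "term_group" for v in violations)


def test_assignment_to_input_binding_is_a_violation(registry, store):
    bindings = {
        "gt0009": ArchetypeBinding("gt0009", C.GLUCOSE_OBS, C.GLUCOSE_VALUE,
                                   "input"),
    }
    rule = Rule("r1", (), (parse_expression("$gt0009=1"),), 0)
    violations = validate_guideline(_minimal([rule], bindings), registry, store)
    assert any(v.kind == "direction" for v in violations)


def test_type_incompatible_comparison_is_a_violation(registry, store):
    bindings = {
        "gt0004": ArchetypeBinding("gt0004", C.DIAGNOSIS, C.DIAG_ONSET, "input"),
        "gt0015": ArchetypeBinding(
            "gt0015", C.THROMB_EVAL, "/data[at0001]/items[at0002]", "output"),
    }
    rule = Rule("r1", (parse_expression("$gt0004 > 25"),),
                (parse_expression("$gt0015=true"),), 0)
    violations = validate_guideline(_minimal([rule], bindings), registry, store)
    assert any(v.kind == "type" for v in violations)


def test_empty_rules_section_is_valid(registry, store):
    text = serialize_guideline(_minimal())
    g = parse_guideline(text)
    assert g.rules == ()
    assert validate_guideline(g, registry, store) == []


def test_duplicate_rule_ids_rejected_on_parse():
    g = knowledge.load_guideline("nihss_score")
    text = serialize_guideline(g)
    dup = text.replace("item01_level1 = <", "item01_level0 = <", 1)
    assert dup != text
    with pytest.raises(Exception):
        parse_guideline(dup)


def test_rule_requires_nonempty_then():
    with pytest.raises(GuidelineFormatError):
        Rule("r1", (), (), 0)


def test_term_group_requires_bindings():
    import strokeaudit.terminology as term
    with pytest.raises(term.TerminologyError):
        TermGroup("gt0102", "stroke", {"SNOMED-CT": ()})
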