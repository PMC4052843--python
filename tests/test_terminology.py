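import pytest
from hypothesis import given, settings, strategies as st

from strokeaudit.terminology import (
    CodeSystem, TermGroup, TerminologyError, TerminologyStore,
    UnknownCodeError, load_terminology, matches_group,
)
from strokeaudit.values import CodedText


def _toy_store():
    return TerminologyStore([CodeSystem(
        "SNOMED-CT",
        {"root": "Root", "230690007": "Stroke", "child": "Ischaemic stroke",
         "50960005": "Haemorrhage"},
        {"230690007": ("root",), "child": ("230690007",),
         "50960005": ("root",)},
    )])


def test_is_a_reflexive():
    store = _toy_store()
    assert store.is_a("SNOMED-CT", "230690007", "230690007")


def test_is_a_transitive_on_toy_hierarchy():
    store = _toy_store()
    assert store.is_a("SNOMED-CT", "child", "230690007")
    assert store.is_a("SNOMED-CT", "child", "root")


def test_is_a_unrelated_codes_false():
    store = _toy_store()
    assert not store.is_a("SNOMED-CT", "50960005", "230690007")


def test_is_a_unknown_code_errors():
    store = _toy_store()
    with pytest.raises(UnknownCodeError):
        store.is_a("SNOMED-CT", "nope", "root")
    with pytest.raises(UnknownCodeError):
        store.is_a("ICD10", "I64", "I64")


def test_empty_store_errors_on_every_query():
    store = load_terminology({})
    with pytest.raises(UnknownCodeError):
        store.is_a("SNOMED-CT", "x", "x")


def test_cycle_detected_on_load():
    with pytest.raises(TerminologyError, match="cycle"):
        load_terminology({"X": {"a": {"parents": ["b"]}, "b": {"parents": ["a"]}}})


def test_dangling_parent_detected_on_load():
    with pytest.raises(TerminologyError, match="dangling"):
        load_terminology({"X": {"a": {"parents": ["ghost"]}}})


def test_group_requires_at_least_one_binding():
    with pytest.raises(TerminologyError):
        TermGroup("gt0102", "stroke", {})


def test_matches_group_across_code_systems(store):
    stroke = TermGroup("gt0102", "stroke",
                       {"ICD10": ("I64",), "SNOMED-CT": ("230690007",)})
    assert matches_group(CodedText("ICD10", "I64"), stroke, store)
    assert matches_group(CodedText("SNOMED-CT", "230690007"), stroke, store)
    postictal = TermGroup("gt0105", "postictal paresis",
                          {"SNOMED-CT": ("66264000",), "ICD10": ("G83.8",)})
    assert matches_group(CodedText("SNOMED-CT", "66264000"), postictal, store)


def test_matches_group_unbound_system_is_false(store):
    stroke = TermGroup("gt0102", "stroke",
                       {"ICD10": ("I64",), "SNOMED-CT": ("230690007",)})
    assert not matches_group(CodedText("ATC", "C07"), stroke, store)


def test_icd10_prefix_nesting_via_parent_links(store):
    group = TermGroup("g", "paralytic", {"ICD10": ("G83",)})
    assert matches_group(CodedText("ICD10", "G83.8"), group, store)


def test_shipped_store_contains_published_codes(store):
    for system, code in [("SNOMED-CT", "230690007"), ("ICD10", "I64"),
                         ("SNOMED-CT", "66264000"), ("ICD10", "G83.8"),
                         ("SNOMED-CT", "50960005"), ("SNOMED-CT", "12738006")]:
        assert store.has_code(system, code), (system, code)


# --- property tests ---------------------------------------------------------

def _brute_force_reachable(parents, code, ancestor):
    seen, frontier = {code}, [code]
    while frontier:
        for p in parents.get(frontier.pop(), ()):
            if p not in seen:
                seen.add(p)
                frontier.append(p)
    return ancestor in seen


@st.composite
def _random_dag(draw):
    n = draw(st.integers(min_value=1, max_value=50))
    codes = [f"c{i}" for i in range(n)]
    parents = {}
    for i in range(1, n):
        k = draw(st.integers(min_value=0, max_value=min(3, i)))
        if k:
            # parents only among earlier codes -> acyclic by construction
            idx = draw(st.lists(st.integers(min_value=0, max_value=i - 1),
                                min_size=k, max_size=k, unique=True))
            parents[codes[i]] = tuple(codes[j] for j in idx)
    return codes, parents


@settings(deadline=None, max_examples=60)
@given(_random_dag(), st.data())
def test_is_a_agrees_with_brute_force_reachability(dag, data):
    codes, parents = dag
    store = TerminologyStore([
        CodeSystem("X", {c: "" for c in codes}, parents)])
    a = data.draw(st.sampled_from(codes))
    b = data.draw(st.sampled_from(codes))
    assert store.is_a("X", a, b) == _brute_force_reachable(parents, a, b)


@settings(deadline=None, max_examples=40)
@given(_random_dag(), st.data())
def test_matches_group_monotone_under_code_addition(dag, data):
    codes, parents = dag
    store = TerminologyStore([CodeSystem("X", {c: "" for c in codes}, parents)])
    base = data.draw(st.lists(st.sampled_from(codes), min_size=1, max_size=5))
    extra = data.draw(st.lists(st.sampled_from(codes), min_size=0, max_size=5))
    value = CodedText("X", data.draw(st.sampled_from(codes)))
    small = TermGroup("g", "", {"X": tuple(base)})
    large = TermGroup("g", "", {"X": tuple(base) + tuple(extra)})
    if matches_group(value, small, store):
        assert matches_group(value, large, store)
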