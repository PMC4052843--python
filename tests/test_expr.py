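import pytest
from hypothesis import given, settings, strategies as st

from strokeaudit.expr import (
    And, Arith, Assignment, CodedLiteral, Comparison, CurrentDateTime,
    DurationLiteral, Exists, ExprSyntaxError, GtRef, IsA, Literal, Not, Or,
    gt_refs, parse_expression, unparse,
)


def test_comparison_against_count_threshold():
    assert parse_expression("$gt0008>25") == \
        Comparison(GtRef("gt0008"), ">", Literal(25))


def test_then_position_boolean_assignment():
    assert parse_expression("$gt0016=true") == \
        Assignment(GtRef("gt0016"), Literal(True))


def test_subsumption_operator_with_group_label():
    assert parse_expression("$gt0003 is_a local::gt0102|stroke|") == \
        IsA(GtRef("gt0003"), "gt0102", "stroke")


def test_datetime_arithmetic_with_current_datetime():
    node = parse_expression("$gt0004 + PT4H30M < currentDateTime")
    assert node == Comparison(
        Arith("+", GtRef("gt0004"), DurationLiteral("PT4H30M")),
        "<", CurrentDateTime())


def test_boolean_connectives_and_precedence():
    node = parse_expression("$gt0009 < 3 || $gt0009 > 22 && $gt0008 > 25")
    assert isinstance(node, Or)
    assert isinstance(node.parts[1], And)


def test_negation_wraps_whole_group():
    node = parse_expression("!($gt0003 is_a local::gt0102|stroke|)")
    assert node == Not(IsA(GtRef("gt0003"), "gt0102", "stroke"))


def test_exists_reads_a_reference():
    assert parse_expression("exists($gt0101)") == Exists(GtRef("gt0101"))


def test_assignment_of_summed_references():
    node = parse_expression("$gt0200 = $gt0101 + $gt0102")
    assert node == Assignment(
        GtRef("gt0200"), Arith("+", GtRef("gt0101"), GtRef("gt0102")))


@pytest.mark.parametrize("bad", [
    "$gt0008>",            # dangling operator
    "$gt0008",             # bare term is not a condition
    ">25",
    "$gt0003 is_a SNOMED-CT::230690007",  # group must be a local gt-code
    "$gt0008 >< 25",
    "(($gt0008>25)",
    "unknownIdent > 2",
])
def test_syntax_errors_carry_a_position(bad):
    with pytest.raises(ExprSyntaxError) as exc:
        parse_expression(bad)
    assert exc.value.position >= 0


def test_bare_assignment_inside_condition_is_an_error():
    with pytest.raises(ExprSyntaxError, match="'=='"):
        parse_expression("$gt0008>25 && $gt0016=true")


def test_gt_refs_collects_all_references():
    node = parse_expression("$gt0001 > 2 && exists($gt0002) || "
                            "$gt0003 is_a local::gt0102|x|")
    assert gt_refs(node) == {"gt0001", "gt0002", "gt0003"}


# --- round-trip property ----------------------------------------------------

_gtref = st.integers(min_value=0, max_value=300).map(lambda n: GtRef(f"gt{n:04d}"))
_literal = st.one_of(
    st.integers(min_value=0, max_value=10**6).map(Literal),
    st.floats(min_value=0, max_value=1e6, allow_nan=False,
              allow_infinity=False).map(lambda f: Literal(round(f, 4))),
    st.booleans().map(Literal),
    st.text(alphabet=st.characters(codec="ascii", exclude_characters="\\'\n"),
            max_size=12).map(Literal),
)
_coded = st.tuples(
    st.sampled_from(["SNOMED-CT", "ICD10", "ATC", "local"]),
    st.from_regex(r"[A-Za-z0-9.]{1,8}", fullmatch=True),
    st.text(alphabet=st.characters(codec="ascii", exclude_characters="|]\n"),
            max_size=10),
).map(lambda t: CodedLiteral(*t))
_duration = st.sampled_from(
    ["PT4H30M", "P7D", "P30D", "P90D", "PT72H", "PT30M", "P1DT6H"]
).map(DurationLiteral)
_term = st.one_of(_gtref, _literal, _coded, _duration, st.just(CurrentDateTime()))


_simple = st.one_of(
    st.builds(Comparison, _term, st.sampled_from(
        ["==", "!=", "<", "<=", ">", ">="]), _term),
    st.builds(IsA, _gtref,
              st.integers(min_value=0, max_value=300).map(lambda n: f"gt{n:04d}"),
              st.text(alphabet=st.characters(codec="ascii",
                                             exclude_characters="|\n"),
                      max_size=10)),
    st.builds(Exists, _gtref),
)


@st.composite
def _cond(draw, depth=0, exclude=""):
    # the parser flattens conjunction/disjunction chains, so direct
    # And-in-And / Or-in-Or nesting cannot round-trip and is not generated
    options = ["simple"]
    if depth < 3:
        options += [k for k in ("not", "and", "or") if k not in exclude]
    kind = draw(st.sampled_from(options))
    if kind == "simple":
        return draw(_simple)
    if kind == "not":
        return Not(draw(_cond(depth=depth + 1)))
    n = draw(st.integers(min_value=2, max_value=3))
    if kind == "and":
        return And(tuple(draw(_cond(depth=depth + 1, exclude="and"))
                         for _ in range(n)))
    return Or(tuple(draw(_cond(depth=depth + 1, exclude="or"))
                    for _ in range(n)))


_condition = _cond()


@settings(deadline=None, max_examples=150)
@given(_condition)
def test_unparse_parse_roundtrip_for_conditions(cond):
    assert parse_expression(unparse(cond)) == cond


@settings(deadline=None, max_examples=80)
@given(_gtref, st.one_of(_literal, _coded))
def test_unparse_parse_roundtrip_for_assignments(target, value):
    node = Assignment(target, value)
    assert parse_expression(unparse(node)) == node


@settings(deadline=None, max_examples=200)
@given(st.text(max_size=40))
def test_grammar_totality_every_string_parses_or_positions_an_error(text):
    try:
        parse_expression(text)
    except ExprSyntaxError as exc:
        assert 0 <= exc.position <= len(text)
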