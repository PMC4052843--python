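import random
from datetime import datetime, timedelta, timezone

import pytest

from strokeaudit import knowledge
from strokeaudit.engine import (
    UNKNOWN, EvaluationContext, apply_outputs, bind_inputs, eval_condition,
    run_guideline, run_chain,
)
from strokeaudit.expr import parse_expression
from strokeaudit.guideline import Guideline
from strokeaudit.model import Entry, PatientCase, get_value
from strokeaudit.cohort import generate_case, probe_case, PROFILES
from strokeaudit.knowledge import criteria as C
from strokeaudit.knowledge.nihss import MAX_TOTAL, NIHSS_ITEMS
from strokeaudit.values import Boolean, CodedText, Count, DateTime, Quantity

UTC = timezone.utc
T0 = datetime(2014, 3, 1, 12, 0, tzinfo=UTC)


def _diag_entry(code, onset, t=None):
    return Entry(C.DIAGNOSIS, "EVALUATION", t or onset,
                 {C.DIAG_CODE: code, C.DIAG_ONSET: DateTime(onset)})


def _proc_entry(code, when):
    return Entry(C.PROCEDURE, "ACTION", when,
                 {C.PROC_CODE: code, C.PROC_TIME: DateTime(when)})


@pytest.fixture(scope="module")
def thromb(guidelines):
    return guidelines["thrombolysis_contraindications"]


# --- bind_inputs ------------------------------------------------------------

def test_two_diagnosis_entries_give_two_candidate_tuples(thromb):
    case = PatientCase("x", T0, (
        _diag_entry(CodedText("ICD10", "I64"), T0 - timedelta(hours=2)),
        _diag_entry(CodedText("ICD10", "G43"), T0 - timedelta(days=30)),
    ))
    tuples = bind_inputs(thromb, case)["haemorrhage_history_set_true"]
    assert len(tuples) == 2


def test_rule_without_entries_gets_no_tuples(thromb):
    case = PatientCase("x", T0, ())
    assert bind_inputs(thromb, case)["nihss_above_25_set_true"] == []


def test_diagnosis_procedure_join_is_cartesian(thromb):
    diags = [_diag_entry(CodedText("ICD10", "I64"),
                         T0 - timedelta(days=d)) for d in (1, 2)]
    procs = [_proc_entry(CodedText("SNOMED-CT", "29303009"),
                         T0 - timedelta(days=d)) for d in (3, 4, 5)]
    case = PatientCase("x", T0, tuple(diags + procs))
    tuples = bind_inputs(thromb, case)["last_three_months_event_set_true"]
    assert len(tuples) == 6


# --- eval_condition ---------------------------------------------------------

def _ctx(thromb, registry, store, case):
    return EvaluationContext(case, case.reference_time, thromb, registry, store)


def _nihss_entry_with_total(total):
    return Entry(C.NIHSS_OBS, "OBSERVATION", T0,
                 {C.NIHSS_TOTAL: Count(total)})


@pytest.mark.parametrize("total,expected", [(26, True), (25, False)])
def test_strict_nihss_threshold(thromb, registry, store, total, expected):
    cond = parse_expression("$gt0008 > 25")
    entry = _nihss_entry_with_total(total)
    case = PatientCase("x", T0, (entry,))
    result = eval_condition(cond, _ctx(thromb, registry, store, case),
                            {C.NIHSS_OBS: entry})
    assert result is expected


def test_missing_value_evaluates_unknown(thromb, registry, store):
    cond = parse_expression("$gt0008 > 25")
    case = PatientCase("x", T0, ())
    result = eval_condition(cond, _ctx(thromb, registry, store, case),
                            {C.NIHSS_OBS: None})
    assert result is UNKNOWN


def test_strict_low_glucose_bound(thromb, registry, store):
    cond = parse_expression("$gt0009 < 3")
    entry = Entry(C.GLUCOSE_OBS, "OBSERVATION", T0,
                  {C.GLUCOSE_VALUE: Quantity(2.9, "mmol/l")})
    case = PatientCase("x", T0, (entry,))
    assert eval_condition(cond, _ctx(thromb, registry, store, case),
                          {C.GLUCOSE_OBS: entry}) is True


def test_kleene_negation_propagates_unknown(thromb, registry, store):
    cond = parse_expression("!($gt0008 > 25)")
    case = PatientCase("x", T0, ())
    assert eval_condition(cond, _ctx(thromb, registry, store, case),
                          {C.NIHSS_OBS: None}) is UNKNOWN


# --- run_guideline ----------------------------------------------------------

def _nihss_flag(case, guidelines, registry, store):
    chained, results = run_chain(
        [guidelines["nihss_score"], guidelines["thrombolysis_contraindications"]],
        case, registry=registry, store=store)
    thromb_result = results["thrombolysis_contraindications"]
    return chained, thromb_result.outputs.get(
        (C.THROMB_EVAL, "/data[at0001]/items[at0003]"))


def test_all_item_levels_zero_totals_zero_and_flag_false(
        guidelines, registry, store):
    case = probe_case(nihss_total=0)
    chained, flag = _nihss_flag(case, guidelines, registry, store)
    assert get_value(chained, C.NIHSS_OBS, C.NIHSS_TOTAL) == [Count(0)]
    assert flag == Boolean(False)


def test_item_maxima_total_forty_two_and_flag_true(guidelines, registry, store):
    case = probe_case(nihss_total=MAX_TOTAL)
    chained, flag = _nihss_flag(case, guidelines, registry, store)
    assert get_value(chained, C.NIHSS_OBS, C.NIHSS_TOTAL) == [Count(42)]
    assert flag == Boolean(True)


def test_single_level_two_item_totals_two(guidelines, registry, store):
    case = probe_case(nihss_total=2)
    chained, _ = _nihss_flag(case, guidelines, registry, store)
    assert get_value(chained, C.NIHSS_OBS, C.NIHSS_TOTAL) == [Count(2)]


def test_onset_five_hours_ago_raises_window_flag(guidelines, registry, store):
    result = run_guideline(guidelines["thrombolysis_contraindications"],
                           probe_case(onset_hours=5.0),
                           registry=registry, store=store)
    assert result.outputs[(C.THROMB_EVAL, "/data[at0001]/items[at0002]")] == \
        Boolean(True)


def test_low_saturation_recommends_nasal_canula_oxygen(
        guidelines, registry, store):
    result = run_guideline(guidelines["euro_stroke_criteria"],
                           probe_case(spo2=94.0), registry=registry, store=store)
    assert result.outputs[(C.PROCEDURE, C.GAS_GAS)] == \
        CodedText("SNOMED-CT", "24099007")
    assert result.outputs[(C.PROCEDURE, C.GAS_DELIVERY)] == \
        CodedText("local", "at0006")


def test_missing_input_leaves_flag_indeterminate_not_false(
        guidelines, registry, store):
    case = probe_case(glucose=None)
    result = run_guideline(guidelines["thrombolysis_contraindications"], case,
                           registry=registry, store=store)
    flag = (C.THROMB_EVAL, "/data[at0001]/items[at0005]")
    assert flag not in result.outputs
    assert flag in result.indeterminate


def test_monotone_flag_adding_qualifying_entry_never_clears_it(
        guidelines, registry, store):
    g = guidelines["thrombolysis_contraindications"]
    base = probe_case()
    flag = (C.THROMB_EVAL, "/data[at0001]/items[at0006]")
    assert run_guideline(g, base, registry=registry,
                         store=store).outputs[flag] == Boolean(False)
    qualifying = _diag_entry(CodedText("SNOMED-CT", "274100004"),
                             T0 - timedelta(days=400))
    richer = PatientCase(base.case_id, base.reference_time,
                         base.entries + (qualifying,))
    assert run_guideline(g, richer, registry=registry,
                         store=store).outputs[flag] == Boolean(True)


def test_fixpoint_is_order_independent_on_shipped_content(
        guidelines, registry, store):
    rng = random.Random(42)
    cases = [generate_case(p, seed=5) for p in PROFILES[:8]]
    for gid, g in guidelines.items():
        for case in cases:
            baseline = run_guideline(g, case, registry=registry, store=store)
            rules = list(g.rules)
            rng.shuffle(rules)
            shuffled = Guideline(g.guideline_id, g.description, g.bindings,
                                 g.term_groups, tuple(rules))
            result = run_guideline(shuffled, case, registry=registry, store=store)
            assert result.outputs == baseline.outputs, (gid, case.case_id)
            assert result.indeterminate == baseline.indeterminate


def test_fixpoint_reached_in_few_passes(guidelines, registry, store):
    case = probe_case()
    result = run_guideline(guidelines["nihss_score"], case,
                           registry=registry, store=store)
    assert result.passes <= 3
    assert "total_score" in result.fired


def test_apply_outputs_creates_missing_evaluation_entry(
        guidelines, registry, store):
    case = probe_case()
    result = run_guideline(guidelines["thrombolysis_contraindications"], case,
                           registry=registry, store=store)
    chained = apply_outputs(case, result, registry)
    flags = get_value(chained, C.THROMB_EVAL, "/data[at0001]/items[at0002]")
    assert flags == [Boolean(False)]
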