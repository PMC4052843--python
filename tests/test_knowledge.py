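import random
from datetime import timedelta

import pytest

from strokeaudit import knowledge
from strokeaudit.compliance import (
    INDETERMINATE, NOT_TRIGGERED, TRIGGERED, engine_check, oracle_check,
)
from strokeaudit.cohort import probe_case, random_item_vector
from strokeaudit.engine import run_guideline, run_chain
from strokeaudit.model import Entry, PatientCase, get_value
from strokeaudit.knowledge import criteria as C
from strokeaudit.knowledge.nihss import MAX_TOTAL, NIHSS_ITEMS
from strokeaudit.values import Boolean, CodedText, Count, DateTime

#: published yes/no assignment for the nineteen contraindications, in order
EXPECTED_REPRESENTED = [
    True, False, False, True, True, False, True, False, True, True,
    False, True, True, True, True, True, True, True, True,
]


def test_nineteen_criteria_with_fourteen_represented():
    assert len(knowledge.CONTRAINDICATIONS) == 19
    assert [c.represented for c in knowledge.CONTRAINDICATIONS] == \
        EXPECTED_REPRESENTED
    assert sum(EXPECTED_REPRESENTED) == 14


def test_unrepresented_criteria_carry_no_flag_binding():
    for c in knowledge.CONTRAINDICATIONS:
        if not c.represented:
            assert c.flag_path is None


def test_thrombolysis_guideline_settable_flags_match_represented_criteria():
    g = knowledge.build_thrombolysis_guideline()
    flag_paths = {
        b.path for b in g.bindings.values()
        if b.direction == "output" and b.archetype_id == C.THROMB_EVAL
    }
    criterion_paths = {
        c.flag_path for c in knowledge.CONTRAINDICATIONS if c.represented
    }
    assert flag_paths == criterion_paths
    assert len(flag_paths) == 14


def test_nihss_instrument_shape():
    assert len(NIHSS_ITEMS) == 15
    assert MAX_TOTAL == 42
    scoring_rules = [r for r in knowledge.build_nihss_guideline().rules
                     if r.rule_id.startswith("item")]
    assert len(scoring_rules) == sum(i.max_score + 1 for i in NIHSS_ITEMS)


def test_clean_case_clears_all_fourteen_contraindications():
    verdicts = engine_check(probe_case())
    for c in knowledge.CONTRAINDICATIONS:
        if c.represented:
            assert verdicts[c.criterion_id] == NOT_TRIGGERED


def _with_extra(case, entry):
    return PatientCase(case.case_id, case.reference_time,
                       case.entries + (entry,))


def _history_diagnosis(case, code, days_before):
    onset = case.reference_time - timedelta(days=days_before)
    return Entry(C.DIAGNOSIS, "EVALUATION", onset, {
        C.DIAG_CODE: code,
        C.DIAG_ONSET: DateTime(onset),
    })


def test_prior_stroke_eighty_days_ago_triggers_three_month_criterion():
    case = probe_case()
    case = _with_extra(case, _history_diagnosis(
        case, CodedText("SNOMED-CT", "230690007"), 80))
    assert engine_check(case)["c18"] == TRIGGERED


def test_lumbar_puncture_eight_days_ago_clears_one_week_criterion():
    case = probe_case()
    when = case.reference_time - timedelta(days=8)
    case = _with_extra(case, Entry(C.PROCEDURE, "ACTION", when, {
        C.PROC_CODE: CodedText("SNOMED-CT", "91602002"),
        C.PROC_TIME: DateTime(when),
    }))
    assert engine_check(case)["c16"] == NOT_TRIGGERED


def test_lumbar_puncture_three_days_ago_triggers_one_week_criterion():
    case = probe_case()
    when = case.reference_time - timedelta(days=3)
    case = _with_extra(case, Entry(C.PROCEDURE, "ACTION", when, {
        C.PROC_CODE: CodedText("SNOMED-CT", "91602002"),
        C.PROC_TIME: DateTime(when),
    }))
    assert engine_check(case)["c16"] == TRIGGERED


def test_index_stroke_itself_does_not_count_as_history():
    # the acute episode (onset hours before the decision) must not trip the
    # three-month look-back, which targets pre-admission history
    assert engine_check(probe_case(onset_hours=3.0))["c18"] == NOT_TRIGGERED


def test_cardiac_set_diagnosis_triggers_example_two_criterion():
    case = probe_case()
    case = _with_extra(case, _history_diagnosis(
        case, CodedText("SNOMED-CT", "3238004", "Pericarditis"), 10))
    assert engine_check(case)["c15"] == TRIGGERED


def test_saturation_above_threshold_yields_no_oxygen_recommendation(
        guidelines, registry, store):
    verdicts = engine_check(probe_case(spo2=96.0))
    assert verdicts["e05"] == NOT_TRIGGERED
    result = run_guideline(guidelines["euro_stroke_criteria"],
                           probe_case(spo2=96.0), registry=registry, store=store)
    assert (C.PROCEDURE, C.GAS_GAS) not in result.outputs


def test_pyrexia_at_ten_hours_post_onset_raises_alert():
    case = probe_case(temp=37.6, onset_hours=12.0, temp_offset_hours=10.0)
    assert engine_check(case)["e04"] == TRIGGERED


def test_posterior_circulation_exam_justifies_mri():
    case = probe_case()
    entries = []
    for e in case.entries:
        if e.archetype_id == C.EXAM_OBS:
            e = Entry(e.archetype_id, e.entry_type, e.event_time, {
                C.EXAM_FINDINGS: CodedText(
                    "SNOMED-CT", "429993008", "Posterior circulation stroke"),
            })
        entries.append(e)
    case = PatientCase(case.case_id, case.reference_time, tuple(entries))
    assert engine_check(case)["e01"] == TRIGGERED


def test_temperature_only_before_onset_clears_monitoring_criterion():
    case = probe_case(temp_offset_hours=-2.0)
    verdicts = engine_check(case)
    assert verdicts["e03"] == NOT_TRIGGERED
    assert verdicts["e04"] == INDETERMINATE


def test_random_item_vectors_total_matches_brute_force_sum(
        guidelines, registry, store):
    rng = random.Random(7)
    levels = {code: score for item in NIHSS_ITEMS for code, score in item.levels}
    for _ in range(100):
        target = rng.randint(0, MAX_TOTAL)
        vector = random_item_vector(rng, target)
        assert sum(levels[code] for code in vector.values()) == target
        case = probe_case(nihss_total=None)
        case = _with_extra(case, Entry(
            C.NIHSS_OBS, "OBSERVATION",
            case.reference_time - timedelta(minutes=20),
            {path: CodedText("local", code) for path, code in vector.items()}))
        chained, _ = run_chain([guidelines["nihss_score"]], case,
                               registry=registry, store=store)
        assert get_value(chained, C.NIHSS_OBS, C.NIHSS_TOTAL) == [Count(target)]
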