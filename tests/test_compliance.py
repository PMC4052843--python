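import pytest

from strokeaudit import knowledge
from strokeaudit.compliance import (
    INDETERMINATE, NOT_TRIGGERED, TRIGGERED, audit, compare, engine_check,
    oracle_check,
)
from strokeaudit.cohort import PROFILES, generate_case, probe_case


def test_oracle_low_glucose_triggered(store):
    assert oracle_check(probe_case(glucose=2.9), store)["c07"] == TRIGGERED


def test_oracle_glucose_at_bound_not_triggered(store):
    assert oracle_check(probe_case(glucose=3.0), store)["c07"] == NOT_TRIGGERED


def test_oracle_missing_glucose_indeterminate(store):
    assert oracle_check(probe_case(glucose=None), store)["c07"] == INDETERMINATE


def test_compare_is_reflexive(store):
    vecs = {f"c{i}": oracle_check(generate_case(PROFILES[i], seed=i), store)
            for i in range(5)}
    summary = compare(vecs, vecs)
    assert summary.complete_match and summary.matches == 5


def test_compare_flags_single_mutated_cell(store):
    case = probe_case()
    ev = {"p": engine_check(case)}
    ov = {"p": dict(ev["p"])}
    ov["p"]["c07"] = TRIGGERED
    summary = compare(ev, ov)
    assert summary.matches == 0
    assert len(summary.discrepancies) == 1
    assert summary.discrepancies[0][:2] == ("p", "c07")


def test_compare_rejects_mismatched_case_ids():
    with pytest.raises(ValueError):
        compare({"a": {}}, {"b": {}})


def test_audit_counts_sum_to_cohort_size(default_cohort):
    report = audit(default_cohort)
    assert report.errors == []
    totals = (report.per_criterion[[TRIGGERED, NOT_TRIGGERED, INDETERMINATE]]
              .sum(axis=1))
    assert (totals == len(default_cohort)).all()
    assert 0 <= report.non_compliance_count <= len(default_cohort)


def test_audit_reports_rows_for_all_audited_criteria(default_cohort):
    report = audit(default_cohort[:3])
    assert list(report.per_criterion.criterion_id) == list(knowledge.VERDICT_KEYS)
    assert len(report.per_criterion) == 19


def test_audit_empty_cohort_is_all_zero():
    report = audit([])
    assert report.non_compliance_count == 0
    assert (report.per_criterion[[TRIGGERED, NOT_TRIGGERED, INDETERMINATE]]
            .to_numpy() == 0).all()


def test_audit_single_clean_case_triggers_nothing(store):
    report = audit([generate_case("clean", seed=1)])
    contra = report.per_criterion[
        report.per_criterion.criterion_id.str.startswith("c")]
    assert contra[TRIGGERED].sum() == 0


def test_audit_detects_thrombolysis_despite_contraindication():
    case = generate_case("thrombolysed_despite_late_onset", seed=4)
    report = audit([case])
    assert report.non_compliance_count == 1
    assert bool(report.case_summary.thrombolysis_given.iloc[0])


def test_audit_flags_untreated_low_saturation():
    flagged = audit([generate_case("low_spo2_untreated", seed=4)])
    treated = audit([generate_case("low_spo2_treated", seed=4)])
    assert bool(flagged.case_summary.oxygen_followup_flagged.iloc[0])
    assert not bool(treated.case_summary.oxygen_followup_flagged.iloc[0])


def test_engine_and_oracle_agree_on_fuzzed_cases(store):
    """Headline property: identical verdict vectors on randomised cases."""
    guidelines = knowledge.load_guidelines()
    registry = knowledge.registry()
    n = 0
    for seed in range(12):
        for profile in PROFILES:
            case = generate_case(profile, seed=seed)
            ev = engine_check(case, guidelines, registry, store)
            ov = oracle_check(case, store)
            assert ev == ov, (profile.profile_id, seed)
            n += 1
    assert n >= 300
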