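"""Programmatic construction of the three shipped guidelines.

These builders are the source of truth for the rule content; the ``.gdl``
files under ``data/guidelines/`` are their serialised form (regenerate
with ``scripts/generate_content.py``) and must parse back equal.

Rule-pair convention: every audited flag has a *set-false* rule (priority
20) and a *set-true* rule (priority 10).  Higher priority runs first and
the last assignment within a pass wins, so one qualifying entry always
forces the flag to true while a definitive negative is still recorded;
when neither rule can fire the flag stays indeterminate.

Temporal conventions (documented in the methods note): look-back windows
are fixed spans (last week = 168 h, last month = 30 d, last three months
= 90 d) measured back from the evaluation instant; diagnosis-history
windows additionally require the onset to predate the evaluation instant
by more than 24 h so the index stroke episode itself does not count as
"history".
"""
from __future__ import annotations

from ..expr import parse_expression, Assignment
from ..guideline import ArchetypeBinding, Guideline, Rule
from ..terminology import TermGroup
from . import criteria as C
from .nihss import NIHSS_ITEMS

__all__ = [
    "build_thrombolysis_guideline",
    "build_nihss_guideline",
    "build_euro_criteria_guideline",
]


def _rule(rule_id: str, priority: int, when: list[str], then: list[str]) -> Rule:
    when_ast = []
    for src in when:
        node = parse_expression(src)
        assert not isinstance(node, Assignment), src
        when_ast.append(node)
    then_ast = []
    for src in then:
        node = parse_expression(src)
        assert isinstance(node, Assignment), src
        then_ast.append(node)
    return Rule(rule_id, tuple(when_ast), tuple(then_ast), priority)


def _bind(code: str, archetype_id: str, path: str, direction: str) -> ArchetypeBinding:
    return ArchetypeBinding(code, archetype_id, path, direction)


def _pair(flag_gt: str, rule_stem: str, true_when: list[str],
          false_when: list[str]) -> list[Rule]:
    return [
        _rule(f"{rule_stem}_set_false", 20, false_when, [f"${flag_gt}=false"]),
        _rule(f"{rule_stem}_set_true", 10, true_when, [f"${flag_gt}=true"]),
    ]


def build_thrombolysis_guideline() -> Guideline:
    """The 14 objectively expressible thrombolysis contraindications."""
    bindings = {
        b.gt_code: b
        for b in [
            _bind("gt0003", C.DIAGNOSIS, C.DIAG_CODE, "input"),
            _bind("gt0004", C.DIAGNOSIS, C.DIAG_ONSET, "input"),
            _bind("gt0005", C.PROCEDURE, C.PROC_CODE, "input"),
            _bind("gt0006", C.PROCEDURE, C.PROC_TIME, "input"),
            _bind("gt0007", C.MEDICATION, C.MED_CODE, "input"),
            _bind("gt0008", C.NIHSS_OBS, C.NIHSS_TOTAL, "input"),
            _bind("gt0009", C.GLUCOSE_OBS, C.GLUCOSE_VALUE, "input"),
            _bind("gt0010", C.IMAGING, C.IMG_FINDINGS, "input"),
            _bind("gt0011", C.IMAGING, C.IMG_SITE, "input"),
            # one boolean flag per represented contraindication
            _bind("gt0015", C.THROMB_EVAL, "/data[at0001]/items[at0002]", "output"),
            _bind("gt0016", C.THROMB_EVAL, "/data[at0001]/items[at0003]", "output"),
            _bind("gt0017", C.THROMB_EVAL, "/data[at0001]/items[at0004]", "output"),
            _bind("gt0018", C.THROMB_EVAL, "/data[at0001]/items[at0005]", "output"),
            _bind("gt0019", C.THROMB_EVAL, "/data[at0001]/items[at0006]", "output"),
            _bind("gt0020", C.THROMB_EVAL, "/data[at0001]/items[at0007]", "output"),
            _bind("gt0021", C.THROMB_EVAL, "/data[at0001]/items[at0008]", "output"),
            _bind("gt0022", C.THROMB_EVAL, "/data[at0001]/items[at0009]", "output"),
            _bind("gt0023", C.THROMB_EVAL, "/data[at0001]/items[at0010]", "output"),
            _bind("gt0024", C.THROMB_EVAL, "/data[at0001]/items[at0011]", "output"),
            _bind("gt0025", C.THROMB_EVAL, "/data[at0001]/items[at0012]", "output"),
            _bind("gt0026", C.THROMB_EVAL, "/data[at0001]/items[at0013]", "output"),
            _bind("gt0027", C.THROMB_EVAL, "/data[at0001]/items[at0014]", "output"),
            _bind("gt0028", C.THROMB_EVAL, "/data[at0001]/items[at0015]", "output"),
        ]
    }
    groups = {
        g.group_code: g
        for g in [
            TermGroup("gt0102", "stroke",
                      {"SNOMED-CT": ("230690007",), "ICD10": ("I64",)}),
            TermGroup("gt0103", "cerebral haemorrhage or intracranial bleeding",
                      {"SNOMED-CT": ("274100004", "1386000"),
                       "ICD10": ("I61", "I62")}),
            TermGroup("gt0104", "explosive headache",
                      {"SNOMED-CT": ("95660002",), "ICD10": ("R51",)}),
            TermGroup("gt0105", "postictal paresis",
                      {"SNOMED-CT": ("66264000",), "ICD10": ("G83.8",)}),
            TermGroup("gt0106", "septic shock",
                      {"SNOMED-CT": ("76571007",), "ICD10": ("R57.2",)}),
            TermGroup("gt0107", "bleeding disorder",
                      {"SNOMED-CT": ("64779008",), "ICD10": ("D68",)}),
            TermGroup("gt0108", "anticoagulant agent", {"ATC": ("B01A",)}),
            TermGroup("gt0109", "cardiac, hepatic or pancreatic condition",
                      {"SNOMED-CT": ("56819008", "3238004", "91434003",
                                     "253276004", "84114007", "75694006",
                                     "235856003"),
                       "ICD10": ("I33", "I30", "I50", "K85", "K72")}),
            TermGroup("gt0110", "lumbar puncture or central venous catheter",
                      {"SNOMED-CT": ("91602002", "392247006")}),
            TermGroup("gt0111", "last-month diagnosis set",
                      {"SNOMED-CT": ("283545005", "51868009", "53298000"),
                       "ICD10": ("K26", "R31")}),
            TermGroup("gt0112", "organ operation or biopsy",
                      {"SNOMED-CT": ("86273004", "107963000")}),
            TermGroup("gt0113", "last-three-months diagnosis set",
                      {"SNOMED-CT": ("230690007", "82271004", "74474003"),
                       "ICD10": ("I64", "S06", "K92.2")}),
            TermGroup("gt0114", "operation in the central nervous system",
                      {"SNOMED-CT": ("118831003",)}),
            TermGroup("gt0115", "pregnancy or breastfeeding",
                      {"SNOMED-CT": ("77386006", "169750002"),
                       "ICD10": ("Z33", "Z39.1")}),
            TermGroup("gt0116", "childbirth",
                      {"SNOMED-CT": ("386216000",), "ICD10": ("O80",)}),
            TermGroup("gt0117", "haemorrhage finding",
                      {"SNOMED-CT": ("50960005",)}),
            TermGroup("gt0118", "brain", {"SNOMED-CT": ("12738006",)}),
        ]
    }

    rules: list[Rule] = []
    rules += _pair(
        "gt0015", "onset_window",
        ["$gt0003 is_a local::gt0102|stroke|",
         "$gt0004 + PT4H30M < currentDateTime"],
        ["$gt0003 is_a local::gt0102|stroke|",
         "$gt0004 + PT4H30M >= currentDateTime"],
    )
    rules += _pair("gt0016", "nihss_above_25", ["$gt0008 > 25"], ["$gt0008 <= 25"])
    rules += _pair(
        "gt0017", "ct_haemorrhage",
        ["$gt0010 is_a local::gt0117|haemorrhage|",
         "$gt0011 is_a local::gt0118|brain|"],
        ["!($gt0010 is_a local::gt0117|haemorrhage| && "
         "$gt0011 is_a local::gt0118|brain|)"],
    )
    rules += _pair(
        "gt0018", "glucose_out_of_range",
        ["$gt0009 < 3 || $gt0009 > 22"],
        ["$gt0009 >= 3", "$gt0009 <= 22"],
    )
    rules += _pair(
        "gt0019", "haemorrhage_history",
        ["$gt0003 is_a local::gt0103|cerebral haemorrhage or intracranial bleeding|"],
        ["!($gt0003 is_a local::gt0103|cerebral haemorrhage or intracranial bleeding|)"],
    )
    rules += _pair(
        "gt0020", "explosive_headache",
        ["$gt0003 is_a local::gt0104|explosive headache|"],
        ["!($gt0003 is_a local::gt0104|explosive headache|)"],
    )
    rules += _pair(
        "gt0021", "postictal_paresis",
        ["$gt0003 is_a local::gt0105|postictal paresis|"],
        ["!($gt0003 is_a local::gt0105|postictal paresis|)"],
    )
    rules += _pair(
        "gt0022", "septic_shock",
        ["$gt0003 is_a local::gt0106|septic shock|"],
        ["!($gt0003 is_a local::gt0106|septic shock|)"],
    )
    rules += _pair(
        "gt0023", "bleeding_disorder_or_anticoagulation",
        ["$gt0003 is_a local::gt0107|bleeding disorder| || "
         "$gt0007 is_a local::gt0108|anticoagulant agent|"],
        ["!($gt0003 is_a local::gt0107|bleeding disorder|)",
         "!($gt0007 is_a local::gt0108|anticoagulant agent|)"],
    )
    rules += _pair(
        "gt0024", "cardiac_hepatic_pancreatic",
        ["$gt0003 is_a local::gt0109|cardiac, hepatic or pancreatic condition|"],
        ["!($gt0003 is_a local::gt0109|cardiac, hepatic or pancreatic condition|)"],
    )
    rules += _pair(
        "gt0025", "last_week_procedure",
        ["$gt0005 is_a local::gt0110|lumbar puncture or central venous catheter|",
         "$gt0006 + P7D >= currentDateTime"],
        ["!($gt0005 is_a local::gt0110|lumbar puncture or central venous catheter| "
         "&& $gt0006 + P7D >= currentDateTime)"],
    )
    month_diag = ("$gt0003 is_a local::gt0111|last-month diagnosis set| && "
                  "$gt0004 + P30D >= currentDateTime && "
                  "$gt0004 + PT24H <= currentDateTime")
    month_proc = ("$gt0005 is_a local::gt0112|organ operation or biopsy| && "
                  "$gt0006 + P30D >= currentDateTime")
    rules += _pair(
        "gt0026", "last_month_event",
        [f"({month_diag}) || ({month_proc})"],
        [f"!({month_diag})", f"!({month_proc})"],
    )
    tri_diag = ("$gt0003 is_a local::gt0113|last-three-months diagnosis set| && "
                "$gt0004 + P90D >= currentDateTime && "
                "$gt0004 + PT24H <= currentDateTime")
    tri_proc = ("$gt0005 is_a local::gt0114|operation in the central nervous system| "
                "&& $gt0006 + P90D >= currentDateTime")
    rules += _pair(
        "gt0027", "last_three_months_event",
        [f"({tri_diag}) || ({tri_proc})"],
        [f"!({tri_diag})", f"!({tri_proc})"],
    )
    childbirth = ("$gt0003 is_a local::gt0116|childbirth| && "
                  "$gt0004 + P30D >= currentDateTime && "
                  "$gt0004 + PT24H <= currentDateTime")
    rules += _pair(
        "gt0028", "pregnancy_childbirth_breastfeeding",
        [f"$gt0003 is_a local::gt0115|pregnancy or breastfeeding| || ({childbirth})"],
        ["!($gt0003 is_a local::gt0115|pregnancy or breastfeeding|)",
         f"!({childbirth})"],
    )

    return Guideline(
        "thrombolysis_contraindications",
        "Screens an acute-stroke case for the objectively expressible "
        "contraindications to thrombolytic treatment; one boolean flag per "
        "criterion, three-valued (indeterminate when data is missing).",
        bindings,
        groups,
        tuple(rules),
    )


def build_nihss_guideline() -> Guideline:
    """NIHSS scoring: one rule per item level plus a summation rule."""
    bindings: dict[str, ArchetypeBinding] = {}
    for item in NIHSS_ITEMS:
        bindings[f"gt{item.index:04d}"] = _bind(
            f"gt{item.index:04d}", C.NIHSS_OBS, item.answer_path, "input")
        bindings[f"gt{100 + item.index:04d}"] = _bind(
            f"gt{100 + item.index:04d}", C.NIHSS_OBS, item.score_path, "output")
    bindings["gt0200"] = _bind("gt0200", C.NIHSS_OBS, C.NIHSS_TOTAL, "output")

    rules: list[Rule] = []
    for item in NIHSS_ITEMS:
        for code, score in item.levels:
            rules.append(_rule(
                f"item{item.index:02d}_level{score}", 10,
                [f"$gt{item.index:04d} == local::{code}"],
                [f"$gt{100 + item.index:04d}={score}"],
            ))
    score_refs = [f"$gt{100 + item.index:04d}" for item in NIHSS_ITEMS]
    rules.append(_rule(
        "total_score", 5,
        [f"exists({ref})" for ref in score_refs],
        ["$gt0200 = " + " + ".join(score_refs)],
    ))

    return Guideline(
        "nihss_score",
        "Maps each recorded NIHSS item answer to its integer contribution "
        "and totals the contributions into the observation's total-score "
        "element (0..42).",
        bindings,
        {},
        tuple(rules),
    )


def build_euro_criteria_guideline() -> Guideline:
    """Sampled compliance criteria from the European stroke guidelines."""
    bindings = {
        b.gt_code: b
        for b in [
            _bind("gt0003", C.DIAGNOSIS, C.DIAG_CODE, "input"),
            _bind("gt0004", C.DIAGNOSIS, C.DIAG_ONSET, "input"),
            _bind("gt0030", C.EXAM_OBS, C.EXAM_FINDINGS, "input"),
            _bind("gt0031", C.IMAGING, C.IMG_FINDINGS, "input"),
            _bind("gt0032", C.OXIMETRY_OBS, C.SPO2_VALUE, "input"),
            _bind("gt0033", C.TEMP_OBS, C.TEMP_VALUE, "input"),
            _bind("gt0034", C.TEMP_OBS, C.TEMP_TIME, "input"),
            _bind("gt0040", C.ALERT_EVAL, "/data[at0001]/items[at0002]", "output"),
            _bind("gt0041", C.ALERT_EVAL, "/data[at0001]/items[at0003]", "output"),
            _bind("gt0042", C.ALERT_EVAL, "/data[at0001]/items[at0004]", "output"),
            _bind("gt0043", C.ALERT_EVAL, "/data[at0001]/items[at0005]", "output"),
            _bind("gt0044", C.ALERT_EVAL, "/data[at0001]/items[at0006]", "output"),
            _bind("gt0045", C.PROCEDURE, C.GAS_GAS, "output"),
            _bind("gt0046", C.PROCEDURE, C.GAS_DELIVERY, "output"),
        ]
    }
    groups = {
        g.group_code: g
        for g in [
            TermGroup("gt0102", "stroke",
                      {"SNOMED-CT": ("230690007",), "ICD10": ("I64",)}),
            TermGroup("gt0130", "posterior circulation variety or uncommon aetiology",
                      {"SNOMED-CT": ("429993008",)}),
            TermGroup("gt0131", "stroke mimic suspected",
                      {"SNOMED-CT": ("373930000",)}),
            TermGroup("gt0132", "acute ischaemic deficit",
                      {"SNOMED-CT": ("50582007", "429993008")}),
        ]
    }

    in_window = "$gt0034 >= $gt0004 && $gt0034 <= $gt0004 + PT72H"
    rules: list[Rule] = []
    rules += _pair(
        "gt0040", "mri_justified",
        ["$gt0030 is_a local::gt0130|posterior circulation variety or uncommon "
         "aetiology| || $gt0031 is_a local::gt0131|stroke mimic suspected|"],
        ["!($gt0030 is_a local::gt0130|posterior circulation variety or "
         "uncommon aetiology|)",
         "!($gt0031 is_a local::gt0131|stroke mimic suspected|)"],
    )
    rules += _pair(
        "gt0041", "thrombolysis_indicated",
        ["$gt0030 is_a local::gt0132|acute ischaemic deficit|",
         "$gt0003 is_a local::gt0102|stroke|",
         "$gt0004 + PT4H30M >= currentDateTime"],
        ["!($gt0030 is_a local::gt0132|acute ischaemic deficit| && "
         "$gt0003 is_a local::gt0102|stroke| && "
         "$gt0004 + PT4H30M >= currentDateTime)"],
    )
    rules += _pair(
        "gt0042", "temperature_monitored",
        ["$gt0003 is_a local::gt0102|stroke|", in_window],
        ["$gt0003 is_a local::gt0102|stroke|", f"!({in_window})"],
    )
    rules += _pair(
        "gt0043", "pyrexia",
        ["$gt0003 is_a local::gt0102|stroke|", in_window, "$gt0033 > 37.5"],
        ["$gt0003 is_a local::gt0102|stroke|", in_window, "$gt0033 <= 37.5"],
    )
    rules.append(_rule(
        "oxygen_set_false", 20, ["$gt0032 >= 95"], ["$gt0044=false"]))
    rules.append(_rule(
        "oxygen_set_true", 10, ["$gt0032 < 95"],
        ["$gt0044=true",
         "$gt0045=SNOMED-CT::24099007|Oxygen gas|",
         "$gt0046=local::at0006|Nasal canula|"]))

    return Guideline(
        "euro_stroke_criteria",
        "Sampled compliance criteria from the European guidelines for "
        "ischaemic stroke management: MRI justification, thrombolysis "
        "indication, 72-hour temperature monitoring with a 37.5 C pyrexia "
        "alert, and oxygen administration below 95% saturation.",
        bindings,
        groups,
        tuple(rules),
    )
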