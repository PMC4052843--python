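"""Catalogue of the audited criteria and the archetype paths they live at.

Nineteen thrombolysis contraindications are catalogued; fourteen are
expressible as objective rules and carry an output flag in the
thrombolysis-contraindications evaluation archetype.  The remaining five
(vague wording — "unclear", "major", unstated temporal intervals) are kept
as specs with ``represented=False`` and are never evaluated.  Five further
compliance criteria from the European ischaemic-stroke management
guidelines carry flags in the alert evaluation archetype.
"""
from __future__ import annotations

from dataclasses import dataclass

# archetype identifiers -------------------------------------------------------
DIAGNOSIS = "openEHR-EHR-EVALUATION.problem_diagnosis"
THROMB_EVAL = "openEHR-EHR-EVALUATION.thrombolysis_contraindications"
NIHSS_OBS = "openEHR-EHR-OBSERVATION.nihss"
GLUCOSE_OBS = "openEHR-EHR-OBSERVATION.lab_test-blood_glucose"
OXIMETRY_OBS = "openEHR-EHR-OBSERVATION.indirect_oximetry"
TEMP_OBS = "openEHR-EHR-OBSERVATION.body_temperature"
BP_OBS = "openEHR-EHR-OBSERVATION.blood_pressure"
EXAM_OBS = "openEHR-EHR-OBSERVATION.exam"
PROCEDURE = "openEHR-EHR-ACTION.procedure"
IV_FLUID = "openEHR-EHR-ACTION.intravenous_fluid_administration"
ALERT_EVAL = "openEHR-EHR-EVALUATION.alert"
IMAGING = "openEHR-EHR-INSTRUCTION.imaging"
MEDICATION = "openEHR-EHR-INSTRUCTION.medication"

# frequently used element paths ----------------------------------------------
DIAG_CODE = "/data[at0001]/items[at0002.1]"
DIAG_ONSET = "/data[at0001]/items[at0003]"
DIAG_CONFIDENCE = "/data[at0001]/items[at0071]"
GLUCOSE_VALUE = "/data[at0001]/items[at0078]"
SPO2_VALUE = "/data[at0001]/items[at0006]"
TEMP_VALUE = "/data[at0001]/items[at0004]"
TEMP_TIME = "/data[at0001]/items[at0005]"
BP_SYSTOLIC = "/data[at0001]/items[at0004]"
BP_DIASTOLIC = "/data[at0001]/items[at0005]"
EXAM_FINDINGS = "/data[at0001]/items[at0010]"
PROC_CODE = "/description[at0001]/items[at0002]"
PROC_TIME = "/description[at0001]/items[at0003]"
GAS_PREFIX = "/description[openEHR-EHR-ITEM_TREE.gas_administration]"
GAS_GAS = GAS_PREFIX + "/items[at0001]"
GAS_DELIVERY = GAS_PREFIX + "/items[at0002]"
IMG_PREFIX = "/activities[at0001]/description[openEHR-EHR-ITEM_TREE.imaging]"
IMG_MODALITY = IMG_PREFIX + "/items[at0001]"
IMG_FINDINGS = IMG_PREFIX + "/items[at0002]"
IMG_SITE = IMG_PREFIX + "/items[at0003]"
MED_PREFIX = "/activities[at0001]/description[openEHR-EHR-ITEM_TREE.medication]"
MED_CODE = MED_PREFIX + "/items[at0001]"
NIHSS_TOTAL = "/data[at0001]/items[at0300]"


@dataclass(frozen=True)
class CriterionSpec:
    criterion_id: str
    title: str
    represented: bool
    flag_archetype: str | None = None
    flag_path: str | None = None


def _flag(n: int) -> str:
    return f"/data[at0001]/items[at{n:04d}]"


CONTRAINDICATIONS: tuple[CriterionSpec, ...] = (
    CriterionSpec("c01", "Stroke onset more than 4.5 hours ago",
                  True, THROMB_EVAL, _flag(2)),
    CriterionSpec("c02", "Symptom presentation suggesting another aetiology than "
                  "that of stroke and/or the patient recovered within 30 minutes",
                  False),
    CriterionSpec("c03", "Unclear stroke symptoms", False),
    CriterionSpec("c04", "National Institutes of Health Stroke Scale (NIHSS) "
                  "score higher than 25", True, THROMB_EVAL, _flag(3)),
    CriterionSpec("c05", "CT scan shows haemorrhage", True, THROMB_EVAL, _flag(4)),
    CriterionSpec("c06", "CT scan shows major stroke that covers more than 30% "
                  "of the middle cerebral artery", False),
    CriterionSpec("c07", "Blood glucose is lower than 3 mmol/litre or higher "
                  "than 22 mmol/litre", True, THROMB_EVAL, _flag(5)),
    CriterionSpec("c08", "Blood pressure is higher than 185/110 mmHg despite "
                  "two attempts of intravenous beta-blocking bolus treatment",
                  False),
    CriterionSpec("c09", "History of cerebral haemorrhage or intracranial "
                  "bleeding", True, THROMB_EVAL, _flag(6)),
    CriterionSpec("c10", "Patient describes an explosive headache",
                  True, THROMB_EVAL, _flag(7)),
    CriterionSpec("c11", "Ongoing or recent severe haemorrhage (extracranial "
                  "or intracranial)", False),
    CriterionSpec("c12", "Likely postictal paresis", True, THROMB_EVAL, _flag(8)),
    CriterionSpec("c13", "Suspected septic shock", True, THROMB_EVAL, _flag(9)),
    CriterionSpec("c14", "Bleeding disorder or anticoagulation treatment",
                  True, THROMB_EVAL, _flag(10)),
    CriterionSpec("c15", "One of the following: infectious endocarditis, "
                  "pericarditis, ventricular thrombosis, atrial septal aneurysm, "
                  "severe heart failure, pancreatitis, severe liver damage",
                  True, THROMB_EVAL, _flag(11)),
    CriterionSpec("c16", "One of the following in the last week: lumbar "
                  "puncture, central venous catheter", True, THROMB_EVAL, _flag(12)),
    CriterionSpec("c17", "One of the following in the last month: "
                  "operation/biopsy from parenchymatous organs, trauma with "
                  "internal injuries, duodenal ulcer, bleeding from the urinary "
                  "tract", True, THROMB_EVAL, _flag(13)),
    CriterionSpec("c18", "One of the following in the last three months: "
                  "stroke, head trauma, operation in the central nervous "
                  "system, definite gastrointestinal bleeding",
                  True, THROMB_EVAL, _flag(14)),
    CriterionSpec("c19", "Pregnancy, childbirth in the last month, "
                  "breastfeeding", True, THROMB_EVAL, _flag(15)),
)

EURO_CRITERIA: tuple[CriterionSpec, ...] = (
    CriterionSpec("e01", "An MRI of the brain is justified",
                  True, ALERT_EVAL, _flag(2)),
    CriterionSpec("e02", "Thrombolysis needs to be performed (ischaemic "
                  "deficit within 4.5 hours of onset)", True, ALERT_EVAL, _flag(3)),
    CriterionSpec("e03", "Body temperature monitored within the first 72 "
                  "hours after stroke onset", True, ALERT_EVAL, _flag(4)),
    CriterionSpec("e04", "Body temperature exceeded 37.5 degrees Celsius "
                  "within the monitoring window", True, ALERT_EVAL, _flag(5)),
    CriterionSpec("e05", "Oxygen administration recommended (oxygen "
                  "saturation below 95%)", True, ALERT_EVAL, _flag(6)),
)

CRITERIA: tuple[CriterionSpec, ...] = CONTRAINDICATIONS + EURO_CRITERIA

#: ids making up a per-case verdict vector, in reporting order
VERDICT_KEYS: tuple[str, ...] = tuple(
    c.criterion_id for c in CRITERIA if c.represented
)

REPRESENTED: tuple[CriterionSpec, ...] = tuple(c for c in CRITERIA if c.represented)
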