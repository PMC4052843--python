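"""Seeded synthetic generator of acute-stroke patient cases.

The default cohort reproduces the shape of the study it emulates: 49 mock
patients with differing features so that every represented criterion is
triggered by at least one case and cleared by at least one.  Cases cycle
through a catalogue of scenario profiles; each profile perturbs a common
"clean" scaffold (an acute ischaemic stroke presentation with unremarkable
labs, vitals and history) within clinically plausible ranges:

* blood glucose 2-25 mmol/l, SpO2 85-100 %, body temperature 36-39 °C,
* NIHSS totals 0-42, onset 0.5-12 h before the thrombolysis decision,
* event-history offsets 1-800 d.

Determinism: every case is generated from ``Random(f"{profile}|{seed}")``
with the per-case seed derived from ``(master_seed, index)``, so any case
can be regenerated independently and a fixed master seed yields a
byte-identical serialised cohort.

``probe_case`` builds fully deterministic single-feature cases (no RNG)
for boundary scans: vary one quantity, hold everything else at the clean
scaffold's fixed values.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Callable, Optional

from .model import Entry, PatientCase
from .values import Boolean, CodedText, Count, DateTime, Quantity
from .knowledge import criteria as C
from .knowledge.nihss import MAX_TOTAL, NIHSS_ITEMS, item_vector_for_total

__all__ = [
    "DEFAULT_COHORT_SEED", "BASE_REFERENCE", "ScenarioProfile", "PROFILES",
    "generate_case", "generate_cohort", "probe_case", "random_item_vector",
]

DEFAULT_COHORT_SEED = 2014
BASE_REFERENCE = datetime(2014, 3, 1, 12, 0, tzinfo=timezone.utc)

_UTC = timezone.utc


@dataclass(frozen=True)
class ScenarioProfile:
    """A named case archetype: which criteria the case should trigger."""

    profile_id: str
    description: str
    triggers: frozenset[str] = field(default_factory=frozenset)


def _sct(code: str, display: str = "") -> CodedText:
    return CodedText("SNOMED-CT", code, display)


def _icd(code: str, display: str = "") -> CodedText:
    return CodedText("ICD10", code, display)


def _hours(h: float) -> timedelta:
    return timedelta(hours=h)


def _days(d: float) -> timedelta:
    return timedelta(days=d)


class _CaseDraft:
    """Mutable scaffold the profile mutators operate on."""

    def __init__(self, case_id: str, reference: datetime) -> None:
        self.case_id = case_id
        self.reference = reference
        self.onset_hours = 2.0
        self.glucose: Optional[float] = 5.5
        self.spo2 = 97.0
        self.temp = 36.8
        self.temp_offset_hours: Optional[float] = 1.0  # after onset; None drops it
        self.nihss_vector: Optional[dict[str, str]] = item_vector_for_total(2)
        self.exam_finding = _sct("50582007", "Hemiplegia")
        self.imaging_findings = _sct("371040005", "No abnormality on CT of brain")
        self.extra_entries: list[Entry] = []
        self.systolic = 150.0
        self.diastolic = 85.0

    @property
    def onset(self) -> datetime:
        return self.reference - _hours(self.onset_hours)

    def add_diagnosis(self, code: CodedText, onset: datetime,
                      confidence: str = "at0075") -> None:
        conf_display = "Certainty" if confidence == "at0075" else "Suspicion"
        self.extra_entries.append(Entry(
            C.DIAGNOSIS, "EVALUATION",
            min(onset + timedelta(minutes=30), self.reference),
            {
                C.DIAG_CODE: code,
                C.DIAG_ONSET: DateTime(onset),
                C.DIAG_CONFIDENCE: CodedText("local", confidence, conf_display),
            },
        ))

    def add_procedure(self, code: CodedText, when: datetime) -> None:
        self.extra_entries.append(Entry(
            C.PROCEDURE, "ACTION", when,
            {C.PROC_CODE: code, C.PROC_TIME: DateTime(when)},
        ))

    def add_medication(self, code: CodedText) -> None:
        self.extra_entries.append(Entry(
            C.MEDICATION, "INSTRUCTION", self.reference - _hours(1),
            {C.MED_CODE: code},
        ))

    def add_gas_administration(self, when: datetime) -> None:
        self.extra_entries.append(Entry(
            C.PROCEDURE, "ACTION", when,
            {
                C.GAS_GAS: _sct("24099007", "Oxygen gas"),
                C.GAS_DELIVERY: CodedText("local", "at0006", "Nasal canula"),
            },
        ))

    def build(self) -> PatientCase:
        ref = self.reference
        onset = self.onset
        entries: list[Entry] = [
            Entry(C.DIAGNOSIS, "EVALUATION",
                  min(onset + timedelta(minutes=10), ref),
                  {
                      C.DIAG_CODE: _sct("230690007", "Cerebrovascular accident"),
                      C.DIAG_ONSET: DateTime(onset),
                      C.DIAG_CONFIDENCE: CodedText("local", "at0075", "Certainty"),
                  }),
            # distant unremarkable history so group criteria can evaluate to
            # a definitive false rather than staying indeterminate
            Entry(C.DIAGNOSIS, "EVALUATION", ref - _days(500),
                  {
                      C.DIAG_CODE: _sct("38341003", "Hypertensive disorder"),
                      C.DIAG_ONSET: DateTime(ref - _days(500)),
                      C.DIAG_CONFIDENCE: CodedText("local", "at0075", "Certainty"),
                  }),
            Entry(C.PROCEDURE, "ACTION", ref - _hours(6),
                  {
                      C.PROC_CODE: _sct("29303009", "Electrocardiogram"),
                      C.PROC_TIME: DateTime(ref - _hours(6)),
                  }),
            Entry(C.MEDICATION, "INSTRUCTION", ref - _days(200),
                  {C.MED_CODE: CodedText("ATC", "N02BE01", "Paracetamol")}),
            Entry(C.OXIMETRY_OBS, "OBSERVATION", ref - timedelta(minutes=25),
                  {C.SPO2_VALUE: Quantity(self.spo2, "%")}),
            Entry(C.BP_OBS, "OBSERVATION", ref - timedelta(minutes=40),
                  {
                      C.BP_SYSTOLIC: Quantity(round(self.systolic, 0), "mmHg"),
                      C.BP_DIASTOLIC: Quantity(round(self.diastolic, 0), "mmHg"),
                  }),
            Entry(C.EXAM_OBS, "OBSERVATION", ref - timedelta(minutes=45),
                  {C.EXAM_FINDINGS: self.exam_finding}),
            Entry(C.IMAGING, "INSTRUCTION", ref - timedelta(minutes=15),
                  {
                      C.IMG_MODALITY: CodedText("local", "at0011", "CT"),
                      C.IMG_FINDINGS: self.imaging_findings,
                      C.IMG_SITE: _sct("12738006", "Brain structure"),
                  }),
        ]
        if self.glucose is not None:
            entries.append(Entry(
                C.GLUCOSE_OBS, "OBSERVATION", ref - timedelta(minutes=30),
                {C.GLUCOSE_VALUE: Quantity(self.glucose, "mmol/l")}))
        if self.nihss_vector is not None:
            entries.append(Entry(
                C.NIHSS_OBS, "OBSERVATION", ref - timedelta(minutes=20),
                {path: CodedText("local", code)
                 for path, code in self.nihss_vector.items()}))
        if self.temp_offset_hours is not None:
            when = onset + _hours(self.temp_offset_hours)
            when = min(when, ref)
            entries.append(Entry(
                C.TEMP_OBS, "OBSERVATION", when,
                {
                    C.TEMP_VALUE: Quantity(self.temp, "°C"),
                    C.TEMP_TIME: DateTime(when),
                }))
        entries.extend(self.extra_entries)
        return PatientCase(self.case_id, ref, tuple(entries))


def random_item_vector(rng: random.Random, total: int) -> dict[str, str]:
    """A random NIHSS answer vector (path -> level code) with an exact sum."""
    if not 0 <= total <= MAX_TOTAL:
        raise ValueError(f"total must be within 0..{MAX_TOTAL}")
    levels = {item.index: 0 for item in NIHSS_ITEMS}
    capacity = {item.index: item.max_score for item in NIHSS_ITEMS}
    remaining = total
    while remaining > 0:
        open_items = [i for i, lvl in levels.items() if lvl < capacity[i]]
        levels[rng.choice(open_items)] += 1
        remaining -= 1
    return {
        item.answer_path: item.level_code(levels[item.index])
        for item in NIHSS_ITEMS
    }


# --- profile mutators --------------------------------------------------------

def _clean(d: _CaseDraft, rng: random.Random) -> None:
    pass


def _late_onset(d: _CaseDraft, rng: random.Random) -> None:
    d.onset_hours = rng.uniform(5.0, 10.0)
    d.temp_offset_hours = rng.uniform(1.0, d.onset_hours - 0.5)


def _nihss_high(d: _CaseDraft, rng: random.Random) -> None:
    d.nihss_vector = random_item_vector(rng, rng.randint(26, MAX_TOTAL))


def _ct_haemorrhage(d: _CaseDraft, rng: random.Random) -> None:
    d.imaging_findings = _sct("50960005", "Haemorrhage")


def _hypoglycaemia(d: _CaseDraft, rng: random.Random) -> None:
    d.glucose = rng.uniform(2.0, 2.8)


def _hyperglycaemia(d: _CaseDraft, rng: random.Random) -> None:
    d.glucose = rng.uniform(22.2, 25.0)


def _prior_ich(d: _CaseDraft, rng: random.Random) -> None:
    code = rng.choice([_sct("274100004", "Cerebral haemorrhage"),
                       _icd("I61", "Intracerebral haemorrhage")])
    d.add_diagnosis(code, d.reference - _days(rng.uniform(200, 800)))


def _explosive_headache(d: _CaseDraft, rng: random.Random) -> None:
    d.add_diagnosis(_sct("95660002", "Thunderclap headache"),
                    d.reference - _hours(rng.uniform(1.0, 3.0)))


def _postictal_paresis(d: _CaseDraft, rng: random.Random) -> None:
    code = rng.choice([_sct("66264000", "Postictal paralysis"),
                       _icd("G83.8", "Other specified paralytic syndromes")])
    d.add_diagnosis(code, d.reference - _hours(rng.uniform(1.0, 4.0)))


def _septic_shock(d: _CaseDraft, rng: random.Random) -> None:
    d.add_diagnosis(_sct("76571007", "Septic shock"),
                    d.reference - _hours(rng.uniform(2.0, 10.0)),
                    confidence="at0074")


def _anticoagulated(d: _CaseDraft, rng: random.Random) -> None:
    code = rng.choice([CodedText("ATC", "B01AA03", "Warfarin"),
                       CodedText("ATC", "B01AB01", "Heparin")])
    d.add_medication(code)


def _bleeding_disorder(d: _CaseDraft, rng: random.Random) -> None:
    code = rng.choice([_sct("64779008", "Blood coagulation disorder"),
                       _icd("D68", "Other coagulation defects")])
    d.add_diagnosis(code, d.reference - _days(rng.uniform(100, 700)))


def _cardiac_condition(d: _CaseDraft, rng: random.Random) -> None:
    code = rng.choice([
        _sct("56819008", "Infective endocarditis"),
        _sct("3238004", "Pericarditis"),
        _sct("84114007", "Heart failure"),
        _sct("75694006", "Pancreatitis"),
        _icd("K72", "Hepatic failure"),
    ])
    d.add_diagnosis(code, d.reference - _days(rng.uniform(5, 300)))


def _recent_lumbar_puncture(d: _CaseDraft, rng: random.Random) -> None:
    d.add_procedure(_sct("91602002", "Lumbar puncture"),
                    d.reference - _days(rng.uniform(1.5, 6.0)))


def _old_lumbar_puncture(d: _CaseDraft, rng: random.Random) -> None:
    d.add_procedure(_sct("91602002", "Lumbar puncture"),
                    d.reference - _days(rng.uniform(8.0, 20.0)))


def _recent_organ_biopsy(d: _CaseDraft, rng: random.Random) -> None:
    d.add_procedure(_sct("86273004", "Biopsy of parenchymatous organ"),
                    d.reference - _days(rng.uniform(2.0, 25.0)))


def _recent_duodenal_ulcer(d: _CaseDraft, rng: random.Random) -> None:
    code = rng.choice([_sct("51868009", "Duodenal ulcer"),
                       _icd("K26", "Duodenal ulcer")])
    d.add_diagnosis(code, d.reference - _days(rng.uniform(2.0, 25.0)))


def _prior_stroke_90d(d: _CaseDraft, rng: random.Random) -> None:
    d.add_diagnosis(_sct("230690007", "Cerebrovascular accident"),
                    d.reference - _days(rng.uniform(30.0, 85.0)))


def _recent_cns_operation(d: _CaseDraft, rng: random.Random) -> None:
    d.add_procedure(_sct("118831003", "Operation on central nervous system"),
                    d.reference - _days(rng.uniform(5.0, 80.0)))


def _pregnancy(d: _CaseDraft, rng: random.Random) -> None:
    d.add_diagnosis(_sct("77386006", "Pregnancy"),
                    d.reference - _days(rng.uniform(30.0, 200.0)))


def _recent_childbirth(d: _CaseDraft, rng: random.Random) -> None:
    code = rng.choice([_sct("386216000", "Recent childbirth"),
                       _icd("O80", "Single spontaneous delivery")])
    d.add_diagnosis(code, d.reference - _days(rng.uniform(2.0, 25.0)))


def _low_spo2_treated(d: _CaseDraft, rng: random.Random) -> None:
    d.spo2 = rng.uniform(88.0, 93.0)
    d.add_gas_administration(d.reference - timedelta(minutes=10))


def _low_spo2_untreated(d: _CaseDraft, rng: random.Random) -> None:
    d.spo2 = rng.uniform(88.0, 93.0)


def _pyrexia(d: _CaseDraft, rng: random.Random) -> None:
    d.temp = rng.uniform(37.7, 39.0)


def _late_temperature(d: _CaseDraft, rng: random.Random) -> None:
    # only temperature reading predates onset -> outside the 72 h window
    d.temp_offset_hours = -rng.uniform(1.0, 5.0)


def _mri_posterior(d: _CaseDraft, rng: random.Random) -> None:
    d.exam_finding = _sct("429993008", "Posterior circulation stroke syndrome")
    d.extra_entries.append(Entry(
        C.IMAGING, "INSTRUCTION", d.reference - timedelta(minutes=5),
        {C.IMG_MODALITY: CodedText("local", "at0012", "MRI")}))


def _stroke_mimic_ct(d: _CaseDraft, rng: random.Random) -> None:
    d.imaging_findings = _sct("373930000", "Stroke mimic suspected")


def _thrombolysed_despite_late_onset(d: _CaseDraft, rng: random.Random) -> None:
    _late_onset(d, rng)
    d.add_procedure(_sct("426347000", "Thrombolysis therapy"),
                    d.reference - timedelta(minutes=5))


def _missing_glucose(d: _CaseDraft, rng: random.Random) -> None:
    d.glucose = None


def _missing_nihss(d: _CaseDraft, rng: random.Random) -> None:
    d.nihss_vector = None


_CATALOGUE: tuple[tuple[ScenarioProfile, Callable], ...] = tuple(
    (ScenarioProfile(pid, desc, frozenset(trig)), fn)
    for pid, desc, trig, fn in [
        ("clean", "acute ischaemic stroke, nothing remarkable",
         {"e02", "e03"}, _clean),
        ("late_onset", "presentation beyond the 4.5 h window",
         {"c01", "e03"}, _late_onset),
        ("nihss_high", "severe deficit, NIHSS total above 25",
         {"c04", "e02", "e03"}, _nihss_high),
        ("ct_haemorrhage", "CT shows haemorrhage in the brain",
         {"c05", "e02", "e03"}, _ct_haemorrhage),
        ("hypoglycaemia", "blood glucose below 3 mmol/l",
         {"c07", "e02", "e03"}, _hypoglycaemia),
        ("hyperglycaemia", "blood glucose above 22 mmol/l",
         {"c07", "e02", "e03"}, _hyperglycaemia),
        ("prior_ich", "history of intracerebral haemorrhage",
         {"c09", "e02", "e03"}, _prior_ich),
        ("explosive_headache", "thunderclap headache on presentation",
         {"c10", "e02", "e03"}, _explosive_headache),
        ("postictal_paresis", "likely postictal paresis",
         {"c12", "e02", "e03"}, _postictal_paresis),
        ("septic_shock", "suspected septic shock",
         {"c13", "e02", "e03"}, _septic_shock),
        ("anticoagulated", "ongoing anticoagulant medication",
         {"c14", "e02", "e03"}, _anticoagulated),
        ("bleeding_disorder", "known coagulation disorder",
         {"c14", "e02", "e03"}, _bleeding_disorder),
        ("cardiac_condition", "endocarditis/pericarditis/heart failure set",
         {"c15", "e02", "e03"}, _cardiac_condition),
        ("recent_lumbar_puncture", "lumbar puncture within the last week",
         {"c16", "e02", "e03"}, _recent_lumbar_puncture),
        ("old_lumbar_puncture", "lumbar puncture older than one week",
         {"e02", "e03"}, _old_lumbar_puncture),
        ("recent_organ_biopsy", "organ biopsy within the last month",
         {"c17", "e02", "e03"}, _recent_organ_biopsy),
        ("recent_duodenal_ulcer", "duodenal ulcer within the last month",
         {"c17", "e02", "e03"}, _recent_duodenal_ulcer),
        ("prior_stroke_90d", "earlier stroke within the last three months",
         {"c01", "c18", "e02", "e03"}, _prior_stroke_90d),
        ("recent_cns_operation", "CNS operation within the last three months",
         {"c18", "e02", "e03"}, _recent_cns_operation),
        ("pregnancy", "pregnant patient",
         {"c19", "e02", "e03"}, _pregnancy),
        ("recent_childbirth", "childbirth within the last month",
         {"c19", "e02", "e03"}, _recent_childbirth),
        ("low_spo2_treated", "SpO2 below 95% with oxygen given",
         {"e02", "e03", "e05"}, _low_spo2_treated),
        ("low_spo2_untreated", "SpO2 below 95% without oxygen",
         {"e02", "e03", "e05"}, _low_spo2_untreated),
        ("pyrexia", "temperature above 37.5 °C within 72 h",
         {"e02", "e03", "e04"}, _pyrexia),
        ("late_temperature", "temperature only recorded outside the window",
         {"e02"}, _late_temperature),
        ("mri_posterior", "posterior-circulation variety, MRI ordered",
         {"e01", "e02", "e03"}, _mri_posterior),
        ("stroke_mimic_ct", "CT raises a stroke-mimic suspicion",
         {"e01", "e02", "e03"}, _stroke_mimic_ct),
        ("thrombolysed_despite_late_onset",
         "thrombolysis given although onset exceeded 4.5 h",
         {"c01", "e03"}, _thrombolysed_despite_late_onset),
        ("missing_glucose", "no blood glucose recorded",
         {"e02", "e03"}, _missing_glucose),
        ("missing_nihss", "no NIHSS assessment recorded",
         {"e02", "e03"}, _missing_nihss),
    ]
)

PROFILES: tuple[ScenarioProfile, ...] = tuple(p for p, _ in _CATALOGUE)
_MUTATORS: dict[str, Callable] = {p.profile_id: fn for p, fn in _CATALOGUE}


def generate_case(profile: ScenarioProfile | str, seed: int | str,
                  case_id: str | None = None,
                  reference_time: datetime | None = None) -> PatientCase:
    """One schema-valid case for a scenario profile; deterministic in
    (profile, seed)."""
    profile_id = profile.profile_id if isinstance(profile, ScenarioProfile) else profile
    if profile_id not in _MUTATORS:
        raise ValueError(f"unknown profile {profile_id!r}")
    rng = random.Random(f"{profile_id}|{seed}")
    reference = reference_time or BASE_REFERENCE
    reference += timedelta(minutes=rng.randint(0, 180))
    draft = _CaseDraft(case_id or f"{profile_id}-{seed}", reference)
    draft.onset_hours = rng.uniform(1.0, 4.0)
    draft.glucose = rng.uniform(4.0, 7.0)
    draft.spo2 = rng.uniform(96.0, 99.0)
    draft.temp = rng.uniform(36.2, 37.2)
    draft.temp_offset_hours = rng.uniform(0.2, draft.onset_hours * 0.8)
    draft.nihss_vector = random_item_vector(rng, rng.randint(0, 8))
    draft.systolic = rng.uniform(120, 180)
    draft.diastolic = rng.uniform(70, 105)
    _MUTATORS[profile_id](draft, rng)
    return draft.build()


def generate_cohort(n: int = 49,
                    master_seed: int = DEFAULT_COHORT_SEED) -> list[PatientCase]:
    """``n`` cases cycling through the profile catalogue (default 49)."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    cases = []
    for i in range(n):
        profile = PROFILES[i % len(PROFILES)]
        cases.append(generate_case(
            profile,
            seed=f"{master_seed}:{i}",
            case_id=f"case-{i + 1:03d}",
            reference_time=BASE_REFERENCE + timedelta(days=i),
        ))
    return cases


def probe_case(case_id: str = "probe", *, onset_hours: float = 2.0,
               glucose: float | None = 5.5, spo2: float = 97.0,
               nihss_total: int | None = 2, temp: float = 36.8,
               temp_offset_hours: float | None = 1.0,
               reference_time: datetime = BASE_REFERENCE) -> PatientCase:
    """A deterministic single-feature scan case (clean scaffold, no RNG)."""
    draft = _CaseDraft(case_id, reference_time)
    draft.onset_hours = onset_hours
    draft.glucose = glucose
    draft.spo2 = spo2
    draft.temp = temp
    draft.temp_offset_hours = temp_offset_hours
    draft.nihss_vector = (
        item_vector_for_total(nihss_total) if nihss_total is not None else None
    )
    return draft.build()
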