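"""Retrospective compliance audit and the independent brute-force oracle.

``engine_check`` runs the shipped guideline chain over a case and extracts
one verdict per audited criterion; ``oracle_check`` re-derives the same
verdicts straight from the entries — no rule language, no parsing, no
forward chaining — formalising the study design of checking every case by
hand and comparing against the automated result.  ``compare`` counts the
cases whose entire verdict vectors agree.

Both sides share the three-valued semantics: a criterion is *triggered*
when some combination of entries definitely satisfies it, *not_triggered*
when some combination definitely clears it (and none satisfies it), and
*indeterminate* when the recorded data cannot decide — missing data never
silently counts as compliant.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .engine import run_guideline, apply_outputs
from .guideline import Guideline
from .model import PatientCase, SchemaRegistry
from .terminology import TerminologyStore
from .values import Boolean, CodedText, DateTime, Quantity
from . import knowledge
from .knowledge import criteria as C
from .knowledge.nihss import NIHSS_ITEMS

__all__ = [
    "TRIGGERED", "NOT_TRIGGERED", "INDETERMINATE",
    "Verdict", "ComplianceReport", "ConcordanceSummary",
    "engine_check", "oracle_check", "audit", "compare",
]

TRIGGERED = "triggered"
NOT_TRIGGERED = "not_triggered"
INDETERMINATE = "indeterminate"

_STATUSES = (TRIGGERED, NOT_TRIGGERED, INDETERMINATE)


@dataclass(frozen=True)
class Verdict:
    case_id: str
    criterion_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class ConcordanceSummary:
    total: int
    matches: int
    discrepancies: tuple[tuple[str, str, str, str], ...]  # case, criterion, engine, oracle

    @property
    def complete_match(self) -> bool:
        return self.matches == self.total


@dataclass
class ComplianceReport:
    per_criterion: pd.DataFrame  # criterion_id, title, triggered/not/indeterminate
    per_case: pd.DataFrame       # long: case_id, criterion_id, status
    case_summary: pd.DataFrame   # case_id, thrombolysis_given, contraindicated, ...
    non_compliance_count: int
    errors: list[tuple[str, str]] = field(default_factory=list)


# --- engine-side verdicts ---------------------------------------------------

def engine_check(case: PatientCase,
                 guidelines: Mapping[str, Guideline] | None = None,
                 registry: SchemaRegistry | None = None,
                 store: TerminologyStore | None = None) -> dict[str, str]:
    """Verdict vector from the rule engine (NIHSS chain first)."""
    registry = registry or knowledge.registry()
    store = store or knowledge.terminology_store()
    guidelines = guidelines or knowledge.load_guidelines()
    nihss_result = run_guideline(guidelines["nihss_score"], case,
                                 registry=registry, store=store)
    chained = apply_outputs(case, nihss_result, registry)
    thromb = run_guideline(guidelines["thrombolysis_contraindications"], chained,
                           registry=registry, store=store)
    euro = run_guideline(guidelines["euro_stroke_criteria"], chained,
                         registry=registry, store=store)
    verdicts: dict[str, str] = {}
    for spec in knowledge.REPRESENTED:
        result = thromb if spec.flag_archetype == C.THROMB_EVAL else euro
        value = result.outputs.get((spec.flag_archetype, spec.flag_path))
        if value is None:
            verdicts[spec.criterion_id] = INDETERMINATE
        else:
            assert isinstance(value, Boolean)
            verdicts[spec.criterion_id] = TRIGGERED if value.value else NOT_TRIGGERED
    return verdicts


# --- the brute-force oracle -------------------------------------------------
#
# Plain per-criterion predicate functions over entry values.  None means
# "unknown".  The terminology closure comes from the store's ancestor sets;
# the criterion membership tables below are written out independently of
# the guideline files.

_STROKE = {"SNOMED-CT": ("230690007",), "ICD10": ("I64",)}
_ICH_HISTORY = {"SNOMED-CT": ("274100004", "1386000"), "ICD10": ("I61", "I62")}
_HEADACHE = {"SNOMED-CT": ("95660002",), "ICD10": ("R51",)}
_POSTICTAL = {"SNOMED-CT": ("66264000",), "ICD10": ("G83.8",)}
_SEPTIC = {"SNOMED-CT": ("76571007",), "ICD10": ("R57.2",)}
_BLEED_DX = {"SNOMED-CT": ("64779008",), "ICD10": ("D68",)}
_ANTICOAG = {"ATC": ("B01A",)}
_CARDIAC = {"SNOMED-CT": ("56819008", "3238004", "91434003", "253276004",
                          "84114007", "75694006", "235856003"),
            "ICD10": ("I33", "I30", "I50", "K85", "K72")}
_WEEK_PROC = {"SNOMED-CT": ("91602002", "392247006")}
_MONTH_DX = {"SNOMED-CT": ("283545005", "51868009", "53298000"),
             "ICD10": ("K26", "R31")}
_MONTH_PROC = {"SNOMED-CT": ("86273004", "107963000")}
_TRIMONTH_DX = {"SNOMED-CT": ("230690007", "82271004", "74474003"),
                "ICD10": ("I64", "S06", "K92.2")}
_TRIMONTH_PROC = {"SNOMED-CT": ("118831003",)}
_PREGNANCY = {"SNOMED-CT": ("77386006", "169750002"), "ICD10": ("Z33", "Z39.1")}
_CHILDBIRTH = {"SNOMED-CT": ("386216000",), "ICD10": ("O80",)}
_HAEM_FINDING = {"SNOMED-CT": ("50960005",)}
_BRAIN = {"SNOMED-CT": ("12738006",)}
_POSTERIOR = {"SNOMED-CT": ("429993008",)}
_MIMIC = {"SNOMED-CT": ("373930000",)}
_DEFICIT = {"SNOMED-CT": ("50582007", "429993008")}
_THROMBOLYSIS_PROC = {"SNOMED-CT": ("426347000",)}

_NIHSS_LEVELS = {
    code: score for item in NIHSS_ITEMS for code, score in item.levels
}


def _and3(*vs):
    if any(v is False for v in vs):
        return False
    if any(v is None for v in vs):
        return None
    return True


def _or3(*vs):
    if any(v is True for v in vs):
        return True
    if any(v is None for v in vs):
        return None
    return False


def _not3(v):
    return None if v is None else not v


class _Oracle:
    def __init__(self, case: PatientCase, store: TerminologyStore) -> None:
        self.case = case
        self.store = store
        self.ref = case.reference_time
        by = lambda aid: [e for e in case.entries if e.archetype_id == aid]
        self.diags = by(C.DIAGNOSIS)
        self.procs = by(C.PROCEDURE)
        self.meds = by(C.MEDICATION)
        self.imgs = by(C.IMAGING)
        self.exams = by(C.EXAM_OBS)
        self.temps = by(C.TEMP_OBS)
        self.spo2s = by(C.OXIMETRY_OBS)
        self.glucoses = by(C.GLUCOSE_OBS)
        self.nihsses = by(C.NIHSS_OBS)

    # -- low-level accessors (None = missing) --

    def _coded(self, entry, path) -> Optional[CodedText]:
        if entry is None:
            return None
        v = entry.elements.get(path)
        return v if isinstance(v, CodedText) else None

    def _qty(self, entry, path) -> Optional[float]:
        if entry is None:
            return None
        v = entry.elements.get(path)
        return v.magnitude if isinstance(v, Quantity) else None

    def _when(self, entry, path) -> Optional[datetime]:
        if entry is None:
            return None
        v = entry.elements.get(path)
        return v.value if isinstance(v, DateTime) else None

    def member(self, value: Optional[CodedText], table: Mapping) -> Optional[bool]:
        """Subsumption membership; None for a missing value, False for an
        unbound system or unknown code (mirrors tolerant group matching)."""
        if value is None:
            return None
        codes = table.get(value.system, ())
        if not codes or not self.store.has_code(value.system, value.code):
            return False
        ancestors = self.store.ancestors(value.system, value.code)
        return any(c in ancestors for c in codes)

    def _fires(self, pools: Sequence[Sequence], fn: Callable) -> bool:
        """Existential instance-join firing over padded entry tuples."""
        if all(len(p) == 0 for p in pools):
            return False
        padded = [list(p) if p else [None] for p in pools]
        return any(fn(*combo) is True for combo in itertools.product(*padded))

    def _status(self, pools, true_fn, false_fn) -> str:
        if self._fires(pools, true_fn):
            return TRIGGERED
        if self._fires(pools, false_fn):
            return NOT_TRIGGERED
        return INDETERMINATE

    # -- shared fragments --

    def _dx_code(self, d):
        return self._coded(d, C.DIAG_CODE)

    def _dx_onset(self, d):
        return self._when(d, C.DIAG_ONSET)

    def _within(self, when: Optional[datetime], span: timedelta,
                history_guard: bool = False) -> Optional[bool]:
        if when is None:
            return None
        inside = when + span >= self.ref
        if history_guard:
            return _and3(inside, when + timedelta(hours=24) <= self.ref)
        return inside

    def nihss_total(self, entry) -> Optional[int]:
        total = 0
        for item in NIHSS_ITEMS:
            v = self._coded(entry, item.answer_path)
            if v is None:
                return None
            score = _NIHSS_LEVELS.get(v.code) if v.system == "local" else None
            if score is None:
                return None
            total += score
        return total

    # -- criteria --

    def verdicts(self) -> dict[str, str]:
        out: dict[str, str] = {}
        ref = self.ref

        def stroke(d):
            return self.member(self._dx_code(d), _STROKE)

        def onset_beyond(d):
            onset = self._dx_onset(d)
            if onset is None:
                return None
            return onset + timedelta(hours=4, minutes=30) < ref

        out["c01"] = self._status(
            [self.diags],
            lambda d: _and3(stroke(d), onset_beyond(d)),
            lambda d: _and3(stroke(d), _not3(onset_beyond(d))),
        )

        def total_cmp(n, above: bool):
            total = self.nihss_total(n)
            if total is None:
                return None
            return total > 25 if above else total <= 25

        out["c04"] = self._status(
            [self.nihsses],
            lambda n: total_cmp(n, True),
            lambda n: total_cmp(n, False),
        )

        def ct_haem(i):
            return _and3(
                self.member(self._coded(i, C.IMG_FINDINGS), _HAEM_FINDING),
                self.member(self._coded(i, C.IMG_SITE), _BRAIN),
            )

        out["c05"] = self._status(
            [self.imgs], ct_haem, lambda i: _not3(ct_haem(i)))

        def glucose_out(g):
            v = self._qty(g, C.GLUCOSE_VALUE)
            if v is None:
                return None
            return v < 3 or v > 22

        out["c07"] = self._status(
            [self.glucoses], glucose_out, lambda g: _not3(glucose_out(g)))

        for cid, table in (("c09", _ICH_HISTORY), ("c10", _HEADACHE),
                           ("c12", _POSTICTAL), ("c13", _SEPTIC),
                           ("c15", _CARDIAC)):
            def in_group(d, table=table):
                return self.member(self._dx_code(d), table)

            out[cid] = self._status(
                [self.diags], in_group, lambda d, f=in_group: _not3(f(d)))

        def bleed_dx(d):
            return self.member(self._dx_code(d), _BLEED_DX)

        def anticoag(m):
            return self.member(self._coded(m, C.MED_CODE), _ANTICOAG)

        out["c14"] = self._status(
            [self.diags, self.meds],
            lambda d, m: _or3(bleed_dx(d), anticoag(m)),
            lambda d, m: _and3(_not3(bleed_dx(d)), _not3(anticoag(m))),
        )

        def week_proc(p):
            return _and3(
                self.member(self._coded(p, C.PROC_CODE), _WEEK_PROC),
                self._within(self._when(p, C.PROC_TIME), timedelta(days=7)),
            )

        out["c16"] = self._status(
            [self.procs], week_proc, lambda p: _not3(week_proc(p)))

        def month_dx(d):
            return _and3(
                self.member(self._dx_code(d), _MONTH_DX),
                self._within(self._dx_onset(d), timedelta(days=30),
                             history_guard=True),
            )

        def month_proc(p):
            return _and3(
                self.member(self._coded(p, C.PROC_CODE), _MONTH_PROC),
                self._within(self._when(p, C.PROC_TIME), timedelta(days=30)),
            )

        out["c17"] = self._status(
            [self.diags, self.procs],
            lambda d, p: _or3(month_dx(d), month_proc(p)),
            lambda d, p: _and3(_not3(month_dx(d)), _not3(month_proc(p))),
        )

        def tri_dx(d):
            return _and3(
                self.member(self._dx_code(d), _TRIMONTH_DX),
                self._within(self._dx_onset(d), timedelta(days=90),
                             history_guard=True),
            )

        def tri_proc(p):
            return _and3(
                self.member(self._coded(p, C.PROC_CODE), _TRIMONTH_PROC),
                self._within(self._when(p, C.PROC_TIME), timedelta(days=90)),
            )

        out["c18"] = self._status(
            [self.diags, self.procs],
            lambda d, p: _or3(tri_dx(d), tri_proc(p)),
            lambda d, p: _and3(_not3(tri_dx(d)), _not3(tri_proc(p))),
        )

        def pregnant(d):
            return self.member(self._dx_code(d), _PREGNANCY)

        def childbirth(d):
            return _and3(
                self.member(self._dx_code(d), _CHILDBIRTH),
                self._within(self._dx_onset(d), timedelta(days=30),
                             history_guard=True),
            )

        out["c19"] = self._status(
            [self.diags],
            lambda d: _or3(pregnant(d), childbirth(d)),
            lambda d: _and3(_not3(pregnant(d)), _not3(childbirth(d))),
        )

        # European-guideline criteria ------------------------------------

        def posterior(e):
            return self.member(self._coded(e, C.EXAM_FINDINGS), _POSTERIOR)

        def mimic(i):
            return self.member(self._coded(i, C.IMG_FINDINGS), _MIMIC)

        out["e01"] = self._status(
            [self.exams, self.imgs],
            lambda e, i: _or3(posterior(e), mimic(i)),
            lambda e, i: _and3(_not3(posterior(e)), _not3(mimic(i))),
        )

        def deficit(e):
            return self.member(self._coded(e, C.EXAM_FINDINGS), _DEFICIT)

        def onset_within(d):
            onset = self._dx_onset(d)
            if onset is None:
                return None
            return onset + timedelta(hours=4, minutes=30) >= ref

        out["e02"] = self._status(
            [self.exams, self.diags],
            lambda e, d: _and3(deficit(e), stroke(d), onset_within(d)),
            lambda e, d: _not3(_and3(deficit(e), stroke(d), onset_within(d))),
        )

        def temp_in_window(t, d):
            when = self._when(t, C.TEMP_TIME)
            onset = self._dx_onset(d)
            if when is None or onset is None:
                return None
            return onset <= when <= onset + timedelta(hours=72)

        out["e03"] = self._status(
            [self.temps, self.diags],
            lambda t, d: _and3(stroke(d), temp_in_window(t, d)),
            lambda t, d: _and3(stroke(d), _not3(temp_in_window(t, d))),
        )

        def temp_cmp(t, above: bool):
            v = self._qty(t, C.TEMP_VALUE)
            if v is None:
                return None
            return v > 37.5 if above else v <= 37.5

        out["e04"] = self._status(
            [self.temps, self.diags],
            lambda t, d: _and3(stroke(d), temp_in_window(t, d), temp_cmp(t, True)),
            lambda t, d: _and3(stroke(d), temp_in_window(t, d), temp_cmp(t, False)),
        )

        def spo2_low(s):
            v = self._qty(s, C.SPO2_VALUE)
            if v is None:
                return None
            return v < 95

        out["e05"] = self._status(
            [self.spo2s], spo2_low, lambda s: _not3(spo2_low(s)))

        return out

    # -- audit extras (not part of the engine/oracle comparison) --

    def thrombolysis_given(self) -> bool:
        return any(
            self.member(self._coded(p, C.PROC_CODE), _THROMBOLYSIS_PROC) is True
            for p in self.procs
        )

    def oxygen_followup_flagged(self) -> bool:
        """True when a sub-95% saturation was never followed by oxygen
        administration before the decision time."""
        low_times = [
            e.event_time for e in self.spo2s
            if (v := self._qty(e, C.SPO2_VALUE)) is not None and v < 95
        ]
        if not low_times:
            return False
        first_low = min(low_times)
        oxygen = CodedText("SNOMED-CT", "24099007")
        for p in self.procs:
            gas = self._coded(p, C.GAS_GAS)
            if gas == oxygen and first_low <= p.event_time <= self.ref:
                return False
        return True


def oracle_check(case: PatientCase,
                 store: TerminologyStore | None = None) -> dict[str, str]:
    """Straight-line per-criterion verdicts computed directly from entries."""
    return _Oracle(case, store or knowledge.terminology_store()).verdicts()


# --- cohort-level audit -----------------------------------------------------

def audit(cases: Iterable[PatientCase],
          guidelines: Mapping[str, Guideline] | None = None,
          registry: SchemaRegistry | None = None,
          store: TerminologyStore | None = None) -> ComplianceReport:
    """Engine verdicts for every case plus cohort statistics.

    A case that fails evaluation is recorded under ``errors`` and the audit
    continues.  Non-compliance counts cases where thrombolysis was given
    despite at least one triggered contraindication.
    """
    registry = registry or knowledge.registry()
    store = store or knowledge.terminology_store()
    guidelines = guidelines or knowledge.load_guidelines()
    rows = []
    summary_rows = []
    errors: list[tuple[str, str]] = []
    non_compliant = 0
    titles = {c.criterion_id: c.title for c in knowledge.REPRESENTED}
    for case in cases:
        try:
            verdicts = engine_check(case, guidelines, registry, store)
        except Exception as exc:  # noqa: BLE001 - audit keeps going
            errors.append((case.case_id, str(exc)))
            continue
        helper = _Oracle(case, store)
        given = helper.thrombolysis_given()
        contraindicated = any(
            verdicts[c.criterion_id] == TRIGGERED
            for c in knowledge.CONTRAINDICATIONS if c.represented
        )
        flagged = given and contraindicated
        non_compliant += int(flagged)
        for cid, status in verdicts.items():
            rows.append({"case_id": case.case_id, "criterion_id": cid,
                         "status": status})
        summary_rows.append({
            "case_id": case.case_id,
            "thrombolysis_given": given,
            "contraindicated": contraindicated,
            "non_compliant": flagged,
            "oxygen_followup_flagged": helper.oxygen_followup_flagged(),
        })
    per_case = pd.DataFrame(rows, columns=["case_id", "criterion_id", "status"])
    counts = []
    for cid in knowledge.VERDICT_KEYS:
        sub = per_case[per_case.criterion_id == cid] if len(per_case) else per_case
        counts.append({
            "criterion_id": cid,
            "title": titles[cid],
            TRIGGERED: int((sub.status == TRIGGERED).sum()) if len(per_case) else 0,
            NOT_TRIGGERED: int((sub.status == NOT_TRIGGERED).sum()) if len(per_case) else 0,
            INDETERMINATE: int((sub.status == INDETERMINATE).sum()) if len(per_case) else 0,
        })
    per_criterion = pd.DataFrame(
        counts, columns=["criterion_id", "title", TRIGGERED, NOT_TRIGGERED,
                         INDETERMINATE])
    case_summary = pd.DataFrame(
        summary_rows,
        columns=["case_id", "thrombolysis_given", "contraindicated",
                 "non_compliant", "oxygen_followup_flagged"])
    return ComplianceReport(per_criterion, per_case, case_summary,
                            non_compliant, errors)


def compare(engine_verdicts: Mapping[str, Mapping[str, str]],
            oracle_verdicts: Mapping[str, Mapping[str, str]]) -> ConcordanceSummary:
    """Per-case whole-vector concordance between engine and oracle."""
    if set(engine_verdicts) != set(oracle_verdicts):
        raise ValueError("engine and oracle cover different case ids")
    matches = 0
    discrepancies = []
    for case_id in engine_verdicts:
        ev, ov = dict(engine_verdicts[case_id]), dict(oracle_verdicts[case_id])
        if ev == ov:
            matches += 1
            continue
        keys = sorted(set(ev) | set(ov))
        for k in keys:
            if ev.get(k) != ov.get(k):
                discrepancies.append(
                    (case_id, k, ev.get(k, "missing"), ov.get(k, "missing")))
    return ConcordanceSummary(len(engine_verdicts), matches,
                              tuple(discrepancies))
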