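"""Forward-chaining evaluation of a guideline over one patient case.

Semantics in brief:

* **Instance joins are existential.** For each rule, candidate tuples are
  the cartesian product of the case's entries over the rule's input
  archetypes; the rule fires when *some* tuple satisfies every ``when``
  condition.  Contraindication screening asks "does any recorded event
  qualify", so one qualifying entry is enough.  An input archetype with no
  entries contributes an empty slot whose references evaluate to unknown
  (Kleene logic); a rule none of whose input archetypes has entries gets
  no tuples at all.

* **Three-valued logic.** A condition over an absent value is *unknown*,
  not false; ``&&``/``||``/``!`` follow Kleene's strong three-valued
  tables.  A rule fires only on definite truth.  Output elements none of
  whose governing rules fired are reported *indeterminate* — an audit must
  never silently assume compliance from missing data.

* **Fixpoint.** Rules run in passes — higher ``priority`` first, file
  order within equal priority, last assignment wins within a pass — and
  passes repeat until a pass leaves working memory unchanged (re-assigning
  an identical value is not a change).  A cap of ``len(rules) + 1`` passes
  guards against non-terminating rule sets.

* **Retrospective clock.** ``currentDateTime`` is fixed for the whole
  evaluation and defaults to the case's ``reference_time`` — "more than
  4.5 hours ago" is anchored to the thrombolysis decision instant, not to
  wall-clock now.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

from .expr import (
    And, Arith, Assignment, CodedLiteral, Comparison, CurrentDateTime,
    DurationLiteral, Exists, GtRef, IsA, Literal, Not, Or, gt_refs,
)
from .guideline import Guideline, Rule
from .model import Entry, PatientCase, SchemaRegistry
from .terminology import TerminologyStore, matches_group
from .values import (
    Boolean, CodedText, Count, DataValue, DateTime, Duration, Quantity, Text,
)

__all__ = [
    "UNKNOWN", "EvaluationContext", "EngineResult", "EngineError",
    "EngineCycleError", "EngineTypeError", "bind_inputs", "eval_condition",
    "run_guideline", "apply_outputs", "run_chain",
]


class EngineError(RuntimeError):
    pass


class EngineCycleError(EngineError):
    """The rule set did not reach a fixpoint within the pass cap."""


class EngineTypeError(EngineError):
    """Runtime operand mismatch (should have been caught by validation)."""


class _Unknown:
    __slots__ = ()

    def __repr__(self) -> str:
        return "UNKNOWN"


#: sentinel for "no value available" in three-valued evaluation
UNKNOWN = _Unknown()


@dataclass
class EvaluationContext:
    case: PatientCase
    current_datetime: datetime
    guideline: Guideline
    registry: SchemaRegistry
    store: TerminologyStore
    working_memory: dict[str, DataValue] = field(default_factory=dict)
    trace: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class EngineResult:
    outputs: Mapping[tuple[str, str], DataValue]
    fired: tuple[str, ...]
    indeterminate: tuple[tuple[str, str], ...]
    passes: int
    trace: tuple[dict, ...] = ()


# --- three-valued connectives ----------------------------------------------

def _and3(values) -> object:
    saw_unknown = False
    for v in values:
        if v is False:
            return False
        if v is UNKNOWN or v is None:
            saw_unknown = True
    return UNKNOWN if saw_unknown else True


def _or3(values) -> object:
    saw_unknown = False
    for v in values:
        if v is True:
            return True
        if v is UNKNOWN or v is None:
            saw_unknown = True
    return UNKNOWN if saw_unknown else False


def _not3(v) -> object:
    if v is UNKNOWN or v is None:
        return UNKNOWN
    return not v


# --- candidate tuples -------------------------------------------------------

def _entries_by_archetype(case: PatientCase) -> dict[str, list[Entry]]:
    out: dict[str, list[Entry]] = {}
    for i, e in enumerate(case.entries):
        out.setdefault(e.archetype_id, []).append(e)
    for aid in out:
        out[aid].sort(key=lambda e: e.event_time)
    return out


def _rule_input_archetypes(g: Guideline, rule: Rule) -> list[str]:
    refs: set[str] = set()
    for cond in rule.when:
        refs |= gt_refs(cond)
    for action in rule.then:
        refs |= gt_refs(action.value)
    archetypes: list[str] = []
    for code in sorted(refs):
        b = g.bindings.get(code)
        if b is not None and b.direction == "input" and b.archetype_id not in archetypes:
            archetypes.append(b.archetype_id)
    return archetypes


def _candidate_tuples(g: Guideline, rule: Rule,
                      by_archetype: Mapping[str, Sequence[Entry]]
                      ) -> list[dict[str, Optional[Entry]]]:
    archetypes = _rule_input_archetypes(g, rule)
    if not archetypes:
        return [{}]  # rule reads only working memory
    pools = [list(by_archetype.get(aid, ())) for aid in archetypes]
    if all(not pool for pool in pools):
        return []
    padded: list[list[Optional[Entry]]] = [pool if pool else [None] for pool in pools]
    return [dict(zip(archetypes, combo)) for combo in itertools.product(*padded)]


def bind_inputs(guideline: Guideline, case: PatientCase
                ) -> dict[str, list[dict[str, Optional[Entry]]]]:
    """Candidate entry tuples per rule (see module docstring for semantics)."""
    by_archetype = _entries_by_archetype(case)
    return {
        rule.rule_id: _candidate_tuples(guideline, rule, by_archetype)
        for rule in guideline.rules
    }


# --- term evaluation --------------------------------------------------------

def _resolve_ref(ref: GtRef, ctx: EvaluationContext,
                 tup: Mapping[str, Optional[Entry]]):
    b = ctx.guideline.bindings.get(ref.code)
    if b is None:
        raise EngineError(f"unbound gt-code {ref.code}")
    if b.direction == "output":
        return ctx.working_memory.get(ref.code, UNKNOWN)
    entry = tup.get(b.archetype_id)
    if entry is None:
        return UNKNOWN
    return entry.elements.get(b.path, UNKNOWN)


def _term_value(term, ctx: EvaluationContext, tup):
    """Evaluate a term to a comparable primitive, or UNKNOWN."""
    if isinstance(term, GtRef):
        return _resolve_ref(term, ctx, tup)
    if isinstance(term, Literal):
        return term.value
    if isinstance(term, CodedLiteral):
        return CodedText(term.system, term.code, term.display)
    if isinstance(term, DurationLiteral):
        return term.delta
    if isinstance(term, CurrentDateTime):
        return ctx.current_datetime
    if isinstance(term, Arith):
        left = _term_value(term.left, ctx, tup)
        right = _term_value(term.right, ctx, tup)
        if left is UNKNOWN or right is UNKNOWN:
            return UNKNOWN
        return _arith(term.op, left, right)
    raise EngineError(f"cannot evaluate term {term!r}")


def _as_plain(v):
    """Unwrap a DataValue to the primitive its comparisons run on."""
    if isinstance(v, Count):
        return v.value
    if isinstance(v, Quantity):
        return v.magnitude
    if isinstance(v, Boolean):
        return v.value
    if isinstance(v, Text):
        return v.value
    if isinstance(v, DateTime):
        return v.value
    if isinstance(v, Duration):
        return v.value
    return v  # CodedText compares as itself; primitives pass through


def _arith(op: str, left, right):
    left, right = _as_plain(left), _as_plain(right)
    try:
        return left + right if op == "+" else left - right
    except TypeError as exc:
        raise EngineTypeError(f"cannot compute {left!r} {op} {right!r}") from exc


_DOMAIN = {bool: "bool", int: "number", float: "number", str: "str",
           datetime: "datetime", timedelta: "duration", CodedText: "coded"}


def _domain(v) -> str:
    for cls, name in _DOMAIN.items():
        if isinstance(v, cls) and not (cls is int and isinstance(v, bool)):
            return name
    raise EngineTypeError(f"value {v!r} is not comparable")


def _compare(op: str, left, right):
    left, right = _as_plain(left), _as_plain(right)
    ld, rd = _domain(left), _domain(right)
    if ld != rd:
        raise EngineTypeError(f"cannot compare {ld} with {rd}")
    if ld in ("bool", "coded") and op not in ("==", "!="):
        raise EngineTypeError(f"{ld} values only support == and !=")
    if op == "==":
        return left == right
    if op == "!=":
        return left != right
    if op == "<":
        return left < right
    if op == "<=":
        return left <= right
    if op == ">":
        return left > right
    return left >= right


def eval_condition(cond, ctx: EvaluationContext,
                   tup: Mapping[str, Optional[Entry]]):
    """Three-valued condition evaluation: True, False, or UNKNOWN."""
    if isinstance(cond, Comparison):
        left = _term_value(cond.lhs, ctx, tup)
        right = _term_value(cond.rhs, ctx, tup)
        if left is UNKNOWN or right is UNKNOWN:
            return UNKNOWN
        return _compare(cond.op, left, right)
    if isinstance(cond, IsA):
        value = _resolve_ref(cond.ref, ctx, tup)
        if value is UNKNOWN:
            return UNKNOWN
        if not isinstance(value, CodedText):
            raise EngineTypeError(f"is_a requires coded text, got {value!r}")
        group = ctx.guideline.term_groups.get(cond.group)
        if group is None:
            raise EngineError(f"unresolved term group {cond.group}")
        return matches_group(value, group, ctx.store)
    if isinstance(cond, Exists):
        return _resolve_ref(cond.ref, ctx, tup) is not UNKNOWN
    if isinstance(cond, Not):
        return _not3(eval_condition(cond.cond, ctx, tup))
    if isinstance(cond, And):
        return _and3(eval_condition(p, ctx, tup) for p in cond.parts)
    if isinstance(cond, Or):
        return _or3(eval_condition(p, ctx, tup) for p in cond.parts)
    raise EngineError(f"cannot evaluate condition {cond!r}")


# --- rule firing ------------------------------------------------------------

def _coerce_output(value, edef) -> DataValue:
    if isinstance(value, DataValue):
        return value
    if edef.kind == "count":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise EngineTypeError(f"cannot store {value!r} in a count element")
        return Count(int(value))
    if edef.kind == "quantity":
        return Quantity(float(value), edef.unit or "1")
    if edef.kind == "boolean":
        if not isinstance(value, bool):
            raise EngineTypeError(f"cannot store {value!r} in a boolean element")
        return Boolean(value)
    if edef.kind == "text":
        return Text(str(value))
    if edef.kind == "date_time":
        if not isinstance(value, datetime):
            raise EngineTypeError(f"cannot store {value!r} in a date_time element")
        return DateTime(value)
    if edef.kind == "duration":
        if not isinstance(value, timedelta):
            raise EngineTypeError(f"cannot store {value!r} in a duration element")
        return Duration(value)
    raise EngineTypeError(f"cannot coerce {value!r} to {edef.kind}")


def run_guideline(guideline: Guideline, case: PatientCase, *,
                  registry: SchemaRegistry, store: TerminologyStore,
                  current_datetime: datetime | None = None) -> EngineResult:
    """Evaluate a validated guideline to fixpoint over one case."""
    ctx = EvaluationContext(
        case=case,
        current_datetime=current_datetime or case.reference_time,
        guideline=guideline,
        registry=registry,
        store=store,
    )
    ordered = sorted(
        enumerate(guideline.rules), key=lambda pair: (-pair[1].priority, pair[0])
    )
    by_archetype = _entries_by_archetype(case)
    output_defs = {
        code: registry.element_defs(b.archetype_id)[b.path]
        for code, b in guideline.bindings.items()
        if b.direction == "output"
    }
    fired: list[str] = []
    max_passes = len(guideline.rules) + 1
    passes = 0
    for _ in range(max_passes):
        passes += 1
        snapshot = dict(ctx.working_memory)
        for _, rule in ordered:
            tuples = _candidate_tuples(guideline, rule, by_archetype)
            match = None
            for tup in tuples:
                if _and3(eval_condition(c, ctx, tup) for c in rule.when) is True:
                    match = tup
                    break
            if match is None:
                continue
            applied = {}
            for action in rule.then:
                value = _term_value(action.value, ctx, match)
                if value is UNKNOWN:
                    continue
                edef = output_defs.get(action.target.code)
                if edef is None:
                    raise EngineError(
                        f"rule {rule.rule_id}: target {action.target.code} "
                        "is not an output binding")
                dv = _coerce_output(value, edef)
                ctx.working_memory[action.target.code] = dv
                applied[action.target.code] = dv
            if applied:
                if rule.rule_id not in fired:
                    fired.append(rule.rule_id)
                ctx.trace.append({
                    "pass": passes,
                    "rule_id": rule.rule_id,
                    "tuple": {
                        aid: (e.event_time.isoformat() if e else None)
                        for aid, e in match.items()
                    },
                    "assigned": {k: v.to_dict() for k, v in applied.items()},
                })
        if ctx.working_memory == snapshot:
            break
    else:
        raise EngineCycleError(
            f"{guideline.guideline_id}: no fixpoint within {max_passes} passes")
    outputs: dict[tuple[str, str], DataValue] = {}
    indeterminate: list[tuple[str, str]] = []
    for code, b in guideline.bindings.items():
        if b.direction != "output":
            continue
        if code in ctx.working_memory:
            outputs[(b.archetype_id, b.path)] = ctx.working_memory[code]
        else:
            indeterminate.append((b.archetype_id, b.path))
    return EngineResult(
        outputs=outputs,
        fired=tuple(fired),
        indeterminate=tuple(sorted(set(indeterminate))),
        passes=passes,
        trace=tuple(ctx.trace),
    )


def apply_outputs(case: PatientCase, result: EngineResult,
                  registry: SchemaRegistry) -> PatientCase:
    """Materialise engine outputs back into the case.

    Values are written into every existing entry of the output archetype;
    archetypes without entries get one new entry stamped at the case's
    reference time (the decision-support system recording its evaluation).
    """
    by_archetype: dict[str, dict[str, DataValue]] = {}
    for (aid, path), value in result.outputs.items():
        by_archetype.setdefault(aid, {})[path] = value
    entries = list(case.entries)
    for aid, values in by_archetype.items():
        found = False
        for i, e in enumerate(entries):
            if e.archetype_id == aid:
                found = True
                elements = dict(e.elements)
                elements.update(values)
                entries[i] = Entry(e.archetype_id, e.entry_type, e.event_time,
                                   elements)
        if not found:
            schema = registry.get(aid)
            entries.append(Entry(aid, schema.entry_type, case.reference_time,
                                 dict(values)))
    return PatientCase(case.case_id, case.reference_time, tuple(entries))


def run_chain(guidelines: Sequence[Guideline], case: PatientCase, *,
              registry: SchemaRegistry, store: TerminologyStore,
              current_datetime: datetime | None = None
              ) -> tuple[PatientCase, dict[str, EngineResult]]:
    """Run guidelines in order, feeding each one's outputs into the case.

    This is forward chaining at guideline granularity: the stroke content
    is stratified (NIHSS item scores -> total -> contraindication flags),
    so the score computed by the scoring guideline becomes case data that
    the contraindication guideline then reads.
    """
    results: dict[str, EngineResult] = {}
    for g in guidelines:
        result = run_guideline(g, case, registry=registry, store=store,
                               current_datetime=current_datetime)
        results[g.guideline_id] = result
        case = apply_outputs(case, result, registry)
    return case, results
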