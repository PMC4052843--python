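"""Guidelines: archetype bindings, rules and term groups, plus file I/O.

A guideline file has three sections mirroring how guideline-definition
content is usually organised — a *definition* section assigning gt-codes
to archetype elements, a *rules* section of when/then rules, and a
*terminology* section binding group gt-codes to external codes::

    guideline_id = <"thrombolysis_contraindications">
    description = <"...">
    definition = <
        ["gt0003"] = <
            archetype_id = <"openEHR-EHR-EVALUATION.problem_diagnosis">
            path = <"/data[at0001]/items[at0002.1]">
            direction = <"input">
        >
    >
    rules = <
        ["nihss_set_true"] = <
            priority = <10>
            when = <"$gt0008>25">
            then = <"$gt0016=true">
        >
    >
    term_groups = <
        ["gt0102"] = <
            text = <"stroke">
            bindings = <
                ["ICD10"] = <"I64">
                ["SNOMED-CT"] = <"230690007">
            >
        >
    >

The ``when`` list is an implicit conjunction; disjunction must be written
explicitly with ``||`` inside one expression.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from . import odin
from .expr import (
    Arith, Assignment, CodedLiteral, Comparison, Condition, CurrentDateTime,
    DurationLiteral, Exists, GtRef, IsA, Literal, parse_expression, unparse,
    gt_refs, And, Or, Not,
)
from .model import SchemaRegistry, Violation, PATH_RE
from .terminology import TermGroup, TerminologyStore

__all__ = [
    "ArchetypeBinding", "Rule", "Guideline", "GuidelineFormatError",
    "parse_guideline", "serialize_guideline", "validate_guideline",
    "guideline_to_dict", "guideline_from_dict",
]


class GuidelineFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ArchetypeBinding:
    gt_code: str
    archetype_id: str
    path: str
    direction: str  # "input" | "output"

    def __post_init__(self) -> None:
        if self.direction not in ("input", "output"):
            raise GuidelineFormatError(
                f"binding {self.gt_code}: direction must be input/output")


@dataclass(frozen=True)
class Rule:
    rule_id: str
    when: tuple[Condition, ...]
    then: tuple[Assignment, ...]
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.then:
            raise GuidelineFormatError(f"rule {self.rule_id}: empty then-part")


@dataclass(frozen=True)
class Guideline:
    guideline_id: str
    description: str = ""
    bindings: Mapping[str, ArchetypeBinding] = field(default_factory=dict)
    term_groups: Mapping[str, TermGroup] = field(default_factory=dict)
    rules: tuple[Rule, ...] = ()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Guideline):
            return NotImplemented
        return (
            self.guideline_id == other.guideline_id
            and self.description == other.description
            and dict(self.bindings) == dict(other.bindings)
            and dict(self.term_groups) == dict(other.term_groups)
            and self.rules == other.rules
        )


def _as_list(v) -> list:
    if isinstance(v, list):
        return v
    if isinstance(v, dict) and not v:
        return []
    return [v]


def serialize_guideline(g: Guideline) -> str:
    doc: dict = {
        "guideline_id": g.guideline_id,
        "description": g.description,
        "definition": {
            code: {
                "archetype_id": b.archetype_id,
                "path": b.path,
                "direction": b.direction,
            }
            for code, b in g.bindings.items()
        },
        "rules": {
            r.rule_id: {
                "priority": r.priority,
                "when": [unparse(c) for c in r.when],
                "then": [unparse(a) for a in r.then],
            }
            for r in g.rules
        },
        "term_groups": {
            grp.group_code: {
                "text": grp.display,
                "bindings": {sys: list(codes) for sys, codes in grp.bindings.items()},
            }
            for grp in g.term_groups.values()
        },
    }
    return odin.dumps(doc, header=f"guideline {g.guideline_id}")


def parse_guideline(text: str) -> Guideline:
    doc = odin.loads(text)
    try:
        gid = doc["guideline_id"]
    except KeyError:
        raise GuidelineFormatError("missing guideline_id") from None
    bindings: dict[str, ArchetypeBinding] = {}
    for code, raw in (doc.get("definition") or {}).items():
        bindings[code] = ArchetypeBinding(
            code, raw["archetype_id"], raw["path"], raw["direction"])
    rules = []
    for rid, raw in (doc.get("rules") or {}).items():
        when: list[Condition] = []
        for src in _as_list(raw.get("when", [])):
            node = parse_expression(src)
            if isinstance(node, Assignment):
                raise GuidelineFormatError(
                    f"rule {rid}: assignment not allowed in when-part: {src!r}")
            when.append(node)
        then: list[Assignment] = []
        for src in _as_list(raw.get("then", [])):
            node = parse_expression(src)
            if not isinstance(node, Assignment):
                raise GuidelineFormatError(
                    f"rule {rid}: then-part must be an assignment: {src!r}")
            then.append(node)
        rules.append(Rule(str(rid), tuple(when), tuple(then),
                          int(raw.get("priority", 0))))
    groups: dict[str, TermGroup] = {}
    for code, raw in (doc.get("term_groups") or {}).items():
        groups[code] = TermGroup(
            str(code),
            str(raw.get("text", "")),
            {
                str(sys): tuple(str(c) for c in _as_list(codes))
                for sys, codes in (raw.get("bindings") or {}).items()
            },
        )
    dup = [r for i, r in enumerate(rules) if r.rule_id in {x.rule_id for x in rules[:i]}]
    if dup:
        raise GuidelineFormatError(f"duplicate rule id {dup[0].rule_id!r}")
    return Guideline(str(gid), str(doc.get("description", "")),
                     bindings, groups, tuple(rules))


def guideline_to_dict(g: Guideline) -> dict:
    """Structured (JSON-ready) serialisation for tooling."""
    return {
        "guideline_id": g.guideline_id,
        "description": g.description,
        "definition": {
            code: {"archetype_id": b.archetype_id, "path": b.path,
                   "direction": b.direction}
            for code, b in g.bindings.items()
        },
        "rules": [
            {"rule_id": r.rule_id, "priority": r.priority,
             "when": [unparse(c) for c in r.when],
             "then": [unparse(a) for a in r.then]}
            for r in g.rules
        ],
        "term_groups": {
            grp.group_code: {"text": grp.display,
                             "bindings": {s: list(c) for s, c in grp.bindings.items()}}
            for grp in g.term_groups.values()
        },
    }


def guideline_from_dict(doc: dict) -> Guideline:
    bindings = {
        code: ArchetypeBinding(code, b["archetype_id"], b["path"], b["direction"])
        for code, b in doc.get("definition", {}).items()
    }
    rules = tuple(
        Rule(
            r["rule_id"],
            tuple(parse_expression(c) for c in r.get("when", [])),  # type: ignore[misc]
            tuple(parse_expression(a) for a in r.get("then", [])),  # type: ignore[misc]
            int(r.get("priority", 0)),
        )
        for r in doc.get("rules", [])
    )
    groups = {
        code: TermGroup(code, raw.get("text", ""),
                        {s: tuple(c) for s, c in raw.get("bindings", {}).items()})
        for code, raw in doc.get("term_groups", {}).items()
    }
    return Guideline(doc["guideline_id"], doc.get("description", ""),
                     bindings, groups, rules)


# --- validation -------------------------------------------------------------

_NUMERIC = ("count", "quantity")


def _term_kind(term, g: Guideline, registry: SchemaRegistry, out: list[Violation],
               where: str) -> str | None:
    """Static kind of a term: one of the element kinds, 'number', 'datetime',
    'duration', 'str', 'bool', 'coded'; None when unknown/invalid."""
    if isinstance(term, GtRef):
        b = g.bindings.get(term.code)
        if b is None:
            out.append(Violation("gt_ref", where, f"unbound gt-code {term.code}"))
            return None
        try:
            defs = registry.element_defs(b.archetype_id)
        except Exception as exc:
            out.append(Violation("binding", where, str(exc)))
            return None
        edef = defs.get(b.path)
        if edef is None:
            out.append(Violation("binding", where,
                                 f"{b.archetype_id} has no element {b.path}"))
            return None
        return edef.kind
    if isinstance(term, Literal):
        if isinstance(term.value, bool):
            return "bool"
        if isinstance(term.value, (int, float)):
            return "number"
        return "str"
    if isinstance(term, CodedLiteral):
        return "coded"
    if isinstance(term, DurationLiteral):
        return "duration"
    if isinstance(term, CurrentDateTime):
        return "datetime"
    if isinstance(term, Arith):
        lk = _term_kind(term.left, g, registry, out, where)
        rk = _term_kind(term.right, g, registry, out, where)
        if lk is None or rk is None:
            return None
        if lk in ("datetime", "date_time") and rk == "duration":
            return "datetime"
        if lk in _NUMERIC + ("number",) and rk in _NUMERIC + ("number",):
            return "number"
        if lk == "duration" and rk == "duration":
            return "duration"
        out.append(Violation("type", where,
                             f"cannot combine {lk} {term.op} {rk}"))
        return None
    return None


_COMPAT = {
    ("count", "number"), ("quantity", "number"), ("number", "count"),
    ("number", "quantity"), ("count", "count"), ("quantity", "quantity"),
    ("count", "quantity"), ("quantity", "count"), ("number", "number"),
    ("date_time", "datetime"), ("datetime", "date_time"),
    ("date_time", "date_time"), ("datetime", "datetime"),
    ("text", "str"), ("str", "text"), ("text", "text"), ("str", "str"),
    ("coded_text", "coded"), ("coded", "coded_text"),
    ("coded_text", "coded_text"), ("text", "coded"), ("coded", "text"),
    ("boolean", "bool"), ("bool", "boolean"), ("boolean", "boolean"),
    ("duration", "duration"),
}


def _check_condition(cond, g: Guideline, registry: SchemaRegistry,
                     out: list[Violation], where: str) -> None:
    if isinstance(cond, Comparison):
        lk = _term_kind(cond.lhs, g, registry, out, where)
        rk = _term_kind(cond.rhs, g, registry, out, where)
        if lk and rk and (lk, rk) not in _COMPAT:
            out.append(Violation("type", where,
                                 f"incompatible comparison {lk} {cond.op} {rk}"))
        if lk in ("coded_text", "coded", "boolean", "bool") and \
                cond.op not in ("==", "!="):
            out.append(Violation("type", where,
                                 f"{lk} values only support == and !="))
    elif isinstance(cond, IsA):
        kind = _term_kind(cond.ref, g, registry, out, where)
        if kind not in (None, "coded_text"):
            out.append(Violation("type", where,
                                 f"is_a requires a coded element, got {kind}"))
        grp = g.term_groups.get(cond.group)
        if grp is None:
            out.append(Violation("term_group", where,
                                 f"unresolved term group {cond.group}"))
        elif not any(grp.bindings.values()):
            out.append(Violation("term_group", where,
                                 f"term group {cond.group} has no bindings"))
    elif isinstance(cond, Exists):
        _term_kind(cond.ref, g, registry, out, where)
    elif isinstance(cond, Not):
        _check_condition(cond.cond, g, registry, out, where)
    elif isinstance(cond, (And, Or)):
        for p in cond.parts:
            _check_condition(p, g, registry, out, where)


def validate_guideline(g: Guideline, registry: SchemaRegistry,
                       store: TerminologyStore) -> list[Violation]:
    """Static checks; an empty list means the guideline is executable."""
    out: list[Violation] = []
    for code, b in g.bindings.items():
        if code != b.gt_code:
            out.append(Violation("binding", code, "key does not match gt_code"))
        if not PATH_RE.match(b.path):
            out.append(Violation("binding", code, f"malformed path {b.path!r}"))
            continue
        if b.archetype_id not in registry:
            out.append(Violation("binding", code,
                                 f"unknown archetype {b.archetype_id}"))
            continue
        if b.path not in registry.element_defs(b.archetype_id):
            out.append(Violation("binding", code,
                                 f"{b.archetype_id} has no element {b.path}"))
    for grp in g.term_groups.values():
        for system_id, codes in grp.bindings.items():
            for code in codes:
                if not store.has_code(system_id, code):
                    out.append(Violation("term_group", grp.group_code,
                                         f"code {system_id}::{code} not in store"))
    seen: set[str] = set()
    for rule in g.rules:
        if rule.rule_id in seen:
            out.append(Violation("rule", rule.rule_id, "duplicate rule id"))
        seen.add(rule.rule_id)
        where = f"rule {rule.rule_id}"
        for cond in rule.when:
            _check_condition(cond, g, registry, out, where)
        for action in rule.then:
            b = g.bindings.get(action.target.code)
            if b is None:
                out.append(Violation("gt_ref", where,
                                     f"unbound gt-code {action.target.code}"))
            elif b.direction != "output":
                out.append(Violation("direction", where,
                                     f"assignment target {action.target.code} "
                                     "is not an output binding"))
            vk = _term_kind(action.value, g, registry, out, where)
            tk = _term_kind(action.target, g, registry, out, where)
            if vk and tk and (tk, vk) not in _COMPAT:
                out.append(Violation("type", where,
                                     f"cannot assign {vk} to {tk} element"))
    return out
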