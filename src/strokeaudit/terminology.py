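"""Code systems with is_a subsumption and guideline-local term groups.

Each :class:`CodeSystem` is a DAG of concepts linked by explicit parent
edges; ``is_a`` is the reflexive-transitive closure of those edges.  ICD-10
code nesting (e.g. ``G83.8`` under ``G83``) is encoded as explicit parent
links in the shipped tables rather than by string-prefix logic, so
subsumption behaves identically across SNOMED CT, ICD-10 and ATC.

A :class:`TermGroup` is the guideline-side binding table: one gt-code
(e.g. ``gt0102`` "stroke") mapped, per code system, to the concrete codes
that count as members.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from .values import CodedText

__all__ = [
    "CodeSystem",
    "TermGroup",
    "TerminologyStore",
    "TerminologyError",
    "UnknownCodeError",
    "load_terminology",
    "load_terminology_dir",
]

log = logging.getLogger(__name__)


class TerminologyError(ValueError):
    """Malformed terminology content (cycles, dangling parents...)."""


class UnknownCodeError(KeyError):
    def __init__(self, system_id: str, code: str) -> None:
        super().__init__(f"unknown code {system_id}::{code}")
        self.system_id = system_id
        self.code = code


@dataclass(frozen=True)
class CodeSystem:
    system_id: str
    concepts: Mapping[str, str]
    parents: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, ps in self.parents.items():
            if code not in self.concepts:
                raise TerminologyError(
                    f"{self.system_id}: parent links for unknown code {code!r}")
            for p in ps:
                if p not in self.concepts:
                    raise TerminologyError(
                        f"{self.system_id}: dangling parent {p!r} of {code!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {c: WHITE for c in self.concepts}
        for start in self.concepts:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(self.parents.get(start, ())))]
            colour[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if colour[parent] == GREY:
                        raise TerminologyError(
                            f"{self.system_id}: cycle through {parent!r}")
                    if colour[parent] == WHITE:
                        colour[parent] = GREY
                        stack.append((parent, iter(self.parents.get(parent, ()))))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = BLACK
                    stack.pop()


@dataclass(frozen=True)
class TermGroup:
    """A guideline-local concept set bound to codes per code system."""

    group_code: str
    display: str = ""
    bindings: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(self.bindings.values()):
            raise TerminologyError(
                f"term group {self.group_code} has no code bindings")


class TerminologyStore:
    def __init__(self, systems: Iterable[CodeSystem] = ()) -> None:
        self.systems: dict[str, CodeSystem] = {}
        self._ancestor_cache: dict[tuple[str, str], frozenset[str]] = {}
        for s in systems:
            self.add_system(s)

    def add_system(self, system: CodeSystem) -> None:
        if system.system_id in self.systems:
            raise TerminologyError(f"code system {system.system_id} already loaded")
        self.systems[system.system_id] = system

    def has_code(self, system_id: str, code: str) -> bool:
        sys = self.systems.get(system_id)
        return sys is not None and code in sys.concepts

    def display(self, system_id: str, code: str) -> str:
        sys = self.systems.get(system_id)
        return sys.concepts.get(code, "") if sys else ""

    def ancestors(self, system_id: str, code: str) -> frozenset[str]:
        """Reflexive-transitive parent closure of a code."""
        key = (system_id, code)
        cached = self._ancestor_cache.get(key)
        if cached is not None:
            return cached
        sys = self.systems.get(system_id)
        if sys is None or code not in sys.concepts:
            raise UnknownCodeError(system_id, code)
        closure = {code}
        frontier = [code]
        while frontier:
            for parent in sys.parents.get(frontier.pop(), ()):
                if parent not in closure:
                    closure.add(parent)
                    frontier.append(parent)
        result = frozenset(closure)
        self._ancestor_cache[key] = result
        return result

    def is_a(self, system_id: str, code: str, ancestor_code: str) -> bool:
        """True iff ``code`` equals or descends from ``ancestor_code``."""
        sys = self.systems.get(system_id)
        if sys is None or ancestor_code not in sys.concepts:
            raise UnknownCodeError(system_id, ancestor_code)
        return ancestor_code in self.ancestors(system_id, code)


def matches_group(value: CodedText, group: TermGroup, store: TerminologyStore) -> bool:
    """True iff the coded value is subsumed by any code the group binds
    for the value's code system.

    Tolerant by design: a system with no binding in the group, or a code
    unknown to the store, yields False (logged) rather than an error, so a
    single oddly-coded entry cannot abort an audit.
    """
    codes = group.bindings.get(value.system, ())
    if not codes:
        log.debug("group %s has no binding for system %s", group.group_code, value.system)
        return False
    if not store.has_code(value.system, value.code):
        log.debug("code %s::%s not in terminology store", value.system, value.code)
        return False
    ancestors = store.ancestors(value.system, value.code)
    return any(c in ancestors for c in codes)


def load_terminology(config: Mapping | str | IO[str]) -> TerminologyStore:
    """Build a store from a config mapping (or YAML text/stream).

    Shape: ``{system_id: {code: {display: str, parents: [code, ...]}}}``.
    Acyclicity and parent existence are verified on load.
    """
    if not isinstance(config, Mapping):
        import yaml

        text = config if isinstance(config, str) else config.read()
        config = yaml.safe_load(text) or {}
    store = TerminologyStore()
    for system_id, concepts_cfg in config.items():
        concepts: dict[str, str] = {}
        parents: dict[str, tuple[str, ...]] = {}
        for code, info in (concepts_cfg or {}).items():
            info = info or {}
            concepts[str(code)] = str(info.get("display", ""))
            ps = tuple(str(p) for p in info.get("parents", ()))
            if ps:
                parents[str(code)] = ps
        store.add_system(CodeSystem(system_id, concepts, parents))
    return store


def load_terminology_dir(path: str | Path,
                         filenames: Mapping[str, str] | None = None) -> TerminologyStore:
    """Load one tab-separated table per code system from a directory.

    Each table has a header row ``code  display  parents`` with parents
    ``|``-separated; ``--`` lines are comments.
    """
    path = Path(path)
    filenames = filenames or {
        "snomed_ct.tsv": "SNOMED-CT",
        "icd10.tsv": "ICD10",
        "atc.tsv": "ATC",
    }
    store = TerminologyStore()
    for filename, system_id in filenames.items():
        concepts: dict[str, str] = {}
        parents: dict[str, tuple[str, ...]] = {}
        lines = (path / filename).read_text(encoding="utf-8").splitlines()
        for line in lines:
            if not line.strip() or line.startswith("--") or line.startswith("code\t"):
                continue
            fields = line.split("\t")
            code = fields[0].strip()
            concepts[code] = fields[1].strip() if len(fields) > 1 else ""
            if len(fields) > 2 and fields[2].strip():
                parents[code] = tuple(p.strip() for p in fields[2].split("|") if p.strip())
        store.add_system(CodeSystem(system_id, concepts, parents))
    return store
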