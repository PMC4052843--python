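"""Archetype-lite clinical records.

An :class:`ArchetypeSchema` declares, for one archetype, which element
paths exist, what value kind each carries, the fixed unit of quantities
and the allowed archetype-internal codes of coded elements.  ITEM_TREE
schemas are never instantiated on their own: a host entry schema declares
a slot and the tree's elements are flattened into the host under a
prefixed path, mirroring how openEHR templates resolve slots.

Patient data is a :class:`PatientCase`: a bag of timestamped entries,
each an instance of a registered archetype with path-addressed values.
``reference_time`` is the retrospective evaluation instant (here: the
thrombolysis decision time) that all look-back rules anchor to.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping

from .values import DataValue, Quantity, CodedText

__all__ = [
    "ENTRY_TYPES",
    "ElementDef",
    "SlotDef",
    "ArchetypeSchema",
    "Entry",
    "PatientCase",
    "Violation",
    "SchemaRegistry",
    "SchemaError",
    "get_value",
    "set_element",
    "validate_case",
]

ENTRY_TYPES = ("OBSERVATION", "EVALUATION", "INSTRUCTION", "ACTION", "ITEM_TREE")

#: slash-and-bracket archetype path grammar, e.g. ``/data[at0001]/items[at0002.1]``
PATH_RE = re.compile(r"^(/[A-Za-z_][A-Za-z0-9_]*(\[[A-Za-z0-9._\-]+\])?)+$")

VALUE_KINDS = ("count", "quantity", "boolean", "text", "coded_text", "date_time", "duration")


class SchemaError(ValueError):
    """Raised for malformed or conflicting schema definitions."""


@dataclass(frozen=True)
class ElementDef:
    path: str
    kind: str
    name: str = ""
    unit: str | None = None
    codes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not PATH_RE.match(self.path):
            raise SchemaError(f"malformed element path: {self.path!r}")
        if self.kind not in VALUE_KINDS:
            raise SchemaError(f"unknown value kind {self.kind!r} at {self.path}")


@dataclass(frozen=True)
class SlotDef:
    item_tree_id: str
    prefix: str


@dataclass(frozen=True)
class ArchetypeSchema:
    archetype_id: str
    entry_type: str
    elements: tuple[ElementDef, ...] = ()
    slots: tuple[SlotDef, ...] = ()

    def __post_init__(self) -> None:
        if self.entry_type not in ENTRY_TYPES:
            raise SchemaError(f"unknown entry type {self.entry_type!r}")
        paths = [e.path for e in self.elements]
        if len(paths) != len(set(paths)):
            raise SchemaError(f"duplicate element paths in {self.archetype_id}")
        codes: list[str] = []
        for e in self.elements:
            codes.extend(e.codes)
        if len(codes) != len(set(codes)):
            raise SchemaError(f"duplicate local codes in {self.archetype_id}")


@dataclass(frozen=True)
class Entry:
    archetype_id: str
    entry_type: str
    event_time: datetime
    elements: Mapping[str, DataValue] = field(default_factory=dict)


@dataclass(frozen=True)
class PatientCase:
    case_id: str
    reference_time: datetime
    entries: tuple[Entry, ...] = ()


@dataclass(frozen=True)
class Violation:
    kind: str
    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.where}: {self.message}"


class SchemaRegistry:
    """Registry of archetype schemas; the data contract for cases and rules.

    Slot resolution is lazy: ITEM_TREE schemas may be registered after their
    hosts, and ``element_defs`` flattens a host's slots into prefixed paths.
    """

    def __init__(self) -> None:
        self._schemas: dict[str, ArchetypeSchema] = {}

    def register_schema(self, schema: ArchetypeSchema) -> "SchemaRegistry":
        if schema.archetype_id in self._schemas:
            raise SchemaError(f"archetype already registered: {schema.archetype_id}")
        self._schemas[schema.archetype_id] = schema
        return self

    def get(self, archetype_id: str) -> ArchetypeSchema:
        try:
            return self._schemas[archetype_id]
        except KeyError:
            raise SchemaError(f"unknown archetype: {archetype_id}") from None

    def __contains__(self, archetype_id: str) -> bool:
        return archetype_id in self._schemas

    def __len__(self) -> int:
        return len(self._schemas)

    def __iter__(self):
        return iter(self._schemas.values())

    def element_defs(self, archetype_id: str) -> dict[str, ElementDef]:
        """Element definitions of an archetype with ITEM_TREE slots flattened."""
        schema = self.get(archetype_id)
        defs = {e.path: e for e in schema.elements}
        for slot in schema.slots:
            tree = self.get(slot.item_tree_id)
            if tree.entry_type != "ITEM_TREE":
                raise SchemaError(
                    f"slot {slot.item_tree_id} in {archetype_id} is not an ITEM_TREE"
                )
            for e in tree.elements:
                path = slot.prefix + e.path
                defs[path] = ElementDef(path, e.kind, e.name, e.unit, e.codes)
        return defs

    def validate_entry(self, entry: Entry) -> list[Violation]:
        """Check an entry against its schema; an empty list means valid."""
        schema = self.get(entry.archetype_id)
        out: list[Violation] = []
        if schema.entry_type == "ITEM_TREE":
            out.append(
                Violation("entry_type", entry.archetype_id,
                          "ITEM_TREE archetypes cannot be instantiated as entries")
            )
            return out
        if entry.entry_type != schema.entry_type:
            out.append(
                Violation("entry_type", entry.archetype_id,
                          f"entry type {entry.entry_type} does not match schema "
                          f"{schema.entry_type}")
            )
        defs = self.element_defs(entry.archetype_id)
        for path, value in entry.elements.items():
            edef = defs.get(path)
            if edef is None:
                out.append(Violation("path", path, "path not declared by schema"))
                continue
            if value.kind != edef.kind:
                out.append(
                    Violation("kind", path,
                              f"expected {edef.kind}, got {value.kind}")
                )
                continue
            if edef.kind == "quantity" and edef.unit is not None:
                assert isinstance(value, Quantity)
                if value.unit != edef.unit:
                    out.append(
                        Violation("unit", path,
                                  f"expected unit {edef.unit!r}, got {value.unit!r}")
                    )
            if edef.kind == "coded_text" and edef.codes:
                assert isinstance(value, CodedText)
                if value.system == "local" and value.code not in edef.codes:
                    out.append(
                        Violation("code", path,
                                  f"local code {value.code} not allowed here")
                    )
        return out


def get_value(case: PatientCase, archetype_id: str, path: str) -> list[DataValue]:
    """All values at ``path`` across the case's entries of one archetype.

    Returned in ascending ``event_time`` (stable for ties); entries lacking
    the path contribute nothing, and a missing archetype yields ``[]``.
    """
    hits = [
        (e.event_time, i, e.elements[path])
        for i, e in enumerate(case.entries)
        if e.archetype_id == archetype_id and path in e.elements
    ]
    hits.sort(key=lambda t: (t[0], t[1]))
    return [v for _, _, v in hits]


def set_element(case: PatientCase, archetype_id: str, path: str,
                value: DataValue) -> PatientCase:
    """Return a copy of the case with ``path`` set in every matching entry."""
    entries = []
    found = False
    for e in case.entries:
        if e.archetype_id == archetype_id:
            found = True
            elements = dict(e.elements)
            elements[path] = value
            e = Entry(e.archetype_id, e.entry_type, e.event_time, elements)
        entries.append(e)
    if not found:
        raise SchemaError(f"case {case.case_id} has no entry of {archetype_id}")
    return PatientCase(case.case_id, case.reference_time, tuple(entries))


def validate_case(case: PatientCase, registry: SchemaRegistry) -> list[Violation]:
    """Validate every entry plus the case-wide timezone discipline.

    Timestamps within one case must be uniformly timezone-aware or uniformly
    naive; mixing the two would make temporal comparisons undefined.
    """
    out: list[Violation] = []
    stamps: list[datetime] = [case.reference_time]
    for e in case.entries:
        out.extend(registry.validate_entry(e))
        stamps.append(e.event_time)
        for v in e.elements.values():
            if v.kind == "date_time":
                stamps.append(v.value)  # type: ignore[attr-defined]
    aware = {s.tzinfo is not None for s in stamps}
    if len(aware) > 1:
        out.append(
            Violation("timezone", case.case_id,
                      "naive and timezone-aware timestamps mixed within one case")
        )
    for e in case.entries:
        if len(aware) == 1 and e.event_time > case.reference_time:
            out.append(
                Violation("reference_time", e.archetype_id,
                          "entry event_time is after the case reference_time")
            )
    return out
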