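"""Readers and writers for patient cases.

Two on-disk forms are supported:

* ``.case.dadl`` — the human-readable ODIN-style dialect (see :mod:`.odin`);
* ``.case.json`` — the normative structured serialisation.

Both round-trip field-for-field.  Value typing in the dADL form is purely
syntactic: integers are counts, ``magnitude,"unit"`` pairs are quantities,
bracketed terms are coded text, bare timestamps are date-times.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from . import odin
from .model import Entry, PatientCase, ENTRY_TYPES
from .values import (
    Boolean, CodedText, Count, DataValue, DateTime, Duration, Quantity, Text,
    format_datetime, format_duration, parse_datetime, value_from_dict,
)

__all__ = ["loads_case", "dumps_case", "read_case", "write_case", "CaseFormatError"]


class CaseFormatError(ValueError):
    """A structurally well-formed document that is not a valid case."""


def _value_to_odin(v: DataValue) -> Any:
    if isinstance(v, Count):
        return v.value
    if isinstance(v, Quantity):
        return [v.magnitude, v.unit]
    if isinstance(v, Boolean):
        return v.value
    if isinstance(v, Text):
        return v.value
    if isinstance(v, CodedText):
        return odin.CodePhrase(v.system, v.code, v.display)
    if isinstance(v, DateTime):
        return v.value
    if isinstance(v, Duration):
        return odin.Dur(format_duration(v.value))
    raise TypeError(f"unserialisable value {v!r}")


def _odin_to_value(raw: Any, where: str) -> DataValue:
    from datetime import datetime

    if isinstance(raw, list):
        if len(raw) == 2 and isinstance(raw[0], (int, float)) and isinstance(raw[1], str):
            return Quantity(float(raw[0]), raw[1])
        raise CaseFormatError(f"{where}: cannot type value {raw!r}")
    if isinstance(raw, bool):
        return Boolean(raw)
    if isinstance(raw, int):
        return Count(raw)
    if isinstance(raw, float):
        raise CaseFormatError(f"{where}: a bare decimal needs a unit (quantity)")
    if isinstance(raw, str):
        return Text(raw)
    if isinstance(raw, odin.CodePhrase):
        return CodedText(raw.system, raw.code, raw.display)
    if isinstance(raw, datetime):
        return DateTime(raw)
    if isinstance(raw, odin.Dur):
        return Duration(raw.delta)
    raise CaseFormatError(f"{where}: cannot type value {raw!r}")


def _as_list(v: Any) -> list:
    if isinstance(v, list):
        return v
    if isinstance(v, dict) and not v:
        return []
    return [v]


def _require(doc: dict, key: str, where: str) -> Any:
    if key not in doc:
        raise CaseFormatError(f"{where}: missing required field {key!r}")
    return doc[key]


def _case_to_odin(case: PatientCase) -> dict:
    entries = []
    for e in case.entries:
        entries.append({
            "archetype_id": e.archetype_id,
            "entry_type": e.entry_type,
            "event_time": e.event_time,
            "elements": {p: _value_to_odin(v) for p, v in e.elements.items()},
        })
    return {
        "case_id": case.case_id,
        "reference_time": case.reference_time,
        "entries": entries,
    }


def _odin_to_case(doc: dict) -> PatientCase:
    from datetime import datetime

    case_id = _require(doc, "case_id", "case")
    ref = _require(doc, "reference_time", "case")
    if not isinstance(ref, datetime):
        raise CaseFormatError("case: reference_time must be a timestamp")
    entries = []
    for i, raw in enumerate(_as_list(doc.get("entries", [])), start=1):
        where = f"entry [{i}]"
        if not isinstance(raw, dict):
            raise CaseFormatError(f"{where}: expected an object")
        etype = _require(raw, "entry_type", where)
        if etype not in ENTRY_TYPES:
            raise CaseFormatError(f"{where}: unknown entry type {etype!r}")
        when = _require(raw, "event_time", where)
        if not isinstance(when, datetime):
            raise CaseFormatError(f"{where}: event_time must be a timestamp")
        elements_raw = raw.get("elements", {})
        if isinstance(elements_raw, list) and not elements_raw:
            elements_raw = {}
        elements = {
            path: _odin_to_value(v, f"{where} {path}")
            for path, v in elements_raw.items()
        }
        entries.append(Entry(_require(raw, "archetype_id", where), etype, when, elements))
    return PatientCase(str(case_id), ref, tuple(entries))


def _case_to_dict(case: PatientCase) -> dict:
    return {
        "case_id": case.case_id,
        "reference_time": format_datetime(case.reference_time),
        "entries": [
            {
                "archetype_id": e.archetype_id,
                "entry_type": e.entry_type,
                "event_time": format_datetime(e.event_time),
                "elements": {p: v.to_dict() for p, v in e.elements.items()},
            }
            for e in case.entries
        ],
    }


def _case_from_dict(doc: dict) -> PatientCase:
    try:
        entries = tuple(
            Entry(
                e["archetype_id"],
                e["entry_type"],
                parse_datetime(e["event_time"]),
                {p: value_from_dict(v) for p, v in e.get("elements", {}).items()},
            )
            for e in doc.get("entries", [])
        )
        return PatientCase(doc["case_id"], parse_datetime(doc["reference_time"]), entries)
    except KeyError as exc:
        raise CaseFormatError(f"missing required field {exc.args[0]!r}") from None


def dumps_case(case: PatientCase, fmt: str = "dadl") -> str:
    if fmt == "dadl":
        return odin.dumps(_case_to_odin(case), header=f"patient case {case.case_id}")
    if fmt == "json":
        return json.dumps(_case_to_dict(case), indent=2) + "\n"
    raise ValueError(f"unknown case format {fmt!r}")


def loads_case(text: str, fmt: str = "dadl") -> PatientCase:
    if fmt == "dadl":
        return _odin_to_case(odin.loads(text))
    if fmt == "json":
        return _case_from_dict(json.loads(text))
    raise ValueError(f"unknown case format {fmt!r}")


def _infer_fmt(path: Path) -> str:
    return "json" if path.name.endswith(".json") else "dadl"


def read_case(path: str | Path, fmt: str | None = None) -> PatientCase:
    path = Path(path)
    return loads_case(path.read_text(encoding="utf-8"), fmt or _infer_fmt(path))


def write_case(case: PatientCase, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    path.write_text(dumps_case(case, fmt or _infer_fmt(path)), encoding="utf-8")
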