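"""Clinical data values.

Small immutable value types modelled on the openEHR reference-model data
values that archetype elements carry: counts, physical quantities with a
unit, booleans, plain and coded text, timestamps and durations.  Every
value knows how to serialise itself to a plain dict (the structured JSON
case format) and back.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, timedelta

__all__ = [
    "DataValue",
    "Count",
    "Quantity",
    "Boolean",
    "Text",
    "CodedText",
    "DateTime",
    "Duration",
    "value_from_dict",
    "parse_duration",
    "format_duration",
    "parse_datetime",
    "format_datetime",
]


class DataValue:
    """Base class for all clinical data values."""

    __slots__ = ()

    #: short lowercase tag used by schemas and the JSON serialisation
    kind: str = ""

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class Count(DataValue):
    """An integer count, e.g. a stroke-scale score."""

    value: int
    kind = "count"

    def __post_init__(self) -> None:
        if isinstance(self.value, bool) or not isinstance(self.value, int):
            raise TypeError(f"Count value must be an int, got {self.value!r}")

    def to_dict(self) -> dict:
        return {"type": "count", "value": self.value}


@dataclass(frozen=True)
class Quantity(DataValue):
    """A decimal magnitude with a non-empty unit (e.g. 2.9 mmol/l)."""

    magnitude: float
    unit: str
    kind = "quantity"

    def __post_init__(self) -> None:
        object.__setattr__(self, "magnitude", float(self.magnitude))
        if not self.unit:
            raise ValueError("Quantity.unit must be non-empty")

    def to_dict(self) -> dict:
        return {"type": "quantity", "magnitude": self.magnitude, "unit": self.unit}


@dataclass(frozen=True)
class Boolean(DataValue):
    value: bool
    kind = "boolean"

    def __post_init__(self) -> None:
        if not isinstance(self.value, bool):
            raise TypeError(f"Boolean value must be a bool, got {self.value!r}")

    def to_dict(self) -> dict:
        return {"type": "boolean", "value": self.value}


@dataclass(frozen=True)
class Text(DataValue):
    value: str
    kind = "text"

    def to_dict(self) -> dict:
        return {"type": "text", "value": self.value}


@dataclass(frozen=True)
class CodedText(DataValue):
    """A term from a code system ("local" denotes archetype-internal codes).

    Equality of coded text is decided on (system, code); the display text is
    carried for humans only and deliberately excluded from comparisons.
    """

    system: str
    code: str
    display: str = ""
    kind = "coded_text"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodedText):
            return NotImplemented
        return (self.system, self.code) == (other.system, other.code)

    def __hash__(self) -> int:
        return hash((self.system, self.code))

    def to_dict(self) -> dict:
        d = {"type": "coded_text", "system": self.system, "code": self.code}
        if self.display:
            d["display"] = self.display
        return d


@dataclass(frozen=True)
class DateTime(DataValue):
    value: datetime
    kind = "date_time"

    def to_dict(self) -> dict:
        return {"type": "date_time", "value": format_datetime(self.value)}


@dataclass(frozen=True)
class Duration(DataValue):
    value: timedelta
    kind = "duration"

    def to_dict(self) -> dict:
        return {"type": "duration", "value": format_duration(self.value)}


_VALUE_CLASSES = {
    "count": Count,
    "quantity": Quantity,
    "boolean": Boolean,
    "text": Text,
    "coded_text": CodedText,
    "date_time": DateTime,
    "duration": Duration,
}


def value_from_dict(d: dict) -> DataValue:
    """Inverse of :meth:`DataValue.to_dict`."""
    kind = d.get("type")
    if kind not in _VALUE_CLASSES:
        raise ValueError(f"unknown data value type {kind!r}")
    if kind == "count":
        return Count(int(d["value"]))
    if kind == "quantity":
        return Quantity(float(d["magnitude"]), d["unit"])
    if kind == "boolean":
        return Boolean(bool(d["value"]))
    if kind == "text":
        return Text(d["value"])
    if kind == "coded_text":
        return CodedText(d["system"], d["code"], d.get("display", ""))
    if kind == "date_time":
        return DateTime(parse_datetime(d["value"]))
    return Duration(parse_duration(d["value"]))


# --- ISO 8601 helpers -------------------------------------------------------

_DURATION_RE = re.compile(
    r"^(?P<sign>-)?P"
    r"(?:(?P<weeks>\d+)W)?"
    r"(?:(?P<days>\d+)D)?"
    r"(?:T"
    r"(?:(?P<hours>\d+)H)?"
    r"(?:(?P<minutes>\d+)M)?"
    r"(?:(?P<seconds>\d+(?:\.\d+)?)S)?"
    r")?$"
)


def parse_duration(text: str) -> timedelta:
    """Parse an ISO 8601 period (weeks/days/time components only).

    Calendar components (years, months) are rejected: look-back windows are
    defined as fixed spans so that date arithmetic stays unambiguous.
    """
    m = _DURATION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"invalid ISO 8601 duration: {text!r}")
    parts = m.groupdict()
    if not any(parts[k] for k in ("weeks", "days", "hours", "minutes", "seconds")):
        raise ValueError(f"duration has no components: {text!r}")
    td = timedelta(
        weeks=int(parts["weeks"] or 0),
        days=int(parts["days"] or 0),
        hours=int(parts["hours"] or 0),
        minutes=int(parts["minutes"] or 0),
        seconds=float(parts["seconds"] or 0),
    )
    return -td if parts["sign"] else td


def format_duration(td: timedelta) -> str:
    """Canonical ISO 8601 rendering of a timedelta (second resolution)."""
    sign = ""
    if td < timedelta(0):
        sign, td = "-", -td
    total = int(round(td.total_seconds()))
    days, rem = divmod(total, 86400)
    hours, rem = divmod(rem, 3600)
    minutes, seconds = divmod(rem, 60)
    out = sign + "P"
    if days:
        out += f"{days}D"
    time_part = ""
    if hours:
        time_part += f"{hours}H"
    if minutes:
        time_part += f"{minutes}M"
    if seconds or (not days and not hours and not minutes):
        time_part += f"{seconds}S"
    if time_part:
        out += "T" + time_part
    return out


def parse_datetime(text: str) -> datetime:
    try:
        return datetime.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValueError(f"invalid ISO 8601 timestamp: {text!r}") from exc


def format_datetime(dt: datetime) -> str:
    return dt.isoformat()
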