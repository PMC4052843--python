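"""A minimal ODIN/dADL-style ``key = <value>`` tree dialect.

This is the storage notation for patient cases and guideline files: nested
objects of ``key = <...>`` pairs, quoted or indexed keys (``["gt0102"]``,
``[1]``), and typed scalars — strings, integers, decimals, booleans, ISO
timestamps and durations, coded terms ``[SNOMED-CT::50960005|Haemorrhage|]``.
It is deliberately a small subset sufficient for this package's files; the
structured JSON serialisation is the normative form.

Parsed documents are plain dicts (ordered), lists (from ``[1] =`` indexed
blocks or comma-separated scalars) and scalars; :class:`CodePhrase` and
:class:`Dur` wrap coded terms and durations so the reader can tell them
apart from plain strings.
"""
from __future__ import annotations

import re
from datetime import datetime, timedelta
from typing import Any, NamedTuple

from .values import format_datetime, format_duration, parse_datetime, parse_duration

__all__ = ["CodePhrase", "Dur", "OdinParseError", "loads", "dumps"]


class CodePhrase(NamedTuple):
    system: str
    code: str
    display: str = ""


class Dur(NamedTuple):
    iso: str

    @property
    def delta(self) -> timedelta:
        return parse_duration(self.iso)


class OdinParseError(ValueError):
    def __init__(self, message: str, line: int, column: int) -> None:
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


class _Token(NamedTuple):
    kind: str
    value: Any
    line: int
    column: int


_TOKEN_SPEC = [
    ("COMMENT", r"--[^\n]*"),
    ("WS", r"[ \t\r\n]+"),
    ("STRING", r'"(?:\\.|[^"\\])*"'),
    ("CODE", r"\[([A-Za-z][A-Za-z0-9._\-]*)::([A-Za-z0-9._\-]+)(?:\|([^|\]]*)\|)?\]"),
    ("DATETIME", r"\d{4}-\d{2}-\d{2}T\d{2}:\d{2}(?::\d{2}(?:\.\d+)?)?(?:Z|[+-]\d{2}:\d{2})?"),
    ("DURATION", r"-?P(?:\d+[WD])+(?:T(?:\d+(?:\.\d+)?[HMS])+)?|-?PT(?:\d+(?:\.\d+)?[HMS])+"),
    ("NUMBER", r"-?\d+(?:\.\d+)?"),
    ("IDENT", r"[A-Za-z_][A-Za-z0-9_]*"),
    ("PUNCT", r"[<>=\[\],]"),
]
_MASTER_RE = re.compile("|".join(f"(?P<{k}>{p})" for k, p in _TOKEN_SPEC))
_CODE_RE = re.compile(_TOKEN_SPEC[3][1])


def _unescape(raw: str) -> str:
    return raw[1:-1].replace('\\"', '"').replace("\\\\", "\\")


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos, line, col = 0, 1, 1
    while pos < len(text):
        m = _MASTER_RE.match(text, pos)
        if m is None:
            raise OdinParseError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup or ""
        raw = m.group()
        if kind == "STRING":
            tokens.append(_Token("STRING", _unescape(raw), line, col))
        elif kind == "CODE":
            cm = _CODE_RE.match(raw)
            assert cm is not None
            tokens.append(
                _Token("CODE", CodePhrase(cm.group(1), cm.group(2), cm.group(3) or ""),
                       line, col)
            )
        elif kind == "DATETIME":
            tokens.append(_Token("DATETIME", parse_datetime(raw), line, col))
        elif kind == "DURATION":
            try:
                parse_duration(raw)
            except ValueError as exc:
                raise OdinParseError(str(exc), line, col) from None
            tokens.append(_Token("DURATION", Dur(raw), line, col))
        elif kind == "NUMBER":
            value = float(raw) if "." in raw else int(raw)
            tokens.append(_Token("NUMBER", value, line, col))
        elif kind == "IDENT":
            if raw in ("true", "false"):
                tokens.append(_Token("BOOL", raw == "true", line, col))
            else:
                tokens.append(_Token("IDENT", raw, line, col))
        elif kind == "PUNCT":
            tokens.append(_Token(raw, raw, line, col))
        # comments and whitespace are dropped
        newlines = raw.count("\n")
        if newlines:
            line += newlines
            col = len(raw) - raw.rfind("\n")
        else:
            col += len(raw)
        pos = m.end()
    tokens.append(_Token("EOF", None, line, col))
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token]) -> None:
        self.tokens = tokens
        self.i = 0

    def peek(self, offset: int = 0) -> _Token:
        return self.tokens[min(self.i + offset, len(self.tokens) - 1)]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        if tok.kind != "EOF":
            self.i += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise OdinParseError(f"expected {kind!r}, found {tok.value!r}",
                                 tok.line, tok.column)
        return tok

    def _at_key(self) -> bool:
        tok = self.peek()
        if tok.kind == "IDENT" and self.peek(1).kind == "=":
            return True
        if tok.kind == "[" and self.peek(1).kind in ("STRING", "NUMBER") \
                and self.peek(2).kind == "]" and self.peek(3).kind == "=":
            return True
        return False

    def _key(self) -> str | int:
        tok = self.next()
        if tok.kind == "IDENT":
            return tok.value
        if tok.kind == "[":
            inner = self.next()
            self.expect("]")
            return inner.value
        raise OdinParseError(f"expected a key, found {tok.value!r}", tok.line, tok.column)

    def object_items(self, stop: str) -> Any:
        items: dict[Any, Any] = {}
        while self._at_key():
            key = self._key()
            self.expect("=")
            self.expect("<")
            value = self.value()
            self.expect(">")
            if key in items:
                tok = self.peek()
                raise OdinParseError(f"duplicate key {key!r}", tok.line, tok.column)
            items[key] = value
        tok = self.peek()
        if tok.kind != stop:
            raise OdinParseError(f"expected {stop!r}, found {tok.value!r}",
                                 tok.line, tok.column)
        if items and all(isinstance(k, int) for k in items):
            return [items[k] for k in sorted(items)]
        return items

    def value(self) -> Any:
        if self.peek().kind == ">":
            return []
        if self._at_key():
            return self.object_items(">")
        scalars = [self._scalar()]
        while self.peek().kind == ",":
            self.next()
            scalars.append(self._scalar())
        return scalars[0] if len(scalars) == 1 else scalars

    def _scalar(self) -> Any:
        tok = self.next()
        if tok.kind in ("STRING", "CODE", "DATETIME", "DURATION", "NUMBER", "BOOL"):
            return tok.value
        raise OdinParseError(f"expected a value, found {tok.value!r}",
                             tok.line, tok.column)


def loads(text: str) -> dict:
    """Parse an ODIN document into nested dicts/lists/scalars."""
    parser = _Parser(_tokenize(text))
    doc = parser.object_items("EOF")
    if not isinstance(doc, dict):
        tok = parser.peek()
        raise OdinParseError("document root must be keyed", tok.line, tok.column)
    return doc


def _format_scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, CodePhrase):
        disp = f"|{v.display}|" if v.display else ""
        return f"[{v.system}::{v.code}{disp}]"
    if isinstance(v, Dur):
        return v.iso
    if isinstance(v, datetime):
        return format_datetime(v)
    if isinstance(v, timedelta):
        return format_duration(v)
    if isinstance(v, str):
        escaped = v.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    if isinstance(v, (int, float)):
        return repr(v)
    raise TypeError(f"cannot serialise scalar {v!r}")


def _format_key(k: Any) -> str:
    if isinstance(k, int):
        return f"[{k}]"
    if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", k):
        return k
    return f'[{_format_scalar(k)}]'


def _dump(value: Any, depth: int) -> str:
    pad = "    " * depth
    if isinstance(value, dict):
        lines = []
        for k, v in value.items():
            lines.append(f"{pad}{_format_key(k)} = <{_dump(v, depth + 1)}{'' if _is_scalarish(v) else pad}>")
        return "\n" + "\n".join(lines) + "\n" if lines else ""
    if isinstance(value, list):
        if all(not isinstance(v, (dict, list)) for v in value):
            return ", ".join(_format_scalar(v) for v in value)
        lines = []
        for i, v in enumerate(value, start=1):
            lines.append(f"{pad}[{i}] = <{_dump(v, depth + 1)}{'' if _is_scalarish(v) else pad}>")
        return "\n" + "\n".join(lines) + "\n" if lines else ""
    return _format_scalar(value)


def _is_scalarish(v: Any) -> bool:
    if isinstance(v, dict):
        return not v
    if isinstance(v, list):
        return all(not isinstance(x, (dict, list)) for x in v)
    return True


def dumps(doc: dict, header: str | None = None) -> str:
    """Serialise nested dicts/lists/scalars to ODIN text."""
    out = []
    if header:
        out.extend(f"-- {line}" for line in header.splitlines())
    for k, v in doc.items():
        out.append(f"{_format_key(k)} = <{_dump(v, 1)}{'' if _is_scalarish(v) else ''}>")
    return "\n".join(out) + "\n"
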