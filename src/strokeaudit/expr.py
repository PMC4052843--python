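"""Expression grammar of the guideline dialect.

``when`` conditions and ``then`` actions are written as compact strings::

    $gt0008>25
    $gt0003 is_a local::gt0102|stroke|
    $gt0004 + PT4H30M < currentDateTime
    ($gt0009 < 3) || ($gt0009 > 22)
    $gt0016=true                      (then-position assignment)
    $gt0200 = $gt0101 + $gt0102       (then-position arithmetic)

Grammar (EBNF-ish, ``|`` alternatives, ``*`` repetition)::

    condition  = or ;
    or         = and { "||" and } ;
    and        = unary { "&&" unary } ;
    unary      = "!" unary | "(" or ")" | simple ;
    simple     = "exists" "(" gtref ")"
               | additive "is_a" coded
               | additive cmp additive ;
    cmp        = "==" | "!=" | "<=" | ">=" | "<" | ">" ;
    additive   = term { ("+" | "-") term } ;
    term       = gtref | number | string | boolean | duration | coded
               | "currentDateTime" ;
    action     = gtref "=" additive ;

A bare ``=`` is assignment and is only legal as a whole ``then`` expression;
in ``when`` position it is a syntax error.  Operator precedence is
``!`` > ``&&`` > ``||``; comparisons bind tighter than both.  Quantity
literals carry no unit — the unit is fixed by the bound element's schema.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

from .values import parse_duration

__all__ = [
    "GtRef", "Literal", "CodedLiteral", "DurationLiteral", "CurrentDateTime",
    "Arith", "Comparison", "IsA", "Exists", "Not", "And", "Or", "Assignment",
    "Condition", "Term", "ExprSyntaxError", "parse_expression", "unparse",
    "gt_refs",
]


class ExprSyntaxError(ValueError):
    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GtRef:
    code: str  # e.g. "gt0008"


@dataclass(frozen=True)
class Literal:
    value: Union[int, float, str, bool]


@dataclass(frozen=True)
class CodedLiteral:
    system: str
    code: str
    display: str = ""


@dataclass(frozen=True)
class DurationLiteral:
    iso: str

    @property
    def delta(self):
        return parse_duration(self.iso)


@dataclass(frozen=True)
class CurrentDateTime:
    pass


@dataclass(frozen=True)
class Arith:
    op: str  # "+" or "-"
    left: "Term"
    right: "Term"


@dataclass(frozen=True)
class Comparison:
    lhs: "Term"
    op: str  # ==, !=, <, <=, >, >=
    rhs: "Term"


@dataclass(frozen=True)
class IsA:
    ref: GtRef
    group: str  # gt-code of the term group
    label: str = ""


@dataclass(frozen=True)
class Exists:
    ref: GtRef


@dataclass(frozen=True)
class Not:
    cond: "Condition"


@dataclass(frozen=True)
class And:
    parts: tuple


@dataclass(frozen=True)
class Or:
    parts: tuple


@dataclass(frozen=True)
class Assignment:
    target: GtRef
    value: "Term"


Term = Union[GtRef, Literal, CodedLiteral, DurationLiteral, CurrentDateTime, Arith]
Condition = Union[Comparison, IsA, Exists, Not, And, Or]

_TOKEN_SPEC = [
    ("WS", r"[ \t]+"),
    ("GTREF", r"\$gt\d+"),
    ("CODED", r"([A-Za-z][A-Za-z0-9._\-]*)::([A-Za-z0-9._\-]+)(?:\|([^|]*)\|)?"),
    ("DURATION", r"P(?:\d+[WD])+(?:T(?:\d+(?:\.\d+)?[HMS])+)?|PT(?:\d+(?:\.\d+)?[HMS])+"),
    ("NUMBER", r"\d+(?:\.\d+)?"),
    ("STRING", r"'(?:\\.|[^'\\])*'"),
    ("OP", r"==|!=|<=|>=|\|\||&&|[!<>=+\-()]"),
    ("IDENT", r"[A-Za-z_][A-Za-z0-9_]*"),
]
_MASTER_RE = re.compile("|".join(f"(?P<{k}>{p})" for k, p in _TOKEN_SPEC))
_CODED_RE = re.compile(_TOKEN_SPEC[2][1])

_CMP_OPS = ("==", "!=", "<=", ">=", "<", ">")


@dataclass(frozen=True)
class _Tok:
    kind: str
    value: object
    pos: int


def _tokenize(text: str) -> list[_Tok]:
    tokens: list[_Tok] = []
    pos = 0
    while pos < len(text):
        m = _MASTER_RE.match(text, pos)
        if m is None:
            raise ExprSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup or ""
        raw = m.group()
        if kind == "GTREF":
            tokens.append(_Tok("GTREF", raw[1:], pos))
        elif kind == "CODED":
            cm = _CODED_RE.match(raw)
            assert cm is not None
            tokens.append(_Tok("CODED", (cm.group(1), cm.group(2), cm.group(3) or ""), pos))
        elif kind == "DURATION":
            parse_duration(raw)  # validates
            tokens.append(_Tok("DURATION", raw, pos))
        elif kind == "NUMBER":
            tokens.append(_Tok("NUMBER", float(raw) if "." in raw else int(raw), pos))
        elif kind == "STRING":
            tokens.append(_Tok("STRING", raw[1:-1].replace("\\'", "'").replace("\\\\", "\\"), pos))
        elif kind == "OP":
            tokens.append(_Tok(raw, raw, pos))
        elif kind == "IDENT":
            if raw in ("true", "false"):
                tokens.append(_Tok("BOOL", raw == "true", pos))
            elif raw in ("is_a", "exists", "currentDateTime"):
                tokens.append(_Tok(raw, raw, pos))
            else:
                raise ExprSyntaxError(f"unknown identifier {raw!r}", pos)
        pos = m.end()
    tokens.append(_Tok("EOF", None, len(text)))
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Tok]) -> None:
        self.tokens = tokens
        self.i = 0

    def peek(self, offset: int = 0) -> _Tok:
        return self.tokens[min(self.i + offset, len(self.tokens) - 1)]

    def next(self) -> _Tok:
        tok = self.tokens[self.i]
        if tok.kind != "EOF":
            self.i += 1
        return tok

    def expect(self, kind: str) -> _Tok:
        tok = self.next()
        if tok.kind != kind:
            raise ExprSyntaxError(f"expected {kind!r}, found {tok.value!r}", tok.pos)
        return tok

    # conditions ---------------------------------------------------------

    def or_expr(self) -> Condition:
        parts = [self.and_expr()]
        while self.peek().kind == "||":
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def and_expr(self) -> Condition:
        parts = [self.unary()]
        while self.peek().kind == "&&":
            self.next()
            parts.append(self.unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def unary(self) -> Condition:
        tok = self.peek()
        if tok.kind == "!":
            self.next()
            return Not(self.unary())
        if tok.kind == "(":
            self.next()
            inner = self.or_expr()
            self.expect(")")
            return inner
        return self.simple()

    def simple(self) -> Condition:
        tok = self.peek()
        if tok.kind == "exists":
            self.next()
            self.expect("(")
            ref = GtRef(str(self.expect("GTREF").value))
            self.expect(")")
            return Exists(ref)
        lhs = self.additive()
        tok = self.peek()
        if tok.kind == "is_a":
            self.next()
            if not isinstance(lhs, GtRef):
                raise ExprSyntaxError("is_a requires a $gt reference on the left", tok.pos)
            coded = self.expect("CODED")
            system, code, label = coded.value  # type: ignore[misc]
            if system != "local" or not re.fullmatch(r"gt\d+", code):
                raise ExprSyntaxError("is_a group must be a local::gtNNNN code", coded.pos)
            return IsA(lhs, code, label)
        if tok.kind in _CMP_OPS:
            self.next()
            rhs = self.additive()
            return Comparison(lhs, tok.kind, rhs)
        if tok.kind == "=":
            raise ExprSyntaxError(
                "assignment '=' is not allowed in a condition (use '==')", tok.pos)
        raise ExprSyntaxError("expected a comparison or is_a", tok.pos)

    # terms --------------------------------------------------------------

    def additive(self) -> Term:
        node = self.term()
        while self.peek().kind in ("+", "-"):
            op = self.next().kind
            node = Arith(op, node, self.term())
        return node

    def term(self) -> Term:
        tok = self.next()
        if tok.kind == "GTREF":
            return GtRef(str(tok.value))
        if tok.kind == "NUMBER":
            return Literal(tok.value)  # type: ignore[arg-type]
        if tok.kind == "STRING":
            return Literal(str(tok.value))
        if tok.kind == "BOOL":
            return Literal(bool(tok.value))
        if tok.kind == "DURATION":
            return DurationLiteral(str(tok.value))
        if tok.kind == "CODED":
            system, code, label = tok.value  # type: ignore[misc]
            return CodedLiteral(system, code, label)
        if tok.kind == "currentDateTime":
            return CurrentDateTime()
        raise ExprSyntaxError(f"expected a value, found {tok.value!r}", tok.pos)


def parse_expression(text: str) -> Union[Condition, Assignment]:
    """Parse one dialect expression into its AST.

    Returns an :class:`Assignment` when the expression has the shape
    ``$gtNNNN = <term>``, otherwise a condition.  Raises
    :class:`ExprSyntaxError` with a character position on any other input.
    """
    tokens = _tokenize(text)
    parser = _Parser(tokens)
    if tokens[0].kind == "GTREF" and tokens[1].kind == "=":
        target = GtRef(str(parser.next().value))
        parser.next()  # '='
        value = parser.additive()
        parser.expect("EOF")
        return Assignment(target, value)
    cond = parser.or_expr()
    parser.expect("EOF")
    return cond


# --- serialisation ----------------------------------------------------------

def _term_text(t: Term) -> str:
    if isinstance(t, GtRef):
        return f"${t.code}"
    if isinstance(t, Literal):
        if isinstance(t.value, bool):
            return "true" if t.value else "false"
        if isinstance(t.value, str):
            escaped = t.value.replace("\\", "\\\\").replace("'", "\\'")
            return f"'{escaped}'"
        return repr(t.value)
    if isinstance(t, CodedLiteral):
        label = f"|{t.display}|" if t.display else ""
        return f"{t.system}::{t.code}{label}"
    if isinstance(t, DurationLiteral):
        return t.iso
    if isinstance(t, CurrentDateTime):
        return "currentDateTime"
    if isinstance(t, Arith):
        return f"{_term_text(t.left)} {t.op} {_term_text(t.right)}"
    raise TypeError(f"not a term: {t!r}")


def unparse(node: Union[Condition, Assignment]) -> str:
    """Render an AST back to canonical dialect text (parse∘unparse = id)."""
    if isinstance(node, Assignment):
        return f"${node.target.code} = {_term_text(node.value)}"
    if isinstance(node, Comparison):
        return f"{_term_text(node.lhs)} {node.op} {_term_text(node.rhs)}"
    if isinstance(node, IsA):
        return f"${node.ref.code} is_a local::{node.group}|{node.label}|"
    if isinstance(node, Exists):
        return f"exists(${node.ref.code})"
    if isinstance(node, Not):
        return f"!({unparse(node.cond)})"
    if isinstance(node, And):
        return " && ".join(
            f"({unparse(p)})" if isinstance(p, Or) else unparse(p) for p in node.parts
        )
    if isinstance(node, Or):
        return " || ".join(unparse(p) for p in node.parts)
    raise TypeError(f"not an expression node: {node!r}")


def gt_refs(node) -> set[str]:
    """All gt-codes referenced anywhere in an expression (groups excluded)."""
    out: set[str] = set()

    def walk(n) -> None:
        if isinstance(n, GtRef):
            out.add(n.code)
        elif isinstance(n, Arith):
            walk(n.left), walk(n.right)
        elif isinstance(n, Comparison):
            walk(n.lhs), walk(n.rhs)
        elif isinstance(n, (IsA, Exists)):
            walk(n.ref)
        elif isinstance(n, Not):
            walk(n.cond)
        elif isinstance(n, (And, Or)):
            for p in n.parts:
                walk(p)
        elif isinstance(n, Assignment):
            walk(n.target), walk(n.value)

    walk(node)
    return out
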