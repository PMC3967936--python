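"""Boolean condition expressions over discrete component levels.

The dialect used in rule files:

* ``Name``      — level of ``Name`` is at least 1 (shorthand for ``Name:1``);
* ``Name:k``    — level is at least ``k``;
* ``Name=k``    — level is exactly ``k`` (needed for "low but not high" conditions);
* ``!``, ``&``, ``|`` and parentheses — negation, conjunction, disjunction,
  with the usual precedence (``!`` > ``&`` > ``|``).

Expressions are parsed once into a small AST and evaluated against a mapping
``name -> level``.  Parsing validates every atom against a component table
(name declared, threshold within the component's range) and reports the
offending token position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping

__all__ = ["Expr", "ExprError", "parse_expr"]


class ExprError(ValueError):
    """Malformed or ill-typed condition expression."""

    def __init__(self, message: str, text: str, pos: int):
        super().__init__(f"{message} (column {pos}): {text!r}")
        self.text = text
        self.pos = pos


@dataclass(frozen=True)
class _Atom:
    name: str
    op: str  # "ge" | "eq"
    level: int

    def eval(self, levels: Mapping[str, int]) -> bool:
        v = levels[self.name]
        return v >= self.level if self.op == "ge" else v == self.level

    def __str__(self) -> str:
        if self.op == "eq":
            return f"{self.name}={self.level}"
        return self.name if self.level == 1 else f"{self.name}:{self.level}"


@dataclass(frozen=True)
class _Not:
    child: "Expr"

    def eval(self, levels: Mapping[str, int]) -> bool:
        return not self.child.eval(levels)

    def __str__(self) -> str:
        c = str(self.child)
        return f"!({c})" if isinstance(self.child, (_And, _Or)) else f"!{c}"


@dataclass(frozen=True)
class _And:
    children: tuple

    def eval(self, levels: Mapping[str, int]) -> bool:
        return all(c.eval(levels) for c in self.children)

    def __str__(self) -> str:
        parts = [f"({c})" if isinstance(c, _Or) else str(c) for c in self.children]
        return " & ".join(parts)


@dataclass(frozen=True)
class _Or:
    children: tuple

    def eval(self, levels: Mapping[str, int]) -> bool:
        return any(c.eval(levels) for c in self.children)

    def __str__(self) -> str:
        return " | ".join(str(c) for c in self.children)


Expr = _Atom | _Not | _And | _Or

_TOKEN = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)(?:(?P<op>[:=])(?P<level>\d+))?"
    r"|(?P<punct>[()!&|]))"
)


def _tokenize(text: str):
    pos = 0
    out = []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExprError("unexpected character", text, pos)
        if m.group("name"):
            op = {"=": "eq", ":": "ge", None: "ge"}[m.group("op")]
            level = int(m.group("level")) if m.group("level") else 1
            out.append(("atom", (m.group("name"), op, level), m.start()))
        else:
            out.append((m.group("punct"), None, m.start()))
        pos = m.end()
    out.append(("end", None, len(text)))
    return out


class _Parser:
    def __init__(self, text: str, ranges: Mapping[str, int] | None):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.ranges = ranges

    def peek(self):
        return self.tokens[self.i]

    def take(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str):
        tok = self.take()
        if tok[0] != kind:
            raise ExprError(f"expected {kind!r}", self.text, tok[2])
        return tok

    def parse(self) -> Expr:
        e = self.disjunction()
        tok = self.peek()
        if tok[0] != "end":
            raise ExprError("trailing input", self.text, tok[2])
        return e

    def disjunction(self) -> Expr:
        parts = [self.conjunction()]
        while self.peek()[0] == "|":
            self.take()
            parts.append(self.conjunction())
        return parts[0] if len(parts) == 1 else _Or(tuple(parts))

    def conjunction(self) -> Expr:
        parts = [self.unary()]
        while self.peek()[0] == "&":
            self.take()
            parts.append(self.unary())
        return parts[0] if len(parts) == 1 else _And(tuple(parts))

    def unary(self) -> Expr:
        tok = self.peek()
        if tok[0] == "!":
            self.take()
            return _Not(self.unary())
        if tok[0] == "(":
            self.take()
            e = self.disjunction()
            self.expect(")")
            return e
        if tok[0] == "atom":
            self.take()
            name, op, level = tok[1]
            if self.ranges is not None:
                if name not in self.ranges:
                    raise ExprError(f"undeclared component {name!r}", self.text, tok[2])
                if not 0 <= level <= self.ranges[name]:
                    raise ExprError(
                        f"level {level} out of range 0..{self.ranges[name]} for {name!r}",
                        self.text,
                        tok[2],
                    )
            return _Atom(name, op, level)
        raise ExprError("expected atom, '!' or '('", self.text, tok[2])


def parse_expr(text: str, ranges: Mapping[str, int] | None = None) -> Expr:
    """Parse a condition expression.

    ``ranges`` maps component name to its maximum level; when given, atoms are
    validated against it.
    """
    return _Parser(text, ranges).parse()


def atoms_of(expr: Expr):
    """Yield every atom in ``expr`` (used to derive the regulatory graph)."""
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, _Atom):
            yield e
        elif isinstance(e, _Not):
            stack.append(e.child)
        else:
            stack.extend(e.children)
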