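"""Gene-protein-reaction (GPR) rules: boolean expression trees and a parser.

A GPR rule links a reaction to the genes whose products catalyse it.  ``and``
joins genes encoding subunits of one enzyme complex (all required), ``or``
joins isoenzymes (any sufficient).  Rules are arbitrary nestings of the two,
e.g. ``(G1 and G2) or G3``.

The grammar is the conventional one: ``and`` binds tighter than ``or`` and
parentheses override precedence.  Operators are case-insensitive; gene
identifiers are any run of characters that is not whitespace, a parenthesis,
or an operator keyword.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

__all__ = ["GPRRule", "Gene", "And", "Or", "parse_gpr", "GPRParseError"]


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene identifier."""

    name: str

    def genes(self) -> frozenset[str]:
        return frozenset([self.name])

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class _NaryNode:
    children: tuple["GPRRule", ...]

    _op = ""

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise GPRParseError(f"{type(self).__name__} needs >=2 operands")

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes()
        return out

    def __str__(self) -> str:
        return "(" + f" {self._op} ".join(str(c) for c in self.children) + ")"


class And(_NaryNode):
    """Enzyme complex: every child subunit is required."""

    _op = "and"


class Or(_NaryNode):
    """Isoenzymes: any child suffices; activities add."""

    _op = "or"


GPRRule = Union[Gene, And, Or]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> Iterator[str]:
    for m in _TOKEN_RE.finditer(text):
        yield m.group(0)


class _Parser:
    """Recursive descent over:  or_expr := and_expr ('or' and_expr)*
    and_expr := atom ('and' atom)* ; atom := gene | '(' or_expr ')'."""

    def __init__(self, text: str):
        self.tokens = list(_tokenize(text))
        self.pos = 0
        self.text = text

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule: {self.text!r}")
        self.pos += 1
        return tok

    def parse(self) -> GPRRule:
        node = self.or_expr()
        if self.peek() is not None:
            raise GPRParseError(
                f"trailing input {self.peek()!r} in rule: {self.text!r}"
            )
        return node

    def or_expr(self) -> GPRRule:
        operands = [self.and_expr()]
        while (tok := self.peek()) is not None and tok.lower() == "or":
            self.advance()
            operands.append(self.and_expr())
        if len(operands) == 1:
            return operands[0]
        return Or(tuple(operands))

    def and_expr(self) -> GPRRule:
        operands = [self.atom()]
        while (tok := self.peek()) is not None and tok.lower() == "and":
            self.advance()
            operands.append(self.atom())
        if len(operands) == 1:
            return operands[0]
        return And(tuple(operands))

    def atom(self) -> GPRRule:
        tok = self.advance()
        if tok == "(":
            node = self.or_expr()
            if self.peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in rule: {self.text!r}")
            self.advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in rule: {self.text!r}")
        return Gene(tok)


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string into an expression tree.

    Parameters
    ----------
    text
        Nonempty rule, e.g. ``"(G1 and G2) or G3"``.  ``and`` binds tighter
        than ``or``.

    Raises
    ------
    GPRParseError
        Empty input, unbalanced parentheses, or a misplaced operator.
    """
    if not text or not text.strip():
        raise GPRParseError("empty GPR rule")
    return _Parser(text).parse()
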