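"""Gene-protein-reaction (GPR) rule trees.

A GPR rule is a boolean expression over gene identifiers linking the genome
to a reaction: AND joins the subunits of an enzyme complex (all required),
OR joins isozymes (any one suffices).  The same tree carries two semantics
in this package:

* boolean evaluation against a set of present genes (knockout simulation);
* quantitative evaluation against expression levels, where AND takes the
  minimum over subunits and OR sums isozyme transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

__all__ = ["GPRExpr", "GPRParseError", "parse_gpr"]


class GPRParseError(ValueError):
    """Raised for malformed GPR rule strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPRExpr:
    """Node of a GPR tree.

    ``kind`` is ``"gene"`` (leaf carrying one gene id), ``"and"`` (complex)
    or ``"or"`` (isozymes).  AND/OR nodes have at least two children.
    """

    kind: str
    gene: Optional[str] = None
    children: tuple["GPRExpr", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene or self.children:
                raise ValueError("gene leaf must carry exactly one gene id")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind!r} node needs >= 2 children")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    # -- constructors ----------------------------------------------------
    @staticmethod
    def leaf(gene: str) -> "GPRExpr":
        return GPRExpr("gene", gene=gene)

    @staticmethod
    def and_(*children: "GPRExpr") -> "GPRExpr":
        return GPRExpr("and", children=tuple(children))

    @staticmethod
    def or_(*children: "GPRExpr") -> "GPRExpr":
        return GPRExpr("or", children=tuple(children))

    # -- queries ---------------------------------------------------------
    def genes(self) -> frozenset[str]:
        """All gene ids mentioned anywhere in the tree."""
        return frozenset(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:
        if self.kind == "gene":
            yield self.gene  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child._iter_genes()

    def evaluate(self, present: frozenset[str] | set[str]) -> bool:
        """Boolean evaluation: is the reaction catalyzable given ``present`` genes?"""
        if self.kind == "gene":
            return self.gene in present
        if self.kind == "and":
            return all(c.evaluate(present) for c in self.children)
        return any(c.evaluate(present) for c in self.children)

    def level(self, levels: Mapping[str, float]) -> Optional[float]:
        """Quantitative evaluation: min over AND children, sum over OR children.

        Returns None ("undefined") if any required gene is missing from
        ``levels``; callers map undefined onto a neutral fold change of 1.
        """
        if self.kind == "gene":
            value = levels.get(self.gene)  # type: ignore[arg-type]
            return None if value is None else float(value)
        child_values = [c.level(levels) for c in self.children]
        if any(v is None for v in child_values):
            return None
        if self.kind == "and":
            return min(child_values)  # type: ignore[arg-type]
        return float(sum(child_values))  # type: ignore[arg-type]

    def to_string(self) -> str:
        """Render with ``and``/``or`` keywords, parenthesizing mixed nesting."""
        if self.kind == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.kind} "
        parts = []
        for child in self.children:
            text = child.to_string()
            if child.kind != "gene" and child.kind != self.kind:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


# ---------------------------------------------------------------------------
# Parsing: a small recursive-descent parser for "a and (b or c)" style rules.
# Connectives are case-insensitive; gene ids are any other token.
# ---------------------------------------------------------------------------

_TOKEN_AND = "and"
_TOKEN_OR = "or"


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in (_TOKEN_AND, _TOKEN_OR):
            tokens.append(("op", low, i))
        elif low in ("&", "&&"):
            tokens.append(("op", _TOKEN_AND, i))
        elif low in ("|", "||"):
            tokens.append(("op", _TOKEN_OR, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", len(self.text))
        self.pos += 1
        return tok

    # grammar: expr := term ('or' term)* ; term := atom ('and' atom)* ;
    # atom := gene | '(' expr ')'.  OR binds loosest, matching the usual
    # COBRA convention.
    def parse(self) -> GPRExpr:
        expr = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def expr(self) -> GPRExpr:
        parts = [self.term()]
        while (tok := self.peek()) is not None and tok[:2] == ("op", _TOKEN_OR):
            self.next()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else _flatten("or", parts)

    def term(self) -> GPRExpr:
        parts = [self.atom()]
        while (tok := self.peek()) is not None and tok[:2] == ("op", _TOKEN_AND):
            self.next()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else _flatten("and", parts)

    def atom(self) -> GPRExpr:
        tok = self.next()
        kind, value, pos = tok
        if kind == "gene":
            return GPRExpr.leaf(value)
        if kind == "paren" and value == "(":
            inner = self.expr()
            closing = self.peek()
            if closing is None or closing[:2] != ("paren", ")"):
                raise GPRParseError("unbalanced parentheses", pos)
            self.next()
            return inner
        raise GPRParseError(f"empty operand or misplaced {value!r}", pos)


def _flatten(kind: str, parts: list[GPRExpr]) -> GPRExpr:
    children: list[GPRExpr] = []
    for part in parts:
        if part.kind == kind:
            children.extend(part.children)
        else:
            children.append(part)
    return GPRExpr(kind, children=tuple(children))


def parse_gpr(text: str) -> GPRExpr:
    """Parse a GPR rule string into a :class:`GPRExpr` tree.

    Accepts case-insensitive ``and``/``or`` (also ``&``/``|``) with optional
    parentheses.  A single gene id parses to a leaf.  Raises
    :class:`GPRParseError` with the offending position on malformed input.
    """
    if not text or not text.strip():
        raise GPRParseError("empty GPR rule", 0)
    return _Parser(text).parse()
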