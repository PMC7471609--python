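"""Gene-protein-reaction (GPR) boolean expressions.

A GPR is a finite AND/OR tree over gene identifiers.  A reaction is
catalytically available under a gene-deletion genotype iff its GPR
evaluates true with deleted genes set false and all other genes true.
An empty GPR (no gene association) always evaluates true: such
reactions cannot be disabled by removing genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Union

from .errors import GPRParseError

__all__ = ["GPRExpression", "GeneRef", "BoolOp", "parse_gpr", "evaluate_gpr"]


@dataclass(frozen=True)
class GeneRef:
    gene: str

    def evaluate(self, deleted: FrozenSet[str]) -> bool:
        return self.gene not in deleted

    def genes(self) -> FrozenSet[str]:
        return frozenset({self.gene})

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple  # of GeneRef | BoolOp

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise ValueError(f"bad boolean operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("boolean node needs at least two children")

    def evaluate(self, deleted: FrozenSet[str]) -> bool:
        results = (c.evaluate(deleted) for c in self.children)
        return all(results) if self.op == "and" else any(results)

    def genes(self) -> FrozenSet[str]:
        out: FrozenSet[str] = frozenset()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, BoolOp) and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


Node = Union[GeneRef, BoolOp]


@dataclass(frozen=True)
class GPRExpression:
    """Boolean availability rule for one reaction; ``root=None`` means no association."""

    root: Node | None = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> FrozenSet[str]:
        return frozenset() if self.root is None else self.root.genes()

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(deleted_genes))

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()


_TOKEN = re.compile(r"\s*(\(|\)|[Aa][Nn][Dd]\b|[Oo][Rr]\b|[&|]{1,2}|[^\s()&|]+)")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            break
        tok = m.group(1)
        at = m.start(1)
        low = tok.lower()
        if tok == "(":
            tokens.append(("lparen", tok, at))
        elif tok == ")":
            tokens.append(("rparen", tok, at))
        elif low == "and" or tok in ("&", "&&"):
            tokens.append(("and", tok, at))
        elif low == "or" or tok in ("|", "||"):
            tokens.append(("or", tok, at))
        else:
            tokens.append(("gene", tok, at))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GPRExpression:
    """Parse a GPR string such as ``"(g1 and g2) or g3"``.

    ``and`` binds tighter than ``or``; ``&``/``|`` are accepted synonyms.
    Raises :class:`GPRParseError` with the character position on malformed
    input.  An empty or whitespace-only string yields the empty GPR.
    """
    if text is None or not text.strip():
        return GPRExpression()
    tokens = _tokenize(text)
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else ("eof", "", len(text))

    def parse_or() -> Node:
        nonlocal idx
        children = [parse_and()]
        while peek()[0] == "or":
            idx += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else BoolOp("or", tuple(children))

    def parse_and() -> Node:
        nonlocal idx
        children = [parse_atom()]
        while peek()[0] == "and":
            idx += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else BoolOp("and", tuple(children))

    def parse_atom() -> Node:
        nonlocal idx
        kind, tok, at = peek()
        if kind == "lparen":
            idx += 1
            node = parse_or()
            kind, tok, at = peek()
            if kind != "rparen":
                raise GPRParseError(f"expected ')' at position {at}", at)
            idx += 1
            return node
        if kind == "gene":
            idx += 1
            return GeneRef(tok)
        raise GPRParseError(f"unexpected token {tok!r} at position {at}", at)

    root = parse_or()
    kind, tok, at = peek()
    if kind != "eof":
        raise GPRParseError(f"trailing token {tok!r} at position {at}", at)
    return GPRExpression(root)


def evaluate_gpr(gpr: GPRExpression, deleted_genes: Iterable[str] = ()) -> bool:
    """True iff the reaction remains active when ``deleted_genes`` are knocked out."""
    return gpr.evaluate(deleted_genes)
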