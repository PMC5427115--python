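"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers: ``and`` joins subunits
of an enzymatic complex, ``or`` joins isozymes/paralogs.  Besides gating a
reaction on gene presence, the tree structure itself matters downstream:
target filtering discards any reaction whose rule involves more than one
gene, and expression integration maps gene-level RPKM onto reactions with
min over ``and`` and max over ``or``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional


class GPRParseError(ValueError):
    """Raised when a rule string cannot be parsed."""


@dataclass(frozen=True)
class GPRNode:
    """A node of a parsed GPR expression tree.

    ``op`` is one of ``"and"``, ``"or"``, ``"gene"`` or ``"empty"``.
    Leaf nodes carry ``gene``; inner nodes carry ``children``.
    """

    op: str
    gene: Optional[str] = None
    children: tuple["GPRNode", ...] = field(default_factory=tuple)

    # -- predicates -------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    @property
    def genes(self) -> frozenset[str]:
        if self.op == "empty":
            return frozenset()
        if self.op == "gene":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes
        return frozenset(out)

    @property
    def has_and(self) -> bool:
        if self.op == "and":
            return True
        return any(c.has_and for c in self.children)

    @property
    def has_or(self) -> bool:
        if self.op == "or":
            return True
        return any(c.has_or for c in self.children)

    # -- evaluation -------------------------------------------------------
    def evaluate(self, values: Mapping[str, float]) -> Optional[float]:
        """Map gene-level values onto the rule: min over AND, max over OR.

        A gene missing from ``values`` is an absent leaf: it is ignored
        inside an OR (the max runs over present genes) but makes an AND
        undeterminable, returning None.  An all-absent OR also returns None.
        """
        if self.op == "empty":
            return None
        if self.op == "gene":
            return values.get(self.gene)  # type: ignore[arg-type]
        parts = [c.evaluate(values) for c in self.children]
        if self.op == "and":
            if any(p is None for p in parts):
                return None
            return min(parts)  # type: ignore[type-var]
        present = [p for p in parts if p is not None]
        return max(present) if present else None

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        out = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            out.append(s)
        return sep.join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_GPR = GPRNode(op="empty")


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    cur = ""
    for ch in text:
        if ch in "()":
            if cur:
                tokens.append(cur)
                cur = ""
            tokens.append(ch)
        elif ch.isspace():
            if cur:
                tokens.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        tokens.append(cur)
    return tokens


def parse_gpr(rule_text: str) -> GPRNode:
    """Parse a rule like ``"g1 or (g2 and g3)"`` into an expression tree.

    ``and``/``or`` are case-insensitive; an empty or whitespace-only string
    yields the empty rule.  Unbalanced parentheses or dangling operators
    raise :class:`GPRParseError`.
    """
    tokens = _tokenize(rule_text)
    if not tokens:
        return EMPTY_GPR
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(parse_and())
        if len(parts) == 1:
            return parts[0]
        return GPRNode(op="or", children=tuple(parts))

    def parse_and() -> GPRNode:
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(parse_atom())
        if len(parts) == 1:
            return parts[0]
        return GPRNode(op="and", children=tuple(parts))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule: {rule_text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in {rule_text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in {rule_text!r}")
        return GPRNode(op="gene", gene=take())

    node = parse_or()
    if pos != len(tokens):
        raise GPRParseError(
            f"trailing tokens {tokens[pos:]!r} in {rule_text!r}"
        )
    return node
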