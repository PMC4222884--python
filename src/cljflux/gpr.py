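"""Gene-protein-reaction (GPR) boolean rules.

A GPR is a boolean tree whose leaves are gene identifiers and whose
internal nodes are AND (all subunits required, e.g. an enzyme complex)
or OR (isozymes).  A reaction with an empty GPR has no gene association
and can never be inactivated by a gene knockout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["GPR", "parse_gpr"]


@dataclass(frozen=True)
class GPR:
    """Boolean gene-association tree.

    ``op`` is one of ``"empty"``, ``"gene"``, ``"and"``, ``"or"``.
    For ``"gene"`` nodes ``gene`` holds the identifier; for ``"and"``/
    ``"or"`` nodes ``children`` holds at least two subtrees.
    """

    op: str = "empty"
    gene: str | None = None
    children: tuple["GPR", ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.op not in ("empty", "gene", "and", "or"):
            raise ValueError(f"unknown GPR node type: {self.op!r}")
        if self.op == "gene" and not self.gene:
            raise ValueError("gene node requires a gene id")
        if self.op in ("and", "or") and len(self.children) < 2:
            raise ValueError(f"{self.op!r} node requires >= 2 children")

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> set[str]:
        """All gene ids appearing in the tree."""
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """True iff the reaction remains catalyzable after the knockouts.

        A leaf is active iff its gene is not knocked out; AND requires all
        children active, OR any; the empty tree is always active.
        """
        ko = set(knocked_out)
        return self._eval(ko)

    def _eval(self, ko: set[str]) -> bool:
        if self.op == "empty":
            return True
        if self.op == "gene":
            return self.gene not in ko
        if self.op == "and":
            return all(c._eval(ko) for c in self.children)
        return any(c._eval(ko) for c in self.children)

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesize mixed nesting so the string round-trips
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(rule: str) -> GPR:
    """Parse a COBRA-style rule string like ``"gA and (gB or gC)"``.

    ``and``/``or`` are case-insensitive; an empty or whitespace-only
    string yields the empty GPR.
    """
    tokens = _tokenize(rule)
    if not tokens:
        return GPR()
    expr, rest = _parse_or(tokens)
    if rest:
        raise ValueError(f"trailing tokens in GPR rule: {rest!r}")
    return expr


def _tokenize(rule: str) -> list[str]:
    out: list[str] = []
    cur = ""
    for ch in rule:
        if ch in "()":
            if cur:
                out.append(cur)
                cur = ""
            out.append(ch)
        elif ch.isspace():
            if cur:
                out.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        out.append(cur)
    return out


def _parse_or(tokens: list[str]):
    left, rest = _parse_and(tokens)
    children = [left]
    while rest and rest[0].lower() == "or":
        nxt, rest = _parse_and(rest[1:])
        children.append(nxt)
    if len(children) == 1:
        return left, rest
    return GPR(op="or", children=tuple(children)), rest


def _parse_and(tokens: list[str]):
    left, rest = _parse_atom(tokens)
    children = [left]
    while rest and rest[0].lower() == "and":
        nxt, rest = _parse_atom(rest[1:])
        children.append(nxt)
    if len(children) == 1:
        return left, rest
    return GPR(op="and", children=tuple(children)), rest


def _parse_atom(tokens: list[str]):
    if not tokens:
        raise ValueError("unexpected end of GPR rule")
    tok = tokens[0]
    if tok == "(":
        expr, rest = _parse_or(tokens[1:])
        if not rest or rest[0] != ")":
            raise ValueError("unbalanced parenthesis in GPR rule")
        return expr, rest[1:]
    if tok == ")" or tok.lower() in ("and", "or"):
        raise ValueError(f"unexpected token {tok!r} in GPR rule")
    return GPR(op="gene", gene=tok), tokens[1:]
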