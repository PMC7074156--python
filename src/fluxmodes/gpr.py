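"""Gene-protein-reaction (GPR) boolean trees.

A GPR rule states which combinations of genes enable a reaction:
``AND`` joins subunits of an enzyme complex (all required), ``OR`` joins
isozymes (any one suffices).  Trees are parsed either from FBC
gene-product associations in SBML or from legacy textual rules such as
``"(b0001 and b0002) or b0003"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

GprKind = Literal["GENE", "AND", "OR"]


@dataclass
class GprNode:
    """One node of a GPR boolean tree.

    ``GENE`` nodes are leaves carrying ``gene_id``; ``AND``/``OR`` nodes
    carry one or more ``children``.
    """

    kind: GprKind
    gene_id: Optional[str] = None
    children: list["GprNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "GENE":
            if not self.gene_id:
                raise ValueError("GENE node requires a gene_id")
            if self.children:
                raise ValueError("GENE nodes are leaves")
        else:
            if not self.children:
                raise ValueError(f"{self.kind} node requires >=1 child")

    def genes(self) -> Iterator[str]:
        """Yield every gene id in the tree (with repeats, left-to-right)."""
        if self.kind == "GENE":
            yield self.gene_id  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child.genes()

    def to_string(self) -> str:
        """Render as a parenthesized and/or expression."""
        if self.kind == "GENE":
            return self.gene_id  # type: ignore[return-value]
        op = " and " if self.kind == "AND" else " or "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.kind != "GENE":
                s = f"({s})"
            parts.append(s)
        return op.join(parts)

    def normalized(self) -> "GprNode":
        """Canonical form: same-kind nodes flattened, children sorted.

        Two trees that differ only in the associativity/ordering of AND/OR
        have equal normalized forms, which is the equality notion used for
        round-trip checks.
        """
        if self.kind == "GENE":
            return GprNode("GENE", gene_id=self.gene_id)
        flat: list[GprNode] = []
        for child in self.children:
            c = child.normalized()
            if c.kind == self.kind:
                flat.extend(c.children)
            else:
                flat.append(c)
        if len(flat) == 1:
            return flat[0]
        flat.sort(key=lambda n: n.to_string())
        return GprNode(self.kind, children=flat)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr_string(rule: str) -> Optional[GprNode]:
    """Parse a textual GPR rule into a tree.

    Follows the usual COBRA convention: ``and`` binds tighter than ``or``,
    parentheses override, keywords are case-insensitive (``&``/``|`` also
    accepted).  Returns None for an empty rule.
    """
    tokens = _TOKEN_RE.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok: Optional[str], name: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == name or (name == "and" and tok == "&") or (
            name == "or" and tok == "|"
        )

    def parse_atom() -> GprNode:
        tok = peek()
        if tok is None:
            raise ValueError(f"unexpected end of GPR rule: {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR rule: {rule!r}")
            take()
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise ValueError(f"unexpected token {tok!r} in GPR rule: {rule!r}")
        return GprNode("GENE", gene_id=take())

    def parse_and() -> GprNode:
        terms = [parse_atom()]
        while is_op(peek(), "and"):
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else GprNode("AND", children=terms)

    def parse_or() -> GprNode:
        terms = [parse_and()]
        while is_op(peek(), "or"):
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprNode("OR", children=terms)

    node = parse_or()
    if peek() is not None:
        raise ValueError(f"trailing tokens in GPR rule: {rule!r}")
    return node
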