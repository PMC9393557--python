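"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers that states which gene
complements can catalyse a reaction, e.g. ``b0001 and (b0002 or b0003)``.
An empty rule means the reaction needs no gene product (spontaneous
reactions, exchanges, biomass) and is treated as always active.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Set, Union

__all__ = ["Gpr", "GprParseError"]

# Node representation: None (empty), str (gene leaf), or ("and"|"or", tuple of nodes)
Node = Union[None, str, tuple]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_GENE_FORBIDDEN = {"and", "or", "AND", "OR", "And", "Or"}


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the offending string."""

    def __init__(self, rule: str, reason: str):
        self.rule = rule
        super().__init__(f"cannot parse GPR rule {rule!r}: {reason}")


@dataclass(frozen=True)
class Gpr:
    """A parsed GPR rule.

    Construct with :meth:`parse` or :meth:`empty`. Immutable; all
    manipulation returns new instances.
    """

    node: Node = None

    # -- construction ------------------------------------------------------
    @classmethod
    def empty(cls) -> "Gpr":
        return cls(None)

    @classmethod
    def parse(cls, rule: str) -> "Gpr":
        rule = (rule or "").strip()
        if not rule:
            return cls.empty()
        tokens = _TOKEN.findall(rule)
        node, pos = _parse_or(tokens, 0, rule)
        if pos != len(tokens):
            raise GprParseError(rule, f"unexpected token {tokens[pos]!r}")
        return cls(node)

    # -- queries -----------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.node is None

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        _collect_genes(self.node, out)
        return out

    def evaluate(self, present: Iterable[str]) -> bool:
        """Standard boolean semantics; an empty rule evaluates True."""
        present = set(present)
        return _eval(self.node, present)

    def substitute(self, mapping: Mapping[str, Optional[str]]) -> "Gpr":
        """Rename gene leaves; genes mapping to None become False and the
        tree is simplified (False is dropped from OR branches, fatal to AND).

        If the whole expression simplifies to False the returned rule has
        ``is_false`` set; callers typically drop the reaction in that case.
        """
        if self.node is None:
            return Gpr.empty()
        node = _substitute(self.node, mapping)
        if node is _FALSE:
            return _FALSE_GPR
        return Gpr(node)

    @property
    def is_false(self) -> bool:
        return self is _FALSE_GPR or self.node is _FALSE

    # -- serialisation -----------------------------------------------------
    def to_string(self) -> str:
        if self.node is None:
            return ""
        return _unparse(self.node, top=True)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


class _FalseSentinel:
    __slots__ = ()

    def __repr__(self):
        return "<GPR false>"


_FALSE = _FalseSentinel()
_FALSE_GPR = Gpr(_FALSE)


# -- parsing helpers (precedence: OR < AND; parentheses) -------------------

def _parse_or(tokens, pos, rule):
    node, pos = _parse_and(tokens, pos, rule)
    parts = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1, rule)
        parts.append(nxt)
    if len(parts) == 1:
        return parts[0], pos
    return ("or", tuple(parts)), pos


def _parse_and(tokens, pos, rule):
    node, pos = _parse_atom(tokens, pos, rule)
    parts = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1, rule)
        parts.append(nxt)
    if len(parts) == 1:
        return parts[0], pos
    return ("and", tuple(parts)), pos


def _parse_atom(tokens, pos, rule):
    if pos >= len(tokens):
        raise GprParseError(rule, "unexpected end of rule")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1, rule)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GprParseError(rule, "unbalanced parenthesis")
        return node, pos + 1
    if tok == ")" or tok in _GENE_FORBIDDEN:
        raise GprParseError(rule, f"unexpected token {tok!r}")
    return tok, pos + 1


def _collect_genes(node: Node, out: Set[str]) -> None:
    if node is None or node is _FALSE:
        return
    if isinstance(node, str):
        out.add(node)
        return
    for child in node[1]:
        _collect_genes(child, out)


def _eval(node: Node, present: Set[str]) -> bool:
    if node is None:
        return True
    if node is _FALSE:
        return False
    if isinstance(node, str):
        return node in present
    op, children = node
    if op == "and":
        return all(_eval(c, present) for c in children)
    return any(_eval(c, present) for c in children)


def _substitute(node: Node, mapping: Mapping[str, Optional[str]]):
    if isinstance(node, str):
        new = mapping.get(node, node)
        return _FALSE if new is None else new
    op, children = node
    subbed = [_substitute(c, mapping) for c in children]
    if op == "and":
        if any(c is _FALSE for c in subbed):
            return _FALSE
        kept = subbed
    else:  # or: drop false branches
        kept = [c for c in subbed if c is not _FALSE]
        if not kept:
            return _FALSE
    if len(kept) == 1:
        return kept[0]
    return (op, tuple(kept))


def _unparse(node: Node, top: bool = False) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    inner = f" {op} ".join(
        _unparse(c) if isinstance(c, str) else f"({_unparse(c)})" for c in children
    )
    return inner
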