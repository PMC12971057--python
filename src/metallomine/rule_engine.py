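"""Detection-rule language: parsing, cutoff filtering and evaluation.

The rule language is the small boolean DSL used by cluster-detection rules:
identifiers name profile HMMs, ``and``/``or``/``not`` combine them
(precedence ``not`` > ``and`` > ``or``, binary operators left-associative),
and ``cds(...)`` restricts its child expression to a single gene — the child
must hold using only one gene's hits, which is how "a gene containing at
least one condensation and one adenylation domain" is expressed as
``cds(Condensation and AMP-binding)``.

Evaluation semantics: an identifier outside ``cds()`` is true iff any gene
in the region carries a significant hit to that profile; inside ``cds()``
the child is true iff some single gene satisfies it with its own hits.
Negative constraints (``not X``) are therefore region-scoped — a veto gene
anywhere in the region suppresses the guarded branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .io_formats import DomainHit, ProfileRegistry

__all__ = [
    "RuleExpr",
    "Identifier",
    "Not",
    "And",
    "Or",
    "CdsScope",
    "RuleVerdict",
    "RuleSyntaxError",
    "parse_rule",
    "parse_rule_file",
    "pretty",
    "apply_cutoffs",
    "evaluate",
    "list_identifiers",
    "default_rule_text",
    "default_rule",
]


class RuleSyntaxError(ValueError):
    """Syntax error in a rule string, carrying the offending position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


@dataclass(frozen=True)
class RuleExpr:
    """Base class for rule AST nodes."""


@dataclass(frozen=True)
class Identifier(RuleExpr):
    name: str


@dataclass(frozen=True)
class Not(RuleExpr):
    child: RuleExpr


@dataclass(frozen=True)
class And(RuleExpr):
    left: RuleExpr
    right: RuleExpr


@dataclass(frozen=True)
class Or(RuleExpr):
    left: RuleExpr
    right: RuleExpr


@dataclass(frozen=True)
class CdsScope(RuleExpr):
    child: RuleExpr


@dataclass(frozen=True)
class RuleVerdict:
    satisfied: bool
    #: profile names that evaluated true and occur positively (outside any
    #: ``not``) on a satisfied path; empty when not satisfied.
    triggering_identifiers: frozenset[str]


# ---------------------------------------------------------------------------
# Tokenizer / parser

_KEYWORDS = {"and", "or", "not", "cds"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Return (kind, value, pos) tokens. Identifier chars: letters, digits,
    underscore, hyphen."""
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c == "#":  # comment to end of line
            while i < n and text[i] != "\n":
                i += 1
            continue
        if c == "(":
            tokens.append(("lparen", "(", i))
            i += 1
            continue
        if c == ")":
            tokens.append(("rparen", ")", i))
            i += 1
            continue
        if c.isalnum() or c in "_-":
            j = i
            while j < n and (text[j].isalnum() or text[j] in "_-"):
                j += 1
            word = text[i:j]
            kind = word if word in _KEYWORDS else "ident"
            tokens.append((kind, word, i))
            i = j
            continue
        raise RuleSyntaxError(f"unknown token {c!r}", i)
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], length: int):
        self.tokens = tokens
        self.i = 0
        self.length = length

    def _peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, str, int]:
        tok = self._peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", self.length)
        self.i += 1
        return tok

    def _expect(self, kind: str) -> tuple[str, str, int]:
        tok = self._next()
        if tok[0] != kind:
            raise RuleSyntaxError(
                f"expected {kind!r}, found {tok[1]!r}", tok[2]
            )
        return tok

    def parse(self) -> RuleExpr:
        expr = self._or(in_cds=False)
        tok = self._peek()
        if tok is not None:
            raise RuleSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return expr

    def _or(self, in_cds: bool) -> RuleExpr:
        node = self._and(in_cds)
        while (tok := self._peek()) is not None and tok[0] == "or":
            self._next()
            node = Or(node, self._and(in_cds))
        return node

    def _and(self, in_cds: bool) -> RuleExpr:
        node = self._factor(in_cds)
        while (tok := self._peek()) is not None and tok[0] == "and":
            self._next()
            node = And(node, self._factor(in_cds))
        return node

    def _factor(self, in_cds: bool) -> RuleExpr:
        tok = self._next()
        kind, value, pos = tok
        if kind == "not":
            return Not(self._factor(in_cds))
        if kind == "cds":
            if in_cds:
                raise RuleSyntaxError("cds() may not be nested inside cds()", pos)
            self._expect("lparen")
            child = self._or(in_cds=True)
            self._expect("rparen")
            return CdsScope(child)
        if kind == "lparen":
            child = self._or(in_cds)
            self._expect("rparen")
            return child
        if kind == "ident":
            return Identifier(value)
        raise RuleSyntaxError(f"unexpected {value!r}", pos)


def parse_rule(text: str) -> RuleExpr:
    """Parse a rule string into its AST.

    Raises :class:`RuleSyntaxError` (with character position) on unbalanced
    parentheses, nested ``cds()``, empty input or unknown tokens.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise RuleSyntaxError("empty expression", 0)
    return _Parser(tokens, len(text)).parse()


def parse_rule_file(path) -> RuleExpr:
    """Parse a rule from a plain-text file (``#`` comments allowed)."""
    with open(path) as fh:
        return parse_rule(fh.read())


def pretty(expr: RuleExpr) -> str:
    """Render an AST back to rule text; ``parse(pretty(parse(s))) == parse(s)``."""
    if isinstance(expr, Identifier):
        return expr.name
    if isinstance(expr, Not):
        return f"not {_paren(expr.child)}"
    if isinstance(expr, And):
        return f"{_paren(expr.left)} and {_paren(expr.right)}"
    if isinstance(expr, Or):
        return f"{_paren(expr.left)} or {_paren(expr.right)}"
    if isinstance(expr, CdsScope):
        return f"cds({pretty(expr.child)})"
    raise TypeError(f"not a RuleExpr: {expr!r}")


def _paren(expr: RuleExpr) -> str:
    if isinstance(expr, (Identifier, CdsScope)):
        return pretty(expr)
    return f"({pretty(expr)})"


# ---------------------------------------------------------------------------
# Cutoff filtering


def apply_cutoffs(
    hits: list[DomainHit], registry: ProfileRegistry
) -> dict[str, set[str]]:
    """Filter hits by per-profile bitscore cutoffs; group survivors by gene.

    A hit survives iff ``bitscore >= cutoff`` for its profile (the boundary
    is inclusive). Returns ``gene_id -> set of significant profile names``.
    A hit whose profile is absent from the registry is an error, not a
    silent drop.
    """
    out: dict[str, set[str]] = {}
    for h in hits:
        if h.profile not in registry:
            raise KeyError(f"profile not in registry: {h.profile}")
        if h.bitscore >= registry.cutoff(h.profile):
            out.setdefault(h.gene_id, set()).add(h.profile)
    return out


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(
    rule: RuleExpr, region_hits: Mapping[str, set[str]]
) -> RuleVerdict:
    """Evaluate a rule against a region's significant hits.

    ``region_hits`` maps gene_id to that gene's significant profile names
    (already cutoff-filtered). See the module docstring for scoping
    semantics.
    """
    region_profiles: set[str] = set()
    for profs in region_hits.values():
        region_profiles |= profs

    def walk(node: RuleExpr, gene_profiles: set[str] | None) -> tuple[bool, frozenset[str]]:
        scope = region_profiles if gene_profiles is None else gene_profiles
        if isinstance(node, Identifier):
            v = node.name in scope
            return v, frozenset({node.name}) if v else frozenset()
        if isinstance(node, Not):
            v, _ = walk(node.child, gene_profiles)
            return (not v), frozenset()
        if isinstance(node, And):
            lv, lt = walk(node.left, gene_profiles)
            rv, rt = walk(node.right, gene_profiles)
            v = lv and rv
            return v, (lt | rt) if v else frozenset()
        if isinstance(node, Or):
            lv, lt = walk(node.left, gene_profiles)
            rv, rt = walk(node.right, gene_profiles)
            v = lv or rv
            trig = (lt if lv else frozenset()) | (rt if rv else frozenset())
            return v, trig
        if isinstance(node, CdsScope):
            trig: frozenset[str] = frozenset()
            sat = False
            for gene_id in sorted(region_hits):
                gv, gt = walk(node.child, region_hits[gene_id])
                if gv:
                    sat = True
                    trig |= gt
            return sat, trig
        raise TypeError(f"not a RuleExpr: {node!r}")

    satisfied, trig = walk(rule, None)
    return RuleVerdict(satisfied, trig if satisfied else frozenset())


def list_identifiers(rule: RuleExpr) -> tuple[set[str], set[str]]:
    """Partition identifiers by polarity of occurrence.

    Returns ``(positive, negated)``: names occurring under an even number of
    ``not`` operators go in ``positive``, odd in ``negated``. A name may
    appear in both sets if it occurs with both polarities.
    """
    positive: set[str] = set()
    negated: set[str] = set()

    def walk(node: RuleExpr, under_not: bool) -> None:
        if isinstance(node, Identifier):
            (negated if under_not else positive).add(node.name)
        elif isinstance(node, Not):
            walk(node.child, not under_not)
        elif isinstance(node, (And, Or)):
            walk(node.left, under_not)
            walk(node.right, under_not)
        elif isinstance(node, CdsScope):
            walk(node.child, under_not)
        else:
            raise TypeError(f"not a RuleExpr: {node!r}")

    walk(rule, False)
    return positive, negated


# ---------------------------------------------------------------------------
# Bundled canonical rule


def default_rule_text() -> str:
    """Text of the bundled NRP-metallophore detection rule."""
    return (
        resources.files("metallomine.data")
        .joinpath("nrp_metallophore.rule")
        .read_text()
    )


def default_rule() -> RuleExpr:
    """Parsed bundled NRP-metallophore detection rule."""
    return parse_rule(default_rule_text())
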