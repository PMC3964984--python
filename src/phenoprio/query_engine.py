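"""Boolean query language over gene annotations, with weighted multi-query
ranking.

Queries combine annotation atoms like ``GO("nervous system development")``
or ``PHENO("abnormal cardiac development")`` with ``and``/``or``/``not``
(precedence: not > and > or; grouping with square brackets). Several
queries can be evaluated together, each with a positive weight; a gene's
score is the sum of the weights of the queries it satisfies, so with unit
weights the ranking is simply "number of conditions met".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_store import AnnotationStore
from .errors import (
    AmbiguousLabelError,
    AtomResolutionError,
    LabelNotFoundError,
    QueryParseError,
)
from .ontology import Ontology

ATOM_KINDS = ("SPECIES", "GO", "PHENO", "PATHWAY", "IP", "OMIM", "REGION")

#: Atom kind → annotation namespaces it searches (SPECIES/REGION are special).
KIND_NAMESPACES: dict[str, tuple[str, ...]] = {
    "GO": ("GO",),
    "PHENO": ("PHENO_A", "PHENO_B"),
    "PATHWAY": ("PATHWAY",),
    "IP": ("MOTIF",),
    "OMIM": ("DISEASE",),
}


# -- AST --------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    kind: str
    label: str

    def __post_init__(self):
        if self.kind not in ATOM_KINDS:
            raise QueryParseError(f"unknown atom kind {self.kind!r}")
        if not self.label:
            raise QueryParseError("empty atom label")


@dataclass(frozen=True)
class And:
    children: tuple

    def __post_init__(self):
        if len(self.children) < 2:
            raise QueryParseError("'and' needs at least two operands")


@dataclass(frozen=True)
class Or:
    children: tuple

    def __post_init__(self):
        if len(self.children) < 2:
            raise QueryParseError("'or' needs at least two operands")


@dataclass(frozen=True)
class Not:
    child: object


QueryAST = Atom | And | Or | Not


# -- parser -----------------------------------------------------------------------

_QUOTES = '"“”‘’'
_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<atom>[A-Za-z_]+\s*\(\s*[{q}](?P<label>[^{q}]*)[{q}]\s*\))
      | (?P<word>[A-Za-z_]+)
      | (?P<lbr>[\[\(])
      | (?P<rbr>[\]\)])
    )""".format(q=_QUOTES),
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise QueryParseError(f"unexpected character {text[pos]!r}", pos)
        if m.group("atom"):
            kind = m.group("atom").split("(")[0].strip().upper()
            tokens.append(("ATOM", f"{kind}\x00{m.group('label')}", pos))
        elif m.group("word"):
            w = m.group("word").lower()
            if w not in ("and", "or", "not"):
                raise QueryParseError(
                    f"expected and/or/not or an atom, got {m.group('word')!r}", pos
                )
            tokens.append((w.upper(), w, pos))
        elif m.group("lbr"):
            tokens.append(("LBR", m.group("lbr"), pos))
        else:
            tokens.append(("RBR", m.group("rbr"), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, text):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self) -> QueryAST:
        node = self.expr()
        kind, _, pos = self.peek()
        if kind is not None:
            raise QueryParseError("trailing input after query", pos)
        return node

    def expr(self) -> QueryAST:  # or-level
        parts = [self.term()]
        while self.peek()[0] == "OR":
            self.next()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def term(self) -> QueryAST:  # and-level; `X not Y` sugars to X and Not(Y)
        parts = [self.factor()]
        while True:
            kind = self.peek()[0]
            if kind == "AND":
                self.next()
                parts.append(self.factor())
            elif kind == "NOT":
                self.next()
                parts.append(Not(self.factor()))
            else:
                break
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def factor(self) -> QueryAST:
        kind, value, pos = self.peek()
        if kind == "NOT":
            self.next()
            return Not(self.factor())
        if kind == "LBR":
            self.next()
            node = self.expr()
            k2, _, p2 = self.next()
            if k2 != "RBR":
                raise QueryParseError("unbalanced bracket", pos)
            return node
        if kind == "ATOM":
            self.next()
            atom_kind, label = value.split("\x00", 1)
            if atom_kind not in ATOM_KINDS:
                raise QueryParseError(f"unknown atom kind {atom_kind!r}", pos)
            if not label.strip():
                raise QueryParseError("empty atom label", pos)
            return Atom(atom_kind, label.strip())
        raise QueryParseError("expected an atom, 'not' or a bracketed group", pos)


def parse_query(text: str) -> QueryAST:
    """Parse query text into an AST (see module docstring for the grammar)."""
    if not text or not text.strip():
        raise QueryParseError("empty query")
    if text.count('"') % 2 or sum(text.count(q) for q in "“”") % 2:
        raise QueryParseError("unbalanced quotes")
    return _Parser(_tokenize(text), text).parse()


def serialize_query(ast: QueryAST) -> str:
    """Render an AST back to query text; ``parse_query`` round-trips it."""
    if isinstance(ast, Atom):
        return f'{ast.kind}("{ast.label}")'
    if isinstance(ast, Not):
        return f"not [{serialize_query(ast.child)}]"
    op = " and " if isinstance(ast, And) else " or "
    return "[" + op.join(serialize_query(c) for c in ast.children) + "]"


# -- evaluation -------------------------------------------------------------------

_REGION_RE = re.compile(r"^\s*(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)\s*$")


@dataclass
class QueryContext:
    """Everything atom evaluation needs: the store and, per namespace, the
    ontology whose terms that namespace's annotations use."""

    store: AnnotationStore
    ontologies: Mapping[str, Ontology]

    def resolve_atom(self, atom: Atom) -> set[str]:
        if atom.kind == "SPECIES":
            if atom.label not in self.store.species:
                raise AtomResolutionError(
                    f'SPECIES("{atom.label}"): unknown species; have '
                    + ", ".join(sorted(self.store.species))
                )
            return self.store.genes_of_species(atom.label)
        if atom.kind == "REGION":
            m = _REGION_RE.match(atom.label)
            if not m:
                raise AtomResolutionError(
                    f'REGION("{atom.label}"): expected "chrom:start-end"'
                )
            return self.store.genes_in_region(
                m.group("chrom"), int(m.group("start")), int(m.group("end"))
            )

        hits: list[tuple[str, str]] = []  # (term, namespace)
        for ns in KIND_NAMESPACES[atom.kind]:
            ont = self.ontologies.get(ns)
            if ont is None:
                continue
            try:
                hits.append((ont.resolve(atom.label), ns))
            except LabelNotFoundError:
                continue
        if not hits:
            raise AtomResolutionError(
                f'{atom.kind}("{atom.label}"): label not found in namespaces '
                + "/".join(KIND_NAMESPACES[atom.kind])
            )
        if len(hits) > 1:
            raise AmbiguousLabelError(atom.label, [t for t, _ in hits])
        term, ns = hits[0]
        return self.store.genes_with_term(self.ontologies[ns], term, ns, propagate=True)


def evaluate(ast: QueryAST, ctx: QueryContext) -> set[str]:
    """Pure set semantics: and=∩, or=∪, not=complement in the store's whole
    gene universe (all species; scope with ``SPECIES(...)`` explicitly)."""
    if isinstance(ast, Atom):
        return ctx.resolve_atom(ast)
    if isinstance(ast, Not):
        return ctx.store.universe() - evaluate(ast.child, ctx)
    sets = [evaluate(c, ctx) for c in ast.children]
    out = sets[0].copy()
    for s in sets[1:]:
        if isinstance(ast, And):
            out &= s
        else:
            out |= s
    return out


# -- weighted query sets ----------------------------------------------------------


@dataclass
class WeightedQuerySet:
    """Ordered queries, each with a positive importance weight."""

    entries: list[tuple[QueryAST, float]]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("a weighted query set needs at least one query")
        for _, w in self.entries:
            if not (w > 0):
                raise ValueError(f"query weights must be positive, got {w}")

    def __len__(self):
        return len(self.entries)


@dataclass(frozen=True)
class RankedCandidate:
    gene: str
    score: float
    matched: tuple[int, ...]  # indices into the query set


def _match_sets(qs: WeightedQuerySet, ctx: QueryContext) -> list[set[str]]:
    return [evaluate(ast, ctx) for ast, _ in qs.entries]


def rank(
    qs: WeightedQuerySet,
    ctx: QueryContext,
    universe: set[str] | None = None,
) -> list[RankedCandidate]:
    """Score every gene by the summed weights of the queries it satisfies.

    Genes matching nothing are omitted. Sorted by (score desc, gene id asc);
    the id tie-break keeps output deterministic. ``universe``, when given,
    restricts candidates (used for region-constrained prioritization).
    """
    sets = _match_sets(qs, ctx)
    scores: dict[str, float] = {}
    matched: dict[str, list[int]] = {}
    for i, (genes, (_, w)) in enumerate(zip(sets, qs.entries)):
        if universe is not None:
            genes = genes & universe
        for g in genes:
            scores[g] = scores.get(g, 0.0) + w
            matched.setdefault(g, []).append(i)
    out = [RankedCandidate(g, s, tuple(matched[g])) for g, s in scores.items()]
    out.sort(key=lambda c: (-c.score, c.gene))
    return out


def annotation_distribution(
    qs: WeightedQuerySet, ctx: QueryContext
) -> tuple[list[int], np.ndarray]:
    """Per-query gene counts and the pairwise-overlap matrix (weights ignored)."""
    sets = _match_sets(qs, ctx)
    counts = [len(s) for s in sets]
    n = len(sets)
    overlap = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            overlap[i, j] = len(sets[i] & sets[j])
    return counts, overlap
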