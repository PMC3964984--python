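"""Enrichment/depletion statistics and conditional-probability correlation.

For a study list of n genes drawn from a reference of N genes, of which K
carry a given annotation term (counting through the true-path rule), the
number k of study genes carrying the term follows the hypergeometric
distribution. The reported P-value is the one-sided tail in the observed
direction — P(X ≥ k) when the term looks enriched (k/n ≥ K/N), P(X ≤ k)
when depleted — corrected for multiple testing with both Bonferroni and
Benjamini–Hochberg over the terms actually tested in the namespace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation_store import AnnotationStore
from .errors import DomainError, UndefinedProbabilityError
from .ontology import Ontology

ENRICHED = "enriched"
DEPLETED = "depleted"


def hypergeom_tail(k: int, n: int, K: int, N: int, direction: str = ENRICHED) -> float:
    """Exact one-sided hypergeometric tail, computed in log space.

    enriched → P(X ≥ k); depleted → P(X ≤ k), with X ~ Hypergeom(N, K, n).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"invalid population: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise DomainError(f"k={k} outside [0, {min(n, K)}]")
    if direction not in (ENRICHED, DEPLETED):
        raise DomainError(f"direction must be {ENRICHED!r} or {DEPLETED!r}")
    lo, hi = max(0, n + K - N), min(n, K)  # support of X
    if direction == ENRICHED and k <= lo:
        return 1.0  # whole support; avoid accumulating rounding error
    if direction == DEPLETED and k >= hi:
        return 1.0
    if direction == ENRICHED:
        xs = np.arange(max(k, lo), hi + 1)
    else:
        if k < lo:
            return 0.0
        xs = np.arange(lo, k + 1)
    logp = hypergeom.logpmf(xs, N, K, n)
    return float(min(1.0, math.exp(logsumexp(logp))))


@dataclass
class EnrichmentRow:
    term: str
    name: str
    k: int  # study genes with term (propagated)
    n: int  # study size
    K: int  # reference genes with term
    N: int  # reference size
    direction: str
    p: float
    p_bonf: float = math.nan
    p_bh: float = math.nan


def _propagated_counts(
    genes: set[str], store: AnnotationStore, ont: Ontology, namespace: str
) -> dict[str, int]:
    """Per-term counts of ``genes`` under true-path propagation.

    Counts are accumulated bottom-up: each gene contributes once to every
    ancestor of every term it is annotated to.
    """
    counts: dict[str, set[str]] = {}
    for g in genes:
        reached: set[str] = set()
        for t in store.terms_of_gene(g, namespace):
            if t in ont:
                reached |= ont.ancestors(t, reflexive=True)
        for t in reached:
            counts.setdefault(t, set()).add(g)
    return {t: len(gs) for t, gs in counts.items()}


def enrich(
    study: Iterable[str],
    reference: Iterable[str],
    store: AnnotationStore,
    ont: Ontology,
    namespace: str,
) -> list[EnrichmentRow]:
    """One row per term with ≥1 propagated annotation in the reference.

    The study list must be a subset of the reference (build a custom
    reference first if it is not). The correction family m is the number of
    rows tested within this namespace, not the whole ontology.
    """
    study, reference = set(study), set(reference)
    if not reference:
        raise DomainError("reference gene set is empty")
    if not study <= reference:
        extra = sorted(study - reference)[:5]
        raise DomainError(
            "study list is not a subset of the reference "
            f"(e.g. {', '.join(extra)}); use a custom reference that contains it"
        )
    ref_counts = _propagated_counts(reference, store, ont, namespace)
    study_counts = _propagated_counts(study, store, ont, namespace)
    n, N = len(study), len(reference)
    rows: list[EnrichmentRow] = []
    for term in sorted(ref_counts):
        K = ref_counts[term]
        k = study_counts.get(term, 0)
        direction = ENRICHED if k * N >= K * n else DEPLETED
        p = hypergeom_tail(k, n, K, N, direction)
        name = ont[term].name if term in ont else ""
        rows.append(EnrichmentRow(term, name, k, n, K, N, direction, p))
    if rows:
        ps = [r.p for r in rows]
        bh = bh_fdr(ps)
        m = len(rows)
        for r, q in zip(rows, bh):
            r.p_bonf = min(1.0, r.p * m)
            r.p_bh = q
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def bonferroni(p: Sequence[float]) -> list[float]:
    _check_pvalues(p)
    m = len(p)
    return [min(1.0, x * m) for x in p]


def bh_fdr(p: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    _check_pvalues(p)
    if not len(p):
        return []
    return list(multipletests(list(p), method="fdr_bh")[1])


def _check_pvalues(p: Sequence[float]) -> None:
    for x in p:
        if not (0.0 <= x <= 1.0):
            raise DomainError(f"p-value {x} outside [0, 1]")


@dataclass(frozen=True)
class ConditionalProbability:
    term_a: str
    term_b: str
    p_a_given_b: float
    p_b_given_a: float
    n_a: int
    n_b: int
    n_both: int


def conditional_probability(
    term_a: str,
    ns_a: str,
    term_b: str,
    ns_b: str,
    store: AnnotationStore,
    ontologies: Mapping[str, Ontology],
) -> ConditionalProbability:
    """P(annotated with A | annotated with B) and the converse.

    Gene sets use true-path propagation. Conditioning on an empty set is an
    explicit error rather than a NaN.
    """
    ga = store.genes_with_term(ontologies[ns_a], term_a, ns_a, propagate=True)
    gb = store.genes_with_term(ontologies[ns_b], term_b, ns_b, propagate=True)
    if not gb:
        raise UndefinedProbabilityError(f"no gene annotated with {term_b} ({ns_b})")
    if not ga:
        raise UndefinedProbabilityError(f"no gene annotated with {term_a} ({ns_a})")
    both = ga & gb
    return ConditionalProbability(
        term_a, term_b, len(both) / len(gb), len(both) / len(ga), len(ga), len(gb), len(both)
    )
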