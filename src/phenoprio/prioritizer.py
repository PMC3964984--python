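"""Disease-to-candidate-gene prioritization.

A disease described by phenotype terms in the source-species ontology is
turned into a weighted query set against the model species: each clinical
feature becomes one query (an Or over the feature's cross-species mapped
terms), weighted by the product of

* a specificity weight — the information content ``-log2 f`` of the
  feature in the disease corpus, so common features like "short stature"
  count less than rare, disease-defining ones; and
* the mapping-method weight (1.0 for entity–quality mappings, lower for
  keyword fallbacks).

Candidates are all annotated model-species genes, or, when a chromosomal
region from CGH/linkage evidence is supplied, the model-species orthologs
of the genes in that region. Region genes without orthologs, and
candidates without any phenotype annotation, are surfaced as "unscorable"
rather than silently dropped.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from .annotation_store import AnnotationStore
from .eq_mapping import EqMapper, TermMapping
from .errors import UnanalyzableDiseaseError
from .ontology import Ontology
from .query_engine import (
    Atom,
    Or,
    QueryContext,
    RankedCandidate,
    WeightedQuerySet,
    rank,
)


@dataclass
class DiseaseDescription:
    """A disease as a list of phenotype terms with optional frequency
    qualifiers (parsed but ignored by the default weighting)."""

    disease_id: str
    features: list[tuple[str, str | None]]

    def __post_init__(self):
        if not self.features:
            raise ValueError(f"disease {self.disease_id} has no features")

    @property
    def terms(self) -> list[str]:
        return [t for t, _ in self.features]


def load_diseases(stream: TextIO) -> list[DiseaseDescription]:
    """Read the hpoa-like TSV ``disease_id \\t term_id \\t frequency`` (headered)."""
    reader = csv.reader(stream, delimiter="\t")
    rows = [r for r in reader if r and not r[0].startswith("#")]
    by_id: dict[str, list[tuple[str, str | None]]] = {}
    order: list[str] = []
    for row in rows[1:]:  # drop header
        if not row or not row[0].strip():
            continue
        did, term = row[0].strip(), row[1].strip()
        freq = row[2].strip() or None if len(row) > 2 else None
        if did not in by_id:
            by_id[did] = []
            order.append(did)
        by_id[did].append((term, freq))
    return [DiseaseDescription(d, by_id[d]) for d in order]


class SpecificityWeights:
    """Corpus-frequency weights for phenotype terms.

    ``f(t)`` is the fraction of corpus diseases annotated to ``t`` or any
    is_a descendant of it; the weight is ``-log2 f``, clamped for unseen
    terms at ``f = 1/(2·corpus size)`` so they stay finite.
    """

    def __init__(self, corpus: Sequence[DiseaseDescription], ont: Ontology):
        if not corpus:
            raise ValueError("disease corpus is empty")
        self.ont = ont
        self.corpus_size = len(corpus)
        # diseases per exact term; propagated counts resolved lazily per query term
        self._disease_terms: list[set[str]] = []
        for d in corpus:
            reached: set[str] = set()
            for t in d.terms:
                if t in ont and not ont[t].obsolete:
                    reached |= ont.ancestors(t, reflexive=True)
            self._disease_terms.append(reached)
        self._cache: dict[str, float] = {}

    def frequency(self, term: str) -> float:
        hits = sum(1 for reached in self._disease_terms if term in reached)
        floor = 1.0 / (2.0 * self.corpus_size)
        return max(hits / self.corpus_size, floor)

    def weight(self, term: str) -> float:
        if term not in self._cache:
            self._cache[term] = -math.log2(self.frequency(term))
        return self._cache[term]


def feature_weights(
    corpus: Sequence[DiseaseDescription], ont: Ontology
) -> SpecificityWeights:
    """Build corpus specificity weights (see :class:`SpecificityWeights`)."""
    return SpecificityWeights(corpus, ont)


@dataclass
class FeatureQuery:
    """Bookkeeping for one disease feature turned into one query."""

    term: str
    mapped_targets: tuple[str, ...]
    method: str
    specificity: float
    method_weight: float

    @property
    def weight(self) -> float:
        return self.specificity * self.method_weight


@dataclass
class DiseaseQuerySet:
    queries: WeightedQuerySet | None
    features: list[FeatureQuery]
    dropped: list[str]  # feature terms with no mapping at any cascade stage


def disease_to_queryset(
    disease: DiseaseDescription,
    mapper: EqMapper,
    weights: SpecificityWeights,
) -> DiseaseQuerySet:
    """One weighted query per mappable feature.

    A feature "fires" if the gene is annotated (with propagation) to any of
    its mapped targets, hence the Or. Unmappable features are reported in
    ``dropped``, not fatal; a disease where everything drops simply yields
    no queries.
    """
    feature_queries: list[FeatureQuery] = []
    dropped: list[str] = []
    entries = []
    for term in disease.terms:
        mappings: list[TermMapping] = mapper.map_term(term)
        if not mappings:
            dropped.append(term)
            continue
        method = mappings[0].method  # cascade exclusivity: all share one method
        method_weight = mappings[0].weight
        fq = FeatureQuery(
            term=term,
            mapped_targets=tuple(m.target for m in mappings),
            method=method,
            specificity=weights.weight(term),
            method_weight=method_weight,
        )
        feature_queries.append(fq)
        atoms = [Atom("PHENO", t) for t in fq.mapped_targets]
        ast = atoms[0] if len(atoms) == 1 else Or(tuple(atoms))
        entries.append((ast, fq.weight))
    qs = WeightedQuerySet(entries) if entries else None
    return DiseaseQuerySet(qs, feature_queries, dropped)


@dataclass
class PrioritizationResult:
    disease_id: str
    ranked: list[RankedCandidate]
    features: list[FeatureQuery]
    dropped_features: list[str]
    unscorable: list[str]
    universe_size: int

    def rank_of(self, gene: str, worst_tie: bool = False) -> int | None:
        """1-based rank of ``gene`` among the candidate universe.

        With ``worst_tie`` the gene takes the last position of its tie
        group (zero-score genes form one tie group at the bottom), which is
        the conservative convention used for benchmarking.
        """
        score = next((c.score for c in self.ranked if c.gene == gene), 0.0)
        higher = sum(1 for c in self.ranked if c.score > score)
        if not worst_tie:
            return higher + 1
        tied = sum(1 for c in self.ranked if c.score == score)
        if score == 0.0:
            tied = self.universe_size - len(self.ranked)
        return higher + tied if score > 0 else len(self.ranked) + tied


def prioritize(
    disease: DiseaseDescription,
    ctx: QueryContext,
    mapper: EqMapper,
    weights: SpecificityWeights,
    model_species: str,
    region: tuple[str, int, int] | None = None,
    region_species: str | None = None,
) -> PrioritizationResult:
    """Rank model-species candidate genes for a disease.

    With ``region``, candidates are the ``model_species`` orthologs of the
    ``region_species`` genes overlapping the interval; otherwise every
    ``model_species`` gene is a candidate.
    """
    dqs = disease_to_queryset(disease, mapper, weights)
    if dqs.queries is None:
        raise UnanalyzableDiseaseError(disease.disease_id)

    store = ctx.store
    unscorable: list[str] = []
    if region is not None:
        chrom, start, end = region
        region_genes = store.genes_in_region(chrom, start, end)
        if region_species is not None:
            region_genes = {g for g in region_genes if store.genes[g].species == region_species}
        universe = store.orthologs(region_genes, model_species)
        unscorable.extend(
            sorted(g for g in region_genes if not store.orthologs({g}, model_species))
        )
    else:
        universe = store.genes_of_species(model_species)

    annotated = store.annotated_genes("PHENO_B")
    unscorable.extend(sorted(universe - annotated))

    ranked = rank(dqs.queries, ctx, universe=universe)
    return PrioritizationResult(
        disease_id=disease.disease_id,
        ranked=ranked,
        features=dqs.features,
        dropped_features=dqs.dropped,
        unscorable=unscorable,
        universe_size=len(universe),
    )
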