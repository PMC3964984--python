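"""Cross-species phenotype-term mapping via the Entity–Quality method.

A phenotype term's logical definition decomposes it into *how* (a quality
term, e.g. hypoplastic) and *what* (one or more anatomical entity terms).
Two phenotype terms from different species match when their qualities are
identical or related by is_a, and at least one entity on each side is
linked through a species-neutral bridge anatomy whose cross-references
point into both species-specific anatomies.

Terms without a usable definition fall back, in order, to the mapping of
their closest annotated is_a ancestor, then to a manually curated keyword
system; keyword mappings carry a lower weight reflecting their lower
precision.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import yaml

from .errors import TermLookupError
from .ontology import Ontology, _strip_trailer

logger = logging.getLogger(__name__)

#: Default down-weighting of keyword-derived mappings relative to E-Q ones.
DEFAULT_KEYWORD_WEIGHT = 0.5

EQ_EXACT = "eq_exact"
EQ_INHERITED = "eq_inherited"
KEYWORD = "keyword"


@dataclass(frozen=True)
class LogicalDefinition:
    """The E-Q decomposition of one phenotype term."""

    term: str
    quality: str
    entities: tuple[str, ...]

    def __post_init__(self):
        if not self.entities:
            raise ValueError(f"definition of {self.term} has no entities")


@dataclass(frozen=True)
class TermMapping:
    source: str
    target: str
    method: str  # eq_exact | eq_inherited | keyword
    weight: float


class AnatomyBridge:
    """Symmetric pairing of species-specific anatomy terms.

    ``(a, b)`` is in the bridge iff some bridge-ontology term
    cross-references both; pairs found via distinct bridge terms are
    unioned.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self.pairs: set[tuple[str, str]] = set()
        self._partners: dict[str, set[str]] = defaultdict(set)
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        self.pairs.add((a, b))
        self._partners[a].add(b)
        self._partners[b].add(a)

    def bridged(self, a: str, b: str) -> bool:
        return b in self._partners.get(a, ())

    def partners(self, a: str) -> set[str]:
        return set(self._partners.get(a, ()))

    def __len__(self) -> int:
        return len(self.pairs)


def build_bridge(anatomy_a: Ontology, anatomy_b: Ontology, bridge: Ontology) -> AnatomyBridge:
    """Derive cross-species anatomy pairs from a bridge ontology's xrefs.

    Cross-references whose prefix belongs to neither anatomy are skipped
    with a logged warning; they are expected in real bridge ontologies.
    """
    prefixes_a = anatomy_a.prefixes
    prefixes_b = anatomy_b.prefixes
    out = AnatomyBridge()
    for term in bridge:
        side_a, side_b = [], []
        for x in term.xrefs:
            prefix = x.split(":", 1)[0]
            if prefix in prefixes_a:
                side_a.append(x)
            elif prefix in prefixes_b:
                side_b.append(x)
            else:
                logger.warning("bridge term %s: xref %s has unknown prefix", term.id, x)
        for a in side_a:
            for b in side_b:
                out.add(a, b)
    return out


class KeywordIndex:
    """Manually curated keyword → phenotype-term sets, one set per species."""

    def __init__(self, entries: Mapping[str, tuple[set[str], set[str]]]):
        if not entries:
            raise ValueError("keyword index must contain at least one keyword")
        self.entries = {k: (set(a), set(b)) for k, (a, b) in entries.items()}
        self._by_source: dict[str, set[str]] = defaultdict(set)
        for kw, (src_terms, _) in self.entries.items():
            for t in src_terms:
                self._by_source[t].add(kw)

    @classmethod
    def from_yaml(cls, stream: TextIO | str, ont_a: Ontology, ont_b: Ontology) -> "KeywordIndex":
        """Load ``keyword: [term ids]`` config; ids are split by ontology membership."""
        raw = yaml.safe_load(stream if hasattr(stream, "read") else str(stream)) or {}
        entries = {}
        for kw, term_ids in raw.items():
            side_a, side_b = set(), set()
            for tid in term_ids or []:
                if tid in ont_a:
                    side_a.add(tid)
                elif tid in ont_b:
                    side_b.add(tid)
                else:
                    raise TermLookupError(tid)
            entries[str(kw)] = (side_a, side_b)
        return cls(entries)

    def keywords_of_source(self, term_id: str) -> set[str]:
        return set(self._by_source.get(term_id, ()))

    def targets_for(self, term_id: str) -> set[str]:
        out: set[str] = set()
        for kw in self.keywords_of_source(term_id):
            out |= self.entries[kw][1]
        return out


# -- logical-definition loading ---------------------------------------------------


def definitions_from_tsv(stream: TextIO) -> dict[str, LogicalDefinition]:
    """Read the 3-column sidecar: ``term_id \\t quality_id \\t entity,entity…`` (headered)."""
    reader = csv.reader(stream, delimiter="\t")
    rows = [r for r in reader if r and not r[0].startswith("#")]
    out: dict[str, LogicalDefinition] = {}
    for row in rows[1:]:  # drop header
        if not row or not row[0].strip():
            continue
        term, quality, entities = row[0].strip(), row[1].strip(), row[2].strip()
        out[term] = LogicalDefinition(
            term=term,
            quality=quality,
            entities=tuple(e.strip() for e in entities.split(",") if e.strip()),
        )
    return out


def definitions_from_ontology(ont: Ontology) -> dict[str, LogicalDefinition]:
    """Extract E-Q definitions from OBO ``intersection_of`` lines.

    Within a stanza the first term-only line names the quality (the genus);
    relation-bearing lines ("inheres_in ANAT:1") contribute entities.
    """
    out: dict[str, LogicalDefinition] = {}
    for term in ont:
        if not term.intersection_of:
            continue
        quality = None
        entities: list[str] = []
        for raw in term.intersection_of:
            parts = _strip_trailer(raw).split()
            if len(parts) == 1 and quality is None:
                quality = parts[0]
            elif len(parts) >= 2:
                entities.append(parts[-1])
        if quality and entities:
            out[term.id] = LogicalDefinition(term.id, quality, tuple(entities))
    return out


def merge_definitions(
    from_obo: Mapping[str, LogicalDefinition],
    from_tsv: Mapping[str, LogicalDefinition],
) -> dict[str, LogicalDefinition]:
    """TSV sidecar wins over intersection_of lines on conflict."""
    merged = dict(from_obo)
    merged.update(from_tsv)
    return merged


# -- matching ---------------------------------------------------------------------


def qualities_compatible(qa: str, qb: str, quality_ont: Ontology) -> bool:
    """Identical, or one is an is_a ancestor of the other (not siblings)."""
    if qa == qb:
        return True
    if qa not in quality_ont or qb not in quality_ont:
        return False
    return qb in quality_ont.ancestors(qa) or qa in quality_ont.ancestors(qb)


def eq_match(
    def_a: LogicalDefinition,
    def_b: LogicalDefinition,
    quality_ont: Ontology,
    bridge: AnatomyBridge,
) -> bool:
    """True iff qualities are compatible and any entity pair is bridged.

    Multi-entity definitions match existentially: one bridged entity pair
    suffices.
    """
    if not qualities_compatible(def_a.quality, def_b.quality, quality_ont):
        return False
    return any(bridge.bridged(ea, eb) for ea in def_a.entities for eb in def_b.entities)


@dataclass
class EqMapper:
    """The three-stage mapping cascade from one phenotype ontology to another.

    Stages, stopping at the first that yields anything:

    1. ``eq_exact`` — target terms whose definition E-Q-matches the
       source's own definition (weight 1.0);
    2. ``eq_inherited`` — ancestors of the source are walked in order of
       increasing is_a distance; at the first depth where any ancestor has
       stage-1 mappings, the union of those mappings is inherited
       (weight 1.0);
    3. ``keyword`` — target terms sharing a curated keyword with the
       source (weight ``keyword_weight``).

    A term that exhausts all three stages maps to nothing.
    """

    source_ont: Ontology
    target_ont: Ontology
    quality_ont: Ontology
    source_defs: Mapping[str, LogicalDefinition]
    target_defs: Mapping[str, LogicalDefinition]
    bridge: AnatomyBridge
    keywords: KeywordIndex | None = None
    keyword_weight: float = DEFAULT_KEYWORD_WEIGHT
    _exact_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not (0 < self.keyword_weight < 1.0):
            raise ValueError("keyword weight must lie strictly between 0 and 1")

    def _exact_targets(self, source: str) -> set[str]:
        if source in self._exact_cache:
            return self._exact_cache[source]
        src_def = self.source_defs.get(source)
        hits: set[str] = set()
        if src_def is not None:
            for tgt, tgt_def in self.target_defs.items():
                if eq_match(src_def, tgt_def, self.quality_ont, self.bridge):
                    hits.add(tgt)
        self._exact_cache[source] = hits
        return hits

    def map_term(self, source: str) -> list[TermMapping]:
        if source not in self.source_ont:
            raise TermLookupError(source)

        # stage 1: own definition
        exact = self._exact_targets(source)
        if exact:
            return [TermMapping(source, t, EQ_EXACT, 1.0) for t in sorted(exact)]

        # stage 2: closest annotated ancestor(s); equally-close ones are unioned
        depths = self.source_ont.ancestor_depths(source)
        by_depth: dict[int, list[str]] = defaultdict(list)
        for anc, d in depths.items():
            if d > 0:
                by_depth[d].append(anc)
        for d in sorted(by_depth):
            inherited: set[str] = set()
            for anc in by_depth[d]:
                inherited |= self._exact_targets(anc)
            if inherited:
                return [TermMapping(source, t, EQ_INHERITED, 1.0) for t in sorted(inherited)]

        # stage 3: keyword fallback, down-weighted
        if self.keywords is not None:
            kw_targets = self.keywords.targets_for(source)
            if kw_targets:
                return [
                    TermMapping(source, t, KEYWORD, self.keyword_weight)
                    for t in sorted(kw_targets)
                ]
        return []
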