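"""Genes, annotations, orthology and coordinates, plus the retrievals that
sequential filtering pipelines chain together: genes by ontology term (with
true-path propagation), orthologs across species, and genes overlapping a
chromosomal interval.

Coordinates are 1-based closed intervals; region queries use overlap, not
containment, matching how CGH/linkage intervals are used in practice.
Strand is ignored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .errors import StoreValidationError, TermLookupError
from .ontology import Ontology

#: Annotation namespaces carried by the store.
NAMESPACES = ("GO", "PHENO_A", "PHENO_B", "PATHWAY", "MOTIF", "DISEASE")


@dataclass
class GeneRecord:
    id: str
    species: str
    symbol: str = ""
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    @property
    def has_coordinates(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None

    @property
    def midpoint(self) -> float:
        if not self.has_coordinates:
            raise ValueError(f"gene {self.id} has no coordinates")
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class Association:
    gene: str
    term: str
    namespace: str


class AnnotationStore:
    """In-memory store with per-namespace term→genes and gene→terms indexes."""

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        associations: Iterable[Association] = (),
        orthology: Iterable[tuple[str, str]] = (),
        ontologies: Mapping[str, Ontology] | None = None,
    ):
        self.genes: dict[str, GeneRecord] = {}
        problems: list[str] = []
        for g in genes:
            if g.id in self.genes:
                problems.append(f"duplicate gene id {g.id!r}")
            if g.start is not None and g.end is not None and g.start > g.end:
                problems.append(f"gene {g.id!r}: start {g.start} > end {g.end}")
            self.genes[g.id] = g

        self.associations: list[Association] = []
        self._term_genes: dict[str, dict[str, set[str]]] = {ns: {} for ns in NAMESPACES}
        self._gene_terms: dict[str, dict[str, set[str]]] = {ns: {} for ns in NAMESPACES}
        for a in associations:
            if a.gene not in self.genes:
                problems.append(f"association to unknown gene {a.gene!r}")
                continue
            if a.namespace not in self._term_genes:
                problems.append(f"unknown namespace {a.namespace!r} for gene {a.gene!r}")
                continue
            if ontologies and a.namespace in ontologies and a.term not in ontologies[a.namespace]:
                problems.append(f"association to unknown term {a.term!r} ({a.namespace})")
                continue
            self.associations.append(a)
            self._term_genes[a.namespace].setdefault(a.term, set()).add(a.gene)
            self._gene_terms[a.namespace].setdefault(a.gene, set()).add(a.term)

        self._partners: dict[str, set[str]] = {}
        self.orthology: set[frozenset[str]] = set()
        for g1, g2 in orthology:
            for g in (g1, g2):
                if g not in self.genes:
                    problems.append(f"orthology pair names unknown gene {g!r}")
            if g1 in self.genes and g2 in self.genes:
                if self.genes[g1].species == self.genes[g2].species:
                    problems.append(f"orthology pair ({g1!r}, {g2!r}) links one species to itself")
                    continue
                self.orthology.add(frozenset((g1, g2)))
                self._partners.setdefault(g1, set()).add(g2)
                self._partners.setdefault(g2, set()).add(g1)

        if problems:
            raise StoreValidationError(problems)

        self._species_genes: dict[str, set[str]] = {}
        for g in self.genes.values():
            self._species_genes.setdefault(g.species, set()).add(g.id)

    # -- basic views --------------------------------------------------------------

    @property
    def species(self) -> set[str]:
        return set(self._species_genes)

    def universe(self) -> set[str]:
        """All gene ids, every species."""
        return set(self.genes)

    def genes_of_species(self, species: str) -> set[str]:
        return set(self._species_genes.get(species, ()))

    def annotated_genes(self, namespace: str) -> set[str]:
        return set(self._gene_terms[namespace])

    def terms_of_gene(self, gene: str, namespace: str) -> set[str]:
        return set(self._gene_terms[namespace].get(gene, ()))

    def terms_used(self, namespace: str) -> set[str]:
        return set(self._term_genes[namespace])

    # -- retrievals ---------------------------------------------------------------

    def genes_with_term(
        self,
        ont: Ontology,
        term: str,
        namespace: str,
        propagate: bool = True,
    ) -> set[str]:
        """Genes annotated to ``term`` — or, under the true-path rule, to any
        is_a descendant of it."""
        if term not in ont:
            raise TermLookupError(term)
        index = self._term_genes[namespace]
        if not propagate:
            return set(index.get(term, ()))
        out: set[str] = set()
        for t in ont.descendants(term, reflexive=True):
            out |= index.get(t, set())
        return out

    def orthologs(self, genes: Iterable[str], target_species: str) -> set[str]:
        """Union of orthology partners of ``genes`` restricted to ``target_species``.

        Genes without partners contribute nothing; 1:many pairs contribute
        every partner.
        """
        if target_species not in self._species_genes:
            raise KeyError(f"unknown species {target_species!r}")
        out: set[str] = set()
        for g in genes:
            for p in self._partners.get(g, ()):
                if self.genes[p].species == target_species:
                    out.add(p)
        return out

    def ortholog_partners(self, gene: str) -> set[str]:
        return set(self._partners.get(gene, ()))

    def genes_in_region(self, chrom: str, start: int, end: int) -> set[str]:
        """Genes whose closed interval overlaps [start, end] on ``chrom``.

        Genes lacking coordinates never match.
        """
        if start > end:
            raise ValueError(f"region start {start} > end {end}")
        return {
            g.id
            for g in self.genes.values()
            if g.has_coordinates and g.chrom == chrom and g.start <= end and g.end >= start
        }


# -- TSV / BED I/O ----------------------------------------------------------------


def _read_tsv(stream: TextIO) -> list[list[str]]:
    reader = csv.reader(stream, delimiter="\t")
    rows = [r for r in reader if r and not r[0].startswith("#")]
    return rows[1:] if rows else []  # drop header


def load_store(
    genes: TextIO,
    associations: TextIO,
    orthology: TextIO,
    ontologies: Mapping[str, Ontology] | None = None,
) -> AnnotationStore:
    """Build a store from the three headered TSV dialects.

    genes: ``gene_id  species  symbol  chrom  start  end`` (last three may be
    empty); associations: ``gene_id  term_id  namespace``; orthology:
    ``gene_id_1  gene_id_2``. Referential problems are collected and raised
    together as one :class:`StoreValidationError`.
    """
    problems: list[str] = []
    gene_records: list[GeneRecord] = []
    for row in _read_tsv(genes):
        if not row or not row[0].strip():
            continue
        row = row + [""] * (6 - len(row))
        gid, species, symbol, chrom, start, end = (c.strip() for c in row[:6])
        coords: dict = {"chrom": chrom or None, "start": None, "end": None}
        try:
            if start:
                coords["start"] = int(start)
            if end:
                coords["end"] = int(end)
        except ValueError:
            problems.append(f"gene {gid!r}: malformed coordinate {start!r}/{end!r}")
        gene_records.append(GeneRecord(gid, species, symbol, **coords))

    assoc_records = [
        Association(row[0].strip(), row[1].strip(), row[2].strip())
        for row in _read_tsv(associations)
        if row and row[0].strip()
    ]
    ortho_pairs = [
        (row[0].strip(), row[1].strip())
        for row in _read_tsv(orthology)
        if row and row[0].strip()
    ]
    if problems:
        raise StoreValidationError(problems)
    return AnnotationStore(gene_records, assoc_records, ortho_pairs, ontologies)


def write_region_bed(store: AnnotationStore, genes: Iterable[str], stream: TextIO) -> None:
    """Export genes as BED lines (0-based half-open conversion at the boundary)."""
    for gid in sorted(genes):
        g = store.genes[gid]
        if g.has_coordinates:
            stream.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.id}\n")
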