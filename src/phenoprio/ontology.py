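"""OBO ontologies as acyclic is_a term graphs.

Terms are read from OBO 1.2 flat files (via :mod:`obonet`) into a small,
validated :class:`Ontology` container. Only ``is_a`` edges drive traversal;
``part_of`` and other relationships present in source files are ignored.
Obsolete terms are retained for id lookup but excluded from closures, so
annotations pointing at dead terms surface as explicit lookup results rather
than vanishing at parse time.

CURIEs are ``PREFIX:LOCALID`` with a single colon.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import networkx as nx
import obonet

from .errors import (
    AmbiguousLabelError,
    CycleError,
    DanglingReferenceError,
    DuplicateTermError,
    LabelNotFoundError,
    TermLookupError,
)

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')
_TRAILER_RE = re.compile(r"\s*(\{[^}]*\}|!.*)\s*$")


def _strip_trailer(value: str) -> str:
    """Drop trailing ``{qualifier}`` blocks and ``!`` comments from a tag value."""
    prev = None
    while prev != value:
        prev = value
        value = _TRAILER_RE.sub("", value).strip()
    return value


def _normalize_label(label: str) -> str:
    return " ".join(label.split()).casefold()


@dataclass
class Term:
    """A single ontology term.

    ``parents`` carries is_a targets only. ``intersection_of`` keeps the raw
    logical-definition lines for the entity–quality mapping layer to
    interpret; this module does not give them semantics.
    """

    id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    namespace: str = ""
    parents: list[str] = field(default_factory=list)
    obsolete: bool = False
    xrefs: list[str] = field(default_factory=list)
    intersection_of: list[str] = field(default_factory=list)

    @property
    def prefix(self) -> str:
        return self.id.split(":", 1)[0]


class Ontology:
    """A collection of terms whose is_a graph is a rooted DAG."""

    def __init__(self, terms: Iterable[Term], name: str = ""):
        self.name = name
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self.terms:
                raise DuplicateTermError([t.id])
            self.terms[t.id] = t
        self._validate()
        # parent-direction DiGraph over non-obsolete terms: edge child -> parent
        g = nx.DiGraph()
        for t in self.terms.values():
            if t.obsolete:
                continue
            g.add_node(t.id)
            for p in t.parents:
                g.add_edge(t.id, p)
        self._graph = g
        self._label_index: dict[str, list[str]] | None = None

    # -- construction-time checks -------------------------------------------------

    def _validate(self) -> None:
        if not self.terms:
            raise DanglingReferenceError(["<empty ontology>"])
        missing = set()
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    missing.add(p)
        if missing:
            raise DanglingReferenceError(missing)
        g = nx.DiGraph(
            (t.id, p)
            for t in self.terms.values()
            if not t.obsolete
            for p in t.parents
        )
        if g.number_of_edges() and not nx.is_directed_acyclic_graph(g):
            cyc = max(nx.strongly_connected_components(g), key=len)
            raise CycleError(cyc)
        if not self.roots:
            raise CycleError(self.terms)  # every term has a parent => cyclic

    # -- container protocol -------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise TermLookupError(term_id) from None

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms.values())

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def roots(self) -> set[str]:
        return {t.id for t in self.terms.values() if not t.obsolete and not t.parents}

    @property
    def prefixes(self) -> set[str]:
        return {t.prefix for t in self.terms.values()}

    # -- traversal ----------------------------------------------------------------

    def _check_traversable(self, term_id: str) -> None:
        term = self[term_id]
        if term.obsolete:
            raise TermLookupError(term_id)

    def ancestors(self, term_id: str, reflexive: bool = False) -> set[str]:
        """Transitive is_a closure above ``term_id`` (excluding it unless reflexive)."""
        self._check_traversable(term_id)
        out = nx.descendants(self._graph, term_id)  # edges run child -> parent
        if reflexive:
            out = out | {term_id}
        return set(out)

    def descendants(self, term_id: str, reflexive: bool = False) -> set[str]:
        self._check_traversable(term_id)
        out = nx.ancestors(self._graph, term_id)
        if reflexive:
            out = out | {term_id}
        return set(out)

    def ancestor_depths(self, term_id: str) -> dict[str, int]:
        """Shortest is_a distance from ``term_id`` to each of its ancestors (and itself: 0)."""
        self._check_traversable(term_id)
        return nx.single_source_shortest_path_length(self._graph, term_id)

    # -- label resolution ---------------------------------------------------------

    def resolve(self, label: str) -> str:
        """Map a human-readable label to a term id.

        Case-insensitive, whitespace-normalized exact match against names
        first, then synonyms. Ambiguity is an error listing every candidate,
        never a silent choice.
        """
        if not label or not label.strip():
            raise LabelNotFoundError(label)
        if label in self.terms:  # CURIEs pass straight through
            return label
        if self._label_index is None:
            names: dict[str, list[str]] = {}
            syns: dict[str, list[str]] = {}
            for t in self.terms.values():
                names.setdefault(_normalize_label(t.name), []).append(t.id)
                for s in t.synonyms:
                    syns.setdefault(_normalize_label(s), []).append(t.id)
            self._names, self._syns = names, syns
            self._label_index = names
        key = _normalize_label(label)
        hits = self._names.get(key, [])
        if not hits:
            hits = self._syns.get(key, [])
        if not hits:
            raise LabelNotFoundError(label)
        if len(set(hits)) > 1:
            raise AmbiguousLabelError(label, set(hits))
        return hits[0]


# -- OBO 1.2 I/O ------------------------------------------------------------------


def parse_obo(stream: TextIO | str, name: str = "") -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Only ``[Term]`` stanzas are interpreted; recognized tags are id, name,
    synonym, is_a, xref, is_obsolete and intersection_of; everything else is
    ignored. Duplicate ids, dangling is_a targets and is_a cycles are
    rejected with the offending ids.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = str(stream)

    # obonet keeps the last stanza on duplicate ids; detect duplicates upfront
    seen: set[str] = set()
    dupes: set[str] = set()
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term and line.startswith("id:"):
            tid = _strip_trailer(line[3:].strip())
            (dupes if tid in seen else seen).add(tid)
            in_term = False  # only the first id line names the stanza
    if dupes:
        raise DuplicateTermError(dupes)

    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    terms: list[Term] = []
    for node, data in graph.nodes(data=True):
        if "name" not in data and not data:
            # node materialized only as an is_a target of some stanza
            continue
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if m:
                synonyms.append(m.group("text").replace('\\"', '"'))
        terms.append(
            Term(
                id=node,
                name=data.get("name", ""),
                synonyms=synonyms,
                namespace=data.get("namespace", ""),
                parents=[_strip_trailer(p) for p in data.get("is_a", [])],
                obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
                xrefs=[_strip_trailer(x).split()[0] for x in data.get("xref", []) if x.strip()],
                intersection_of=list(data.get("intersection_of", [])),
            )
        )
    return Ontology(terms, name=name)


def write_obo(ont: Ontology, stream: TextIO) -> None:
    """Serialize the recognized tag subset back to OBO 1.2.

    Terms are emitted in sorted id order so output is deterministic.
    """
    stream.write("format-version: 1.2\n")
    if ont.name:
        stream.write(f"ontology: {ont.name}\n")
    for tid in sorted(ont.terms):
        t = ont.terms[tid]
        stream.write(f"\n[Term]\nid: {t.id}\n")
        if t.name:
            stream.write(f"name: {t.name}\n")
        if t.namespace:
            stream.write(f"namespace: {t.namespace}\n")
        for s in t.synonyms:
            escaped = s.replace('"', '\\"')
            stream.write(f'synonym: "{escaped}" EXACT []\n')
        for p in sorted(t.parents):
            stream.write(f"is_a: {p}\n")
        for x in sorted(t.xrefs):
            stream.write(f"xref: {x}\n")
        for line in t.intersection_of:
            stream.write(f"intersection_of: {line}\n")
        if t.obsolete:
            stream.write("is_obsolete: true\n")
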