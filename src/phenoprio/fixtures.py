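"""Synthetic study universe: ontologies, logical definitions, bridge,
keywords, genes, annotations, orthology and a disease corpus with planted
causal genes.

The generator emulates the statistical structure of a cross-species
prioritization study: two mirrored phenotype ontologies (a "human" side and
a "mouse" side) share a set of paired *concepts*; a concept's pair is
recoverable by the entity–quality match when both sides carry logical
definitions and their anatomy terms are bridged, by closest-annotated-parent
inheritance when only the concept's family is defined, or by a curated
keyword as a last resort. Diseases are described by concept terms of the
human side; each disease's causal human gene has a mouse ortholog annotated
with exactly the corresponding mouse concepts, while decoy genes share
concepts at a configurable rate.

Everything is deterministic given the seed, and the returned ledger records
what was planted — including each planted gene's expected score, computed
by construction rather than by running the engine — so tests can check
recovery against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .annotation_store import AnnotationStore, load_store
from .eq_mapping import (
    EqMapper,
    KeywordIndex,
    definitions_from_ontology,
    definitions_from_tsv,
    merge_definitions,
)
from .ontology import Ontology, Term, parse_obo, write_obo
from .prioritizer import DiseaseDescription, load_diseases
from .query_engine import QueryContext

SPECIES_A = "human"
SPECIES_B = "mouse"

EXACT, INHERITED, KEYWORD_CLASS, UNMAPPABLE = "exact", "inherited", "keyword", "unmappable"

_N_CATEGORIES = 3
_N_QUALITIES = 12
_N_CHROMS = 5


class FixtureInfeasibleError(ValueError):
    """The requested configuration cannot be realized."""


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic universe.

    Defaults are the package's standard conditions (see docs/methods.md for
    the rationale behind each value).
    """

    seed: int = 0
    phenotype_terms: int = 180          # per side, incl. root/categories/families
    n_concepts: int = 48                # paired cross-species phenotype concepts
    n_families: int = 12                # mid-level groups concepts hang under
    definition_coverage: float = 0.7    # P(a concept carries E-Q definitions)
    bridge_coverage: float = 0.9        # P(a defined concept's anatomy is bridged)
    keyword_coverage: float = 0.8       # P(keyword rescue | E-Q stages fail)
    genes_per_species: int = 300
    annotations_per_gene: int = 3       # background GO annotations
    n_diseases: int = 120
    features_per_disease: int = 6
    noise_q: float = 0.0                # P(feature replaced by a random filler term)
    decoy_share_rate: float = 0.05      # P(decoy gene carries a given concept)
    ortholog_coverage: float = 0.9
    unmappable_disease_fraction: float = 0.1
    keyword_weight: float = 0.5
    gene_spacing: int = 100_000         # bp between gene starts on a chromosome
    gene_length: int = 50_000

    def validate(self) -> None:
        fracs = dict(
            definition_coverage=self.definition_coverage,
            bridge_coverage=self.bridge_coverage,
            keyword_coverage=self.keyword_coverage,
            noise_q=self.noise_q,
            decoy_share_rate=self.decoy_share_rate,
            ortholog_coverage=self.ortholog_coverage,
            unmappable_disease_fraction=self.unmappable_disease_fraction,
        )
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise FixtureInfeasibleError(f"{name}={v} outside [0, 1]")
        for name in ("phenotype_terms", "n_concepts", "n_families", "genes_per_species",
                     "n_diseases", "features_per_disease", "gene_spacing", "gene_length"):
            if getattr(self, name) < 1:
                raise FixtureInfeasibleError(f"{name} must be >= 1")
        if self.features_per_disease > self.n_concepts:
            raise FixtureInfeasibleError("more features per disease than concepts exist")
        if self.n_families > self.n_concepts:
            raise FixtureInfeasibleError("more families than concepts")
        if self.phenotype_terms < 1 + _N_CATEGORIES + self.n_families + self.n_concepts:
            raise FixtureInfeasibleError(
                "phenotype_terms too small for root + categories + families + concepts"
            )
        if not (0 < self.keyword_weight < 1):
            raise FixtureInfeasibleError("keyword_weight must lie in (0, 1)")


@dataclass
class FixtureLedger:
    """Ground truth for one generated universe."""

    planted: dict[str, dict[str, str]]              # disease -> {human_gene, mouse_gene}
    disease_features: dict[str, list[dict]]
    expected_scores: dict[str, float | None]        # exact only at noise_q = 0
    concept_classes: dict[int, str]
    concept_family: dict[int, int]
    planted_eq_pairs: list[tuple[str, str]]         # stage-1 recoverable (source, target)
    unmappable_diseases: list[str]
    counts: dict[str, int]

    def mappable_feature_count(self, disease_id: str) -> int:
        return sum(1 for f in self.disease_features[disease_id] if f["mappable"])

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureLedger":
        d = json.loads(text)
        d["concept_classes"] = {int(k): v for k, v in d["concept_classes"].items()}
        d["concept_family"] = {int(k): v for k, v in d["concept_family"].items()}
        d["planted_eq_pairs"] = [tuple(p) for p in d["planted_eq_pairs"]]
        return cls(**d)


# -- id helpers -------------------------------------------------------------------


def _curie(prefix: str, n: int) -> str:
    return f"{prefix}:{n:07d}"


def hp_id(n: int) -> str:
    return _curie("HP", n)


def mp_id(n: int) -> str:
    return _curie("MP", n)


CONCEPT_BASE, FAMILY_BASE, CATEGORY_BASE, FILLER_BASE = 3000, 2000, 1000, 4000


def concept_term(side: str, k: int) -> str:
    return _curie(side, CONCEPT_BASE + k)


def family_term(side: str, f: int) -> str:
    return _curie(side, FAMILY_BASE + f)


# -- generation -------------------------------------------------------------------


def _build_phenotype_side(
    prefix: str,
    cfg: FixtureConfig,
    concept_family: dict[int, int],
    filler_parent: list[tuple[int, int, bool]],
    human_style: bool,
) -> list[Term]:
    """One phenotype ontology: root → categories → families → concepts/fillers."""
    terms = [Term(_curie(prefix, 0), name="phenotypic abnormality")]
    for c in range(_N_CATEGORIES):
        terms.append(
            Term(
                _curie(prefix, CATEGORY_BASE + c),
                name=f"{'Abnormality of system' if human_style else 'abnormal system'} {c}"
                + ("" if human_style else " phenotype"),
                parents=[_curie(prefix, 0)],
            )
        )
    for f in range(cfg.n_families):
        name = (
            f"Abnormality of organ {f}" if human_style else f"abnormal organ {f} phenotype"
        )
        terms.append(
            Term(
                _curie(prefix, FAMILY_BASE + f),
                name=name,
                parents=[_curie(prefix, CATEGORY_BASE + f % _N_CATEGORIES)],
            )
        )
    for k in range(cfg.n_concepts):
        name = (
            f"Abnormality of structure {k}" if human_style else f"abnormal structure {k} morphology"
        )
        syn = f"structure {k} anomaly" if human_style else f"structure {k} defect"
        terms.append(
            Term(
                _curie(prefix, CONCEPT_BASE + k),
                name=name,
                synonyms=[syn],
                parents=[_curie(prefix, FAMILY_BASE + concept_family[k])],
            )
        )
    for j, parent_idx, parent_is_filler in filler_parent:
        pid = _curie(prefix, (FILLER_BASE if parent_is_filler else FAMILY_BASE) + parent_idx)
        name = f"Nonspecific finding {j}" if human_style else f"nonspecific trait {j}"
        terms.append(Term(_curie(prefix, FILLER_BASE + j), name=name, parents=[pid]))
    return terms


def generate(config: FixtureConfig, outdir: str | Path) -> FixtureLedger:
    """Write the complete universe under ``outdir`` and return its ledger.

    Byte-identical across runs with the same config (files carry the seed in
    a comment header, contents are emitted in sorted order).
    """
    cfg = config
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rng_onto = np.random.default_rng((cfg.seed + 11) % (2**31 - 1))
    rng_genes = np.random.default_rng((cfg.seed + 23) % (2**31 - 1))
    rng_dis = np.random.default_rng((cfg.seed + 37) % (2**31 - 1))
    rng_annot = np.random.default_rng((cfg.seed + 51) % (2**31 - 1))

    # -- concept classes and family layout ---------------------------------------
    # definition coverage 0 means no definitions anywhere, families included,
    # so the keyword stage is the only route left
    if cfg.definition_coverage == 0:
        n_def_fam = 0
    else:
        n_def_fam = max(1, cfg.n_families // 2)
        if cfg.n_families >= 2:
            n_def_fam = min(n_def_fam, cfg.n_families - 1)
    defined_families = list(range(n_def_fam))
    undefined_families = list(range(n_def_fam, cfg.n_families))

    concept_classes: dict[int, str] = {}
    concept_has_def: dict[int, bool] = {}
    concept_bridged: dict[int, bool] = {}
    for k in range(cfg.n_concepts):
        has_def = bool(rng_onto.random() < cfg.definition_coverage)
        bridged = bool(rng_onto.random() < cfg.bridge_coverage)
        concept_has_def[k] = has_def
        concept_bridged[k] = bridged
        if has_def and bridged:
            cls = EXACT
        elif rng_onto.random() < 0.5:
            cls = INHERITED
        elif rng_onto.random() < cfg.keyword_coverage:
            cls = KEYWORD_CLASS
        else:
            cls = UNMAPPABLE
        if cls in (KEYWORD_CLASS, UNMAPPABLE) and not undefined_families:
            cls = INHERITED  # single-family configs cannot escape stage 2
        if cls == INHERITED and not defined_families:
            cls = KEYWORD_CLASS if rng_onto.random() < cfg.keyword_coverage else UNMAPPABLE
        concept_classes[k] = cls

    concept_family: dict[int, int] = {}
    counters = {"all": 0, "def": 0, "undef": 0}
    for k in range(cfg.n_concepts):
        cls = concept_classes[k]
        if cls == EXACT:
            concept_family[k] = counters["all"] % cfg.n_families
            counters["all"] += 1
        elif cls == INHERITED:
            concept_family[k] = defined_families[counters["def"] % len(defined_families)]
            counters["def"] += 1
        else:
            concept_family[k] = undefined_families[counters["undef"] % len(undefined_families)]
            counters["undef"] += 1

    # fillers pad each side out to the requested term count; half chain one
    # level deeper so closest-parent walks see nontrivial depths
    n_fillers = cfg.phenotype_terms - (1 + _N_CATEGORIES + cfg.n_families + cfg.n_concepts)
    filler_parent: list[tuple[int, int, bool]] = []
    for j in range(n_fillers):
        if j >= cfg.n_families and j % 2 == 1:
            filler_parent.append((j, int(rng_onto.integers(0, j)), True))
        else:
            filler_parent.append((j, j % cfg.n_families, False))

    # -- ontologies ---------------------------------------------------------------
    hp_terms = _build_phenotype_side("HP", cfg, concept_family, filler_parent, True)
    mp_terms = _build_phenotype_side("MP", cfg, concept_family, filler_parent, False)

    ql_terms = [Term(_curie("QL", 0), name="quality")]
    ql_terms += [
        Term(_curie("QL", q), name=f"abnormal quality {q}", parents=[_curie("QL", 0)])
        for q in range(1, _N_QUALITIES + 1)
    ]

    n_anat = cfg.n_concepts + cfg.n_families
    aa_terms = [Term(_curie("AA", 0), name="anatomical entity (species A)")]
    ab_terms = [Term(_curie("AB", 0), name="anatomical entity (species B)")]
    for i in range(1, n_anat + 1):
        aa_terms.append(Term(_curie("AA", i), name=f"structure {i} (A)", parents=[_curie("AA", 0)]))
        ab_terms.append(Term(_curie("AB", i), name=f"structure {i} (B)", parents=[_curie("AB", 0)]))

    ub_terms = [Term(_curie("UB", 0), name="bridge anatomical entity")]
    for k in range(cfg.n_concepts):
        if concept_bridged[k]:
            ub_terms.append(
                Term(
                    _curie("UB", 5000 + k),
                    name=f"bridged structure {k}",
                    parents=[_curie("UB", 0)],
                    xrefs=[_curie("AA", k + 1), _curie("AB", k + 1)],
                )
            )
    for f in range(cfg.n_families):  # family anatomies are always bridged
        ub_terms.append(
            Term(
                _curie("UB", 6000 + f),
                name=f"bridged organ {f}",
                parents=[_curie("UB", 0)],
                xrefs=[_curie("AA", cfg.n_concepts + f + 1), _curie("AB", cfg.n_concepts + f + 1)],
            )
        )

    # -- logical definitions ------------------------------------------------------
    def quality_of_concept(k: int) -> str:
        return _curie("QL", (k % _N_QUALITIES) + 1)

    def quality_of_family(f: int) -> str:
        return _curie("QL", (f % _N_QUALITIES) + 1)

    defs_a: dict[str, tuple[str, str]] = {}
    defs_b: dict[str, tuple[str, str]] = {}
    for k in range(cfg.n_concepts):
        if concept_has_def[k]:
            defs_a[concept_term("HP", k)] = (quality_of_concept(k), _curie("AA", k + 1))
            defs_b[concept_term("MP", k)] = (quality_of_concept(k), _curie("AB", k + 1))
    for f in defined_families:
        defs_a[family_term("HP", f)] = (quality_of_family(f), _curie("AA", cfg.n_concepts + f + 1))
        defs_b[family_term("MP", f)] = (quality_of_family(f), _curie("AB", cfg.n_concepts + f + 1))

    # mirror definitions into intersection_of lines so both carriers are exercised
    for terms, defs, rel in ((hp_terms, defs_a, "inheres_in"), (mp_terms, defs_b, "inheres_in")):
        by_id = {t.id: t for t in terms}
        for tid, (q, e) in defs.items():
            by_id[tid].intersection_of = [q, f"{rel} {e}"]

    planted_eq_pairs = sorted(
        [(concept_term("HP", k), concept_term("MP", k))
         for k in range(cfg.n_concepts) if concept_classes[k] == EXACT]
        + [(family_term("HP", f), family_term("MP", f)) for f in defined_families]
    )

    # -- keyword index ------------------------------------------------------------
    keywords: dict[str, list[str]] = {"general phenotype": []}
    for k in range(cfg.n_concepts):
        if concept_classes[k] == KEYWORD_CLASS:
            keywords[f"structure-{k}"] = [concept_term("HP", k), concept_term("MP", k)]

    # -- auxiliary vocabularies ---------------------------------------------------
    def flat_vocab(prefix: str, root_name: str, leaf_names: list[str]) -> list[Term]:
        terms = [Term(_curie(prefix, 0), name=root_name)]
        terms += [
            Term(_curie(prefix, i + 1), name=nm, parents=[_curie(prefix, 0)])
            for i, nm in enumerate(leaf_names)
        ]
        return terms

    go_terms = flat_vocab("GO", "biological process", [f"process {i}" for i in range(30)])
    pw_terms = flat_vocab("PW", "pathway", [f"signaling pathway {i}" for i in range(10)])
    ip_terms = flat_vocab("IP", "protein motif", [f"domain {i}" for i in range(15)])

    # -- genes, coordinates, orthology --------------------------------------------
    genes: list[tuple[str, str, str, str, int, int]] = []
    per_chrom = math.ceil(cfg.genes_per_species / _N_CHROMS)
    for species, prefix in ((SPECIES_A, "HG"), (SPECIES_B, "MG")):
        for i in range(cfg.genes_per_species):
            chrom = f"chr{i % _N_CHROMS + 1}"
            idx = i // _N_CHROMS
            start = idx * cfg.gene_spacing + 1
            genes.append(
                (f"{prefix}{i:05d}", species, f"{prefix[0]}SYM{i}", chrom, start,
                 start + cfg.gene_length - 1)
            )

    ortho_pairs: list[tuple[str, str]] = []
    orthologed: list[int] = []
    for i in range(cfg.genes_per_species):
        if rng_genes.random() < cfg.ortholog_coverage:
            ortho_pairs.append((f"HG{i:05d}", f"MG{i:05d}"))
            orthologed.append(i)
    if len(orthologed) < cfg.n_diseases:
        raise FixtureInfeasibleError(
            f"only {len(orthologed)} orthologed genes for {cfg.n_diseases} diseases"
        )

    # -- diseases -----------------------------------------------------------------
    causal_idx = rng_dis.choice(orthologed, size=cfg.n_diseases, replace=False)
    unmappable_filler_pool = sorted(
        j for j, parent, is_filler in filler_parent
        if not is_filler and parent in undefined_families
    )

    disease_ids = [f"D{d:04d}" for d in range(cfg.n_diseases)]
    disease_features: dict[str, list[dict]] = {}
    planted: dict[str, dict[str, str]] = {}
    unmappable_diseases: list[str] = []
    seen_sets: set[frozenset] = set()

    fam_concepts: dict[int, set[int]] = {f: set() for f in range(cfg.n_families)}
    for k, f in concept_family.items():
        fam_concepts[f].add(k)

    def _matched_by(concepts: frozenset, k: int) -> bool:
        """Would a gene annotated with ``concepts`` fire the feature for concept k?

        Exact/keyword features need the concept itself; inherited features
        match through the whole family (true-path propagation of the
        family-level mapping)."""
        cls = concept_classes[k]
        if cls == INHERITED:
            return bool(concepts & fam_concepts[concept_family[k]])
        return k in concepts

    def _dominates(concepts: frozenset, feature_set: frozenset) -> bool:
        mappable = [k for k in feature_set if concept_classes[k] != UNMAPPABLE]
        return bool(mappable) and all(_matched_by(concepts, k) for k in mappable)

    for d, did in enumerate(disease_ids):
        hg = f"HG{causal_idx[d]:05d}"
        mg = f"MG{causal_idx[d]:05d}"
        planted[did] = {"human_gene": hg, "mouse_gene": mg}
        if rng_dis.random() < cfg.unmappable_disease_fraction and unmappable_filler_pool:
            n_feat = min(cfg.features_per_disease, len(unmappable_filler_pool))
            picks = rng_dis.choice(unmappable_filler_pool, size=n_feat, replace=False)
            disease_features[did] = [
                {"term": hp_id(FILLER_BASE + int(j)), "concept": None,
                 "class": UNMAPPABLE, "mappable": False, "weight": None}
                for j in sorted(int(j) for j in picks)
            ]
            unmappable_diseases.append(did)
            continue
        # feature sets are sampled so no disease's planted concept set
        # dominates another's features under propagated matching; this is
        # what makes the planted gene the unique best candidate at q = 0
        for _attempt in range(1000):
            picks = rng_dis.choice(cfg.n_concepts, size=cfg.features_per_disease, replace=False)
            fs = frozenset(int(k) for k in picks)
            if fs in seen_sets:
                continue
            if any(_dominates(prev, fs) or _dominates(fs, prev) for prev in seen_sets):
                continue
            seen_sets.add(fs)
            break
        else:
            raise FixtureInfeasibleError(
                f"could not sample a non-dominated feature set for disease {did}; "
                "reduce n_diseases or raise n_concepts"
            )
        feats = []
        for k in sorted(fs):
            cls = concept_classes[k]
            entry = {
                "term": concept_term("HP", k), "concept": k, "class": cls,
                "mappable": cls != UNMAPPABLE, "weight": None,
            }
            if cfg.noise_q > 0 and rng_dis.random() < cfg.noise_q and n_fillers > 0:
                j = int(rng_dis.integers(0, n_fillers))
                entry.update(term=hp_id(FILLER_BASE + j), **{"class": "noise"}, mappable=False)
                entry["concept"] = k  # the concept the causal gene still carries
            feats.append(entry)
        disease_features[did] = feats

    # -- annotations --------------------------------------------------------------
    # planted phenotype annotations (protected from the uniqueness pass)
    pheno_ann: dict[str, set[str]] = {f"MG{i:05d}": set() for i in range(cfg.genes_per_species)}
    protected: dict[str, set[str]] = {g: set() for g in pheno_ann}
    for did in disease_ids:
        mg = planted[did]["mouse_gene"]
        for feat in disease_features[did]:
            if feat["concept"] is not None:
                t = concept_term("MP", feat["concept"])
            else:
                t = mp_id(FILLER_BASE + int(feat["term"].split(":")[1]) - FILLER_BASE)
            pheno_ann[mg].add(t)
            protected[mg].add(t)

    # decoy sharing: any mouse gene may carry any concept at the configured rate
    share = rng_annot.random((cfg.genes_per_species, cfg.n_concepts)) < cfg.decoy_share_rate
    for i in range(cfg.genes_per_species):
        g = f"MG{i:05d}"
        for k in np.nonzero(share[i])[0]:
            pheno_ann[g].add(concept_term("MP", int(k)))

    # -- specificity weights and the q=0 planted-rank-1 guarantee ------------------
    term_listings: dict[str, int] = {}
    for did in disease_ids:
        for feat in disease_features[did]:
            term_listings[feat["term"]] = term_listings.get(feat["term"], 0) + 1

    def spec_weight(term: str) -> float:
        f = max(term_listings.get(term, 0) / cfg.n_diseases, 1.0 / (2 * cfg.n_diseases))
        return -math.log2(f)

    method_w = {EXACT: 1.0, INHERITED: 1.0, KEYWORD_CLASS: cfg.keyword_weight}

    # structural descendant sets on the MP side (family -> member terms)
    family_members: dict[int, set[str]] = {
        f: {family_term("MP", f)} for f in range(cfg.n_families)
    }
    for k, f in concept_family.items():
        family_members[f].add(concept_term("MP", k))
    filler_family: dict[int, int] = {}
    for j, parent, is_filler in filler_parent:
        filler_family[j] = filler_family[parent] if is_filler else parent
        family_members[filler_family[j]].add(mp_id(FILLER_BASE + j))

    def feature_match_set(feat: dict) -> set[str] | None:
        cls, k = feat["class"], feat["concept"]
        if cls in (EXACT, KEYWORD_CLASS):
            return {concept_term("MP", k)}
        if cls == INHERITED:
            return family_members[concept_family[k]]
        if cls == "noise":
            j = int(feat["term"].split(":")[1]) - FILLER_BASE
            fam = filler_family[j]
            if fam in defined_families:  # noise filler inherits its family's mapping
                return family_members[fam]
        return None

    expected_scores: dict[str, float | None] = {}
    for did in disease_ids:
        feats = disease_features[did]
        mappable = [f for f in feats if f["mappable"]]
        for f in mappable:
            f["weight"] = spec_weight(f["term"]) * method_w[f["class"]]
        if not mappable:
            expected_scores[did] = None
            continue
        if cfg.noise_q == 0:
            expected_scores[did] = sum(f["weight"] for f in mappable)
        else:
            expected_scores[did] = None

    if cfg.noise_q == 0:
        _enforce_planted_top(
            disease_ids, disease_features, planted, pheno_ann, protected,
            feature_match_set, expected_scores,
        )

    # -- assemble association table ------------------------------------------------
    associations: list[tuple[str, str, str]] = []
    for g in sorted(pheno_ann):
        for t in sorted(pheno_ann[g]):
            associations.append((g, t, "PHENO_B"))
    for did in disease_ids:  # human causal gene mirrors the original description
        hg = planted[did]["human_gene"]
        for feat in disease_features[did]:
            if feat["concept"] is not None:
                associations.append((hg, concept_term("HP", feat["concept"]), "PHENO_A"))

    ds_terms = flat_vocab("DS", "genetic disease", [f"disease {did}" for did in disease_ids])
    for d, did in enumerate(disease_ids):
        associations.append((planted[did]["human_gene"], _curie("DS", d + 1), "DISEASE"))

    for species_prefix in ("HG", "MG"):
        for i in range(cfg.genes_per_species):
            g = f"{species_prefix}{i:05d}"
            for leaf in rng_annot.choice(30, size=cfg.annotations_per_gene, replace=False):
                associations.append((g, _curie("GO", int(leaf) + 1), "GO"))
            if rng_annot.random() < 0.3:
                associations.append((g, _curie("PW", int(rng_annot.integers(1, 11))), "PATHWAY"))
            if rng_annot.random() < 0.4:
                associations.append((g, _curie("IP", int(rng_annot.integers(1, 16))), "MOTIF"))
    associations = sorted(set(associations))

    # -- write everything ----------------------------------------------------------
    header = f"# seed: {cfg.seed}\n"

    def write_ont(fname: str, terms: list[Term], name: str) -> None:
        with open(outdir / fname, "w") as fh:
            fh.write(f"! seed: {cfg.seed}\n")
            write_obo(Ontology(terms, name=name), fh)

    write_ont("phenotype_a.obo", hp_terms, "phenotype-a")
    write_ont("phenotype_b.obo", mp_terms, "phenotype-b")
    write_ont("quality.obo", ql_terms, "quality")
    write_ont("anatomy_a.obo", aa_terms, "anatomy-a")
    write_ont("anatomy_b.obo", ab_terms, "anatomy-b")
    write_ont("bridge.obo", ub_terms, "bridge-anatomy")
    write_ont("go.obo", go_terms, "go-surrogate")
    write_ont("pathway.obo", pw_terms, "pathway-vocab")
    write_ont("motif.obo", ip_terms, "motif-vocab")
    write_ont("disease_vocab.obo", ds_terms, "disease-vocab")

    for fname, defs in (("logical_defs_a.tsv", defs_a), ("logical_defs_b.tsv", defs_b)):
        with open(outdir / fname, "w") as fh:
            fh.write(header + "term_id\tquality_id\tentity_ids\n")
            for tid in sorted(defs):
                q, e = defs[tid]
                fh.write(f"{tid}\t{q}\t{e}\n")

    with open(outdir / "keywords.yaml", "w") as fh:
        fh.write(header)
        yaml.safe_dump(keywords, fh, sort_keys=True)

    with open(outdir / "genes.tsv", "w") as fh:
        fh.write(header + "gene_id\tspecies\tsymbol\tchrom\tstart\tend\n")
        for row in sorted(genes):
            fh.write("\t".join(str(c) for c in row) + "\n")

    with open(outdir / "associations.tsv", "w") as fh:
        fh.write(header + "gene_id\tterm_id\tnamespace\n")
        for row in associations:
            fh.write("\t".join(row) + "\n")

    with open(outdir / "orthology.tsv", "w") as fh:
        fh.write(header + "gene_id_1\tgene_id_2\n")
        for a, b in sorted(ortho_pairs):
            fh.write(f"{a}\t{b}\n")

    with open(outdir / "diseases.tsv", "w") as fh:
        fh.write(header + "disease_id\tterm_id\tfrequency\n")
        for did in disease_ids:
            for feat in disease_features[did]:
                fh.write(f"{did}\t{feat['term']}\t\n")

    with open(outdir / "fixture.yaml", "w") as fh:
        fh.write(header)
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)

    ledger = FixtureLedger(
        planted=planted,
        disease_features=disease_features,
        expected_scores=expected_scores,
        concept_classes=concept_classes,
        concept_family=concept_family,
        planted_eq_pairs=planted_eq_pairs,
        unmappable_diseases=unmappable_diseases,
        counts={
            "genes": len(genes),
            "associations": len(associations),
            "orthology_pairs": len(ortho_pairs),
            "diseases": cfg.n_diseases,
        },
    )
    (outdir / "ledger.json").write_text(ledger.to_json())
    return ledger


def _enforce_planted_top(
    disease_ids, disease_features, planted, pheno_ann, protected,
    feature_match_set, expected_scores,
) -> None:
    """At q=0, guarantee by construction that no decoy matches a weight sum
    ≥ the planted gene's: remove non-protected decoy annotations until every
    rival scores strictly less. Protected (planted) annotations are never
    touched, so other diseases' guarantees survive."""
    for did in disease_ids:
        if expected_scores.get(did) is None:
            continue
        feats = [f for f in disease_features[did] if f["mappable"]]
        match_sets = [(feature_match_set(f), f["weight"]) for f in feats]
        target = expected_scores[did]
        mg_star = planted[did]["mouse_gene"]
        for g in sorted(pheno_ann):
            if g == mg_star:
                continue
            while True:
                score = 0.0
                removable: str | None = None
                for ms, w in match_sets:
                    hit = pheno_ann[g] & ms
                    if hit:
                        score += w
                        if removable is None:
                            free = sorted(hit - protected[g])
                            if free:
                                removable = free[0]
                if score < target - 1e-9:  # strictly below: ties count as rivals
                    break
                if removable is None:
                    raise FixtureInfeasibleError(
                        f"gene {g} dominates the planted gene for {did} via protected annotations"
                    )
                pheno_ann[g].discard(removable)


# -- loading a generated universe -------------------------------------------------


@dataclass
class FixtureUniverse:
    """Everything needed to run the pipeline on a generated universe."""

    ontologies: dict[str, Ontology]     # keyed by annotation namespace
    quality: Ontology
    anatomy_a: Ontology
    anatomy_b: Ontology
    bridge_ont: Ontology
    store: AnnotationStore
    mapper: EqMapper
    diseases: list[DiseaseDescription]
    config: dict
    ledger: FixtureLedger

    @property
    def context(self) -> QueryContext:
        return QueryContext(self.store, self.ontologies)

    def cases(self) -> list[tuple[DiseaseDescription, str]]:
        """(disease, true human gene) pairs for benchmarking."""
        return [(d, self.ledger.planted[d.disease_id]["human_gene"]) for d in self.diseases]


def load_universe(outdir: str | Path) -> FixtureUniverse:
    """Parse a generated universe back through the package's own readers."""
    from .eq_mapping import LogicalDefinition, build_bridge

    outdir = Path(outdir)

    def ont(fname: str, name: str) -> Ontology:
        with open(outdir / fname) as fh:
            return parse_obo(fh, name=name)

    hp = ont("phenotype_a.obo", "phenotype-a")
    mp = ont("phenotype_b.obo", "phenotype-b")
    ql = ont("quality.obo", "quality")
    aa = ont("anatomy_a.obo", "anatomy-a")
    ab = ont("anatomy_b.obo", "anatomy-b")
    ub = ont("bridge.obo", "bridge-anatomy")
    ontologies = {
        "PHENO_A": hp,
        "PHENO_B": mp,
        "GO": ont("go.obo", "go-surrogate"),
        "PATHWAY": ont("pathway.obo", "pathway-vocab"),
        "MOTIF": ont("motif.obo", "motif-vocab"),
        "DISEASE": ont("disease_vocab.obo", "disease-vocab"),
    }

    with open(outdir / "logical_defs_a.tsv") as fh:
        tsv_a = definitions_from_tsv(fh)
    with open(outdir / "logical_defs_b.tsv") as fh:
        tsv_b = definitions_from_tsv(fh)
    defs_a = merge_definitions(definitions_from_ontology(hp), tsv_a)
    defs_b = merge_definitions(definitions_from_ontology(mp), tsv_b)

    with open(outdir / "keywords.yaml") as fh:
        keywords = KeywordIndex.from_yaml(fh, hp, mp)

    bridge = build_bridge(aa, ab, ub)

    config = yaml.safe_load((outdir / "fixture.yaml").read_text())
    mapper = EqMapper(
        source_ont=hp, target_ont=mp, quality_ont=ql,
        source_defs=defs_a, target_defs=defs_b,
        bridge=bridge, keywords=keywords,
        keyword_weight=config.get("keyword_weight", 0.5),
    )

    with open(outdir / "genes.tsv") as g, open(outdir / "associations.tsv") as a, \
            open(outdir / "orthology.tsv") as o:
        store = load_store(g, a, o, ontologies)

    with open(outdir / "diseases.tsv") as fh:
        diseases = load_diseases(fh)

    ledger = FixtureLedger.from_json((outdir / "ledger.json").read_text())
    return FixtureUniverse(
        ontologies=ontologies, quality=ql, anatomy_a=aa, anatomy_b=ab, bridge_ont=ub,
        store=store, mapper=mapper, diseases=diseases, config=config, ledger=ledger,
    )
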