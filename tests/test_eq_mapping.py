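"""Entity–Quality matching, the anatomy bridge and the mapping cascade."""

import io

import numpy as np
import pytest

from phenoprio.eq_mapping import (
    EQ_EXACT,
    EQ_INHERITED,
    KEYWORD,
    AnatomyBridge,
    EqMapper,
    KeywordIndex,
    LogicalDefinition,
    TermMapping,
    build_bridge,
    definitions_from_ontology,
    definitions_from_tsv,
    eq_match,
    merge_definitions,
)
from phenoprio.ontology import Ontology, Term


def flat_ont(prefix, n, extra_parents=None):
    terms = [Term(f"{prefix}:0", name=f"{prefix} root")]
    terms += [
        Term(f"{prefix}:{i}", name=f"{prefix} {i}",
             parents=(extra_parents or {}).get(i, [f"{prefix}:0"]))
        for i in range(1, n + 1)
    ]
    return Ontology(terms)


@pytest.fixture
def quality_ont():
    # Q:2 is_a Q:1 so ancestor/descendant compatibility can be exercised
    return flat_ont("Q", 4, extra_parents={2: ["Q:1"]})


def bridge_of(pairs):
    return AnatomyBridge(pairs)


class TestBridge:
    def test_single_bridge_term_pairs_its_two_sides(self):
        aa, ab = flat_ont("FA", 2), flat_ont("MA", 2)
        ub = Ontology([
            Term("U:0", name="u root"),
            Term("U:1", name="u1", parents=["U:0"], xrefs=["FA:1", "MA:2"]),
        ])
        bridge = build_bridge(aa, ab, ub)
        assert bridge.pairs == {("FA:1", "MA:2")}
        assert bridge.bridged("FA:1", "MA:2") and bridge.bridged("MA:2", "FA:1")

    def test_no_xrefs_means_empty_bridge(self):
        aa, ab = flat_ont("FA", 1), flat_ont("MA", 1)
        assert len(build_bridge(aa, ab, flat_ont("U", 3))) == 0

    def test_unknown_prefix_xref_warns_but_is_ignored(self, caplog):
        aa, ab = flat_ont("FA", 1), flat_ont("MA", 1)
        ub = Ontology([Term("U:0", name="r", xrefs=["ZZ:9", "FA:1", "MA:1"])])
        with caplog.at_level("WARNING"):
            bridge = build_bridge(aa, ab, ub)
        assert bridge.pairs == {("FA:1", "MA:1")}
        assert "ZZ:9" in caplog.text

    def test_random_bridge_matches_exhaustive_triple_enumeration(self):
        rng = np.random.default_rng(7)
        aa, ab = flat_ont("FA", 30), flat_ont("MA", 30)
        terms = [Term("U:0", name="u root")]
        for i in range(1, 101):
            xrefs = [f"FA:{rng.integers(1, 31)}" for _ in range(rng.integers(0, 3))]
            xrefs += [f"MA:{rng.integers(1, 31)}" for _ in range(rng.integers(0, 3))]
            terms.append(Term(f"U:{i}", name=f"u{i}", parents=["U:0"], xrefs=xrefs))
        bridge = build_bridge(aa, ab, Ontology(terms))
        expected = set()
        for t in terms:  # oracle: nested loop over (bridge term, xrefA, xrefB)
            for xa in t.xrefs:
                for xb in t.xrefs:
                    if xa.startswith("FA") and xb.startswith("MA"):
                        expected.add((xa, xb))
        assert bridge.pairs == expected


class TestEqMatch:
    def test_identical_quality_bridged_entities(self, quality_ont):
        da = LogicalDefinition("P:1", "Q:1", ("FA:1",))
        db = LogicalDefinition("M:1", "Q:1", ("MA:1",))
        assert eq_match(da, db, quality_ont, bridge_of([("FA:1", "MA:1")]))

    def test_unrelated_qualities_fail_even_when_bridged(self, quality_ont):
        da = LogicalDefinition("P:1", "Q:3", ("FA:1",))
        db = LogicalDefinition("M:1", "Q:4", ("MA:1",))
        assert not eq_match(da, db, quality_ont, bridge_of([("FA:1", "MA:1")]))

    def test_ancestor_quality_is_compatible_but_sibling_is_not(self, quality_ont):
        bridge = bridge_of([("FA:1", "MA:1")])
        specialized = LogicalDefinition("P:1", "Q:2", ("FA:1",))  # Q:2 is_a Q:1
        general = LogicalDefinition("M:1", "Q:1", ("MA:1",))
        sibling = LogicalDefinition("M:2", "Q:3", ("MA:1",))
        assert eq_match(specialized, general, quality_ont, bridge)
        assert eq_match(general, specialized, quality_ont, bridge)  # symmetry
        assert not eq_match(specialized, sibling, quality_ont, bridge)

    def test_multi_entity_matching_is_existential(self, quality_ont):
        da = LogicalDefinition("P:1", "Q:1", ("FA:1", "FA:2"))
        db = LogicalDefinition("M:1", "Q:1", ("MA:9",))
        assert eq_match(da, db, quality_ont, bridge_of([("FA:2", "MA:9")]))
        assert not eq_match(da, db, quality_ont, bridge_of([("FA:3", "MA:9")]))


class TestDefinitionSources:
    def test_tsv_sidecar_wins_over_intersection_lines(self):
        ont = Ontology([
            Term("P:0", name="root"),
            Term("P:1", name="one", parents=["P:0"],
                 intersection_of=["Q:1", "inheres_in FA:1"]),
        ])
        from_obo = definitions_from_ontology(ont)
        assert from_obo["P:1"] == LogicalDefinition("P:1", "Q:1", ("FA:1",))
        tsv = definitions_from_tsv(io.StringIO(
            "term_id\tquality_id\tentity_ids\nP:1\tQ:2\tFA:7,FA:8\n"
        ))
        merged = merge_definitions(from_obo, tsv)
        assert merged["P:1"] == LogicalDefinition("P:1", "Q:2", ("FA:7", "FA:8"))


def make_cascade_mapper(quality_ont, keywords=None):
    """Source chain P:root <- P:parent <- P:child; target M:1, M:2."""
    src = Ontology([
        Term("P:0", name="src root"),
        Term("P:1", name="parent pheno", parents=["P:0"]),
        Term("P:2", name="child pheno", parents=["P:1"]),
        Term("P:3", name="orphan pheno", parents=["P:0"]),
    ])
    tgt = Ontology([
        Term("M:0", name="tgt root"),
        Term("M:1", name="tgt one", parents=["M:0"]),
        Term("M:2", name="tgt two", parents=["M:0"]),
    ])
    src_defs = {"P:1": LogicalDefinition("P:1", "Q:1", ("FA:1",))}
    tgt_defs = {"M:1": LogicalDefinition("M:1", "Q:1", ("MA:1",))}
    kw = KeywordIndex(keywords) if keywords else None
    return EqMapper(
        source_ont=src, target_ont=tgt, quality_ont=quality_ont,
        source_defs=src_defs, target_defs=tgt_defs,
        bridge=bridge_of([("FA:1", "MA:1")]), keywords=kw,
    )


class TestCascade:
    def test_own_definition_yields_eq_exact(self, quality_ont):
        mapper = make_cascade_mapper(quality_ont)
        assert mapper.map_term("P:1") == [TermMapping("P:1", "M:1", EQ_EXACT, 1.0)]

    def test_undefined_term_inherits_closest_annotated_parent(self, quality_ont):
        mapper = make_cascade_mapper(quality_ont)
        [m] = mapper.map_term("P:2")
        assert (m.target, m.method, m.weight) == ("M:1", EQ_INHERITED, 1.0)

    def test_keyword_fallback_is_down_weighted(self, quality_ont):
        mapper = make_cascade_mapper(
            quality_ont, {"muscle": ({"P:3"}, {"M:1", "M:2"})}
        )
        mappings = mapper.map_term("P:3")
        assert [(m.target, m.method, m.weight) for m in mappings] == [
            ("M:1", KEYWORD, 0.5), ("M:2", KEYWORD, 0.5),
        ]

    def test_exhausted_cascade_returns_empty(self, quality_ont):
        assert make_cascade_mapper(quality_ont).map_term("P:3") == []

    def test_results_never_mix_methods(self, small_universe):
        for term in small_universe.ontologies["PHENO_A"].terms:
            methods = {m.method for m in small_universe.mapper.map_term(term)}
            assert len(methods) <= 1


def test_stage1_recovers_all_and_only_planted_pairs(small_universe):
    """Exact E-Q recovery on the fixture's planted correspondences."""
    found = set()
    for term in small_universe.ontologies["PHENO_A"].terms:
        for m in small_universe.mapper.map_term(term):
            if m.method == EQ_EXACT:
                found.add((m.source, m.target))
    assert found == set(map(tuple, small_universe.ledger.planted_eq_pairs))


def test_concept_mapping_method_follows_planted_class(small_universe):
    from phenoprio.fixtures import concept_term

    expected_method = {"exact": EQ_EXACT, "inherited": EQ_INHERITED, "keyword": KEYWORD}
    for k, cls in small_universe.ledger.concept_classes.items():
        mappings = small_universe.mapper.map_term(concept_term("HP", k))
        if cls == "unmappable":
            assert mappings == []
        else:
            assert {m.method for m in mappings} == {expected_method[cls]}
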