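"""Specificity weighting, query-set construction and candidate ranking."""

import io
import math

import pytest

from phenoprio.errors import UnanalyzableDiseaseError
from phenoprio.fixtures import concept_term
from phenoprio.ontology import Ontology, Term
from phenoprio.prioritizer import (
    DiseaseDescription,
    disease_to_queryset,
    feature_weights,
    load_diseases,
    prioritize,
)


@pytest.fixture(scope="module")
def weights(small_universe):
    return feature_weights(small_universe.diseases, small_universe.ontologies["PHENO_A"])


class TestFeatureWeights:
    def test_ubiquitous_term_has_zero_weight(self):
        ont = Ontology([Term("P:1", name="root"), Term("P:2", name="leaf", parents=["P:1"])])
        corpus = [DiseaseDescription(f"d{i}", [("P:2", None)]) for i in range(4)]
        w = feature_weights(corpus, ont)
        # every disease is annotated below the root, so f(root) = 1
        assert w.weight("P:1") == pytest.approx(0.0)

    def test_half_corpus_term_has_weight_one(self):
        ont = Ontology([Term("P:1", name="root"),
                        Term("P:2", name="a", parents=["P:1"]),
                        Term("P:3", name="b", parents=["P:1"])])
        corpus = [DiseaseDescription("d1", [("P:2", None)]),
                  DiseaseDescription("d2", [("P:3", None)])]
        w = feature_weights(corpus, ont)
        assert w.weight("P:2") == pytest.approx(1.0)

    def test_unseen_term_clamped_at_half_inverse_corpus(self, small_universe, weights):
        unseen = "HP:0001000"  # category terms never appear as features... unless propagated
        d = len(small_universe.diseases)
        expected_floor = -math.log2(1 / (2 * d))
        leafish = "HP:0004000"
        if weights.frequency(leafish) == 1 / (2 * d):
            assert weights.weight(leafish) == pytest.approx(expected_floor)
        assert weights.weight(unseen) <= expected_floor

    def test_matches_per_disease_descendant_oracle(self, small_universe, weights):
        ont = small_universe.ontologies["PHENO_A"]
        corpus = small_universe.diseases
        for term in [concept_term("HP", k) for k in range(0, 40, 5)] + ["HP:0002003"]:
            below = ont.descendants(term, reflexive=True)
            count = sum(1 for d in corpus if any(t in below for t in d.terms))
            f = max(count / len(corpus), 1 / (2 * len(corpus)))
            assert weights.weight(term) == pytest.approx(-math.log2(f))


class TestDiseaseToQueryset:
    def test_weights_are_specificity_times_method_products(self, small_universe, weights):
        led = small_universe.ledger
        method_w = {"exact": 1.0, "inherited": 1.0, "keyword": 0.5}
        for disease in small_universe.diseases[:10]:
            dqs = disease_to_queryset(disease, small_universe.mapper, weights)
            feats = [f for f in led.disease_features[disease.disease_id] if f["mappable"]]
            assert len(dqs.features) == len(feats)
            for fq, feat in zip(dqs.features, feats):
                assert fq.term == feat["term"]
                expected = weights.weight(fq.term) * method_w[feat["class"]]
                assert fq.weight == pytest.approx(expected)

    def test_keyword_feature_weight_is_halved(self, small_universe, weights):
        led = small_universe.ledger
        kw_concepts = [k for k, c in led.concept_classes.items() if c == "keyword"]
        assert kw_concepts, "fixture should contain keyword-stage concepts"
        term = concept_term("HP", kw_concepts[0])
        d = DiseaseDescription("synthetic", [(term, None)])
        dqs = disease_to_queryset(d, small_universe.mapper, weights)
        assert dqs.features[0].method_weight == 0.5
        assert dqs.features[0].weight == pytest.approx(0.5 * weights.weight(term))

    def test_unmappable_features_are_reported_not_fatal(self, small_universe, weights):
        led = small_universe.ledger
        dead = [k for k, c in led.concept_classes.items() if c == "unmappable"]
        assert dead, "fixture should contain unmappable concepts"
        mappable = concept_term("HP", next(k for k, c in led.concept_classes.items()
                                           if c == "exact"))
        d = DiseaseDescription("synthetic", [(concept_term("HP", dead[0]), None),
                                             (mappable, None)])
        dqs = disease_to_queryset(d, small_universe.mapper, weights)
        assert dqs.dropped == [concept_term("HP", dead[0])]
        assert len(dqs.queries) == 1


class TestPrioritize:
    def test_planted_gene_ranks_first_with_maximal_score(self, small_universe, weights):
        led = small_universe.ledger
        for disease in small_universe.diseases:
            if led.expected_scores[disease.disease_id] is None:
                continue
            res = prioritize(disease, small_universe.context, small_universe.mapper,
                             weights, model_species="mouse")
            mg = led.planted[disease.disease_id]["mouse_gene"]
            assert res.ranked[0].gene == mg
            assert res.rank_of(mg, worst_tie=True) == 1
            assert res.ranked[0].score == pytest.approx(
                led.expected_scores[disease.disease_id]
            )

    def test_region_constraint_shrinks_universe_but_keeps_scores(
        self, small_universe, weights
    ):
        led = small_universe.ledger
        store = small_universe.store
        disease = next(d for d in small_universe.diseases
                       if led.expected_scores[d.disease_id] is not None)
        hg = led.planted[disease.disease_id]["human_gene"]
        g = store.genes[hg]
        region = (g.chrom, max(1, g.start - 500_000), g.end + 500_000)
        full = prioritize(disease, small_universe.context, small_universe.mapper,
                          weights, model_species="mouse")
        constrained = prioritize(disease, small_universe.context, small_universe.mapper,
                                 weights, model_species="mouse",
                                 region=region, region_species="human")
        assert constrained.universe_size <= full.universe_size
        full_scores = {c.gene: c.score for c in full.ranked}
        for c in constrained.ranked:  # scores identical, only the universe shrank
            assert c.score == pytest.approx(full_scores[c.gene])
        mg = led.planted[disease.disease_id]["mouse_gene"]
        assert constrained.rank_of(mg, worst_tie=True) <= full.rank_of(mg, worst_tie=True)

    def test_score_decomposes_into_matched_feature_weights(self, small_universe, weights):
        disease = small_universe.diseases[0]
        res = prioritize(disease, small_universe.context, small_universe.mapper,
                         weights, model_species="mouse")
        for c in res.ranked[:20]:
            recomputed = sum(res.features[i].weight for i in c.matched)
            assert c.score == pytest.approx(recomputed)

    def test_fully_unmappable_disease_is_explicit_outcome(self, small_universe, weights):
        led = small_universe.ledger
        assert led.unmappable_diseases, "fixture should plant unmappable diseases"
        disease = next(d for d in small_universe.diseases
                       if d.disease_id in led.unmappable_diseases)
        with pytest.raises(UnanalyzableDiseaseError):
            prioritize(disease, small_universe.context, small_universe.mapper,
                       weights, model_species="mouse")

    def test_region_genes_without_orthologs_are_unscorable(self, small_universe, weights):
        led = small_universe.ledger
        store = small_universe.store
        orphan = next(g for g in sorted(store.genes_of_species("human"))
                      if not store.ortholog_partners(g))
        disease = next(d for d in small_universe.diseases
                       if led.expected_scores[d.disease_id] is not None)
        g = store.genes[orphan]
        res = prioritize(disease, small_universe.context, small_universe.mapper,
                         weights, model_species="mouse",
                         region=(g.chrom, g.start, g.end), region_species="human")
        assert orphan in res.unscorable


def test_load_diseases_parses_frequency_qualifiers():
    text = ("disease_id\tterm_id\tfrequency\n"
            "D1\tHP:0003000\tfrequent\n"
            "D1\tHP:0003001\t\n"
            "D2\tHP:0003002\toccasional\n")
    diseases = load_diseases(io.StringIO(text))
    assert [d.disease_id for d in diseases] == ["D1", "D2"]
    assert diseases[0].features == [("HP:0003000", "frequent"), ("HP:0003001", None)]
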