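"""Query grammar, set semantics, weighted ranking and their oracles."""

import numpy as np
import pytest

from phenoprio.errors import AtomResolutionError, QueryParseError
from phenoprio.query_engine import (
    And,
    Atom,
    Not,
    Or,
    WeightedQuerySet,
    annotation_distribution,
    evaluate,
    parse_query,
    rank,
    serialize_query,
)

NOTCH_STYLE = (
    '[SPECIES("mouse") and PATHWAY("signaling pathway 1") '
    'and GO("process 2")] not IP("domain 3")'
)


class TestParser:
    def test_complex_query_with_postfix_not(self):
        ast = parse_query(NOTCH_STYLE)
        assert isinstance(ast, And)
        inner, negation = ast.children
        assert isinstance(inner, And)
        assert [a.kind for a in inner.children] == ["SPECIES", "PATHWAY", "GO"]
        assert isinstance(negation, Not) and negation.child == Atom("IP", "domain 3")

    def test_single_atom(self):
        assert parse_query('GO("x")') == Atom("GO", "x")

    def test_precedence_not_over_and_over_or(self):
        ast = parse_query('GO("a") or GO("b") and not GO("c")')
        assert isinstance(ast, Or)
        right = ast.children[1]
        assert isinstance(right, And) and isinstance(right.children[1], Not)

    def test_curly_quotes_accepted(self):
        assert parse_query("GO(“fancy label”)") == Atom("GO", "fancy label")

    @pytest.mark.parametrize("bad", [
        "", "   ", 'GO("unterminated)', '[GO("a") and GO("b")',
        'FROB("x")', 'GO("")', 'GO("a") banana GO("b")',
    ])
    def test_malformed_queries_raise_parse_error(self, bad):
        with pytest.raises(QueryParseError):
            parse_query(bad)

    @pytest.mark.parametrize("seed", range(4))
    def test_serialize_parse_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            ast = random_ast(rng, depth=3)
            assert parse_query(serialize_query(ast)) == ast


def random_ast(rng, depth, curies=None):
    """Random AST over CURIE-labelled atoms (CURIEs resolve unambiguously)."""
    curies = curies or {
        "GO": [f"GO:{i:07d}" for i in range(1, 20)],
        "PHENO": [f"MP:{3000 + k:07d}" for k in range(20)],
        "IP": [f"IP:{i:07d}" for i in range(1, 10)],
        "PATHWAY": [f"PW:{i:07d}" for i in range(1, 8)],
    }
    if depth == 0 or rng.random() < 0.35:
        r = rng.random()
        if r < 0.12:
            return Atom("SPECIES", rng.choice(["human", "mouse"]))
        if r < 0.2:
            a, b = sorted(rng.integers(1, 2_000_000, size=2))
            return Atom("REGION", f"chr{rng.integers(1, 6)}:{a}-{b}")
        kind = rng.choice(sorted(curies))
        return Atom(kind, str(rng.choice(curies[kind])))
    op = rng.random()
    if op < 0.25:
        return Not(random_ast(rng, depth - 1, curies))
    cls = And if op < 0.65 else Or
    n = int(rng.integers(2, 4))
    return cls(tuple(random_ast(rng, depth - 1, curies) for _ in range(n)))


def gene_predicate(ast, gene, ctx):
    """Independent oracle: evaluate the query as a per-gene predicate using
    upward annotation closure instead of downward term propagation."""
    store, onts = ctx.store, ctx.ontologies
    if isinstance(ast, Atom):
        if ast.kind == "SPECIES":
            return store.genes[gene].species == ast.label
        if ast.kind == "REGION":
            chrom, span = ast.label.split(":")
            a, b = map(int, span.split("-"))
            g = store.genes[gene]
            return g.has_coordinates and g.chrom == chrom and g.start <= b and g.end >= a
        from phenoprio.query_engine import KIND_NAMESPACES

        for ns in KIND_NAMESPACES[ast.kind]:
            ont = onts.get(ns)
            if ont is None or ast.label not in ont:
                continue
            for t in store.terms_of_gene(gene, ns):
                if t == ast.label or ast.label in ont.ancestors(t):
                    return True
        return False
    if isinstance(ast, Not):
        return not gene_predicate(ast.child, gene, ctx)
    results = [gene_predicate(c, gene, ctx) for c in ast.children]
    return all(results) if isinstance(ast, And) else any(results)


class TestEvaluate:
    def test_or_is_no_smaller_than_either_branch(self, small_universe):
        ctx = small_universe.context
        a, b = Atom("GO", "GO:0000001"), Atom("PHENO", "MP:0003001")
        union = evaluate(Or((a, b)), ctx)
        assert len(union) >= max(len(evaluate(a, ctx)), len(evaluate(b, ctx)))
        assert union == evaluate(a, ctx) | evaluate(b, ctx)

    def test_noncontradiction(self, small_universe):
        x = Atom("GO", "GO:0000002")
        assert evaluate(And((x, Not(x))), small_universe.context) == set()

    def test_unresolvable_atom_names_the_atom(self, small_universe):
        with pytest.raises(AtomResolutionError, match="no such label"):
            evaluate(Atom("GO", "no such label"), small_universe.context)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_gene_predicate_oracle(self, small_universe, seed):
        ctx = small_universe.context
        rng = np.random.default_rng(seed)
        for _ in range(30):
            ast = random_ast(rng, depth=3)
            expected = {g for g in ctx.store.genes if gene_predicate(ast, g, ctx)}
            assert evaluate(ast, ctx) == expected

    def test_de_morgan(self, small_universe):
        ctx = small_universe.context
        rng = np.random.default_rng(42)
        for _ in range(20):
            a, b = random_ast(rng, 2), random_ast(rng, 2)
            assert evaluate(Not(And((a, b))), ctx) == evaluate(Or((Not(a), Not(b))), ctx)

    def test_monotonicity_of_or_and_and(self, small_universe):
        ctx = small_universe.context
        rng = np.random.default_rng(8)
        for _ in range(20):
            base, extra = random_ast(rng, 2), random_ast(rng, 2)
            s = evaluate(base, ctx)
            assert evaluate(Or((base, extra)), ctx) >= s
            assert evaluate(And((base, extra)), ctx) <= s


class TestRank:
    def test_gene_meeting_both_conditions_outranks_single_match(self, small_universe):
        ctx = small_universe.context
        qs = WeightedQuerySet([
            (Atom("SPECIES", "mouse"), 1.0),
            (Atom("PHENO", "MP:0002000"), 1.0),
        ])
        ranked = rank(qs, ctx)
        both = [c for c in ranked if len(c.matched) == 2]
        one = [c for c in ranked if len(c.matched) == 1]
        assert both and one
        assert max(c.score for c in one) < min(c.score for c in both)
        assert ranked.index(both[0]) < ranked.index(one[0])

    def test_single_query_ranking_is_id_ordered_equal_scores(self, small_universe):
        ctx = small_universe.context
        qs = WeightedQuerySet([(Atom("GO", "GO:0000003"), 2.0)])
        ranked = rank(qs, ctx)
        assert [c.gene for c in ranked] == sorted(evaluate(qs.entries[0][0], ctx))
        assert {c.score for c in ranked} == {2.0}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_scoring(self, small_universe, seed):
        ctx = small_universe.context
        rng = np.random.default_rng(seed)
        entries = [(random_ast(rng, 2), float(rng.uniform(0.1, 3))) for _ in range(5)]
        qs = WeightedQuerySet(entries)
        ranked = {c.gene: c for c in rank(qs, ctx)}
        sets = [evaluate(a, ctx) for a, _ in entries]
        for g in ctx.store.genes:
            expected = sum(w for s, (_, w) in zip(sets, entries) if g in s)
            if expected > 0:
                c = ranked[g]
                assert c.score == pytest.approx(expected)
                assert c.score == pytest.approx(
                    sum(entries[i][1] for i in c.matched)
                )
            else:
                assert g not in ranked

    def test_uniform_weights_reproduce_conditions_met_ordering(self, small_universe):
        ctx = small_universe.context
        rng = np.random.default_rng(12)
        qs = WeightedQuerySet([(random_ast(rng, 2), 1.0) for _ in range(4)])
        for c in rank(qs, ctx):
            assert c.score == len(c.matched)


class TestAnnotationDistribution:
    def test_identical_queries_fully_overlap(self, small_universe):
        ctx = small_universe.context
        a = Atom("GO", "GO:0000004")
        qs = WeightedQuerySet([(a, 1.0), (a, 5.0)])
        counts, overlap = annotation_distribution(qs, ctx)
        assert counts[0] == counts[1] == overlap[0, 1] == overlap[0, 0]

    def test_random_set_matches_pairwise_intersections(self, small_universe):
        ctx = small_universe.context
        rng = np.random.default_rng(21)
        entries = [(random_ast(rng, 2), 1.0) for _ in range(4)]
        counts, overlap = annotation_distribution(WeightedQuerySet(entries), ctx)
        sets = [evaluate(a, ctx) for a, _ in entries]
        for i in range(4):
            assert counts[i] == len(sets[i])
            for j in range(4):
                assert overlap[i, j] == len(sets[i] & sets[j])
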