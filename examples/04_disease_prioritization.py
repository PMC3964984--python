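"""Prioritize candidate genes for a disease, with and without a region
constraint.

A disease described by human phenotype terms is translated into weighted
mouse-phenotype queries (specificity weight x mapping-method weight) and
candidate mouse genes are ranked. Supplying the linkage interval around the
true gene shrinks the candidate universe, mimicking how mapping information
sharpens predictions.
"""

from tempfile import TemporaryDirectory

from phenoprio import FixtureConfig, generate, load_universe
from phenoprio.prioritizer import feature_weights, prioritize

with TemporaryDirectory() as tmp:
    generate(FixtureConfig(seed=4, n_diseases=15, genes_per_species=80), tmp)
    uni = load_universe(tmp)
    weights = feature_weights(uni.diseases, uni.ontologies["PHENO_A"])

    disease = next(d for d in uni.diseases
                   if uni.ledger.expected_scores[d.disease_id] is not None)
    truth = uni.ledger.planted[disease.disease_id]
    print(f"disease {disease.disease_id}: features {', '.join(disease.terms)}")
    print(f"planted causal gene: {truth['human_gene']} (mouse ortholog {truth['mouse_gene']})\n")

    res = prioritize(disease, uni.context, uni.mapper, weights, model_species="mouse")
    print(f"unconstrained search over {res.universe_size} mouse genes:")
    for i, c in enumerate(res.ranked[:5], 1):
        print(f"  {i}. {c.gene}  score {c.score:.3f}  ({len(c.matched)} features matched)")

    g = uni.store.genes[truth["human_gene"]]
    region = (g.chrom, max(1, g.start - 400_000), g.end + 400_000)
    res_region = prioritize(disease, uni.context, uni.mapper, weights,
                            model_species="mouse", region=region, region_species="human")
    print(f"\nconstrained to {region[0]}:{region[1]}-{region[2]} "
          f"({res_region.universe_size} candidates):")
    for i, c in enumerate(res_region.ranked[:5], 1):
        print(f"  {i}. {c.gene}  score {c.score:.3f}")
    if res_region.unscorable:
        print(f"  unscorable region genes (no ortholog / no phenotype): "
              f"{', '.join(res_region.unscorable)}")

print(
    "\nScores are identical in both runs — the region only shrinks the"
    "\nuniverse — so the true gene can never rank worse once the interval"
    "\ncontains it. Features that map only via keyword contribute at half"
    "\nweight; features that map nowhere are dropped and reported."
)
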