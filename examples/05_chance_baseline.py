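"""Benchmark planted disease genes against the analytic chance expectation.

Every disease's true gene is searched inside windows centred on it; the
fraction of cases ranked in the top k is compared with the expectation
under uniformly random ordering of each region's candidates:
E_i = sum over regions with n_j >= i of 1/n_j.
"""

from tempfile import TemporaryDirectory

from phenoprio import FixtureConfig, generate, load_universe
from phenoprio.evaluation import rank_summary, run_benchmark
from phenoprio.prioritizer import feature_weights

with TemporaryDirectory() as tmp:
    # a noisy universe: clinical descriptions are imperfect, so ranking is hard
    generate(FixtureConfig(seed=4, n_diseases=60, genes_per_species=200, noise_q=0.4), tmp)
    uni = load_universe(tmp)
    weights = feature_weights(uni.diseases, uni.ontologies["PHENO_A"])

    windows = [1e6, 1e7]  # ~10 and ~100 genes at 100 kb spacing
    tables = run_benchmark(uni.cases(), uni.context, uni.mapper, weights,
                           windows, "mouse", "human")
    for w in windows:
        table = tables[w]
        print(f"window {w:g} bp: {len(table.analyzable)} analyzable cases, "
              f"{table.unanalyzable_fraction:.0%} unanalyzable")
        df = rank_summary(table, [1, 5, 10])
        for row in df.itertuples(index=False):
            print(f"  top-{row.k:<3} observed {row.fraction_observed:6.1%}   "
                  f"chance {row.fraction_chance:6.1%}")
        print()

print(
    "Observed fractions far above the chance column show the phenotype"
    "\nsignal is doing the work; the narrow window beats the wide one because"
    "\nfewer decoys share the disease features. Unanalyzable cases (no"
    "\nmappable feature) are excluded from the fractions but always reported."
)
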