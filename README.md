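# phenoprio

Cross-species phenotype-term mapping, weighted Boolean gene queries, and
disease-to-candidate-gene prioritization — with the analytic chance
baseline needed to judge how good a ranking actually is.

## The problem

Human genetic diseases are described by clinical phenotype terms, but most
of the phenotype evidence linking genes to phenotypes comes from model
organisms, above all mouse knockouts. Exploiting that evidence requires
three things this package provides:

1. **Cross-species term mapping.** A human phenotype term and a mouse
   phenotype term are related through their *entity–quality* (E-Q) logical
   definitions: each term decomposes into a quality ("how" — e.g.
   hypoplastic) from a shared quality ontology and anatomical entities
   ("what") from species-specific anatomies linked by a bridging anatomy's
   cross-references. Terms match when their qualities are identical or
   is_a-related and at least one entity pair is bridged. Terms without a
   usable definition inherit the mapping of their closest annotated is_a
   ancestor; a manually curated keyword index is the last resort, at a
   lower weight (default 0.5) reflecting its lower precision.
2. **Weighted Boolean querying.** Queries like
   `[SPECIES("Mus musculus") and GO("nervous system development")] not IP("Notch domain")`
   combine annotation atoms with and/or/not over a gene annotation store
   (true-path propagation throughout). Several queries run together, each
   with a positive weight; a gene's score is the summed weight of the
   queries it satisfies, so with unit weights genes are ordered by the
   number of conditions they meet.
3. **Prioritization and its null.** A disease's feature list becomes one
   query per feature, weighted by specificity (the information content
   −log₂ f of the feature's corpus frequency) times the mapping-method
   weight. Candidates are all annotated model-species genes or, when
   linkage/CGH evidence restricts the search to a chromosomal interval,
   the model-species orthologs of the region's genes. Rankings are
   compared with the chance expectation under uniformly random ordering of
   each region's candidates: writing n_j for region j's candidate count,
   the expected number of true genes at rank i is

   E_i = Σ_{j : n_j ≥ i} 1/n_j,

   whose cumulative sum gives the expected top-k hit count.

Everything runs on a fully synthetic, seeded universe produced by the
built-in generator (`phenoprio.fixtures`), which plants causal genes with
known classes and expected scores so recovery can be verified exactly.

## Worked example

`python examples/04_disease_prioritization.py` prints (seed 4):

```
disease D0000: features HP:0003002, HP:0003022, HP:0003025, HP:0003037, HP:0003041, HP:0003042
planted causal gene: HG00008 (mouse ortholog MG00008)

unconstrained search over 80 mouse genes:
  1. MG00008  score 17.686  (6 features matched)
  2. MG00055  score 12.458  (4 features matched)
  ...

constrained to chr4:1-550000 (4 candidates):
  1. MG00008  score 17.686
  unscorable region genes (no ortholog / no phenotype): HG00013, HG00028, MG00003
```

The planted causal gene matches all six disease features and tops both
rankings; its score 17.686 is the sum over matched features of
(specificity × method) weights. The region constraint leaves scores
untouched and only shrinks the candidate universe from 80 to 4; region
genes that cannot be scored (no mouse ortholog, no phenotype annotation)
are reported rather than silently dropped. The other examples cover the
mapping cascade (`01`), Boolean querying (`02`), enrichment and
conditional probability (`03`), and the chance baseline (`05`).

A thin CLI mirrors the library:
`phenoprio fixture-generate --seed 7 --out store/`, then
`phenoprio prioritize --store store/ --disease D0003`,
`phenoprio enrich --study genes.txt --store store/`, etc.

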