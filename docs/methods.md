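# Methods

## Model and procedure

### Ontology layer

Ontologies are OBO 1.2 flat files parsed (via `obonet`) into validated
term graphs. Only `is_a` edges drive traversal; `part_of` and other
relationships present in source files are ignored, because closure
semantics over mixed relations are not well defined for the matching rules
below — the is_a-only choice is the conservative one, and the alternative
(adding part_of to closures) would only ever *add* matches. Duplicate ids,
dangling `is_a` targets and cycles are rejected at parse time with the
offending ids. Obsolete terms stay loadable by id but are excluded from
closures and from label resolution targets, so annotations to dead terms
surface explicitly instead of vanishing. Label resolution is exact
(case-insensitive, whitespace-normalized) against names first, then
synonyms; an ambiguous label is an error listing every candidate — never a
silent choice. CURIEs pass through resolution untouched.

### Entity–quality mapping cascade

A phenotype term's logical definition is one quality term plus one or more
anatomy entities; definitions arrive as OBO `intersection_of` lines (first
term-only line = quality, relation-bearing lines = entities) or as a
three-column TSV sidecar, the sidecar winning on conflict. The anatomy
bridge contains (a, b) exactly when some bridge-ontology term
cross-references both a and b. Two definitions E-Q-match when

* the qualities are identical or related by is_a (ancestor/descendant,
  not siblings — "abnormal morphology" should match its specializations
  but not unrelated qualities), and
* at least one entity pair is bridged (existential semantics; conjunction
  over multiple entities has no agreed meaning and would silently drop
  matches).

Mapping a source term runs a three-stage cascade, stopping at the first
productive stage, so one result never mixes methods:

1. `eq_exact` — targets whose definition matches the source's own
   definition; weight 1.0.
2. `eq_inherited` — ancestors are visited in order of increasing is_a
   distance; at the first depth with any stage-1-mapped ancestor, the
   union of those ancestors' mappings is returned (equally close annotated
   ancestors are unioned rather than arbitrarily tie-broken); weight 1.0.
   Inheritance happens on the source side only.
3. `keyword` — targets sharing a curated keyword with the source; weight
   `w_kw` = 0.5 by default (configurable). The precise down-weighting of
   keyword mappings is a free parameter of the method; 0.5 penalizes the
   coarse fallback without silencing it.

### Annotation store and queries

Gene coordinates are 1-based closed intervals; region queries use overlap
(not containment) semantics, matching how CGH/linkage intervals are used,
and strand is ignored. Term retrieval follows the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor, so querying
a high-level term captures descendants' annotations.

The query grammar is `KIND("label")` atoms (SPECIES, GO, PHENO, PATHWAY,
IP, OMIM, REGION) combined with `and`/`or`/`not`, precedence not > and >
or, square-bracket grouping, straight or curly quotes; `X not Y` is sugar
for `X and not Y`. Evaluation is pure set algebra. `not` complements
within the store's whole gene universe, not within a species — users scope
with `SPECIES(...)` explicitly; this is the simplest composable semantics
and the one under which De Morgan's laws hold exactly (property-tested).
Ranking sorts by (score desc, gene id asc); the id tie-break exists purely
for determinism.

### Prioritization

Feature specificity is realized as information content: f(t) is the
fraction of corpus diseases annotated to t or an is_a descendant, and the
weight is −log₂ f(t), clamped at f = 1/(2·corpus size) for unseen terms.
The frequency-weighting *principle* admits several realizations (1 − f,
rank-based); information content was chosen because it is the standard
specificity measure for ontology terms and is additive across independent
features. Disease-side frequency qualifiers ("occasional", "frequent") are
parsed but ignored by default. Weights are not normalized per disease:
scores are comparable within a disease's ranking, which is the only
comparison the method makes. Each feature becomes one query — an Or over
its mapped targets, so a feature fires if any mapped target's annotation
matches — weighted by specificity × method weight. Features that map
nowhere are dropped and reported; a disease where every feature drops is
an explicit "unanalyzable" outcome, never a silent empty ranking. Region
genes without model-species orthologs, and candidates without phenotype
annotation, are listed as unscorable.

### Chance expectation and benchmarking

For regions with candidate counts n_j, the expected number of true genes
landing at rank i under uniformly random ordering is
E_i = Σ_{j: n_j ≥ i} 1/n_j, because each region's true gene is equally
likely to occupy any of its n_j positions (and can only reach rank i if
n_j ≥ i). Σ_i E_i equals the number of regions exactly — each true gene
lands somewhere — and this conservation law plus Monte-Carlo agreement
(10⁵ orderings, 3 SE) are the formula's validation.

Benchmarks centre a window of w bp on the true gene's midpoint
(configurable offset available for sensitivity checks), prioritize within
it, and record the true gene's rank using the conservative
worst-within-tie convention — zero-score candidates form one tie group at
the bottom — so ties never flatter the method. The per-window region
profile records exactly the benchmarked universe sizes, so the chance
curve refers to the same regions as the observed curve. Unanalyzable
cases are excluded from rank statistics but always reported as a fraction.

## Hypergeometric enrichment

The one-sided tail (P(X ≥ k) when enriched by count, P(X ≤ k) when
depleted) is computed from log-pmf values combined with log-sum-exp;
full-support tails short-circuit to exactly 1. Sidedness is chosen by the
observed direction and the direction is reported, so a user wanting
two-sided values can double post hoc. The correction family m is the
number of terms actually tested in the namespace (those with ≥ 1
propagated reference annotation), not the whole ontology. Bonferroni is
min(1, p·m); Benjamini–Hochberg uses the standard step-up (via
`statsmodels`, cross-checked in tests against the explicit running-minimum
definition). A study list not contained in its reference is rejected —
building a custom reference is the correct fix, not silent intersection.

## The synthetic universe

The generator emulates the statistical structure of a cross-species
prioritization study without any real corpus. Two mirrored phenotype
ontologies (depth 4–5 layered DAGs: root → 3 categories → families →
concepts, with filler leaves and chained fillers) share paired *concepts*.
Per concept, definitions exist with probability `definition_coverage` and
its anatomy pair is bridged with probability `bridge_coverage`; both
together make the pair stage-1 recoverable ("exact"). Otherwise the
concept is assigned to a defined family (stage-2 "inherited", the family
holding the definitions), to a keyword entry (stage-3), or left
unmappable — so the coverage dials decide exactly which cascade stage
fires, and the ledger records the class per concept. When
`definition_coverage` is 0 no definitions exist at all, families included,
leaving keywords as the only route.

Diseases draw `features_per_disease` distinct concepts; the causal human
gene's mouse ortholog is annotated with exactly the corresponding mouse
concepts. Two construction rules make the planted gene the unique best
candidate at zero noise: feature sets are sampled so that no disease's
planted concept set dominates another's features under propagated
matching, and a deterministic post-pass removes non-planted decoy
annotations from any gene whose matched-weight sum would tie or beat the
planted gene's. The pass runs only at q = 0; under noise (each feature
replaced by a random filler term with probability `noise_q`) decoys may
legitimately outrank the planted gene — that degradation is the signal the
noise benchmark measures. Expected planted scores are computed inside the
generator from its own counts, not by running the engine, so the
engine-vs-ledger equality test is a real cross-check.

Default conditions, chosen once as a realistic desk-scale study: 300
genes per species (spaced 100 kb on 5 chromosomes, so windows translate
cleanly into genes-per-region), 48 concepts in 12 families, ~180 phenotype
terms per side, 120 diseases × 6 features (six features mirrors a typical
multi-system syndrome description), definition coverage 0.7, bridge
coverage 0.9, keyword coverage 0.8, ortholog coverage 0.9, decoy sharing
0.05, unmappable-disease fraction 0.1. The acceptance study scales
diseases to 200. All output is byte-deterministic given the seed
(per-section streams at fixed offsets, sorted emission, seed recorded in
file headers).

What the generator does **not** emulate: real HPO/MP term-frequency
distributions, realistic chromosome lengths and gene density, annotation
incompleteness structured by research bias, many-to-many orthology, or
textual phenotype descriptions. Passing tests therefore demonstrate the
machinery is correct and calibrated, not that any particular recovery rate
transfers to real corpora.

## Numerical choices and degenerate inputs

* Hypergeometric tails: exact log-space summation; domain violations are
  errors, not NaNs.
* p-values outside [0, 1] are rejected before correction.
* Conditioning on an empty gene set is an explicit
  undefined-probability error.
* Probability-one tails are clamped to exactly 1.0.
* Rank ties: display order breaks by gene id; *evaluation* assigns the
  true gene the worst rank in its tie group.
* Empty benchmark tables produce NaN fractions, never division by zero.
* Seeds derived for sub-streams stay below 2³¹.

## Problem sizes

The shipped test suite and acceptance script run universes of 80–300
genes per species and 15–200 diseases, 10⁴–10⁵ Monte-Carlo replicates,
exhaustive hypergeometric enumeration to N = 12, and 200-vector correction
oracles — sizes chosen so the full validation completes in well under a
minute while every guarantee is exercised at meaningful scale.

## Known limitations

* `resolve()` is exact match only; no fuzzy suggestion.
* Orthology is stored as raw pairs; ortholog-group clustering is upstream.
* Stage-2 inheritance walks the source side only; target-side inheritance
  is a possible extension with different precision trade-offs.
* One-sided p-values by observed direction; configurable doubling is left
  to the caller.
* The chance model assumes one true gene per region and independence
  between regions.
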