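# Methods

## Statistical model

All enrichment statistics are exact hypergeometric upper-tail probabilities.
For a query of size *n* drawn without replacement from a background of *N*
proteins of which *K* carry an annotation, the over-representation p-value
of observing *k* carriers is the **inclusive** tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n).

The inclusive convention is the field standard for over-representation (the
observed configuration counts as evidence). The tail is computed through the
log-domain survival function of `scipy.stats.hypergeom`, which is accurate
for populations far beyond 1e5; argument bounds (0 ≤ K ≤ N, 0 ≤ n ≤ N,
0 ≤ k ≤ min(n, K)) are validated here and violations name the offending
argument. `k = 0` returns exactly 1.

Multiple testing is controlled with the Benjamini–Hochberg step-up
adjustment (via `statsmodels`), applied over exactly the tested family. The
family for term enrichment is "all terms with background count K ≥ min_K
and query count k ≥ 1": terms absent from the query cannot be enriched
under an upper-tail test, and including them would only deflate the
adjustment. `min_K` defaults to 1; a preset of 10 is the documented choice
for GO namespaces, mirroring the common practice of pruning rarely
annotated terms before testing.

Reported fractions (`k / n_query`) keep unannotated query members in the
denominator — the "x% of preys" convention. A configuration that drops
query proteins absent from the annotation source from *n* was considered
and rejected as a default because it makes fractions incomparable across
namespaces; the counts (k, n, K, N) are always reported so either
convention can be recovered from the output.

### Drug-target and therapeutic-category tests

Drug-target enrichment among baits is a single hypergeometric test
(N = protein-coding genome size, K = number of drug targets, n = baits,
k = targeted baits); with one test the adjusted p equals the raw p. With
the standard published parameterization of the GPCR screen this package
models (N = 19,008, K = 4,333, n = 48, k = 28) the exact inclusive tail is
1.1877e-7 (the exclusive tail is 2.36e-8). The value printed alongside
these parameters in the original analysis, 3.1e-8, is not reproducible
from them under any tail convention, binomial or normal approximation we
could identify; the package reports the exact computation.

Therapeutic-category enrichment uses the same engine per category with the
interactome's baits∪preys as the query and BH over all tested categories.

## Domain co-occurrence-set pair enrichment

Domains that annotate exactly the same proteins within a universe are
indistinguishable to any enrichment test over that universe, so they are
grouped into **co-occurrence sets** (equivalence classes by identical
carrier sets; a domain that never co-occurs forms a singleton set). This
avoids redundant results and artificial multiple-testing penalties from
perfectly dependent tests.

Bait-side classes are computed over the full bait panel; prey-side classes
over the **detected preys**. The prey universe choice is genuinely open
(detected preys vs whole proteome); computing classes on detected preys
matches the screen-centric reading and is the package default, while the
carrier count entering *n* is always taken over the **full proteome**
(a carrier must hold all member domains jointly). Switching the class
universe only refines/coarsens the partition; the counting definitions are
unchanged.

Each observed (bait-set, prey-set) pair is scored with

    N = n_baits × proteome_size   (possible bait-involving pairs)
    M = number of detected (deduplicated, filtered) interactions
    n = carriers(bait set | baits) × carriers(prey set | proteome)
    m = detected interactions matching both sets
    p = P(X >= m), X ~ HG(N, M, n),  BH over all tested pairs.

The BH family is all pairs with m ≥ 1. A single interaction whose endpoints
carry several sets contributes to every combination; an interaction whose
prey lacks domain annotation contributes to none. Ties in the output
ranking are broken by (p_adj, p_raw, bait set id, prey set id), where a
set's id is its smallest member domain, so output order is deterministic.

## Screen filtering

"Unique interaction" means a distinct **ordered** bait→prey pair: the assay
is directional (bait construct vs prey construct), so reciprocal
detections, if any, remain distinct. Deduplication unions evidence flags
and concatenates screen labels.

Contaminant removal applies to preys only (baits are pre-validated
constructs). A prey is a contaminant if it carries a configured term
(default GO:0006465, signal peptide processing), a term whose *name*
matches a configured case-insensitive keyword (default "ribosom" — the
ribosomal class has no single term id), or is on an explicit list.
Membrane annotation is a configurable term set (default the plasma-membrane
component term GO:0005886); no ontology-graph traversal is performed —
supply descendant terms explicitly if the annotation source is not
pre-propagated.

## Validation-rate summaries

An interaction counts as validated overall if at least one orthogonal
method validated it; attempts scored `untestable` (e.g. uninterpretable
blots) are excluded from numerator and denominator. Rates are rendered to
one decimal percent. The packaged fixtures transcribe published aggregate
counts (40 tested / 28 validated overall; 34 / 22 by co-IP; 50 / 12 on the
known-interaction retest); their per-row membership is synthetic, as only
the aggregates were published, and the files are named and commented
accordingly.

## Synthetic-data generator

The generator's defaults are the stated world of the screen it emulates:
48 baits, a reduced proteome of 2,000 proteins, 1,500 raw hits, a domain
vocabulary of 150 with Zipf-skewed frequencies (exponent 1.2) and
Poisson(1.5) domains per protein, 10 contaminant preys each hitting every
bait with probability 0.5, 10% duplicated rows, a planted
(bait-domain, prey-domain) affinity at odds multiplier 20, and a planted
prey category carried by preys at rate 0.3 vs 0.05 in the background.

Choices worth recording:

* **Planted domains** default to D002 (bait side) and D005 (prey side) —
  a common and a moderately common domain under the Zipf profile — so the
  carrier guarantees (≥ 3 baits, ≥ 20 proteome proteins) hold with high
  probability per draw; the domain assignment is redrawn from the same
  stream until they hold.
* **Domain sampling** uses the Gumbel top-k trick, an exact weighted
  without-replacement (Plackett–Luce) draw, vectorized over the proteome.
* **Category planting** is prey-conditional labeling, not sampling bias: a
  realized non-contaminant prey carries the planted category with
  probability `rate_in_preys`, every other protein with
  `rate_in_background` (implemented as background-rate assignment plus a
  post-screen top-up draw with probability (rp−rb)/(1−rb)). This realizes
  both configured rates exactly and keeps the category independent of which
  edges were drawn, so it does not confound the domain-pair null. An
  earlier design that over-sampled category carriers at the hit level was
  rejected: it cannot reach a 0.3 distinct-prey carrier rate from a 0.05
  background, and the induced prey-weight heterogeneity produced spurious
  domain-pair discoveries under the null.
* **Draw order** is fixed (proteome → domain annotations → contaminant
  choice/GO → categories → edges → contaminant attachment → duplicates →
  category top-up) under a single `numpy` generator seeded with one
  integer, making outputs byte-stable across refactors.

What the generator does **not** emulate: assay biochemistry (expression,
reporter dynamics, selection thresholds), bait-specific prey libraries,
GO/InterPro ontology structure (terms are flat labels), and realistic
identifier spaces. A green planted-recovery test therefore establishes that
the statistics find the planted structure under the stated noise model —
not that real-database enrichment tables are reproduced, which depends on
external annotation releases.

## Numerical and formatting choices

* p-values are written in scientific notation with six significant digits;
  all writers emit identical bytes for identical inputs, and the pipeline
  manifest contains no timestamps, so run directories are digest-comparable.
* Identifier normalization: strip whitespace; upper-case bare symbols;
  leave accession-style ids (namespace prefixes like `GO:`, InterPro/Pfam
  patterns) untouched. Idempotent.
* Degenerate inputs: empty interaction lists yield empty outputs everywhere;
  a world with no domain annotations yields an empty domain-pair table;
  k = 0 terms are never tested.

## Known limitations

* GO namespaces are tested with flat hypergeometric tests; graph-aware
  decorrelation (weight/elim-style algorithms) is intentionally out of
  scope, so GO results are comparable in spirit, not numerically, to
  graph-aware analyses.
* Real-data reproduction of interactome-scale counts (e.g. unique-edge or
  membrane-protein totals of the original screen) requires the deposited
  dataset and a matching annotation release; the pipeline's real-data mode
  consumes user-exported files and makes no attempt to pin releases.
* The domain-pair model treats detected interactions as exchangeable draws
  from bait×proteome; per-bait degree heterogeneity beyond that is not
  modeled and is conservative at the planted effect sizes tested.
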