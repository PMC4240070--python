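# Methods

## Scope and model

The package reconstructs a guilt-by-association analysis chain for a
deleted genomic region that carries both miRNA genes and a miRNA-processing
factor. Two dosage mechanisms are modeled: loss of the region's own miRNAs
(their predicted targets are de-repressed) and genome-wide miRNA
dysregulation from reduced processing capacity (represented by an input
list of dysregulated miRNAs — their differential expression analysis is out
of scope here). Both mechanisms are reduced to gene sets and confronted
with an independently built disease gene network.

## Region density

For a query region of width *w*, every miRNA locus genome-wide centers a
window of the same width (*flank* = *w*/2 = 1.3 Mb on either side of the
locus transcript start, clipped at position 1, never spanning
chromosomes). The statistic is the fraction of windows whose locus count is
strictly below the region's count. "Contained" means full interval
containment of the primary transcript; because the source data cannot
adjudicate between counting whole transcripts and counting transcript
starts, both conventions are implemented (`start_only` toggle, containment
default). Windows centered on the region's own loci are excluded from the
comparison by default, since the statistic asks about *other* loci; the
exclusion set is configurable.

## Percentile integration of two prediction tools

Raw scores are tool-specific and differ in polarity (tool 1:
smaller-is-stronger; tool 2: larger-is-stronger). Each score maps to
percentile(s) = |{records with strength ≥ s}| / N over the tool's **entire**
table — all miRNAs and both arms pooled (the pooling across arms is the one
reading consistent with transforming "all putative targets and all
miRNAs"). The max-tie convention makes the top-10% boundary score map to
exactly 0.10 and puts every percentile in (0, 1]. Arm percentiles (−5p,
−3p) of the same locus are arithmetically averaged per gene, then the two
tools' percentiles are averaged — but only for genes predicted by both
tools. The intersection rule is deliberate conservatism: a gene scored by a
single tool gets no final score, which is why a miRNA can retain far fewer
targets than either tool predicted, or drop out entirely when one tool has
no predictions for it. Ranking is ascending in the final score with
lexicographic gene-id tie-breaks, so identical inputs always produce
identical rankings.

## Enrichment testing

Per miRNA and top-k level (k ∈ {200, 400, 800}), each gene-set is tested
with the 2×2 table: (a) the miRNA's targets in the set, (b) its targets in
at least one *other* set, (c) other miRNAs' targets in the set, (d) other
miRNAs' targets in other sets only. The background is the union of all
miRNAs' predicted targets, which makes the test robust to functions
over-represented among miRNA targets as a class; genes belonging to no
gene-set contribute to no cell. Gene-sets are restricted to the background
universe before the inclusive 15–900 size filter. The right-tail
hypergeometric p is computed via `scipy.stats.hypergeom.sf` (an exact
enumeration oracle over all tables with margins ≤ 30 verifies it in the
tests). BH FDR is adjusted within each (miRNA, k) run across the gene-set
collection — the correction family is otherwise unstated in the source
design, and the per-run choice matches the per-run reporting and the
per-miRNA consensus logic; a joint-across-miRNAs correction is not
implemented. Consensus: nominal p ≤ 0.01 in ≥ 2 of 3 runs; a miRNA whose
full list is shorter than the smallest k has a single run judged at
p ≤ 0.005. Enrichment-map edges use the equal-weight mean of the Jaccard
and overlap coefficients at threshold 0.225 (weights configurable).

## Network construction

The two candidate lists are merged by set union. Brain relevance is three
boolean criteria per gene (expression, function, phenotype); candidates
need ≥ 1 of 3, all other genes ≥ 2 of 3, and a missing annotation counts as
zero criteria (logged). Interactions below weight 0.02 are dropped at read
time, along with self-loops and duplicate unordered pairs (max weight
wins), so downstream code assumes a simple weighted graph. Every
brain-relevant gene present in the graph is scored over its first-degree
neighbors in the **full** weight-filtered network (scoring happens before
network induction): +2.5 per candidate neighbor, +0.5 per brain-relevant
neighbor, −1 per other neighbor. Genes with score ≥ 1.5 (inclusive) are
retained as partners; the final network is the subgraph induced on
candidates ∪ partners, and nodes left without any edge are dropped — the
only reading under which a substantial minority of candidates can be absent
from the final network. Candidates are not scored during construction, but
the ranking stage applies the same additive formula to them so a single
ranking covers the whole network.

## Overlap testing

The region mechanism set is the union of the region miRNAs' top-200
targets; the processing-factor set contains genes in the top-200 lists of
≥ 2 dysregulated miRNAs minus the region set (the two sets are disjoint by
construction). Each is tested against the network's genes with the
one-sided Fisher exact test. The gene universe defaults to all genes of the
weight-filtered interaction network — the source design never states its
universe, and this is the major reproduction caveat for the overlap odds
ratios; the universe is configurable. Mechanism genes outside the universe
are dropped and counted before testing. The reported odds ratio is the
sample (cross-product) estimate, infinite when b·c = 0; the conditional
MLE is available from `scipy.stats.contingency.odds_ratio` if wanted, but
the cross-product is the default because "point estimate" is ambiguous in
the source design.

## Synthetic data

`SynthSpec` defaults encode the study conditions where they are stated:
a 7-locus cluster in a 2.6 Mb window; candidate lists of 35 and 107 genes
sharing one; candidates passing the relevance filter at the observed
118/141 rate; relevance marginals ≈ (0.46, 0.16, 0.17), the approximate
genome fractions of the three criteria; interaction mean degree ≈ 12.8
(edge/node ratio of the weight-filtered network); one region miRNA without
predictions from either tool. Scaled-down choices (4 chromosomes × 60 Mb,
150 background miRNAs, 4,000 genes, 60 gene-sets, 1,200 targets per miRNA
at inter-tool overlap 0.7 so the intersection ≈ 840 spans all three top-k
levels) keep a full run in seconds.

Scores are generated from a latent per-(miRNA, gene) strength shared
between tools for shared targets, which yields positively correlated ranks
across tools; tool 1 emits smaller-is-stronger scores, tool 2
larger-is-stronger, exercising polarity handling. Planted enrichment
places a chosen fraction of a miRNA's targets inside a named gene-set and
routes them through the shared portion so they survive the two-tool
intersection. The interaction network uses an expected-degree model with
exponential node propensities (approximately geometric degrees); core
partners get candidate edges boosted by `core_density_boost` and forced
all-true relevance flags. Edge weights are drawn so a configurable
fraction (default 0.2) falls below the 0.02 retention threshold.

What the generator does **not** emulate: real prediction-score semantics
(seed-match classes, conservation), gene-set overlap structure
(ontology-style nesting), scale-free degree distributions, or correlated
relevance criteria. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted signal at realistic
sizes — not performance on real annotation databases, whose headline
counts (background sizes, network sizes, specific overlap odds ratios)
depend on resources this package deliberately does not download.

## Numerical choices and degenerate inputs

- Percentile ties share the maximal percentile; all percentiles in (0, 1].
- Fisher p for a table with a = 0 (including the empty table) is exactly 1.
- All thresholds are inclusive (≥ 0.02 weight, ≥ 1.5 retention, 15–900
  sizes, ≤ 0.01 / ≤ 0.005 p-values, ≥ 0.225 similarity).
- Ties in every ranking break lexicographically on gene id; outputs are
  invariant to input row order.
- Coordinates are 1-based inclusive throughout; density windows clip at
  position 1.
- An empty comparison set for the density percentile, an empty enrichment
  background, or overlapping candidate/brain sets raise errors rather than
  returning silently wrong values.

## Problem sizes used in tests and analysis

Property suites use exhaustive enumeration up to table total 30, 200-locus
density fixtures against an O(n²) recount, and 100 random 500-node graphs
against an independent neighbor recount. Signal-recovery suites use 20
seeds per condition with 30 background miRNAs, 300 targets per miRNA and
40 gene-sets (enrichment), the full default network spec at boosts 40 and
0 (core recovery), and 3 preference levels × 20 seeds of 2,000-gene
universes (overlap monotonicity). These sizes were chosen so the complete
suite runs in about a minute while leaving the planted effects far from
the acceptance margins.

## Known limitations

- The percentile pool is per-tool across both arms jointly; a per-arm pool
  is not offered.
- Only the stated additive scoring weights ship as defaults; alternative
  schemes are expressible through configuration but not systematically
  explored.
- BH FDR across miRNAs jointly is not implemented (see above).
- The enrichment-map export writes node/edge tables only; no rendering.
- Symbol-to-stable-id conversion is a plain two-column mapping applied at
  read time, with unmapped genes dropped and counted.
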