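# Methods

## Evidence model

An evidence string carries a target identifier (Ensembl-gene style), a
disease identifier (EFO / Orphanet / HP style), its data source, and a
source-specific payload.  Sources belong to exactly one of seven data
types: genetic associations, somatic mutations, drugs, affected pathways,
RNA expression, animal models and text mining.  Identifier *syntax* is
checked (non-empty; prefix conventions under `strict=True`) but never
resolved against live services, and unknown payload fields are preserved
on read/write so newer producers do not break older consumers.  The
interchange format is JSON Lines; a flat TSV export
(`target_id, disease_id, datasource, datatype, score, overall`) is
provided for spreadsheet use.

## Source scoring rules

All rules return scores in [0, 1].

**P-value scale.**  The map from p-value to score is linear in −log₁₀ p
between two boundaries, clipped to [0, 1].  Defaults: `p_max = 0.05`
(score 0) and `p_min = 1e-25` (score 1).  Linearity in −log₁₀ p is the
simplest monotone map honouring both boundaries; any monotone
reparameterisation between the same endpoints would preserve the ranking
of evidence but not the intermediate values.

**PheWAS.**  `min(n_cases / max_cases, 1) × pvalue_score(p)` with
`max_cases = 8800`, the maximum case count of the PheWAS dataset.  The two
printed scalings are combined by product: the product preserves the unit
interval and is monotone non-increasing in p and non-decreasing in
n_cases, both of which are asserted as property tests.

**PanelApp.**  Green genes on version-1+ panels are expert-curated
diagnostic-grade associations and score exactly 1, independent of the
disease (which must be ontology-mapped, i.e. non-empty).

**Cancer Gene Census.**  Base score 0.5.  Tier-1 genes gain 0.25 for each
of the two Poisson recurrence tests (within-disease and pan-disease) with
FDR < 0.025; tier-2 genes stay at 0.5 regardless of test results.
Non-fusion mutations of genes that drive cancer only through fusions are
reset to 0.5.  Records with a single mutated sample lose 0.25.  The reset
is applied *before* the single-sample subtraction (`fusion_override_first`,
default on): the ordering is otherwise undetermined, and this order is the
one that cannot inflate a score (the subtraction always bites).  The two
Poisson FDR values are inputs; recomputing them from mutation matrices is
out of scope.

**ClinVar.**  Clinical-significance terms map through a configurable
table.  Defaults: `pathogenic`/`likely pathogenic` 1.0; `protective`,
`association`, `risk factor`, `affects`, `drug response` 0.5.  These
defaults are configuration choices, anchoring the curated pathogenic end
of the vocabulary at the maximum and placing the weaker/ambiguous terms at
the midpoint; an unmapped term is an error rather than a silent zero, so
configuration gaps surface immediately.

**Pass-through sources** (drugs, text mining, animal models, expression,
pathway methods) carry a `precomputed_score` taken verbatim; those
pipelines' internals are upstream of this package.

## Harmonic-sum aggregation

For scores sorted descending, `HS(s) = Σ_{i≤min(n,cap)} s₍ᵢ₎/i^e`,
normalised by the same-length maximum `Σ 1/i^e`.  Defaults `e = 2`,
`cap = 100`.  Normalisation by the *same-length* truncated maximum makes
singletons and constant vectors fixed points, which both makes scores
interpretable (an association supported by one 0.8 evidence scores 0.8)
and gives the test surface exact expected values.  The cap bounds the
influence of arbitrarily deep sources such as text mining.  The overall
association score aggregates the data-source scores directly (a config
switch aggregates type scores instead; the two differ whenever one type
holds several sources).  Ties in the descending sort cannot affect the
sum, so no tie-break is needed beyond a stable sort.

## Similarity network

Associations become edges of a target–disease bipartite graph only when
supported by at least 3 evidence strings (inclusive) and an overall score
strictly greater than 0.1 — a noise filter, since one or two weak evidence
strings are common artefacts of text mining and high-throughput sources.

The relationship score between two targets is the ratio of shared diseases
to the total diseases of both.  "Total" is read as the *union* (a Jaccard
index), because the union keeps identical neighbour sets at exactly 1; the
sum reading (`|A| + |B|`, Sørensen-style) is available via
`denominator="sum"`.  The default *weighted* mode weights each disease by
the inverse of its target degree: sharing a rare disease moves the score
more than sharing a data-rich disease such as a common cancer, and targets
linked to few diseases are implicitly more specific.  Inverse degree is
the simplest weight with both properties; no published formula exists for
this weighting, so the mode is configurable and the unweighted Jaccard is
always available.  Shared diseases are reported rarest-first, truncated at
20.  Disease–disease similarity reuses the same operations with sides
swapped.

**MinHash LSH.**  Signatures use `num_hashes = 128` universal hash
functions `h(x) = (a·x + b) mod (2⁶¹ − 1)` over 64-bit digests of
neighbour identifiers, banded as 32 bands × 4 rows.  A pair with Jaccard J
collides per hash with probability J and becomes a candidate with
probability `1 − (1 − J⁴)³²` (≈ 0.99 at J = 0.6, ≈ 0.007 at J = 0.1).  All
hash draws come from one seeded generator, so candidate sets are
deterministic given the seed, which is recorded in the run manifest.  A
size-ratio bound `J(a,b) ≤ min(|A|,|B|)/max(|A|,|B|)` skips pairs that
cannot reach the candidate threshold before any scoring.  Graph sides with
at most 1000 entities bypass LSH entirely and are scored exactly — at that
size the quadratic scan is cheaper than signature construction and the
results are exact.

## Enrichment statistics

Batch queries accept at most 200 identifiers; duplicates are collapsed
with a warning, and resolution against the universe may use a local
synonym table (no live lookups).  Each annotation term overlapping the
query is tested with the hypergeometric upper tail P(X ≥ k) — an
over-representation test; under-representation is not of interest when
ranking candidate disease/pathway/GO terms for a target list.  P-values
are Benjamini–Hochberg adjusted *within* each category (categories are
different hypothesis families with very different sizes); `adjust=False`
disables the adjustment for fidelity with pipelines that rank on raw
p-values.  Drugs are reported by direct lookup of modulating drugs, not
tested.  The pathway-alteration statistic for mutation cohorts is the
Poisson-binomial upper tail over per-sample alteration probabilities
`π_sample = 1 − Π_g (1 − q_g)` (a pathway is altered in a sample if at
least one of its genes is mutated), computed by the O(n·k)
dynamic-programming convolution with the ≥ k mass absorbed in place —
exact, with no normal or Poisson approximation.

## Synthetic fixtures

The generator emulates the *shape* of an evidence corpus: per-source
background evidence over a universe of `n_targets × n_diseases` pairs with
payloads sampled uniformly inside each rule's valid domain (p-values
log-uniform on [1e-30, 1], case counts uniform up to 12 000, tiers,
sample counts and FDRs uniform over their ranges).  Defaults (50 targets,
30 diseases, ~320 evidence strings over seven sources) keep every stage
sub-second while leaving the per-pair evidence depth (≈ 0.2 background
strings/pair, 3+ on planted pairs) in a realistic sparse regime.  What it
does **not** emulate: correlated evidence across sources, ontology
structure among diseases, realistic score distributions per source, or
release-scale corpus sizes — so passing planting tests demonstrates the
pipeline's correctness and sensitivity, not calibration on production
data.

Planted pairs receive three pass-through evidence strings sharing a score
found by bisection *through the real scoring and aggregation engines*
until the aggregated overall score is within ±0.05 of the request;
background sampling avoids planted pairs so the request is not confounded
by random collisions, and an unreachable request (e.g. two conflicting
requests on one pair) raises a planting error.  Three strings per plant
means every planted pair passes the similarity graph's evidence filter on
its own.  A single integer seed drives one explicit generator per artifact
(evidence uses `seed`, annotations `seed + 1`), so identical configs give
byte-identical files.

## Numerical choices and degenerate inputs

* Hypergeometric tails go through scipy's survival function (log-space
  internally); the full grid N ≤ 12 is checked against exhaustive draw
  enumeration.
* The Poisson-binomial DP tracks the pmf only below k and absorbs the
  ≥ k mass, avoiding the O(n²) full convolution; checked against 2ⁿ
  enumeration for n ≤ 12 and the closed-form binomial tail for equal
  probabilities.
* Empty score vectors harmonic-sum to 0; an empty graph side yields an
  empty candidate set; an empty enrichment input yields an empty report
  row set.
* Relationship ties are broken lexicographically by identifier so top-k
  lists are deterministic.

## Limitations

* No ontology propagation: associations are not expanded to ancestor
  disease terms, and GO/Reactome hierarchies are not rolled up.
* Production association pipelines may weight sources inside the harmonic
  sum or use a different normalisation constant; the defaults here are the
  fixed-point-preserving choice and are configurable.
* The CGC rule ordering and the similarity weighting formula are
  documented design choices where no canonical form is published.
* Identifier resolution is local-table only.
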