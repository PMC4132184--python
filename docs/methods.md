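# Methods

This note documents the models and procedures the package implements,
the defaults it ships, and what its synthetic benchmarks do and do not
demonstrate.

## Problem setting

A TAP-MS experiment (tandem affinity purification followed by mass
spectrometry) yields, per purification run, a list of proteins with
unique-peptide counts. Runs come in two conditions: *bait* replicates
(the tagged protein of interest, here the spliceosome-associated
C. elegans protein CACN-1) and *negative controls* (untagged animals).
Downstream questions: which co-purifying proteins are credible
interactors; do they form a coherent physical module in the known
interactome; and do their knockdowns produce the bait's phenotype
(distal-tip-cell migration defects read out from gonad-arm shapes)?

## Candidate filtering

A protein is retained iff it (1) appears in at least `min_replicates`
(default 2) distinct bait replicates, (2) never appears in any control
run, and (3) belongs to no user-supplied contaminant blocklist. The
audit records the first failing rule in the fixed order
replicate → control → blocklist. Peptide counts are reported but never
used as a criterion; replicate reproducibility and control subtraction
carry the specificity. "Found in control" means *any* appearance — the
strictest reading — rather than a ratio test; with deeply sampled
controls this can over-exclude, which is the conservative direction
for an interaction claim.

Blocklists (heat-shock proteins, organellar proteins, …) are explicit
input files rather than built-in annotation lookups: contaminant
category membership is curation-dependent, so reproducing a particular
published candidate list requires the corresponding lists. This is a
documented limitation, not a defect; the filtering logic itself is
fully specified.

## Network assembly and parsimony expansion

Candidates become seed nodes; their induced subgraph is taken from a
reference interactome (an undirected simple graph of known plus
predicted interactions; all edges unweighted and undirected). The
network is then expanded to first-order neighbours under a parsimony
rule: a non-seed protein is added only if it interacts with at least
`min_links` (default 2) *seed* proteins. Qualification is single-pass
against the original seed set — an added node never qualifies another
— but the final edge set is the induced subgraph on seeds plus added
nodes, so added–added edges are included. Because the "new edges"
count of an expansion can be read inclusively (any edge touching an
added node) or strictly (added–added only), the node-role output
reports both tallies.

## PIE cohesiveness test

The physical interaction enrichment (PIE) statistic compares the
observed number of induced edges of a gene set against degree-matched
random gene sets drawn from the reference:

    PIE = observed edges / mean(null edges),
    p   = (1 + #{null >= observed}) / (1 + n_rand).

Degrees are measured in the full reference, and the null must be
degree-matched because hub-containing sets induce many edges under any
selection scheme; matching removes that confounder. Sampling is
uniform without replacement within each degree class, so every draw
satisfies the matching contract by construction (no rejection loop).
Defaults: `n_rand = 10,000` draws, exact matching. When a required
degree class is degenerate (fewer than two candidates, or fewer than
required), the sampler falls back to binned matching over geometric
bins 0 / 1 / 2 / 3–4 / 5–8 / 9–16 / 17+ with a logged notice; the
result records which mode was effective. The add-one (permutation)
p estimator never returns 0; its floor at 10,000 draws is 1/10,001,
i.e. "p < 0.0001". Ties count as extreme (`>=`), the conservative
convention. With a fixed seed the whole test is bit-reproducible.

Degenerate cases: a null mean of zero flags the score undefined (NaN)
while the p-value remains valid; a zero-edge test set scores 0.

The reference must include *all* genes eligible for selection —
including the majority with no curated interactions — hence the
one-column companion node file for isolated nodes.

## RNAi screen statistics

Phenotype tables carry five mutually exclusive gonad-arm outcome
categories (normal, extra turn, wandering, overshoot, other) per
treatment. Published tables print integer percentages with the number
of arms `n`; counts are reconstructed as round-half-up(p/100 · n) in
exact rational arithmetic, and any residual against `n` is repaired
largest-remainder style: a missing unit goes to the category rounded
down with the largest fractional part, a surplus unit comes off the
category rounded up with the smallest fractional part (ties in column
order). The direction-aware rule matters: repairing "largest fraction
first" in both directions can decrement a category that was rounded
*up* correctly and silently shift its reprinted percentage. With the
direction-aware rule, a percent row that was printed from real counts
reconstructs to counts that reprint identically (property-tested).

Testing collapses the categories to normal-vs-defective, exactly as
screen figures compare "% normal", and applies Fisher's exact test
(two-sided, sum of tables no more probable than the observed one;
scipy's implementation, cross-checked in the tests against a full
hypergeometric enumeration in rational arithmetic). Significance tiers
are p < 0.05 and p < 0.0005. No multiple-testing correction is applied
by default, matching per-comparison reporting conventions for small
directed screens; a Benjamini–Hochberg q column is emitted alongside.
Treatments whose animals arrest before scoring are carried as
unscored records: excluded from testing and never counted as hits.

## Synthetic data

The generators produce inputs with the statistical structure the
analysis assumes, at a desk scale chosen once:

* **Reference network** — 2,000 nodes / 2,800 edges by default, a
  uniform random simple graph. This preserves the ~1.39 edges-per-gene
  sparsity of a whole-proteome interaction database (≈20,500 genes /
  ≈28,400 interactions) so null edge counts behave comparably at ~10%
  scale. An explicit degree sequence is realised exactly via
  configuration-model pairing with rejection of non-simple outcomes.
* **Planted cohesive module** — members are a connected snowball
  sample grown from the network's best-connected hub (a protein
  complex is a connected subnetwork; a 27-member connected module
  carries at least 26 internal edges). Internal edges are then
  multiplied (default ×3) by double-edge swaps
  (a,x),(b,y) → (a,b),(x,y) with a,b inside and x,y outside the
  module, each moving exactly one edge inside. Swaps preserve every
  node's degree exactly, so the degree-matched null remains honest —
  planting by edge *addition* would change member degrees and
  contaminate the null. Rewiring stops at the target or when no legal
  swap remains. Member selection on typical-degree nodes of a graph
  this sparse was rejected: such a module starts with ~0–2 internal
  edges, a multiplicative target is then nearly vacuous, and the few
  high-degree alternatives sit in singleton degree classes whose
  binned null keeps re-drawing the module's own hubs.
* **TAP-MS tables** — true interactors appear in each bait replicate
  with probability `p_true` (default 0.9) and never in controls;
  background proteins appear in any run independently with `p_bg`
  (default 0.05), the shared-contaminant model that
  replicate-intersection plus control-subtraction assumes. Peptide
  counts are uniform on 1..30 (reporting only).
* **Phenotype screens** — multinomial draws of 100 animals per
  treatment. The control distribution (0.99, 0, 0.01, 0, 0) mirrors a
  clean empty-vector control; the strong-defect preset
  (0.25, 0.13, 0.11, 0.46, 0.05) mirrors an overshoot-dominated
  migration defect.

What the synthetic benchmarks do **not** show: real TAP-MS background
is abundance-structured (not i.i.d. across proteins), real
interactomes have heavy-tailed degree distributions and study bias,
and real screens have between-plate variation. Passing the synthetic
recovery and calibration checks demonstrates the statistics and
machinery are correct under their stated models, not that the
biological conclusions of any particular dataset are right.

## Reproducibility and numerics

All randomness flows from numpy `default_rng` seeds; the pipeline uses
one master seed with fixed per-stage offsets so stages are
independently reproducible, and identical seeds give bit-identical
outputs (asserted). Exact rational arithmetic is used where rounding
conventions matter (count reconstruction; the Fisher oracle in tests).
Permutation draws are processed in blocks with vectorised
induced-edge counting (boolean membership against the edge array), so
10,000 draws on the desk-scale reference take well under a second.

## Problem sizes used in the checks

The automated checks run at: 12-node references for exhaustive
enumeration against the Monte-Carlo null (3 fixtures × 10,000 draws);
100 generator seeds × 10,000 draws for planted-module recovery at
desk scale; 200 simulated null screens × 20 treatments for type-I
calibration; 300-protein background pools for the filtering oracle.

## Known limitations

* Reproducing a particular published candidate list requires the
  original contaminant blocklists and database snapshot; with other
  inputs the counts (e.g. how many proteins survive filtering, how
  many nodes an expansion adds) will differ. Database-dependent
  figures such as a specific PIE score are therefore not regression
  targets here; the package instead verifies the machinery on
  enumerable fixtures and planted synthetic truth.
* The control-appearance filter is binary; spectral-count ratio
  scoring (CRAPome-style) is out of scope.
* The PIE null treats the reference as fixed and error-free;
  interaction-detection bias is not modelled.
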