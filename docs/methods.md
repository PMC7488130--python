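# Methods

## Problem and data model

The package operates per patient on an aligned *bundle* of m ≥ 2 omics
layers over a shared gene set G and sample vector I. Layers are plain
genes × samples TSV matrices; alignment intersects genes and samples across
layers (restricted to a user gene list, or to genes derived from BED
regions), sorts both lexicographically, and fixes the layer order to
(expression, copy_number, methylation, mutation, other) so the per-patient
matrix **M**ᵢ = (G × m) has a reproducible column order. Gene/sample
matching is exact, case-sensitive string equality; an optional CLI flag
trims sample ids at the first whitespace, off by default. Missing cells
("" / "NA") are imputed as 0 in mutation layers and as the gene's row
median otherwise, with a logged count; layers are validated on read
(methylation beta in [0, 1], mutation counts non-negative integers,
unique gene and sample ids).

Continuous columns of **M**ᵢ are standardized to zero mean / unit variance
across genes (constant columns map to all-zero); a mutation column that is
already a 0/1 indicator is left unscaled so tree splits and rules see the
raw indicator. Standardization can be disabled (`--no-standardize`); the
raw values are kept alongside because rules with absolute thresholds must
not see z-scores.

## M1: unsupervised random-forest proximity + k-means

The unsupervised forest follows Breiman's two-class device: a synthetic
class is drawn by independently permuting each column of **M**ᵢ (product of
marginals), and a classification forest (default 500 trees, mtry =
⌊√m⌋ with minimum 1) is trained on real-vs-synthetic. Proximity(a, b) is
the fraction of **all** trees in which real rows a and b share a terminal
node — counting all trees rather than out-of-bag ones makes identical gene
profiles come out at exactly 1.0, a property the tests pin down. The
proximity matrix is symmetric with unit diagonal by construction.

Genes are clustered by Euclidean k-means on the proximity **rows** (each
gene represented by its proximity profile to all genes), k-means++
seeding, 10 restarts, 300 iterations. The literal reading — the proximity
matrix itself as clustering input, not a 1−proximity dissimilarity with a
medoid method — was adopted; on block-structured proximities the two agree.
When k is `auto`, the mean silhouette coefficient (Euclidean on proximity
rows) is evaluated for each k in 2..min(10, |G|−1) and the argmax is
returned, ties toward smaller k (parsimony). Module labels are renumbered
canonically — module 1 is the cluster containing the lexicographically
first gene — so outputs are comparable across runs.

Per-patient seeds are derived as `seed + patient_index`, making results
independent of processing order and bit-reproducible from one seed.

## M2: logic rules + k-modes

Seven default crisp rules binarize the patient matrix, each individually
overridable and restricted to layers actually provided:

| rule | layer | condition | polarity |
|---|---|---|---|
| over_expressed | expression | z > +1 | activating |
| under_expressed | expression | z < −1 | suppressing |
| cn_gain | copy_number | value > +0.3 | activating |
| cn_loss | copy_number | value < −0.3 | suppressing |
| hyper_methylated | methylation | beta > 0.7 | suppressing |
| hypo_methylated | methylation | beta < 0.3 | activating |
| mutated | mutation | count ≥ 1 | activating |

Expression rules are scale-free (within-patient z-scores across genes);
copy number uses the conventional ±0.3 log-ratio cut, which also flags
GISTIC-style integer calls; methylation uses the common 0.3/0.7 beta
conventions. Directions are `above` (strict >), `below` (strict <) and
`at_least` (≥) — the last exists because "mutated" is naturally a ≥ 1
condition that a strict inequality cannot express with an overridable
threshold. Custom rule tables (name, layer, direction, threshold, optional
effect) are accepted; a missing effect column defaults to activating for
above/at_least and suppressing for below. Rules are crisp 0/1 outcomes by
design; no fuzzy membership degrees are computed.

K-modes is implemented in `gmiec.kmodes` (Huang's algorithm): Hamming
dissimilarity, per-column-mode centroids, best of `n_init` restarts by
total within-cluster cost. All tie-breaks are deterministic: assignment
ties go to the smallest cluster index; mode ties keep the current centroid
value; emptied clusters are re-seeded with the point farthest from its
centroid. Restarts initialize from distinct data rows — *ordered* tuples,
enumerated exhaustively when there are no more of them than restarts
(ordering matters because assignment ties depend on centroid order) — and
each converged restart is polished by a best-improvement single-point
relocation descent, which removes the shallow local optima batch k-modes
is prone to on small inputs. On instances with ≤ 8 rows and 50 restarts
the algorithm attains the exhaustively enumerated partition optimum in
every tested case. If fewer than k distinct rows exist, the effective k
drops to the distinct-row count (logged). The per-iteration cost history
is recorded and is non-increasing, which the tests assert.

## Scoring and selection

Both strategies share one scoring path: a rule matrix (default rules) is
computed for every patient — for M1 runs purely for scoring. For each
module: `score_genes` is the mean of the binary rule matrix over module
genes × applied rules (alteration density, [0, 1]); `score_drugs` is the
fraction of module genes with at least one association in the gene–drug
table ([0, 1]); per-rule sub-scores are the column means (exported as
`module_j_sub_<rule>`); and the S-score is the mean of the activating
sub-scores minus the mean of the suppressing ones, each mean over the rule
columns actually present (an empty side contributes 0), giving a signed
value in [−1, 1]. The S-score is signed deliberately so both over-activated
and over-suppressed modules can be ranked from one quantity.

Selection is total and deterministic: per patient, among modules with
≥ `min_drugs` drugs (default 1), take the maximal (active) or minimal
(inactive) S-score; ties break toward larger `score_drugs`, then smaller
module index. If no module meets the drug constraint, the best-scoring
module overall is reported but can never be AOMD/IOMD. Category AOMD
requires the drug constraint plus a strictly positive score; IOMD the
mirror. The selection table has columns patient_id, score, genes, drugs
(and category, on by default).

## Synthetic cohorts

The generator emulates a tumor cohort at analysis scale: four layers over
a shared gene partition (shared cohort-wide by default; per-patient with a
flag), each patient receiving a random assignment of one activated module,
one suppressed module, and neutral remainder. Draws per state: activated —
expression N(+δ, 1), copy number N(+0.6, 0.15), methylation Beta with mean
0.2 (concentration 10, so values stay in [0, 1] by construction), mutation
Bernoulli(0.3); suppressed mirrors the continuous layers (expression
N(−δ, 1), copy number N(−0.6, 0.15), methylation mean 0.8) with mutation
at the background 0.02 rate, since mutation has no suppressive direction;
neutral — N(0, 1), N(0, 0.1), Beta mean 0.5, Bernoulli(0.02). δ is 3 / 1.5
/ 0.5 for strong / moderate / weak effects. A `druggable_fraction`
(default 0.3, roughly the drug-interaction coverage of a typical cancer
gene list) of genes receives 1–3 synthetic drug names.

One consequence worth knowing: because the over_expressed rule z-scores
across *all* genes of a patient, and a third of genes sit at +δ and a
third at −δ, the across-gene SD at the strong effect is ≈ 2.65, so only
~64% of activated-module genes individually pass z > 1. Module recovery
does not suffer — copy number and methylation carry most of the
discriminative signal and nearly every activated gene passes at least one
activating rule — and the tests compare this pass rate against an
independent re-simulation rather than assuming a neutral-only background.

`recovery_experiment` runs the full pipeline on freshly generated cohorts
and reports the mean per-patient adjusted Rand index against the planted
partition plus the fraction of planted activated-druggable patients
flagged AOMD. At the default evaluation scale (10 patients × 60 genes × 3
modules, 5 cohorts — small enough that a full run takes well under a
minute per strategy) measured values are ≈ 0.92 (M1) and ≈ 0.84 (M2) mean
ARI with AOMD detection 1.0, monotone in effect size.

What the generator does **not** emulate: realistic marginal distributions,
copy-number segment structure, methylation probe correlation, batch
effects, or gene–gene correlation within modules beyond the shared state.
Passing recovery tests therefore demonstrates algorithmic correctness
under planted structure, not performance on real tumors.

## Region-to-gene mapping

BED regions and the 4-column annotation table (chrom, start, end, gene)
both use 0-based half-open coordinates; 1-based inclusive exports (e.g.
RefSeq tables) must be shifted by one first. A gene is selected when any
of its annotation intervals overlaps any region by ≥ 1 bp under the
half-open test (a.start < b.end and b.start < a.end) — touching intervals
do not overlap, strand is ignored, and there is no nearest-gene fallback:
an empty result is a hard error because the analysis needs a non-empty
gene set. Lookup uses an interval tree; tests check equality with an
all-pairs brute-force scan.

## Numerical and format choices

* All TSVs: tab separator, UTF-8, header row, "." decimal point, no
  quoting; gene column header `gene`; empty drug lists serialize as `NA`.
* Floats in the results table are written with `repr`, so read → write →
  read round-trips exactly.
* The results table is wide (one row per sample, one column block per
  module, padded with NA when patients have fewer modules); clinical
  variables, when provided, are appended as `clinical_<name>` columns by
  sample id and never enter any computation.
* The HTML report is a single self-contained file (embedded PNG heatmaps
  of S-score / gene score / drug score, per-patient module tables with
  NCBI and DGIdb links); it is a static rendering, not an interactive
  viewer.

## Known limitations

* Forest proximities are Monte-Carlo estimates; module boundaries on weak
  effects vary with `n_trees` and seed (determinism holds for a fixed
  seed, platform-stability up to the forest library's floating point).
* Silhouette selection occasionally merges two planted modules on noisy
  proximity matrices (it picks the k that maximizes mean silhouette, which
  can legitimately be smaller than the planted count).
* K-modes with very few distinct rule patterns collapses modules; the
  effective k is reported rather than padded.
* Automatic k selection is deliberately limited to M1; for M2 the user
  chooses k.
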