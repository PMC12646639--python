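# Methods

## The model

`scregnet` infers a directed, weighted gene regulatory network for every
single cell by combining scRNA-seq and scATAC-seq measurements. The
working hypothesis is that the expression of a target gene q is a
(nonlinear) function of the expression of its regulators and the
accessibility of the chromatin peaks associated with q:

    X_q = f_q(X_-q, Y_q) + eps_q

where `X_-q` is the expression of every gene except q, `Y_q` the
accessibility of the peaks linked to q, and `eps_q` mean-zero noise. For
each cell c, `f_q` is fit by a random-forest regression whose rows are c
and its k nearest neighbors, so the network of c reflects c's own local
molecular state. Feature importances become regulatory weights:

    w[q, j] = z[q, j] + sum_l p[q, l] * I[q, j, l]

with `z[q, j]` the importance of gene j in the regression of q,
`p[q, l]` the importance of linked peak l, and `I[q, j, l] = 1` iff gene
j is a transcription factor (TF) with a motif hit inside linked peak l of
q. Non-TF genes never receive the peak bonus. Weights are nonnegative
(impurity importances are nonnegative; permutation importances are
clipped at 0) and edges are directed regulator -> target with no
self-loops.

Two inference modes exist:

* **multiome mode** — peaks enter the regressions and neighbors come from
  the weighted-nearest-neighbor (WNN) graph over both modalities;
* **expression-only mode** — peaks are dropped and neighbors come from the
  RNA PCA space alone. It serves as the ablation baseline.

## Gene-peak links

A peak is a candidate for a gene when it intersects the closed window 250
kb either side of the TSS (strand does not flip the window; it is
symmetric). Candidates become links when |Spearman rho| between gene
expression and peak accessibility across all cells exceeds 0.1 (strict;
signed filtering is available by flag). Constant vectors give rho = 0 and
are dropped; correlations are computed once, on all cells, before
per-cell inference. Motif occupancy is either read as a precomputed
binary TF x peak matrix or scanned from JASPAR PFMs: log-odds PWM against
a 0-order background estimated from the scanned sequences, both strands,
hit when any window clears the score threshold whose false-positive rate
is 1e-4 (the threshold and background are config knobs because tools
differ here).

## Neighbor identification

Paired data: per-cell modality weights are learned by cross-modality
prediction. Each cell's RNA coordinates are predicted by averaging its
RNA-kNN and, separately, its ATAC-kNN; the ratio of the two errors (and
the symmetric ATAC quantities) feeds a softmax that yields (w_rna,
w_atac), which always sum to 1. The combined affinity to every other cell
is `w_rna * exp(-d_rna/sigma_rna) + w_atac * exp(-d_atac/sigma_atac)`
with per-cell bandwidths (median distance to the 20 nearest neighbors),
and the k cells with highest affinity are the neighbors (ties broken by
cell index; k = 30 by default). If the ATAC representation duplicates the
RNA one, weights are exactly 0.5/0.5; if it is uninformative noise, the
median RNA weight exceeds 0.5.

Unpaired data: ATAC cells are summarized as gene-activity scores (counts
over the gene body plus 2 kb upstream, strand-aware; TSS +/- 2 kb
fallback when no body extent is annotated), co-embedded with the RNA
cells by one PCA over the shared highly-variable-gene space, and aligned
by iterative per-cluster centroid matching (ATAC cells of each joint
cluster are shifted onto the RNA centroid; at most 10 iterations,
stopping when the largest shift drops below 1e-3). Every RNA cell then
receives its nearest ATAC cell as accessibility donor; donors may be
reused, and the regression rows of a cell's neighborhood use each
member's donor row for the peak predictors. An externally computed
embedding can be passed in to bypass this alignment entirely. This
pseudo-pairing rule is an interpretation: how neighborhood rows are
assembled from unpaired data is genuinely underdetermined, and
cluster-level aggregation would be an equally defensible choice.

## Preprocessing

RNA: library-size normalization to the median total, log1p, top-H highly
variable genes (H = 500 default), z-score, PCA (20 components). ATAC:
TF-IDF, top variable peaks, truncated SVD with component 1 dropped (it
tracks depth). Regressions consume log-normalized expression and TF-IDF
accessibility so predictor scales are comparable.

## Forests

Defaults mirror the classic R randomForest regression defaults: 500
trees, mtry = sqrt(#predictors), unlimited depth, bootstrap on. Impurity
decrease is the default importance (an IncNodePurity analogue);
permutation importance (IncMSE analogue) is behind a flag with negative
values clipped to 0. Candidate regulators are all other genes by default;
a TF-only restriction is available both for the regressor pool and for
post-hoc filtering of ranked networks. Every (cell, target) regression
derives its own seed as `crc32(global_seed:cell_id:gene_id)`, and
neighborhood rows are ordered by cell id before fitting, so results are
independent of execution order and of how cells happen to be stored.
Neighborhoods smaller than 5 rows are refused; a constant response yields
zero importances with a warning.

## Cell-type networks and evaluation

A cell-type network is either the arithmetic mean of the type's
cell-specific networks (indirect; absent edges count as 0) or a single
fit whose rows are exactly the type's cells, i.e. k equals the type
population (direct). Network similarity between two cells is the number
of shared directed pairs among each network's top 3000 weight-ranked
edges (ties broken lexicographically). Cells are clustered by Ward
hierarchical clustering of gene outdegrees over top-ranked edges
(complete linkage and indegree available by flag; the clustering
function's linkage is a deliberate choice — Ward is more robust on count
features than the R default complete linkage) and scored against known
labels with the adjusted Rand index. Precision/recall against a reference
edge set match on directed (regulator, target) pairs, ignoring weights.

## Cell-enriched regulators

Expression is smoothed over 50 equal pseudotime intervals (bin = mean
log-normalized expression; empty bins linearly interpolated; profiles
z-scored per gene). Pseudotime comes from any external tool, or from a
deterministic fallback (rank of the first principal coordinate oriented
by a root cell type). K-means with 10 restarts runs for K = 2..12 and the
K with the best mean silhouette wins (ties to the smaller K). For each
cell network, a TF's target set is its targets among the network's top
3000 ranked edges (configurable; small gene panels want a smaller
cutoff), and each (TF, module) pair is tested with the upper-tail
hypergeometric distribution over the clustered-gene universe
(network-gene universe by flag). Benjamini-Hochberg correction is applied
within each cell across all (TF, module) pairs — enrichment is defined
per cell-specific network — and a TF is enriched at q < 0.01 in at least
one module. Per-type regulator rankings are enrichment frequencies across
the type's cells.

## Trait gene analysis

Given a trait gene list and cell-type networks, each TF's trait overlap
is |top-500 trans-regulated targets ∩ trait genes|. A type's trait
relevance is the two-sample t-test between the overlaps of its 20
top-expressed TFs and 20 seeded-random TFs. Key TFs are ranked by the sum
of z-scored mean expression and z-scored overlap (the exact scaling of
this composite is a design choice; z-scores keep both terms commensurate).

## The synthetic benchmark

Real multiome experiments are large and external, so the package ships a
generator whose default configuration is the standard benchmark: 4 cell
types x 100 cells, 10 TFs, 50 target genes, 2 peaks per gene on one
synthetic contig with genes spaced 600 kb apart (so TSS windows never
collide; shrink the spacing to build a collision fixture). Cell types are
stages of a linear trajectory; pseudotime is the stage index plus
within-stage jitter. TFs belong to six temporal modules (one peaked per
stage, plus broad-early and broad-late), with activity `6 x multiplier`
(multiplier 1 to 8 across stages) times lognormal cell jitter (sigma
0.3). Each target is driven by one primary regulator from its module
(strength U(0.8, 1.5)) and optionally a weaker secondary one (U(0.3,
0.7), repressive with probability 0.2) — secondaries are deliberately
weaker so that module shapes remain identifiable from smoothed profiles.
Peak openness is a saturating function of the gene's regulatory drive
(promoter peak at the TSS plus distal peaks within +/-250 kb), target
expression couples regulator activity with peak openness, and counts are
Poisson with 10% dropout on RNA. Motif hits are planted for every true
TF on every peak of each of its targets, plus 5% false hits. With
`noise_sd = 0` and `dropout_rate = 0` sampling is skipped entirely and
deterministic latent intensities are emitted (the noise-free mode used by
exactness tests).

What the generator does not emulate: batch effects, doublets, ambient
RNA, branching trajectories, realistic motif composition, peak co-
accessibility beyond the planted gene coupling, or genome-scale feature
counts. Passing tests therefore demonstrate the machinery is correct and
well calibrated under the stated generative assumptions, not that any
particular biological dataset will reach the same scores.

## Problem sizes and numerical choices

The shipped tests and the reproduction script fit per-cell forests with
50 trees for a subset of 20 cells per type (80 networks; 5 per type for
the expression-only ablation), which preserves every qualitative
conclusion of the full-size runs while keeping a complete run in single-
digit minutes on one core. Silhouette-based K selection uses 10 K-means
restarts per candidate. Spearman uses average ranks for ties; kNN ties
break by cell index; top-edge ties break by (regulator, target). With 60
genes the dense all-pairs edge space is ~3.5k edges, so top-3000
similarity saturates partially — the within/between contrast survives,
but enrichment target sets use a top-300 cutoff on this panel.

## Known limitations

* Per-cell inference is O(cells x genes) forest fits; genome-scale panels
  need the TF-only regressor pool or subsampled cells.
* The unpaired path assumes the modalities share cell states; a modality
  observed in only one cluster gets cross-cluster donors and a warning.
* The motif scanner is a straightforward PWM scanner; it does not model
  dinucleotide backgrounds or soft-masked sequence.
* Importance-based weights are not calibrated probabilities; only their
  ranking is meaningful, which is why all evaluation is rank-based.
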