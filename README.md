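# scregnet

Cell-specific gene regulatory network inference from scRNA-seq and
scATAC-seq data, paired or unpaired.

Bulk and cell-type-level network inference averages away the regulatory
heterogeneity between individual cells. `scregnet` infers a directed,
weighted regulator -> target network for *every single cell*: it embeds
cells jointly across modalities, finds each cell's k nearest neighbors
with per-cell modality weighting, links genes to nearby correlated
chromatin peaks, and fits one random-forest regression per target gene
over the cell's neighborhood. Tree importances become edge weights

    w[q, j] = z[q, j] + Σ_l p[q, l] · I[q, j, l]

where `z[q, j]` is the importance of gene j for target q, `p[q, l]` the
importance of q's linked peak l, and `I[q, j, l]` indicates that j is a
transcription factor with a motif hit in that peak. Downstream tools
cover network similarity, degree-based cell clustering (ARI against known
labels), precision/recall against a reference edge set, cell-enriched
regulator discovery (pseudotime modules + per-cell hypergeometric tests)
and trait-gene overlap analysis. A synthetic multiome generator with a
planted ground truth makes the whole pipeline testable offline.

Audience: computational biologists working with 10x-style multiome or
separate scRNA/scATAC experiments who want regulatory networks at
single-cell resolution.

## Worked example

```python
import numpy as np, pandas as pd
import scregnet as sr

# a paired multiome experiment with known regulators:
# 4 cell types x 100 cells, 10 TFs, 50 targets, 2 peaks per gene
cfg = sr.SimulationConfig(seed=1)
ds, annot, peaks, hits, truth, cell_types, pseudotime = sr.simulate_multiome(cfg)

# link genes to peaks (TSS +/- 250 kb, |Spearman rho| > 0.1, motif hits)
links = sr.build_links(annot, peaks, ds.rna, ds.atac.values,
                       ds.atac.peak_ids, hits)

# weighted-nearest-neighbor graph, then one network per cell
graph = sr.wnn_neighbors(ds, k=30, seed=1)
nets = sr.infer_networks_for_cells(range(0, 400, 5), graph, ds, links, annot,
                                   mode="multiome", n_trees=50, seed=1)

# how well are the planted edges recovered?
aupr = np.mean([sr.aupr_vs_truth(n, truth.edge_pairs, ds.rna.genes)
                for n in nets.values()])
density = len(truth.edge_pairs) / (60 * 59)
print(f"mean per-cell AUPR {aupr:.3f} vs random baseline {density:.3f}")

# do the networks alone separate the cell types?
dm = sr.degree_matrix(nets, n=500, genes=ds.rna.genes)
labels = sr.cluster_cells(dm, n_clusters=4)
print("clustering ARI", round(sr.adjusted_rand_index(
    labels, cell_types.loc[dm.values.index]), 3))
```

Output:

```
mean per-cell AUPR 0.179 vs random baseline 0.019
clustering ARI 0.932
```

The mean per-cell area under the precision-recall curve for the planted
TF -> target edges is ~10x the random-guessing baseline (the planted edge
density), and hierarchical clustering of gene outdegrees from the top 500
regulation pairs of each cell's network recovers the four simulated cell
types nearly perfectly.

A command-line interface mirrors the stages:

```bash
scregnet simulate --out data --seed 1
scregnet integrate --data data --paired --k 30 --out emb
scregnet infer --data data --k 30 --ntrees 50 --seed 1 --out nets
scregnet cluster nets/network_*.tsv --top 500 --n-clusters 4 --out labels.tsv
scregnet enrich nets/network_*.tsv --data data \
    --pseudotime data/pseudotime.tsv --out enrichment
```

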