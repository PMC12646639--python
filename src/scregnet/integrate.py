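"""Cell clustering, embeddings and per-cell neighbor sets.

Paired data get a weighted-nearest-neighbor (WNN) graph: per-cell modality
weights are learned by cross-modality prediction and combined into one
affinity. Unpaired data are put in a joint PCA space through ATAC
gene-activity scores, lightly aligned per cluster, and every RNA cell is
assigned its nearest ATAC cell as accessibility donor (pseudo-pairing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .io import AccessibilityMatrix, ExpressionMatrix, GeneAnnotation, MultiomeDataset

DEFAULT_K = 30


@dataclass
class Embedding:
    """Low-dimensional cell coordinates with per-cell modality provenance."""

    cells: list[str]
    coords: np.ndarray                # N x d
    modality_of_cell: np.ndarray      # "rna" | "atac" | "paired" per cell
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValueError("embedding must be N x d with d >= 2")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinates")


@dataclass
class NeighborGraph:
    """Per-cell ordered k-nearest-neighbor index lists.

    ``affinities`` are non-increasing along each row; ``modality_weights``
    (w_rna, w_atac) sum to 1 per cell where defined (paired WNN).
    """

    cells: list[str]
    k: int
    neighbors: np.ndarray             # N x k int indices into cells
    affinities: np.ndarray            # N x k, non-increasing per row
    modality_weights: np.ndarray | None = None  # N x 2

    def __post_init__(self) -> None:
        n = len(self.cells)
        if self.neighbors.shape != (n, self.k):
            raise ValueError("neighbor list shape mismatch")
        if (self.neighbors == np.arange(n)[:, None]).any():
            raise ValueError("a cell lists itself as neighbor")
        if self.modality_weights is not None:
            w = self.modality_weights
            if ((w < 0) | (w > 1)).any() or not np.allclose(w.sum(axis=1), 1.0):
                raise ValueError("modality weights must lie in [0,1] and sum to 1")

    def neighborhood(self, i: int) -> np.ndarray:
        """The cell itself plus its k neighbors (k+1 row indices)."""
        return np.concatenate([[i], self.neighbors[i]])


# ---------------------------------------------------------------------------
# normalisation helpers
# ---------------------------------------------------------------------------


def lognorm(values: sp.spmatrix) -> np.ndarray:
    """Library-size normalisation to the median total, then log1p (dense)."""
    x = np.asarray(sp.csr_matrix(values).todense(), dtype=float)
    totals = x.sum(axis=1)
    target = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(totals[:, None] > 0, x / totals[:, None] * target, 0.0)
    return np.log1p(x)


def tfidf(values: sp.spmatrix) -> np.ndarray:
    """Term-frequency / inverse-document-frequency of a cells x peaks count matrix."""
    x = np.asarray(sp.csr_matrix(values).todense(), dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    tf = np.where(totals > 0, x / totals, 0.0)
    df = (x > 0).sum(axis=0)
    idf = x.shape[0] / np.maximum(df, 1)
    return np.log1p(tf * idf * 1e4)


def _top_variable(x: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n most variable columns (stable order by index)."""
    v = x.var(axis=0)
    n = min(n, x.shape[1])
    idx = np.argpartition(-v, n - 1)[:n]
    return np.sort(idx)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def rna_embedding(rna: ExpressionMatrix, n_hvg: int = 500, n_dims: int = 20,
                  seed: int = 0) -> np.ndarray:
    """Lognorm -> top-HVG -> z-score -> PCA coordinates."""
    x = lognorm(rna.values)
    x = _zscore(x[:, _top_variable(x, n_hvg)])
    d = _clip_dims(n_dims, x.shape)
    return PCA(n_components=d, random_state=seed).fit_transform(x)


def atac_embedding(atac: AccessibilityMatrix, n_top_peaks: int = 10_000,
                   n_dims: int = 20, seed: int = 0) -> np.ndarray:
    """TF-IDF -> top variable peaks -> truncated SVD, dropping component 1.

    The first LSI component tracks sequencing depth and is discarded, as is
    conventional for scATAC-seq.
    """
    x = tfidf(atac.values)
    x = x[:, _top_variable(x, n_top_peaks)]
    d = _clip_dims(n_dims + 1, x.shape)
    svd = TruncatedSVD(n_components=d, random_state=seed).fit_transform(x)
    return svd[:, 1:] if svd.shape[1] > 1 else svd


def _clip_dims(requested: int, shape: tuple[int, int]) -> int:
    limit = min(shape[0] - 1, shape[1])
    if requested > limit:
        warnings.warn(f"reducing embedding dims from {requested} to {limit}")
        return max(limit, 2)
    return requested


# ---------------------------------------------------------------------------
# gene activity (unpaired bridge)
# ---------------------------------------------------------------------------


def compute_gene_activity(
    atac: AccessibilityMatrix, annot: GeneAnnotation, upstream: int = 2000
) -> ExpressionMatrix:
    """Per-cell gene activity: ATAC counts over the gene body + 2 kb upstream.

    activity(cell, gene) = sum of counts of peaks intersecting
    [start - upstream, end) for ``+`` genes and [start, end + upstream) for
    ``-`` genes. Genes whose annotation lacks a body extent fall back to a
    TSS +/- ``upstream`` window (with a warning).
    """
    table = annot.table
    has_body = annot.has_gene_body()
    if not has_body:
        warnings.warn("annotation lacks gene body extent; using TSS +/- upstream windows")

    trees: dict[str, IntervalTree] = {}
    for pi, (_, row) in enumerate(atac.peaks.table.iterrows()):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, pi)

    x = sp.csc_matrix(atac.values)
    out = np.zeros((len(atac.cells), len(table)))
    for gi, (_, row) in enumerate(table.iterrows()):
        if has_body and not (pd.isna(row.get("start")) or pd.isna(row.get("end"))):
            lo, hi = int(row["start"]), int(row["end"])
            if row["strand"] == "+":
                lo -= upstream
            else:
                hi += upstream
        else:
            lo, hi = int(row["tss"]) - upstream, int(row["tss"]) + upstream + 1
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.overlap(max(lo, 0), hi))
        if hits:
            out[:, gi] = np.asarray(x[:, hits].sum(axis=1)).ravel()
    return ExpressionMatrix(list(atac.cells), list(table.index), sp.csr_matrix(out), layer="gene_activity")


# ---------------------------------------------------------------------------
# joint embedding
# ---------------------------------------------------------------------------


def preprocess_and_embed(
    dataset: MultiomeDataset,
    annot: GeneAnnotation | None = None,
    n_hvg: int = 500,
    n_dims: int = 20,
    n_clusters: int = 4,
    max_align_iter: int = 10,
    align_tol: float = 1e-3,
    seed: int = 0,
) -> Embedding:
    """Joint embedding of all cells.

    Paired: z-scored concatenation of the RNA PCA and ATAC LSI coordinates.
    Unpaired: ATAC cells are represented by gene-activity scores in the
    shared HVG gene space, all cells are co-embedded with one PCA, and the
    two modalities are aligned by iterative per-cluster centroid matching
    (ATAC cells in each joint cluster are shifted onto the RNA centroid).
    """
    if dataset.paired:
        r = _zscore(rna_embedding(dataset.rna, n_hvg, n_dims, seed))
        a = _zscore(atac_embedding(dataset.atac, n_dims=n_dims, seed=seed))
        coords = np.hstack([r, a])
        return Embedding(list(dataset.rna.cells), coords,
                         np.array(["paired"] * len(dataset.rna.cells)))

    if annot is None:
        raise ValueError("unpaired embedding needs a gene annotation for gene activity")
    activity = compute_gene_activity(dataset.atac, annot)
    # shared gene space: HVGs of the RNA side that exist in the activity matrix
    rna_ln = lognorm(dataset.rna.values)
    act_ln = lognorm(activity.values)
    gene_pos = {g: i for i, g in enumerate(activity.genes)}
    shared = [g for g in dataset.rna.genes if g in gene_pos]
    hvg_local = _top_variable(rna_ln[:, [dataset.rna.genes.index(g) for g in shared]], n_hvg)
    rna_x = _zscore(rna_ln[:, [dataset.rna.genes.index(shared[i]) for i in hvg_local]])
    act_x = _zscore(act_ln[:, [gene_pos[shared[i]] for i in hvg_local]])

    stacked = np.vstack([rna_x, act_x])
    d = _clip_dims(n_dims, stacked.shape)
    coords = PCA(n_components=d, random_state=seed).fit_transform(stacked)
    n_rna = rna_x.shape[0]
    modality = np.array(["rna"] * n_rna + ["atac"] * act_x.shape[0])

    # iterative per-cluster centroid alignment of ATAC onto RNA
    for _ in range(max_align_iter):
        km = KMeans(n_clusters=min(n_clusters, len(coords) - 1), n_init=10,
                    random_state=seed).fit(coords)
        shift_norm = 0.0
        for c in np.unique(km.labels_):
            sel = km.labels_ == c
            rna_sel, atac_sel = sel & (modality == "rna"), sel & (modality == "atac")
            if rna_sel.any() and atac_sel.any():
                delta = coords[rna_sel].mean(axis=0) - coords[atac_sel].mean(axis=0)
                coords[atac_sel] += delta
                shift_norm = max(shift_norm, float(np.linalg.norm(delta)))
            elif sel.any() and not (rna_sel.any() and atac_sel.any()):
                # single-modality cluster: nothing to match here
                pass
        if shift_norm < align_tol:
            break
    cells = list(dataset.rna.cells) + list(dataset.atac.cells)
    return Embedding(cells, coords, modality)


# ---------------------------------------------------------------------------
# neighbor graphs
# ---------------------------------------------------------------------------


def _knn(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Self-excluding kNN (indices, distances), stable ties by index."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(coords))).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop the self column wherever it appears
    out_i = np.empty((len(coords), k), dtype=int)
    out_d = np.empty((len(coords), k))
    for i in range(len(coords)):
        mask = idx[i] != i
        out_i[i] = idx[i][mask][:k]
        out_d[i] = dist[i][mask][:k]
    return out_i, out_d


def _prediction_error(target: np.ndarray, source_nn: np.ndarray) -> np.ndarray:
    """Per-cell error of predicting ``target`` rows from neighbor averages."""
    pred = target[source_nn].mean(axis=1)
    return np.linalg.norm(target - pred, axis=1)


def wnn_neighbors(
    dataset: MultiomeDataset,
    k: int = DEFAULT_K,
    rna_coords: np.ndarray | None = None,
    atac_coords: np.ndarray | None = None,
    k_weight: int = 20,
    n_hvg: int = 500,
    n_dims: int = 20,
    seed: int = 0,
) -> NeighborGraph:
    """Weighted-nearest-neighbor graph for paired data.

    Modality weights per cell come from cross-modality prediction: each
    cell's RNA coordinates are predicted from the average of its RNA-kNN
    and, separately, its ATAC-kNN; the two errors (and the symmetric ATAC
    pair) are turned into (w_rna, w_atac) by a softmax over relative error
    ratios. Combined affinity to every other cell is
    w_rna * exp(-d_rna/sigma_rna) + w_atac * exp(-d_atac/sigma_atac) with a
    per-cell bandwidth, and the top-k cells by affinity are the neighbors.
    """
    if not dataset.paired:
        raise ValueError("wnn_neighbors requires paired data")
    n = dataset.n_cells
    if not 0 < k < n:
        raise ValueError(f"k must be in (0, {n})")
    if rna_coords is None:
        rna_coords = rna_embedding(dataset.rna, n_hvg, n_dims, seed)
    if atac_coords is None:
        atac_coords = atac_embedding(dataset.atac, n_dims=n_dims, seed=seed)

    kw = min(k_weight, n - 1)
    rna_nn, _ = _knn(rna_coords, kw)
    atac_nn, _ = _knn(atac_coords, kw)
    eps = 1e-12
    err_rr = _prediction_error(rna_coords, rna_nn)
    err_ra = _prediction_error(rna_coords, atac_nn)
    err_aa = _prediction_error(atac_coords, atac_nn)
    err_ar = _prediction_error(atac_coords, rna_nn)
    theta_rna = err_ra / (err_rr + eps)
    theta_atac = err_ar / (err_aa + eps)
    theta = np.clip(np.column_stack([theta_rna, theta_atac]), 0, 50)
    w = np.exp(theta)
    w = w / w.sum(axis=1, keepdims=True)

    d_rna = _pairwise_dist(rna_coords)
    d_atac = _pairwise_dist(atac_coords)
    sigma_rna = np.maximum(np.median(np.sort(d_rna, axis=1)[:, 1:kw + 1], axis=1), eps)
    sigma_atac = np.maximum(np.median(np.sort(d_atac, axis=1)[:, 1:kw + 1], axis=1), eps)
    affinity = (
        w[:, :1] * np.exp(-d_rna / sigma_rna[:, None])
        + w[:, 1:] * np.exp(-d_atac / sigma_atac[:, None])
    )
    np.fill_diagonal(affinity, -np.inf)
    order = np.lexsort((np.tile(np.arange(n), (n, 1)), -affinity), axis=1)
    neighbors = order[:, :k]
    aff = np.take_along_axis(affinity, neighbors, axis=1)
    return NeighborGraph(list(dataset.rna.cells), k, neighbors, aff, w)


def _pairwise_dist(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(x))


def rna_only_neighbors(rna: ExpressionMatrix, k: int = DEFAULT_K, n_hvg: int = 500,
                       n_dims: int = 20, seed: int = 0) -> NeighborGraph:
    """kNN graph in the RNA PCA space alone (expression-only inference mode)."""
    coords = rna_embedding(rna, n_hvg, n_dims, seed)
    if not 0 < k < len(coords):
        raise ValueError(f"k must be in (0, {len(coords)})")
    idx, dist = _knn(coords, k)
    return NeighborGraph(list(rna.cells), k, idx, -dist, None)


def unpaired_neighbors_and_pairing(
    embedding: Embedding, k: int = DEFAULT_K
) -> tuple[NeighborGraph, pd.Series]:
    """Neighbors among RNA cells plus a nearest-ATAC accessibility donor.

    Each RNA cell's k neighbors are drawn from the RNA cells of the joint
    embedding; its donor is the closest ATAC cell in the same space (donors
    may be reused; with a single ATAC cell every RNA cell shares it).
    """
    rna_mask = embedding.modality_of_cell == "rna"
    atac_mask = embedding.modality_of_cell == "atac"
    if not rna_mask.any() or not atac_mask.any():
        raise ValueError("unpaired pairing needs both modalities in the embedding")
    rna_coords = embedding.coords[rna_mask]
    atac_coords = embedding.coords[atac_mask]
    rna_cells = [c for c, m in zip(embedding.cells, rna_mask) if m]
    atac_cells = [c for c, m in zip(embedding.cells, atac_mask) if m]
    if not 0 < k < len(rna_cells):
        raise ValueError(f"k must be in (0, {len(rna_cells)})")
    idx, dist = _knn(rna_coords, k)
    graph = NeighborGraph(rna_cells, k, idx, -dist, None)
    nn = NearestNeighbors(n_neighbors=1).fit(atac_coords)
    donor_idx = nn.kneighbors(rna_coords, return_distance=False).ravel()
    donors = pd.Series([atac_cells[j] for j in donor_idx], index=rna_cells, name="atac_donor")
    return graph, donors
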