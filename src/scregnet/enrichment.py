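"""Cell-enriched regulator identification.

Expression is smoothed over 50 equal pseudotime intervals, genes are
partitioned into co-expression modules by K-means (K chosen by mean
silhouette), and each cell network's TF target sets are tested for module
over-representation with an upper-tail hypergeometric test, BH-corrected
within the cell; a TF is enriched at q < 0.01. Frequencies of enrichment
across a cell type's cells rank its characteristic regulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .infer import CellNetwork, top_pairs

DEFAULT_N_BINS = 50
DEFAULT_FDR = 0.01
DEFAULT_TOP_EDGES = 3000


@dataclass
class ModulePartition:
    """Gene -> module assignment with the silhouette profile used to pick K."""

    assignment: pd.Series
    k: int
    silhouette_by_k: dict[int, float]

    @property
    def genes(self) -> list[str]:
        return list(self.assignment.index)

    def module_members(self, m: int) -> set[str]:
        return set(self.assignment.index[self.assignment == m])


@dataclass
class EnrichmentResult:
    """Per-cell hypergeometric enrichment rows: (tf, module, x, p, q, enriched)."""

    cell_id: str
    table: pd.DataFrame

    def enriched_tfs(self) -> set[str]:
        return set(self.table.loc[self.table["enriched"], "tf"])


def smooth_by_pseudotime(
    expression: pd.DataFrame, pseudotime: pd.Series, n_bins: int = DEFAULT_N_BINS
) -> pd.DataFrame:
    """Genes x bins matrix of z-scored mean expression along pseudotime.

    The pseudotime range is cut into ``n_bins`` equal-width intervals; each
    bin holds the mean (log-normalised) expression of its cells, empty bins
    are filled by linear interpolation between flanking occupied bins, and
    every gene profile is z-scored across bins.
    """
    pt = pseudotime.loc[expression.index].to_numpy(dtype=float)
    if not np.isfinite(pt).all():
        raise ValueError("pseudotime must be finite")
    lo, hi = pt.min(), pt.max()
    if hi == lo:
        raise ValueError("degenerate pseudotime: all cells at one value")
    bins = np.minimum(((pt - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
    occupied = np.unique(bins)
    if occupied.size == 1:
        raise ValueError("degenerate pseudotime: all cells fall in one bin")

    x = expression.to_numpy(dtype=float)
    prof = np.full((x.shape[1], n_bins), np.nan)
    for b in occupied:
        prof[:, b] = x[bins == b].mean(axis=0)
    missing = np.flatnonzero(np.isnan(prof[0]))
    if missing.size:
        for gi in range(prof.shape[0]):
            prof[gi, missing] = np.interp(missing, occupied, prof[gi, occupied])
    mean = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((prof - mean) / sd, index=expression.columns,
                        columns=[f"bin{b:02d}" for b in range(n_bins)])


def cluster_gene_modules(
    smoothed: pd.DataFrame,
    k_candidates: range = range(2, 13),
    seed: int = 0,
    n_init: int = 10,
) -> ModulePartition:
    """K-means over candidate K; K maximising mean silhouette wins (ties: smaller K)."""
    best_k, best_sil, best_labels = None, -np.inf, None
    sil_by_k: dict[int, float] = {}
    x = smoothed.to_numpy()
    for k in k_candidates:
        if k >= len(smoothed):
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        sil = float(silhouette_score(x, km.labels_))
        sil_by_k[k] = sil
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, km.labels_
    if best_k is None:
        raise ValueError("no feasible K among candidates")
    return ModulePartition(
        pd.Series(best_labels, index=smoothed.index, name="module"), best_k, sil_by_k
    )


def enrich_regulators(
    network: CellNetwork,
    partition: ModulePartition,
    tfs: list[str],
    n_top_edges: int = DEFAULT_TOP_EDGES,
    fdr: float = DEFAULT_FDR,
    universe: set[str] | None = None,
) -> EnrichmentResult:
    """Hypergeometric module enrichment of each TF's targets in one network.

    Targets of a TF are its targets among the network's ``n_top_edges``
    strongest edges, restricted to the universe (the clustered genes by
    default). For TF t and module m with population size U, module size M,
    draws D = |targets(t)| and observed x = |targets(t) & m|:
    p = P(X >= x) upper-tail. BH correction runs across all (t, m) pairs of
    the cell; enriched means q < ``fdr``. TFs with no targets are omitted.
    """
    if universe is None:
        universe = set(partition.genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top = top_pairs(network, n_top_edges)
    targets_of = {
        tf: set(grp["target"]) & universe
        for tf, grp in top.groupby("regulator")
        if tf in set(tfs)
    }
    rows = []
    for tf in sorted(targets_of):
        draws = targets_of[tf]
        if not draws:
            continue
        for m in sorted(partition.assignment.unique()):
            members = partition.module_members(m) & universe
            x = len(draws & members)
            p = float(hypergeom.sf(x - 1, len(universe), len(members), len(draws)))
            rows.append((tf, m, x, p))
    table = pd.DataFrame(rows, columns=["tf", "module", "overlap", "p"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["enriched"] = table["q"] < fdr
    else:
        table["q"], table["enriched"] = [], []
    return EnrichmentResult(network.cell_id, table)


def rank_enriched_regulators(
    results: dict[str, EnrichmentResult],
    cell_types: pd.Series,
    top_m: int = 30,
) -> pd.DataFrame:
    """Per-type enrichment frequency table, long format, ranked within type.

    frequency(tf, type) = fraction of the type's cells where the TF is
    enriched in at least one module. Only the union of each type's top
    ``top_m`` TFs is reported; TFs never enriched are absent.
    """
    frames = []
    for t in pd.unique(cell_types):
        cell_ids = [c for c in cell_types.index[cell_types == t] if c in results]
        if not cell_ids:
            continue
        counts: dict[str, int] = {}
        for c in cell_ids:
            for tf in results[c].enriched_tfs():
                counts[tf] = counts.get(tf, 0) + 1
        if not counts:
            continue
        freq = pd.Series(counts, dtype=float) / len(cell_ids)
        freq = freq.sort_values(ascending=False)
        df = freq.head(top_m).rename("frequency").rename_axis("tf").reset_index()
        df.insert(0, "cell_type", t)
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["cell_type", "tf", "frequency", "rank"])
    return pd.concat(frames, ignore_index=True)


def pseudotime_fallback(coords: np.ndarray, cells: list[str],
                        cell_types: pd.Series | None = None,
                        root_type: str | None = None) -> pd.Series:
    """Rank of the first principal coordinate as a deterministic pseudotime.

    Oriented so the designated root type has the smallest mean when labels
    are provided.
    """
    pc1 = np.asarray(coords)[:, 0].astype(float)
    if cell_types is not None and root_type is not None:
        root_mask = (cell_types.loc[cells] == root_type).to_numpy()
        if root_mask.any() and pc1[root_mask].mean() > pc1[~root_mask].mean():
            pc1 = -pc1
    ranks = pd.Series(pc1, index=cells).rank(method="average")
    return (ranks - 1) / (len(ranks) - 1)
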