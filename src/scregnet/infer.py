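"""Per-cell regulatory network inference.

For every target gene q, the expression of q over a cell's neighborhood
(the cell plus its k nearest neighbors) is regressed on the expression of
all other genes and the accessibility of q's linked peaks with a random
forest. Tree importance scores become regulatory weights: gene j's weight
on target i is its own importance plus the importance of every linked peak
of i that j -- if j is a TF -- has a motif hit in:

    w[i, j] = z[i, j] + sum_l p[i, l] * I[i, j, l]

Expression enters the regressions log-normalised and accessibility
TF-IDF-normalised so predictor scales are comparable. Dropping the peak
predictors and using RNA-only neighbors gives the expression-only mode.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .integrate import NeighborGraph, lognorm, tfidf
from .io import GeneAnnotation, MultiomeDataset
from .links import GenePeakLinks

DEFAULT_N_TREES = 500
MIN_ROWS = 5


@dataclass
class ImportanceScores:
    """Random-forest importances for one target gene's regression."""

    target: str
    z: pd.Series          # regulator gene -> importance
    p: pd.Series          # linked peak -> importance
    model_meta: dict = field(default_factory=dict)


@dataclass
class CellNetwork:
    """Directed regulator -> target weights for one cell (or cell type)."""

    cell_id: str
    edges: pd.DataFrame   # columns regulator, target, weight

    def __post_init__(self) -> None:
        e = self.edges
        if (e["regulator"] == e["target"]).any():
            raise ValueError("self-edge in network")
        if not np.isfinite(e["weight"]).all() or (e["weight"] < 0).any():
            raise ValueError("weights must be finite and >= 0")

    def top(self, n: int) -> pd.DataFrame:
        return top_pairs(self, n)

    def edge_set(self, n: int | None = None) -> set[tuple[str, str]]:
        df = self.edges if n is None else self.top(n)
        return set(zip(df["regulator"], df["target"]))


def derive_seed(global_seed: int, cell_id: str, gene_id: str) -> int:
    """Stable per-(cell, target) RNG seed, independent of execution order."""
    return zlib.crc32(f"{global_seed}:{cell_id}:{gene_id}".encode()) & 0x7FFFFFFF


def prepare_layers(dataset: MultiomeDataset) -> tuple[np.ndarray, np.ndarray]:
    """(log-normalised expression, TF-IDF accessibility) as dense arrays."""
    return lognorm(dataset.rna.values), tfidf(dataset.atac.values)


def fit_target_model(
    target: str,
    rows: np.ndarray,
    expr: np.ndarray,
    genes: list[str],
    acc: np.ndarray | None,
    linked_peaks: list[str],
    peak_ids: list[str] | None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    importance: str = "impurity",
    regulator_pool: list[str] | None = None,
) -> ImportanceScores:
    """One target regression over a neighborhood.

    ``rows`` are the k+1 row indices of the neighborhood; ``expr`` is the
    full cells x genes layer and ``acc`` the cells x peaks layer (None in
    expression-only mode). Importances are impurity decrease by default or
    permutation importance (clipped at 0) with ``importance="permutation"``.
    A constant response yields all-zero importances with a warning.
    """
    if len(rows) < MIN_ROWS:
        raise ValueError(f"neighborhood of {len(rows)} rows is too small to fit (need >= {MIN_ROWS})")
    qi = genes.index(target)
    pool = [g for g in (regulator_pool if regulator_pool is not None else genes) if g != target]
    pool_idx = [genes.index(g) for g in pool]
    y = expr[rows, qi]
    if acc is not None and linked_peaks:
        pk_idx = [peak_ids.index(p) for p in linked_peaks]
        X = np.hstack([expr[np.ix_(rows, pool_idx)], acc[np.ix_(rows, pk_idx)]])
    else:
        linked_peaks = []
        X = expr[np.ix_(rows, pool_idx)]
    meta = {"n_trees": n_trees, "seed": seed, "importance": importance}

    if y.std() == 0:
        warnings.warn(f"target {target} constant over neighborhood; zero importances")
        imp = np.zeros(X.shape[1])
    else:
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        ).fit(X, y)
        if importance == "permutation":
            from sklearn.inspection import permutation_importance

            res = permutation_importance(forest, X, y, n_repeats=5, random_state=seed)
            imp = res.importances_mean
        else:
            imp = forest.feature_importances_
    imp = np.clip(imp, 0.0, None)
    z = pd.Series(imp[: len(pool)], index=pool, name=target)
    p = pd.Series(imp[len(pool):], index=linked_peaks, name=target)
    return ImportanceScores(target, z, p, meta)


def aggregate_weights(scores: ImportanceScores, links: GenePeakLinks) -> pd.Series:
    """w[i, j] = z[i, j] + sum of importances of i's linked peaks bound by TF j."""
    w = scores.z.copy()
    if len(scores.p):
        for tf in list(w.index):
            bonus = scores.p.reindex(
                sorted(links.indicator_peaks(scores.target, tf))
            ).dropna().sum()
            if bonus:
                w[tf] += bonus
    return w


def infer_cell_network(
    cell: int | str,
    graph: NeighborGraph,
    expr: np.ndarray,
    genes: list[str],
    acc: np.ndarray | None,
    peak_ids: list[str] | None,
    links: GenePeakLinks,
    targets: list[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    importance: str = "impurity",
    regulator_pool: list[str] | None = None,
) -> CellNetwork:
    """Full network of one cell: one regression per target, then Eq. 3-4.

    ``acc`` rows must be aligned with ``expr`` rows (for unpaired data the
    caller substitutes each RNA cell's donor accessibility row). Results
    are deterministic given the global seed: each (cell, target) regression
    uses its own derived seed, so execution order cannot matter.
    """
    ci = graph.cells.index(cell) if isinstance(cell, str) else cell
    cell_id = graph.cells[ci]
    # sort the neighborhood by cell id so relabeling/storage order cannot
    # change bootstrap draws
    rows = np.array(sorted(graph.neighborhood(ci), key=lambda r: graph.cells[r]))
    return _network_from_rows(
        cell_id, rows, expr, genes, acc, peak_ids, links, targets,
        n_trees, seed, importance, regulator_pool,
    )


def _network_from_rows(
    cell_id, rows, expr, genes, acc, peak_ids, links, targets,
    n_trees, seed, importance, regulator_pool,
) -> CellNetwork:
    frames = []
    for q in (targets if targets is not None else genes):
        s = fit_target_model(
            q, rows, expr, genes, acc, links.linked_peaks(q), peak_ids,
            n_trees=n_trees, seed=derive_seed(seed, cell_id, q),
            importance=importance, regulator_pool=regulator_pool,
        )
        w = aggregate_weights(s, links)
        w = w[w > 0]
        if len(w):
            frames.append(pd.DataFrame({"regulator": w.index, "target": q, "weight": w.to_numpy()}))
    edges = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["regulator", "target", "weight"])
    )
    return CellNetwork(str(cell_id), edges)


def infer_cell_type_network(
    cells_of_type: list[int],
    mode: str,
    expr: np.ndarray,
    genes: list[str],
    acc: np.ndarray | None,
    peak_ids: list[str] | None,
    links: GenePeakLinks,
    cell_networks: list[CellNetwork] | None = None,
    type_id: str = "type",
    targets: list[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    importance: str = "impurity",
    regulator_pool: list[str] | None = None,
) -> CellNetwork:
    """Cell-type network, direct (one fit, k = type size) or indirect (mean).

    Direct: a single set of regressions whose rows are exactly the cells of
    the type, i.e. the neighbor count equals the type's population. Indirect:
    the arithmetic mean of the type's cell-specific networks, with absent
    edges counted as 0.
    """
    if mode == "direct":
        if len(cells_of_type) < MIN_ROWS:
            raise ValueError("need >= 5 cells of the type for a direct fit")
        rows = np.asarray(cells_of_type)
        return _network_from_rows(
            type_id, rows, expr, genes, acc, peak_ids, links, targets,
            n_trees, seed, importance, regulator_pool,
        )
    if mode == "indirect":
        if not cell_networks:
            raise ValueError("indirect mode needs the per-cell networks")
        stacked = pd.concat([n.edges for n in cell_networks], ignore_index=True)
        mean_w = (
            stacked.groupby(["regulator", "target"], as_index=False)["weight"].sum()
        )
        mean_w["weight"] /= len(cell_networks)
        return CellNetwork(type_id, mean_w)
    raise ValueError(f"unknown mode {mode!r} (expected 'direct' or 'indirect')")


def top_pairs(network: CellNetwork, n: int) -> pd.DataFrame:
    """Top-n edges by weight; ties broken by (regulator, target) lexicographic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    e = network.edges
    if n > len(e):
        warnings.warn(f"requested top {n} of {len(e)} edges; returning all")
        n = len(e)
    ordered = e.sort_values(
        ["weight", "regulator", "target"], ascending=[False, True, True], kind="stable"
    )
    return ordered.head(n).reset_index(drop=True)


def infer_networks_for_cells(
    cell_indices,
    graph: NeighborGraph,
    dataset: MultiomeDataset,
    links: GenePeakLinks,
    annot: GeneAnnotation | None = None,
    mode: str = "multiome",
    donor_rows: np.ndarray | None = None,
    targets: list[str] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    tf_only: bool = False,
) -> dict[str, CellNetwork]:
    """Convenience driver over many cells.

    ``mode="multiome"`` uses expression + linked-peak accessibility;
    ``mode="expression"`` drops the peaks (the RNA-only variant). For
    unpaired data pass ``donor_rows`` mapping each RNA row to its ATAC
    donor row.
    """
    expr = lognorm(dataset.rna.values)
    if mode == "multiome":
        acc = tfidf(dataset.atac.values)
        if donor_rows is not None:
            acc = acc[donor_rows]
        peak_ids = dataset.atac.peak_ids
    elif mode == "expression":
        acc, peak_ids = None, None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pool = annot.tf_ids if (tf_only and annot is not None) else None
    out = {}
    for ci in cell_indices:
        net = infer_cell_network(
            ci, graph, expr, dataset.rna.genes, acc, peak_ids, links,
            targets=targets, n_trees=n_trees, seed=seed, regulator_pool=pool,
        )
        out[net.cell_id] = net
    return out
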