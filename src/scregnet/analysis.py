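"""Network-level evaluation and downstream statistics.

Similarity between two cells' networks is the count of shared directed
(regulator, target) pairs among each network's top-ranked edges; gene
outdegrees over the top edges feed hierarchical cell clustering scored by
the adjusted Rand index; precision/recall compare predictions against a
reference edge set (e.g. ChIP-derived TF->target pairs); and the trait
module links cell-type networks to a trait gene list via target-set
overlaps of top-expressed versus random TFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, spearmanr, ttest_ind
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score, average_precision_score
from statsmodels.stats.multitest import multipletests

from .infer import CellNetwork, top_pairs

DEFAULT_TOP_PAIRS = 3000


@dataclass
class ReferenceEdgeSet:
    """Gold-standard directed (regulator, target) pairs."""

    edges: set[tuple[str, str]]
    source_label: str = "reference"

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("reference edge set is empty")

    @classmethod
    def from_tsv(cls, path, source_label: str = "reference") -> "ReferenceEdgeSet":
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:2])
        return cls(set(zip(df[cols[0]], df[cols[1]])), source_label)


@dataclass
class DegreeMatrix:
    """Cells x genes outdegree counts over each network's top-n edges."""

    values: pd.DataFrame
    n: int


def network_similarity(net_a: CellNetwork, net_b: CellNetwork,
                       n: int = DEFAULT_TOP_PAIRS) -> int:
    """|top-n edges of A  intersect  top-n edges of B| as directed pairs."""
    if net_a.edges.empty or net_b.edges.empty:
        raise ValueError("both networks must be nonempty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return len(net_a.edge_set(n) & net_b.edge_set(n))


def degree_matrix(networks: dict[str, CellNetwork], n: int = DEFAULT_TOP_PAIRS,
                  genes: list[str] | None = None, direction: str = "out") -> DegreeMatrix:
    """Outdegree (or indegree) of every gene within each cell's top-n edges."""
    col = {"out": "regulator", "in": "target"}[direction]
    rows = {}
    for cid, net in networks.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top = top_pairs(net, n)
        rows[cid] = top[col].value_counts()
    df = pd.DataFrame(rows).T.fillna(0).astype(int)
    if genes is not None:
        df = df.reindex(columns=genes, fill_value=0)
    return DegreeMatrix(df, n)


def cluster_cells(dm: DegreeMatrix, n_clusters: int, linkage: str = "ward") -> pd.Series:
    """Hierarchical clustering (Euclidean; Ward by default) of the degree rows."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if len(dm.values) < n_clusters:
        raise ValueError("fewer cells than clusters")
    labels = AgglomerativeClustering(n_clusters=n_clusters, linkage=linkage).fit_predict(
        dm.values.to_numpy()
    )
    return pd.Series(labels, index=dm.values.index, name="cluster")


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (permutation-model ARI)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def precision_recall(predicted: set[tuple[str, str]] | pd.DataFrame,
                     reference: ReferenceEdgeSet) -> tuple[float, float]:
    """Directed-pair precision and recall of predictions vs the reference."""
    if isinstance(predicted, pd.DataFrame):
        predicted = set(zip(predicted["regulator"], predicted["target"]))
    if not predicted:
        warnings.warn("empty prediction; precision/recall are 0")
        return 0.0, 0.0
    hit = len(predicted & reference.edges)
    return hit / len(predicted), hit / len(reference.edges)


def aupr_vs_truth(network: CellNetwork, truth_pairs: set[tuple[str, str]],
                  genes: list[str]) -> float:
    """Area under precision-recall over all ordered gene pairs.

    Absent edges score 0; labels are membership in the planted edge set.
    """
    weights = {(r, t): w for r, t, w in network.edges.itertuples(index=False)}
    y, s = [], []
    for r in genes:
        for t in genes:
            if r == t:
                continue
            y.append((r, t) in truth_pairs)
            s.append(weights.get((r, t), 0.0))
    return float(average_precision_score(y, s))


def regulator_stats(dm: DegreeMatrix, expression: pd.DataFrame,
                    cell_types: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-regulator degree statistics across cells and cell types.

    Returns Spearman rho of degree vs expression over cells, a
    Kruskal-Wallis p for degree differences across types, BH-adjusted
    q-values and a significance flag at adjusted p < alpha. Regulators with
    constant degree get a missing rho.
    """
    types = cell_types.loc[dm.values.index]
    groups = list(pd.unique(types))
    if len(groups) < 2:
        raise ValueError("need >= 2 cell types")
    if min((types == g).sum() for g in groups) < 3:
        raise ValueError("need >= 3 cells per type")
    rows = []
    for gene in dm.values.columns:
        deg = dm.values[gene].to_numpy(dtype=float)
        rho = np.nan
        if gene in expression.columns and deg.std() > 0:
            ex = expression.loc[dm.values.index, gene].to_numpy(dtype=float)
            if ex.std() > 0:
                rho = spearmanr(deg, ex).statistic
        by_type = [deg[(types == g).to_numpy()] for g in groups]
        if deg.std() == 0:
            p = 1.0
        else:
            p = kruskal(*by_type).pvalue
        rows.append((gene, rho, p))
    out = pd.DataFrame(rows, columns=["regulator", "rho_degree_expression", "kw_p"])
    out["kw_q"] = multipletests(out["kw_p"], method="fdr_bh")[1]
    out["significant"] = out["kw_q"] < alpha
    return out.set_index("regulator")


@dataclass
class TraitOverlapResult:
    per_type_p: pd.Series          # trait-relevance t-test p per cell type
    overlaps: pd.DataFrame         # TFs x cell types: |top targets & trait genes|
    key_scores: pd.DataFrame       # per (type, TF): standardized score and rank


def trait_overlap_analysis(
    type_networks: dict[str, CellNetwork],
    trait_genes: set[str],
    expression: pd.DataFrame,
    cell_types: pd.Series,
    tfs: list[str],
    n_top_targets: int = 500,
    n_tf: int = 20,
    seed: int = 0,
) -> TraitOverlapResult:
    """Link cell-type networks to a trait gene list.

    Per TF and type: the TF's ``n_top_targets`` strongest targets in the
    type network are intersected with the trait genes. Per type: a
    two-sample t-test compares the overlap counts of the ``n_tf``
    top-expressed TFs against ``n_tf`` randomly chosen TFs (seeded). Key
    TFs are ranked by the sum of the z-scored mean expression and z-scored
    overlap across TFs.
    """
    if not trait_genes:
        raise ValueError("trait gene list is empty")
    rng = np.random.default_rng(seed)
    if len(tfs) < n_tf:
        warnings.warn(f"only {len(tfs)} TFs available; using all for both groups")
        n_tf = len(tfs)

    overlaps = pd.DataFrame(0, index=tfs, columns=list(type_networks))
    for t, net in type_networks.items():
        by_reg = net.edges.sort_values(
            ["weight", "target"], ascending=[False, True], kind="stable"
        ).groupby("regulator")
        for tf in tfs:
            if tf in by_reg.groups:
                tops = by_reg.get_group(tf)["target"].head(n_top_targets)
                overlaps.loc[tf, t] = len(set(tops) & trait_genes)

    per_type_p, key_frames = {}, []
    for t in type_networks:
        cells_t = cell_types.index[cell_types == t]
        cells_t = [c for c in cells_t if c in expression.index]
        mean_expr = (
            expression.loc[cells_t, [g for g in tfs if g in expression.columns]].mean()
            .reindex(tfs).fillna(0.0)
        )
        top_tfs = list(mean_expr.sort_values(ascending=False).index[:n_tf])
        random_tfs = list(rng.choice(tfs, size=n_tf, replace=len(tfs) < n_tf))
        a = overlaps.loc[top_tfs, t].to_numpy(dtype=float)
        b = overlaps.loc[random_tfs, t].to_numpy(dtype=float)
        if np.std(np.concatenate([a, b])) == 0:
            per_type_p[t] = 1.0
        else:
            per_type_p[t] = float(ttest_ind(a, b).pvalue)
        score = _safe_z(mean_expr) + _safe_z(overlaps[t].astype(float))
        key_frames.append(pd.DataFrame({
            "cell_type": t, "tf": tfs, "key_score": score.to_numpy(),
        }))
    key = pd.concat(key_frames, ignore_index=True)
    key["rank"] = key.groupby("cell_type")["key_score"].rank(ascending=False, method="first")
    return TraitOverlapResult(pd.Series(per_type_p), overlaps, key)


def _safe_z(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    return (s - s.mean()) / sd if sd > 0 else s * 0.0
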