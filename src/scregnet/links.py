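"""Gene-peak association map and the TF-peak binding indicator.

A peak is a candidate for a gene when it intersects the window 250 kb
either side of the gene's TSS; candidates are kept as links when the
absolute Spearman correlation between the gene's expression and the peak's
accessibility across cells exceeds a threshold (0.1 by default). The
indicator records, per (target, TF), the linked peaks of the target that
carry a motif hit for the TF -- the peaks whose importance scores the TF
inherits during weight aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree
from scipy.stats import spearmanr

from .io import AccessibilityMatrix, ExpressionMatrix, GeneAnnotation, MotifHits, PeakSet

DEFAULT_WINDOW_BP = 250_000
DEFAULT_RHO_MIN = 0.1


@dataclass
class GenePeakLinks:
    """Per-gene linked peaks with Spearman rho, plus the TF binding indicator."""

    links: dict[str, list[tuple[str, float]]]
    indicator: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    # indicator[target][tf] = set of linked peak ids of target bound by tf

    def linked_peaks(self, gene: str) -> list[str]:
        return [p for p, _ in self.links.get(gene, [])]

    def indicator_peaks(self, target: str, tf: str) -> set[str]:
        return self.indicator.get(target, {}).get(tf, set())

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, p, r) for g, lst in self.links.items() for p, r in lst]
        return pd.DataFrame(rows, columns=["gene", "peak", "rho"])

    def write(self, links_path: str | Path, indicator_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(links_path, sep="\t", index=False)
        if indicator_path is not None:
            rows = [
                (tgt, tf, p)
                for tgt, by_tf in self.indicator.items()
                for tf, peaks in by_tf.items()
                for p in sorted(peaks)
            ]
            pd.DataFrame(rows, columns=["target", "tf", "peak"]).to_csv(
                indicator_path, sep="\t", index=False
            )


def window_candidates(
    annot: GeneAnnotation, peaks: PeakSet, window_bp: int = DEFAULT_WINDOW_BP
) -> dict[str, list[str]]:
    """Peaks intersecting [tss - window, tss + window] per gene.

    The window is anchored at the TSS and symmetric; strand does not flip
    it. Genes with no peak in range get an empty list.
    """
    trees: dict[str, IntervalTree] = {}
    for pid, row in peaks.table.iterrows():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, pid)
    out: dict[str, list[str]] = {}
    for gene, row in annot.table.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            out[gene] = []
            continue
        lo = max(int(row["tss"]) - window_bp, 0)
        hi = int(row["tss"]) + window_bp + 1  # closed window end -> half-open query
        out[gene] = sorted(iv.data for iv in tree.overlap(lo, hi))
    return out


def correlation_filter(
    candidates: dict[str, list[str]],
    rna: ExpressionMatrix,
    atac_view: np.ndarray | sp.spmatrix,
    peak_ids: list[str],
    rho_min: float = DEFAULT_RHO_MIN,
    signed: bool = False,
) -> GenePeakLinks:
    """Keep candidate pairs whose Spearman correlation clears the threshold.

    ``atac_view`` must share the cell axis with ``rna`` (paired cells, or
    pseudo-paired donor rows for unpaired data). The filter is
    |rho| > rho_min (strict) by default; ``signed=True`` tests rho > rho_min
    instead. Constant vectors give rho = 0 and are dropped. Spearman uses
    average ranks for ties.
    """
    x = np.asarray(sp.csr_matrix(rna.values).todense(), dtype=float)
    y = np.asarray(sp.csr_matrix(atac_view).todense(), dtype=float) \
        if sp.issparse(atac_view) else np.asarray(atac_view, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("rna and atac_view must share the cell axis")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 shared cells for the correlation filter")
    gene_pos = {g: i for i, g in enumerate(rna.genes)}
    peak_pos = {p: i for i, p in enumerate(peak_ids)}
    links: dict[str, list[tuple[str, float]]] = {}
    for gene, cand in candidates.items():
        kept: list[tuple[str, float]] = []
        gi = gene_pos.get(gene)
        if gi is not None:
            gx = x[:, gi]
            if gx.std() > 0:
                for pid in cand:
                    pj = peak_pos.get(pid)
                    if pj is None:
                        continue
                    py = y[:, pj]
                    if py.std() == 0:
                        continue
                    rho = spearmanr(gx, py).statistic
                    stat = rho if signed else abs(rho)
                    if np.isfinite(rho) and stat > rho_min:
                        kept.append((pid, float(rho)))
        links[gene] = kept
    return GenePeakLinks(links)


def attach_motif_indicator(links: GenePeakLinks, motif_hits: MotifHits,
                           annot: GeneAnnotation) -> GenePeakLinks:
    """Fill indicator[target][tf] with linked peaks of the target the TF binds.

    Non-TF genes (and TFs binding no linked peak) get no entry, which reads
    back as the empty set.
    """
    tf_set = set(annot.tf_ids)
    bound = {tf: motif_hits.peaks_bound_by(tf) for tf in motif_hits.tfs if tf in tf_set}
    indicator: dict[str, dict[str, set[str]]] = {}
    for gene, lst in links.links.items():
        linked = {p for p, _ in lst}
        by_tf = {}
        for tf, peaks in bound.items():
            inter = linked & peaks
            if inter:
                by_tf[tf] = inter
        if by_tf:
            indicator[gene] = by_tf
    links.indicator = indicator
    return links


def build_links(
    annot: GeneAnnotation,
    peaks: PeakSet,
    rna: ExpressionMatrix,
    atac_view,
    peak_ids: list[str],
    motif_hits: MotifHits,
    window_bp: int = DEFAULT_WINDOW_BP,
    rho_min: float = DEFAULT_RHO_MIN,
    signed: bool = False,
) -> GenePeakLinks:
    """Window -> correlation filter -> motif indicator, in one call."""
    cand = window_candidates(annot, peaks, window_bp)
    links = correlation_filter(cand, rna, atac_view, peak_ids, rho_min, signed)
    return attach_motif_indicator(links, motif_hits, annot)
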