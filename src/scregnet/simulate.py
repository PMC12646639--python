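"""Synthetic paired/unpaired multiome data with a planted regulatory truth.

The generator emulates the joint structure the inference pipeline exploits:
transcription factors (TFs) whose activity varies across cell types along a
linear differentiation axis, target genes (TGs) whose expression is driven
by their regulators, ATAC peaks near each gene whose openness saturates
with regulatory drive, and motif occurrences planted on the peaks of each
TF's targets. Cell types double as pseudotime stages, and TFs/targets are
organised into temporal modules (stage-peaked, rising, falling) so that
module discovery and per-type master regulators are recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    AccessibilityMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    MotifHits,
    MultiomeDataset,
    PeakSet,
)

__all__ = ["SimulationConfig", "GroundTruthGRN", "simulate_multiome", "split_unpaired"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic multiome generator.

    The defaults describe the standard benchmark condition: 4 cell types x
    100 cells, 10 TFs, 50 targets, 2 peaks per gene on one synthetic contig
    with genes spaced 600 kb apart (so +/-250 kb TSS windows never collide;
    lower ``gene_spacing`` to build a collision fixture).
    """

    n_cell_types: int = 4
    cells_per_type: int = 100
    n_tfs: int = 10
    n_targets: int = 50
    n_peaks_per_gene: int = 2
    noise_sd: float = 0.2          # sd of additive expression noise, relative scale
    dropout_rate: float = 0.1      # Bernoulli zeroing of RNA counts, post-Poisson
    seed: int = 0
    paired: bool = True
    n_modules: int = 6             # temporal co-expression modules
    motif_false_hit_rate: float = 0.05
    link: str = "saturating"       # peak->expression coupling: "saturating" | "linear"
    gene_spacing: int = 600_000    # bp between consecutive TSSs on the contig
    gene_body_len: int = 10_000
    tf_base: float = 6.0           # baseline TF activity (count scale)
    tf_noise_sigma: float = 0.3    # lognormal cell-to-cell TF activity jitter
    secondary_regulator_prob: float = 0.5
    negative_sign_prob: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "cells_per_type", "n_tfs", "n_targets", "n_peaks_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.link not in {"saturating", "linear"}:
            raise ValueError(f"unknown link {self.link!r}")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")


@dataclass
class GroundTruthGRN:
    """Planted edges, module map and per-type TF activity multipliers."""

    edges: list[tuple[str, str, str, float]]  # (tf, target, sign, strength)
    modules: dict[str, int]
    cell_type_activity: pd.DataFrame          # TFs x cell types
    master_tfs: dict[str, str] = field(default_factory=dict)  # cell type -> TF

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(tf, tg) for tf, tg, _, _ in self.edges}


def _module_patterns(n_modules: int, n_types: int) -> np.ndarray:
    """Activity multiplier per (module, cell type stage).

    The first ``n_types`` modules peak at one stage each; further modules
    are rising/falling ramps and broad plateaus. Used for reporting and as
    anchors; per-cell activity is evaluated continuously along pseudotime
    by :func:`_module_activity`.
    """
    mid = (np.arange(n_types) + 0.5) / n_types
    return np.array([_module_activity(m, mid, n_types) for m in range(n_modules)])


_HI, _LO = 8.0, 1.0


def _module_activity(m: int, pt: np.ndarray, n_types: int) -> np.ndarray:
    """Activity multiplier of module ``m`` at pseudotime ``pt`` in [0, 1].

    Stage modules are Gaussian bumps at stage midpoints; the next two are
    monotone rising/falling ramps; extras are early/late sigmoidal
    plateaus. Smooth profiles keep the modules identifiable from binned
    expression and give cells within a type graded regulatory states.
    """
    pt = np.asarray(pt, dtype=float)
    stage = np.clip((pt * n_types).astype(int), 0, n_types - 1)
    half = max(1, n_types // 2)
    if m < n_types:  # active in one stage
        shape = (stage == m).astype(float)
    elif m == n_types:  # broad early
        shape = (stage < half).astype(float)
    elif m == n_types + 1:  # broad late
        shape = (stage >= half).astype(float)
    elif m == n_types + 2:  # rising
        shape = stage / max(n_types - 1, 1)
    else:  # falling
        shape = 1.0 - stage / max(n_types - 1, 1)
    return _LO + (_HI - _LO) * shape


def simulate_multiome(cfg: SimulationConfig):
    """Generate one synthetic multiome experiment.

    Returns ``(dataset, annot, peaks, motif_hits, truth, cell_types,
    pseudotime)``. With ``noise_sd == 0`` and ``dropout_rate == 0`` the
    count-sampling step is skipped and the deterministic latent intensities
    are emitted directly (noise-free mode, used by exactness tests).
    """
    rng = np.random.default_rng(cfg.seed)
    n_types, n_cells = cfg.n_cell_types, cfg.n_cell_types * cfg.cells_per_type
    n_modules = min(cfg.n_modules, cfg.n_tfs)

    cells = [f"cell{i:04d}" for i in range(n_cells)]
    type_of = np.repeat(np.arange(n_types), cfg.cells_per_type)
    cell_types = pd.Series([f"type{t}" for t in type_of], index=cells, name="cell_type")
    pseudotime = pd.Series(
        (type_of + rng.uniform(0.0, 0.95, n_cells)) / n_types, index=cells, name="pseudotime"
    )

    tf_ids = [f"TF{j:02d}" for j in range(cfg.n_tfs)]
    tg_ids = [f"TG{i:02d}" for i in range(cfg.n_targets)]
    genes = tf_ids + tg_ids

    # --- gene geometry on one synthetic contig -----------------------------
    first_tss = 300_000 + cfg.gene_body_len
    tss = first_tss + cfg.gene_spacing * np.arange(len(genes))
    strands = np.where(np.arange(len(genes)) % 2 == 0, "+", "-")
    starts = np.where(strands == "+", tss, tss - cfg.gene_body_len + 1)
    ends = np.where(strands == "+", tss + cfg.gene_body_len, tss + 1)
    annot = GeneAnnotation(
        pd.DataFrame(
            {
                "chrom": "chrS",
                "tss": tss,
                "strand": strands,
                "is_tf": [g in set(tf_ids) for g in genes],
                "start": starts,
                "end": ends,
            },
            index=pd.Index(genes, name="gene_id"),
        )
    )

    # --- modules, edges, activity patterns ---------------------------------
    patterns = _module_patterns(n_modules, n_types)
    tf_module = {tf: j % n_modules for j, tf in enumerate(tf_ids)}
    module_tfs: dict[int, list[str]] = {m: [] for m in range(n_modules)}
    for tf in tf_ids:
        module_tfs[tf_module[tf]].append(tf)

    modules = dict(tf_module)
    edges: list[tuple[str, str, str, float]] = []
    for i, tg in enumerate(tg_ids):
        m = i % n_modules
        modules[tg] = m
        regs = [module_tfs[m][0]]
        if len(module_tfs[m]) > 1 and rng.random() < cfg.secondary_regulator_prob:
            regs.append(module_tfs[m][1])
        for r, tf in enumerate(regs):
            # the primary regulator drives the target; secondaries modulate
            sign = "+" if r == 0 or rng.random() >= cfg.negative_sign_prob else "-"
            strength = rng.uniform(0.8, 1.5) if r == 0 else rng.uniform(0.3, 0.7)
            edges.append((tf, tg, sign, strength))

    activity = pd.DataFrame(
        patterns[[tf_module[tf] for tf in tf_ids]],
        index=tf_ids,
        columns=[f"type{t}" for t in range(n_types)],
    )
    master_tfs = {f"type{t}": module_tfs[t][0] for t in range(min(n_types, n_modules))}
    truth = GroundTruthGRN(edges, modules, activity, master_tfs)

    # --- latent TF activity per cell: smooth along pseudotime ---------------
    jitter = rng.lognormal(0.0, cfg.tf_noise_sigma, (n_cells, cfg.n_tfs))
    pt_vals = pseudotime.to_numpy()
    act = np.column_stack(
        [_module_activity(tf_module[tf], pt_vals, n_types) for tf in tf_ids]
    )
    tf_latent = cfg.tf_base * act * jitter

    # --- latent target expression and regulatory drive ----------------------
    drive = np.zeros((n_cells, cfg.n_targets))        # positive regulatory input
    signed = np.zeros((n_cells, cfg.n_targets))       # signed contribution to expression
    tf_index = {tf: j for j, tf in enumerate(tf_ids)}
    tg_index = {tg: i for i, tg in enumerate(tg_ids)}
    for tf, tg, sign, strength in edges:
        a = tf_latent[:, tf_index[tf]]
        drive[:, tg_index[tg]] += strength * a
        signed[:, tg_index[tg]] += (1.0 if sign == "+" else -1.0) * strength * a

    sat_k = cfg.tf_base * np.mean(patterns)           # half-saturation of peak openness
    openfrac = drive / (drive + sat_k)                # in [0, 1)
    base = 1.0
    if cfg.link == "saturating":
        tg_latent = base + signed * openfrac
    else:
        tg_latent = base + signed
    tg_latent = np.clip(tg_latent, 0.0, None)
    if cfg.noise_sd > 0:
        # additive noise scaled to each gene's mean level (mean-zero, Eq.-style epsilon)
        scale = tg_latent.mean(axis=0, keepdims=True)
        tg_latent = np.clip(tg_latent + rng.normal(0.0, cfg.noise_sd, tg_latent.shape) * scale, 0.0, None)
    expr_latent = np.hstack([tf_latent, tg_latent])

    # --- peaks: one promoter + distal peaks within +/-250 kb of the TSS -----
    peak_rows, peak_gene, peak_drive_cols = [], [], []
    for gi, g in enumerate(genes):
        g_tss = tss[gi]
        offsets = [0] + list(rng.integers(20_000, 200_000, cfg.n_peaks_per_gene - 1)
                             * rng.choice([-1, 1], cfg.n_peaks_per_gene - 1))
        for pk, off in enumerate(offsets):
            center = int(g_tss + off)
            start, end = center - 250, center + 250
            if start < 0:
                raise ValueError("infeasible geometry: peak before contig start")
            peak_rows.append((f"peak_{g}_{pk}", "chrS", start, end))
            peak_gene.append(g)
            peak_drive_cols.append(gi)
    peaks = PeakSet(
        pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end"]).set_index("peak_id")
    )

    # openness follows the gene's regulatory drive (targets) or own activity (TFs)
    gene_drive = np.hstack([tf_latent, drive])
    open_latent = 3.0 * gene_drive[:, peak_drive_cols] / (gene_drive[:, peak_drive_cols] + sat_k)
    # keep column order aligned with the sorted PeakSet
    order = [peaks.peak_ids.index(r[0]) for r in peak_rows]
    open_sorted = np.empty_like(open_latent)
    open_sorted[:, order] = open_latent

    # --- count sampling ------------------------------------------------------
    noise_free = cfg.noise_sd == 0 and cfg.dropout_rate == 0
    if noise_free:
        rna_counts, atac_counts = expr_latent, open_sorted
    else:
        rna_counts = rng.poisson(expr_latent).astype(float)
        if cfg.dropout_rate > 0:
            rna_counts *= rng.random(rna_counts.shape) >= cfg.dropout_rate
        atac_counts = rng.poisson(open_sorted).astype(float)

    rna = ExpressionMatrix(cells, genes, sp.csr_matrix(rna_counts), layer="counts")
    atac = AccessibilityMatrix(cells, peaks, sp.csr_matrix(atac_counts))
    dataset = MultiomeDataset(rna, atac, paired=True, cell_types={"rna": cell_types, "atac": cell_types.copy()})

    # --- motif hits: true TF on every peak of each of its targets ------------
    hits = np.zeros((cfg.n_tfs, len(peaks)), dtype=int)
    pid_by_gene: dict[str, list[int]] = {}
    sorted_ids = peaks.peak_ids
    for pid, g in zip([r[0] for r in peak_rows], peak_gene):
        pid_by_gene.setdefault(g, []).append(sorted_ids.index(pid))
    for tf, tg, _, _ in edges:
        for pi in pid_by_gene[tg]:
            hits[tf_index[tf], pi] = 1
    # TFs also bind their own promoters (self-loops are excluded downstream)
    for tf in tf_ids:
        for pi in pid_by_gene[tf]:
            hits[tf_index[tf], pi] = 1
    if cfg.motif_false_hit_rate > 0:
        flip = (rng.random(hits.shape) < cfg.motif_false_hit_rate) & (hits == 0)
        hits[flip] = 1
    motif_hits = MotifHits(tf_ids, sorted_ids, hits)

    if not cfg.paired:
        dataset = split_unpaired(dataset, 0.5, seed=int(rng.integers(2**31)))
    return dataset, annot, peaks, motif_hits, truth, cell_types, pseudotime


def split_unpaired(dataset: MultiomeDataset, fraction_rna: float, seed: int) -> MultiomeDataset:
    """Split a paired dataset into disjoint RNA-only and ATAC-only cell sets.

    Stratified by cell type (within +/-1 cell per type) so both modalities
    retain the type composition. Per-modality labels are kept.
    """
    if not dataset.paired:
        raise ValueError("split_unpaired needs a paired dataset")
    if not 0 < fraction_rna < 1:
        raise ValueError("fraction_rna must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cells = np.array(dataset.rna.cells)
    types = dataset.cell_types.get("rna")
    if types is None:
        types = pd.Series("all", index=cells)
    rna_idx: list[int] = []
    for t in pd.unique(types):
        idx = np.flatnonzero((types == t).to_numpy())
        take = int(round(fraction_rna * len(idx)))
        rna_idx.extend(rng.permutation(idx)[:take])
    rna_mask = np.zeros(len(cells), dtype=bool)
    rna_mask[rna_idx] = True

    rna = ExpressionMatrix(
        list(cells[rna_mask]), dataset.rna.genes, dataset.rna.values[rna_mask], dataset.rna.layer
    )
    atac = AccessibilityMatrix(
        list(cells[~rna_mask]), dataset.atac.peaks, dataset.atac.values[~rna_mask]
    )
    return MultiomeDataset(
        rna,
        atac,
        paired=False,
        cell_types={"rna": types[rna_mask], "atac": types[~rna_mask]},
    )
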