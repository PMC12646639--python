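"""Readers, writers and validated domain containers.

All genomic intervals are 0-based half-open internally (BED convention);
GTF coordinates (1-based inclusive) are converted once at parse time, with
the TSS taken strand-aware (start for ``+``, end-1 for ``-``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file failed structural validation; the message names the file."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Gene metadata: chromosome, TSS, strand, TF status, optional gene body.

    ``table`` is indexed by gene_id with columns ``chrom``, ``tss``,
    ``strand``, ``is_tf`` and optional ``start``/``end`` (gene body extent,
    0-based half-open). The TSS anchors the +/-250 kb peak-association
    window; ``is_tf`` marks genes eligible for the motif-based weight bonus.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            raise FormatError("duplicate gene ids in annotation")
        if (t["tss"] < 0).any():
            raise FormatError("negative TSS in annotation")
        bad = set(t["strand"]) - {"+", "-"}
        if bad:
            raise FormatError(f"unknown strand symbol(s): {sorted(bad)}")
        if "is_tf" not in t.columns:
            t["is_tf"] = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_tf"]])

    def has_gene_body(self) -> bool:
        return "start" in self.table.columns and "end" in self.table.columns


@dataclass
class PeakSet:
    """ATAC peak intervals, 0-based half-open, sorted per chromosome."""

    table: pd.DataFrame  # index peak_id; columns chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            raise FormatError("duplicate peak ids")
        if (t["start"] >= t["end"]).any():
            raise FormatError("peak with start >= end")
        self.table = t.sort_values(["chrom", "start"], kind="stable")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix (sparse), with a named layer."""

    cells: list[str]
    genes: list[str]
    values: sp.csr_matrix
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        n, g = self.values.shape
        if n != len(self.cells) or g != len(self.genes):
            raise FormatError(
                f"expression matrix is {n}x{g} but {len(self.cells)} cells / "
                f"{len(self.genes)} genes were given"
            )
        if len(set(self.cells)) != n or len(set(self.genes)) != g:
            raise FormatError("duplicate cell or gene ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative entries in expression matrix")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class AccessibilityMatrix:
    """Cells x peaks matrix (sparse) tied to a PeakSet."""

    cells: list[str]
    peaks: PeakSet
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        n, p = self.values.shape
        if n != len(self.cells) or p != len(self.peaks):
            raise FormatError(
                f"accessibility matrix is {n}x{p} but {len(self.cells)} cells / "
                f"{len(self.peaks)} peaks were given"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative entries in accessibility matrix")

    @property
    def peak_ids(self) -> list[str]:
        return self.peaks.peak_ids


@dataclass
class MultiomeDataset:
    """Paired or unpaired RNA + ATAC measurements.

    Paired: the two modalities index the same cells in the same order.
    Unpaired: disjoint cell sets; per-modality type labels may be given.
    """

    rna: ExpressionMatrix
    atac: AccessibilityMatrix
    paired: bool
    cell_types: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.paired and self.rna.cells != self.atac.cells:
            raise FormatError("paired dataset but RNA and ATAC barcodes differ")

    @property
    def n_cells(self) -> int:
        return self.rna.n_cells


@dataclass
class MotifHits:
    """Binary TF x peak motif-occurrence matrix."""

    tfs: list[str]
    peaks: list[str]
    hits: np.ndarray  # (n_tf, n_peak), values in {0, 1}

    def __post_init__(self) -> None:
        self.hits = np.asarray(self.hits)
        if self.hits.shape != (len(self.tfs), len(self.peaks)):
            raise FormatError("motif hit matrix shape mismatch")
        if not np.isin(self.hits, (0, 1)).all():
            raise FormatError("motif hits must be binary")

    def peaks_bound_by(self, tf: str) -> set[str]:
        if tf not in self.tfs:
            return set()
        row = self.hits[self.tfs.index(tf)]
        return {self.peaks[i] for i in np.flatnonzero(row)}


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def _read_lines(path: str | Path) -> list[str]:
    return Path(path).read_text().splitlines()


def read_mtx_matrix(mtx_path, barcodes_path, features_path) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read an MTX triplet (features x cells on disk, 10x style) as cells x features."""
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path))).T
    barcodes = [l.split("\t")[0] for l in _read_lines(barcodes_path) if l]
    features = [l.split("\t")[0] for l in _read_lines(features_path) if l]
    n, g = mat.shape
    if n != len(barcodes):
        raise FormatError(f"{mtx_path}: {n} columns but {len(barcodes)} barcodes")
    if g != len(features):
        raise FormatError(f"{mtx_path}: {g} rows but {len(features)} features")
    return mat, barcodes, features


def write_mtx_matrix(mat, barcodes, features, mtx_path, barcodes_path, features_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(sp.csr_matrix(mat).T))
    Path(barcodes_path).write_text("\n".join(barcodes) + "\n")
    Path(features_path).write_text("\n".join(features) + "\n")


def read_bed(path: str | Path) -> PeakSet:
    """BED3/BED4; a missing name column synthesizes ids as chrom:start-end."""
    rows = []
    for i, line in enumerate(_read_lines(path), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}: line {i} has {len(parts)} columns, need >= 3")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        name = parts[3] if len(parts) >= 4 else f"{chrom}:{start}-{end}"
        rows.append((name, chrom, start, end))
    df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"]).set_index("peak_id")
    return PeakSet(df)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, row in peaks.table.iterrows():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{pid}\n")


def read_gene_annotation(path: str | Path, tf_list_path=None) -> GeneAnnotation:
    """Gene annotation from a 4+-column TSV or a GTF.

    TSV columns: gene_id, chrom, tss, strand [, start, end] with a header.
    GTF: ``gene`` features; TSS derived strand-aware and converted to
    0-based; gene body retained.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        df = _parse_gtf_genes(path)
    else:
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
        df = df.set_index("gene_id")
    if tf_list_path is not None:
        tfs = {l.strip() for l in _read_lines(tf_list_path) if l.strip()}
        df["is_tf"] = df.index.isin(tfs)
    elif "is_tf" in df.columns:
        df["is_tf"] = df["is_tf"].astype(bool)
    else:
        df["is_tf"] = False
    return GeneAnnotation(df)


def _parse_gtf_genes(path: Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(_read_lines(path), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise FormatError(f"{path}: line {i} has {len(parts)} columns, need 9")
        if parts[2] != "gene":
            continue
        chrom, start1, end1, strand, attrs = parts[0], int(parts[3]), int(parts[4]), parts[6], parts[8]
        gene_id = None
        for token in attrs.split(";"):
            token = token.strip()
            if token.startswith("gene_id"):
                gene_id = token.split(None, 1)[1].strip().strip('"')
        if gene_id is None:
            raise FormatError(f"{path}: line {i} lacks gene_id attribute")
        start0, end0 = start1 - 1, end1  # to 0-based half-open
        tss = start0 if strand == "+" else end0 - 1
        rows.append((gene_id, chrom, tss, strand, start0, end0))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "strand", "start", "end"]
    ).set_index("gene_id")


def write_gene_annotation(annot: GeneAnnotation, path: str | Path) -> None:
    df = annot.table.reset_index()
    if "index" in df.columns:
        df = df.rename(columns={"index": "gene_id"})
    df.to_csv(path, sep="\t", index=False)


def load_multiome(
    rna_mtx, rna_barcodes, rna_features,
    atac_mtx, atac_barcodes, peaks_bed,
    paired: bool,
    cell_types: dict[str, pd.Series] | None = None,
) -> MultiomeDataset:
    """Assemble and validate a MultiomeDataset from on-disk pieces."""
    rna_vals, rna_cells, genes = read_mtx_matrix(rna_mtx, rna_barcodes, rna_features)
    peaks = read_bed(peaks_bed)
    atac_vals = sp.csr_matrix(scipy.io.mmread(str(atac_mtx))).T
    atac_cells = [l.split("\t")[0] for l in _read_lines(atac_barcodes) if l]
    if atac_vals.shape[0] != len(atac_cells):
        raise FormatError(f"{atac_mtx}: {atac_vals.shape[0]} columns but {len(atac_cells)} barcodes")
    if atac_vals.shape[1] != len(peaks):
        raise FormatError(f"{atac_mtx}: {atac_vals.shape[1]} features but {len(peaks)} BED rows in {peaks_bed}")
    rna = ExpressionMatrix(rna_cells, genes, rna_vals)
    atac = AccessibilityMatrix(atac_cells, peaks, atac_vals)
    empty = int((np.asarray(rna.values.sum(axis=1)).ravel() == 0).sum())
    if empty:
        logger.warning("%d all-zero RNA cells in %s", empty, rna_mtx)
    return MultiomeDataset(rna, atac, paired, cell_types or {})


# ---------------------------------------------------------------------------
# motif handling
# ---------------------------------------------------------------------------


def read_motif_hits_tsv(path: str | Path, annot: GeneAnnotation | None = None) -> MotifHits:
    """Precomputed binary TF x peak matrix: first column TF ids, header = peak ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    tfs = list(df.index)
    if annot is not None:
        known = set(annot.gene_ids)
        keep = [t in known for t in tfs]
        if not all(keep):
            dropped = [t for t, k in zip(tfs, keep) if not k]
            warnings.warn(f"dropping motif TFs absent from annotation: {dropped}")
            df = df.loc[[t for t, k in zip(tfs, keep) if k]]
            tfs = list(df.index)
    return MotifHits(tfs, list(df.columns), df.to_numpy())


def write_motif_hits_tsv(hits: MotifHits, path: str | Path) -> None:
    pd.DataFrame(hits.hits, index=hits.tfs, columns=hits.peaks).to_csv(path, sep="\t")


def scan_motifs(
    jaspar_path: str | Path,
    peaks: PeakSet,
    genome_fasta: str | Path,
    annot: GeneAnnotation | None = None,
    pvalue: float = 1e-4,
) -> MotifHits:
    """Scan peak sequences with JASPAR PFMs (log-odds PWM, both strands).

    The score threshold is the log-odds value whose false-positive rate
    under a 0-order background -- estimated from the scanned sequences
    themselves -- equals ``pvalue``. A peak is a hit for a TF if any window
    on either strand reaches the threshold.
    """
    from Bio import SeqIO, motifs as bio_motifs
    from Bio.Seq import Seq

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    seqs = {}
    for pid, row in peaks.table.iterrows():
        if row.chrom not in contigs:
            raise FormatError(f"FASTA contig {row.chrom!r} missing for peak {pid}")
        seqs[pid] = contigs[row.chrom][row.start:row.end]

    # 0-order background from the scanned sequences
    counts = {b: 1.0 for b in "ACGT"}  # pseudocount avoids zero frequencies
    for s in seqs.values():
        for b in "ACGT":
            counts[b] += s.count(b)
    total = sum(counts.values())
    background = {b: counts[b] / total for b in "ACGT"}

    with open(jaspar_path) as fh:
        pfms = list(bio_motifs.parse(fh, "jaspar"))
    if annot is not None:
        known = set(annot.gene_ids)
        dropped = [m.name for m in pfms if m.name not in known]
        if dropped:
            warnings.warn(f"dropping motif TFs absent from annotation: {dropped}")
        pfms = [m for m in pfms if m.name in known]

    peak_ids = peaks.peak_ids
    hits = np.zeros((len(pfms), len(peak_ids)), dtype=int)
    for mi, motif in enumerate(pfms):
        pwm = motif.counts.normalize(pseudocounts=0.5)
        pssm = pwm.log_odds(background)
        dist = pssm.distribution(background=background, precision=10**3)
        threshold = dist.threshold_fpr(pvalue)
        rpssm = pssm.reverse_complement()
        for pi, pid in enumerate(peak_ids):
            s = seqs[pid]
            if len(s) < motif.length:
                continue
            seq = Seq(s)
            scores = np.concatenate([
                np.asarray(pssm.calculate(seq), dtype=float).ravel(),
                np.asarray(rpssm.calculate(seq), dtype=float).ravel(),
            ])
            scores = scores[np.isfinite(scores)]
            if scores.size and scores.max() >= threshold:
                hits[mi, pi] = 1
    return MotifHits([m.name for m in pfms], peak_ids, hits)


def load_motifs(
    source: str | Path,
    peaks: PeakSet,
    genome_fasta: str | Path | None = None,
    annot: GeneAnnotation | None = None,
    pvalue: float = 1e-4,
) -> MotifHits:
    """Direct mode (TSV hit matrix) when no FASTA is given, else scan mode."""
    if genome_fasta is None:
        return read_motif_hits_tsv(source, annot)
    return scan_motifs(source, peaks, genome_fasta, annot, pvalue)


# ---------------------------------------------------------------------------
# network edge TSVs
# ---------------------------------------------------------------------------

EDGE_HEADER = ["regulator", "target", "weight"]


def write_network(edges: pd.DataFrame, path: str | Path) -> None:
    """Write (regulator, target, weight) triples with a header."""
    edges.loc[:, EDGE_HEADER].to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> pd.DataFrame:
    rows = []
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != EDGE_HEADER:
        raise FormatError(f"{path}: expected header {' '.join(EDGE_HEADER)}")
    for i, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: line {i} has {len(parts)} columns, need 3")
        reg, tgt, w = parts[0], parts[1], float(parts[2])
        if reg == tgt:
            warnings.warn(f"{path}: line {i} is a self-loop ({reg}); dropped")
            continue
        rows.append((reg, tgt, w))
    return pd.DataFrame(rows, columns=EDGE_HEADER)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """YAML key/value run configuration (input paths, k, window, thresholds, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
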