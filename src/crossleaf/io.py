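"""Readers and writers for the external formats the pipeline touches.

Count matrices travel as Matrix Market + gene/cell label TSVs and live in
memory as :class:`anndata.AnnData` (cells as ``obs``, genes as ``var``).
Peaks are BED6+N (extra columns are per-cell-type accessibility counts),
motifs are JASPAR-format PFM text, TSSs and orthology maps are plain TSV.
All genomic coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

REQUIRED_CELL_COLUMNS = ("species", "cell_type", "time_h", "batch")

__all__ = [
    "PeakRecord",
    "PWMModel",
    "read_counts",
    "write_counts",
    "read_jaspar_pfm",
    "read_jaspar_library",
    "write_jaspar_library",
    "read_bed_peaks",
    "write_bed_peaks",
    "read_fasta",
    "write_fasta",
    "read_tss",
    "write_tss",
    "read_gene_bodies",
    "write_gene_bodies",
    "read_orthology",
    "write_orthology",
    "read_truth",
    "write_truth",
]


@dataclass
class PeakRecord:
    """An accessible-chromatin interval with per-cell-type fragment counts.

    Coordinates are 0-based half-open.  ``counts`` maps cell-type label to
    the summed accessibility count for that cell type; ``sequence`` is the
    peak's genomic sequence when available (upper-case, Ns preserved).
    """

    chrom: str
    start: int
    end: int
    peak_id: str
    counts: dict = field(default_factory=dict)
    sequence: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.peak_id}: start ({self.start}) must be < end ({self.end})"
            )
        for ct, v in self.counts.items():
            if v < 0:
                raise ValueError(f"peak {self.peak_id}: negative count for {ct}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class PWMModel:
    """Position probability matrix over A,C,G,T with a background model.

    ``probs`` has shape (4, width) with rows in A,C,G,T order; each column
    sums to 1.  ``background`` is the 4-vector of base frequencies used for
    log-odds scoring.  ``pseudocount`` records the per-cell pseudocount that
    was applied when normalizing raw counts.
    """

    motif_id: str
    name: str
    probs: np.ndarray
    background: np.ndarray = None
    pseudocount: float = 0.01

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("probability matrix must have 4 rows (A,C,G,T)")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("each PWM column must sum to 1 (after normalization)")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(cls, motif_id, name, counts, background=None, pseudocount=0.01):
        """Build from a raw count PFM; adds ``pseudocount`` per cell before
        column normalization (a column of counts (1,0,0,0) with eps=0.01
        becomes (1.01, .01, .01, .01)/1.04)."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A,C,G,T)")
        if (counts < 0).any():
            raise ValueError(f"motif {motif_id}: negative counts in PFM")
        padded = counts + pseudocount
        probs = padded / padded.sum(axis=0, keepdims=True)
        return cls(motif_id, name, probs, background, pseudocount)

    @classmethod
    def from_consensus(cls, motif_id, consensus, strength=0.97, background=None):
        """Near-deterministic PWM for a consensus string (each column puts
        ``strength`` on the consensus base, the rest spread evenly)."""
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        w = len(consensus)
        probs = np.full((4, w), (1.0 - strength) / 3.0)
        for j, base in enumerate(consensus.upper()):
            probs[idx[base], j] = strength
        return cls(motif_id, consensus.upper(), probs, background)


# ---------------------------------------------------------------------------
# count matrices (Matrix Market + label TSVs)
# ---------------------------------------------------------------------------

def read_counts(mtx_path, genes_path, cells_path) -> ad.AnnData:
    """Read a genes x cells Matrix Market file plus label TSVs into AnnData.

    The returned AnnData is cells x genes (scanpy convention); per-cell
    metadata (species, cell_type, time_h, batch) lives in ``.obs``.
    """
    mtx_path, genes_path, cells_path = map(Path, (mtx_path, genes_path, cells_path))
    mat = scipy.io.mmread(str(mtx_path))
    mat = sp.csr_matrix(mat)
    dense_check = mat.data
    if dense_check.size and not np.allclose(dense_check, np.round(dense_check)):
        raise ValueError(f"{mtx_path}: matrix contains non-integer entries")
    if dense_check.size and dense_check.min() < 0:
        raise ValueError(f"{mtx_path}: matrix contains negative entries")
    genes = pd.read_csv(genes_path, sep="\t")
    if "gene" not in genes.columns:
        raise ValueError(f"{genes_path}: missing required column 'gene'")
    cells = pd.read_csv(cells_path, sep="\t")
    for col in ("cell",) + REQUIRED_CELL_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"{cells_path}: missing required column '{col}'")
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch: {mtx_path} is {mat.shape} but "
            f"{genes_path} has {len(genes)} genes and {cells_path} has {len(cells)} cells"
        )
    if genes["gene"].duplicated().any():
        raise ValueError(f"{genes_path}: duplicated gene identifiers")
    if cells["cell"].duplicated().any():
        raise ValueError(f"{cells_path}: duplicated cell identifiers")
    obs = cells.set_index("cell")
    obs.index = obs.index.astype(str)
    obs["time_h"] = obs["time_h"].astype(float)
    var = genes.set_index("gene")
    var.index = var.index.astype(str)
    adata = ad.AnnData(X=mat.T.tocsr(), obs=obs, var=var)
    return adata


def write_counts(adata: ad.AnnData, outdir, prefix) -> None:
    """Write AnnData back to <prefix>.mtx / <prefix>.genes.tsv / <prefix>.cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X).T  # genes x cells on disk
    scipy.io.mmwrite(str(outdir / f"{prefix}.mtx"), sp.coo_matrix(X.astype(int)))
    pd.DataFrame({"gene": adata.var_names}).to_csv(
        outdir / f"{prefix}.genes.tsv", sep="\t", index=False
    )
    cells = adata.obs.reset_index(names="cell")
    cells.to_csv(outdir / f"{prefix}.cells.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------

def _parse_jaspar_row(line, motif_id):
    # "A  [ 4 19 0 0 ]" or bare numbers
    body = line.split("[", 1)[-1].rsplit("]", 1)[0] if "[" in line else line[1:]
    try:
        vals = [float(tok) for tok in body.split()]
    except ValueError as exc:
        raise ValueError(f"motif {motif_id}: malformed count row: {line!r}") from exc
    return line.strip()[0].upper(), vals


def read_jaspar_library(text, background=None, pseudocount=0.01) -> list[PWMModel]:
    """Parse JASPAR 2016+ text (">ID NAME" header + 4 bracketed A/C/G/T rows)."""
    motifs = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    order = "ACGT"
    while i < len(lines):
        header = lines[i].strip()
        if not header.startswith(">"):
            raise ValueError(f"expected JASPAR header line, got: {header!r}")
        parts = header[1:].split(None, 1)
        if not parts or not parts[0]:
            raise ValueError(f"malformed JASPAR header: {header!r}")
        motif_id = parts[0]
        name = parts[1] if len(parts) > 1 else motif_id
        rows = {}
        for j in range(4):
            if i + 1 + j >= len(lines):
                raise ValueError(f"motif {motif_id}: truncated PFM")
            base, vals = _parse_jaspar_row(lines[i + 1 + j], motif_id)
            rows[base] = vals
        if set(rows) != set(order):
            raise ValueError(f"motif {motif_id}: expected rows A,C,G,T, got {sorted(rows)}")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"motif {motif_id}: count rows of unequal length")
        counts = np.array([rows[b] for b in order])
        motifs.append(
            PWMModel.from_counts(motif_id, name, counts, background, pseudocount)
        )
        i += 5
    return motifs


def read_jaspar_pfm(text, background=None, pseudocount=0.01) -> PWMModel:
    """Parse a single JASPAR-format PFM."""
    lib = read_jaspar_library(text, background, pseudocount)
    if len(lib) != 1:
        raise ValueError(f"expected exactly one motif, found {len(lib)}")
    return lib[0]


def write_jaspar_library(motifs, path, scale=100) -> None:
    """Write PWMs back out as integer-count JASPAR text (probs x scale)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name}\n")
            counts = np.round(m.probs * scale).astype(int)
            for base, row in zip("ACGT", counts):
                fh.write(f"{base} [ " + " ".join(str(v) for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------

def read_bed_peaks(path, celltype_columns=None, assume_sorted=False) -> list[PeakRecord]:
    """Read BED6+N peaks; extra numeric columns are per-cell-type counts.

    ``celltype_columns`` names the extra columns (read from a ``#`` header
    line when present).  Validates start < end with line numbers.
    """
    peaks = []
    header_types = celltype_columns
    prev = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser")):
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                if len(fields) > 6 and header_types is None:
                    header_types = fields[6:]
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end, peak_id = fields[:4]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            extra = fields[6:] if len(fields) > 6 else []
            if header_types is not None and extra:
                counts = {ct: float(v) for ct, v in zip(header_types, extra)}
            elif extra:
                counts = {f"ct{i}": float(v) for i, v in enumerate(extra)}
            else:
                counts = {}
            if not assume_sorted and prev is not None:
                if chrom == prev[0] and start < prev[1]:
                    raise ValueError(f"{path}:{lineno}: BED not coordinate-sorted")
            prev = (chrom, start)
            peaks.append(PeakRecord(chrom, start, end, peak_id, counts))
    return peaks


def write_bed_peaks(peaks, path, celltype_columns=None) -> None:
    if celltype_columns is None:
        celltype_columns = sorted({ct for p in peaks for ct in p.counts})
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\t" + "\t".join(celltype_columns) + "\n")
        for p in sorted(peaks, key=lambda q: (q.chrom, q.start)):
            extras = "\t".join(repr(float(p.counts.get(ct, 0))) for ct in celltype_columns)
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t+\t{extras}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """FASTA -> {id: sequence}; sequences upper-cased, Ns preserved."""
    seqs = {}
    name = None
    chunks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict, path, width=80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSS / gene-body / orthology TSVs
# ---------------------------------------------------------------------------

def read_tss(path) -> pd.DataFrame:
    """TSV with columns chrom, pos, strand, gene (strand must be + or -)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    for col in ("chrom", "pos", "strand", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    df["strand"] = df["strand"].replace({"−": "-"})  # unicode minus
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: invalid strand value(s): {df.loc[bad, 'strand'].unique()}")
    df["pos"] = df["pos"].astype(int)
    return df


def write_tss(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "strand", "gene"]].to_csv(path, sep="\t", index=False)


def read_gene_bodies(path) -> pd.DataFrame:
    """TSV with columns chrom, start, end, strand, gene (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    for col in ("chrom", "start", "end", "strand", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    df["strand"] = df["strand"].replace({"−": "-"})
    if (~df["strand"].isin(["+", "-"])).any():
        raise ValueError(f"{path}: invalid strand value(s)")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: start >= end in gene body table")
    return df


def write_gene_bodies(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "strand", "gene"]].to_csv(path, sep="\t", index=False)


def read_orthology(path) -> pd.DataFrame:
    """TSV with columns gene_a, gene_b, orthogroup (one-to-many rows allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b", "orthogroup"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if df["orthogroup"].isna().any() or (df["orthogroup"] == "").any():
        raise ValueError(f"{path}: empty orthogroup identifiers")
    return df


def write_orthology(df: pd.DataFrame, path) -> None:
    df[["gene_a", "gene_b", "orthogroup"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# truth tables (JSON)
# ---------------------------------------------------------------------------

def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path):
    from .simulate import TruthTable

    with open(path) as fh:
        return TruthTable.from_dict(json.load(fh))
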