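"""Data model and on-disk formats.

The in-memory unit is :class:`CountMatrix`: a sparse cells x genes UMI
count matrix with per-cell barcodes and sample labels and per-gene IDs
and organelle class. On disk we use the 10x-style triplet layout
(MatrixMarket matrix + barcode and feature tables, optionally gzipped)
with the 10x orientation convention of genes as rows; the reader
returns cells x genes regardless of the stored orientation.

Gene sets and gene -> diurnal-phase tables are plain TSV. Phases live
on a half-hour grid from 0 h to 24.5 h (dawn = 0), the resolution of
the diurnal time-course the phase annotations derive from.
"""
from __future__ import annotations

import gzip
import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

ORGANELLE_CLASSES = ("nuclear", "mito", "chloro")

PHASE_GRID_MAX_H = 24.5
PHASE_GRID_STEP_H = 0.5


@dataclass
class GeneSet:
    """A named list of gene IDs."""

    name: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} contains duplicate members")

    def __len__(self):
        return len(self.members)


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs: cells with fewer than `min_genes` genes
    detected or fewer than `min_umis` UMIs are discarded."""

    min_genes: int = 100
    min_umis: int = 300

    def __post_init__(self):
        if self.min_genes < 0 or self.min_umis < 0:
            raise ValueError("QC thresholds must be >= 0")


class PhaseTable:
    """Mapping gene ID -> diurnal phase (hours after dawn).

    Phases are validated against the half-hour grid {0.0, 0.5, ...,
    24.5}; exactly one phase per gene.
    """

    def __init__(self, mapping):
        ser = pd.Series(mapping, dtype=float)
        if ser.index.has_duplicates:
            dup = ser.index[ser.index.duplicated()][0]
            raise ValueError(f"duplicate gene in phase table: {dup!r}")
        bad = ~_on_grid(ser.to_numpy())
        if bad.any():
            g = ser.index[bad][0]
            raise ValueError(
                f"phase {ser[g]} for gene {g!r} is off the 0.5-h grid [0, {PHASE_GRID_MAX_H}]"
            )
        self._ser = ser

    def __len__(self):
        return len(self._ser)

    def __getitem__(self, gene):
        return float(self._ser[gene])

    def __contains__(self, gene):
        return gene in self._ser.index

    @property
    def genes(self):
        return self._ser.index.to_numpy()

    @property
    def phases(self):
        return self._ser.to_numpy()

    def to_series(self):
        return self._ser.copy()


def _on_grid(phase):
    p = np.asarray(phase, dtype=float)
    steps = p / PHASE_GRID_STEP_H
    return (
        (p >= 0)
        & (p <= PHASE_GRID_MAX_H)
        & (np.abs(steps - np.round(steps)) < 1e-9)
    )


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI counts with annotations.

    counts
        Non-negative integer CSR matrix, one row per cell.
    barcodes, genes
        Unique cell and gene identifiers matching the matrix axes.
    sample
        Per-cell sample label (e.g. "Fe+", "Fe-", "N-", "Mix").
    organelle_class
        Per-gene label in {nuclear, mito, chloro}, used for the QC
        percentages of organellar expression.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    genes: np.ndarray
    sample: np.ndarray
    organelle_class: np.ndarray

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and np.any(data != np.round(data)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        self.sample = np.asarray(self.sample, dtype=object)
        self.organelle_class = np.asarray(self.organelle_class, dtype=object)
        n, g = self.counts.shape
        if len(self.barcodes) != n:
            raise ValueError(f"{len(self.barcodes)} barcodes for {n} matrix rows")
        if len(self.genes) != g:
            raise ValueError(f"{len(self.genes)} gene IDs for {g} matrix columns")
        if len(self.sample) != n:
            raise ValueError("sample labels must match number of cells")
        if len(self.organelle_class) != g:
            raise ValueError("organelle_class must match number of genes")
        if len(set(self.barcodes)) != n:
            raise ValueError("barcodes are not unique")
        if len(set(self.genes)) != g:
            raise ValueError("gene IDs are not unique")
        bad = set(self.organelle_class) - set(ORGANELLE_CLASSES)
        if bad:
            raise ValueError(f"unknown organelle class(es): {sorted(bad)}")

    @property
    def n_cells(self):
        return self.counts.shape[0]

    @property
    def n_genes(self):
        return self.counts.shape[1]

    def equals(self, other):
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.genes, other.genes)
            and np.array_equal(self.sample, other.sample)
            and np.array_equal(self.organelle_class, other.organelle_class)
        )

    def subset_cells(self, mask_or_idx):
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            counts=self.counts[idx],
            barcodes=self.barcodes[idx],
            genes=self.genes,
            sample=self.sample[idx],
            organelle_class=self.organelle_class,
        )


def _open_maybe_gz(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(path, stem):
    """Locate `stem` or `stem`.gz under `path`, trying common 10x names."""
    for cand in (stem, stem + ".gz"):
        p = os.path.join(path, cand)
        if os.path.exists(p):
            return p
    return None


def read_10x_dir(path) -> CountMatrix:
    """Read a 10x-style triplet directory into a CountMatrix.

    The matrix may be stored genes x cells (the 10x convention) or
    cells x genes; orientation is resolved against the barcode and
    feature table lengths, a square ambiguous matrix being treated as
    genes x cells. Duplicate feature IDs are disambiguated in file
    order by appending ".1", ".2", ...
    """
    mtx_path = _find(path, "matrix.mtx")
    if mtx_path is None:
        raise FileNotFoundError(f"no matrix.mtx[.gz] in {path}")
    bc_path = _find(path, "barcodes.tsv")
    if bc_path is None:
        raise FileNotFoundError(f"no barcodes.tsv[.gz] in {path}")
    ft_path = _find(path, "features.tsv") or _find(path, "genes.tsv")
    if ft_path is None:
        raise FileNotFoundError(f"no features.tsv[.gz] or genes.tsv[.gz] in {path}")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(_io.BytesIO(fh.read()))
    mat = sp.csr_matrix(mat)

    bc = _read_tsv_allow_empty(bc_path)
    ft = _read_tsv_allow_empty(ft_path)
    barcodes = (
        bc[0].to_numpy(dtype=object) if len(bc) else np.array([], dtype=object)
    )
    sample = (
        bc[1].to_numpy(dtype=object)
        if bc.shape[1] > 1 and len(bc)
        else np.full(len(bc), "sample0", object)
    )
    genes = ft[0].to_numpy(dtype=object) if len(ft) else np.array([], dtype=object)

    n_b, n_f = len(barcodes), len(genes)
    r, c = mat.shape
    if (r, c) == (n_f, n_b):
        mat = sp.csr_matrix(mat.T)
    elif (r, c) == (n_b, n_f):
        pass
    else:
        raise ValueError(
            f"{mtx_path}: matrix is {r} x {c} but {bc_path} has {n_b} barcodes "
            f"and {ft_path} has {n_f} features"
        )

    genes = _dedupe_ids(genes)

    organelle = np.full(n_f, "nuclear", object)
    if ft.shape[1] > 2:
        col = ft[2].to_numpy(dtype=object)
        known = np.isin(col, ORGANELLE_CLASSES)
        organelle[known] = col[known]

    return CountMatrix(
        counts=mat, barcodes=barcodes, genes=genes, sample=sample, organelle_class=organelle
    )


def _dedupe_ids(ids):
    seen: dict = {}
    out = np.empty(len(ids), dtype=object)
    for i, g in enumerate(ids):
        k = seen.get(g, 0)
        out[i] = g if k == 0 else f"{g}.{k}"
        seen[g] = k + 1
    return out


def write_10x_dir(matrix: CountMatrix, path, gzip_files: bool = False) -> None:
    """Write a CountMatrix as a triplet directory (genes as rows on disk).

    Round-trips bit-exactly through :func:`read_10x_dir`.
    """
    os.makedirs(path, exist_ok=True)
    suffix = ".gz" if gzip_files else ""

    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(matrix.counts.T), field="integer")
    with _open_maybe_gz(os.path.join(path, "matrix.mtx" + suffix), "wb") as fh:
        fh.write(buf.getvalue())

    with _open_maybe_gz(os.path.join(path, "barcodes.tsv" + suffix), "wt") as fh:
        for b, s in zip(matrix.barcodes, matrix.sample):
            fh.write(f"{b}\t{s}\n")
    with _open_maybe_gz(os.path.join(path, "features.tsv" + suffix), "wt") as fh:
        for g, o in zip(matrix.genes, matrix.organelle_class):
            fh.write(f"{g}\t{g}\t{o}\n")


def read_gene_sets(path) -> list[GeneSet]:
    """Read a two-column (set, gene) TSV into GeneSets, header optional.

    Row order is irrelevant; sets are returned in order of first
    appearance, members in file order. Unknown genes are retained here
    and filtered later at scoring time.
    """
    df = _read_two_col(path, ("set", "gene"))
    sets = []
    for name, grp in df.groupby(0, sort=False):
        members = list(dict.fromkeys(grp[1]))
        sets.append(GeneSet(name=str(name), members=members))
    return sets


def read_phase_table(path) -> PhaseTable:
    """Read a (gene, phase-hours) TSV, validating the half-hour grid."""
    df = _read_two_col(path, ("gene", "phase"))
    phases = pd.to_numeric(df[1], errors="coerce")
    if phases.isna().any():
        row = int(df.index[phases.isna()][0]) + 1
        raise ValueError(f"{path}: non-numeric phase at data row {row}")
    ok = _on_grid(phases.to_numpy())
    if not ok.all():
        i = int(np.flatnonzero(~ok)[0])
        raise ValueError(
            f"{path}: phase {phases.iloc[i]} at data row {i + 1} is off the "
            f"0.5-h grid [0, {PHASE_GRID_MAX_H}]"
        )
    if df[0].duplicated().any():
        g = df[0][df[0].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene {g!r}")
    return PhaseTable(dict(zip(df[0], phases)))


def write_gene_sets(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("set\tgene\n")
        for s in sets:
            for g in s.members:
                fh.write(f"{s.name}\t{g}\n")


def write_phase_table(pt: PhaseTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tphase\n")
        for g, p in zip(pt.genes, pt.phases):
            fh.write(f"{g}\t{p:g}\n")


def _read_tsv_allow_empty(path):
    try:
        return pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=[0, 1])


def _read_two_col(path, header_names):
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: empty file")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    first = tuple(str(x).strip().lower() for x in df.iloc[0, :2])
    if first == tuple(header_names):
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"{path}: no data rows")
    return df
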