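"""QC, depth normalization, variable-gene selection, scaling, and PCA.

The stage order is fixed: filter -> normalize -> HVG -> scale -> PCA.
Cells with fewer than 100 genes or 300 UMIs (read as strict "fewer
than": exactly 100 / 300 is retained) are discarded; counts are depth
normalized to a scale factor of 10,000 and natural-log transformed;
2,000 variable genes are ranked by a variance-stabilized dispersion;
scaled values are clipped at +/-10 before an exact-SVD PCA.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io import CountMatrix, QCThresholds

DEFAULT_SCALE_FACTOR = 10_000.0
SCALE_CLIP = 10.0


@dataclass
class NormalizedMatrix:
    """Cells x genes natural-log of (1 + depth-scaled counts).

    For every cell with nonzero counts, sum over genes of
    expm1(value) equals `scale_factor` up to floating tolerance.
    """

    values: sp.csr_matrix
    barcodes: np.ndarray
    genes: np.ndarray
    sample: np.ndarray
    scale_factor: float = DEFAULT_SCALE_FACTOR

    @property
    def n_cells(self):
        return self.values.shape[0]

    @property
    def n_genes(self):
        return self.values.shape[1]

    def gene_index(self, ids):
        """Column positions of the given gene IDs (error if absent)."""
        lookup = pd.Index(self.genes)
        idx = lookup.get_indexer(np.asarray(ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(ids, dtype=object)[idx < 0][:5]
            raise KeyError(f"genes not in matrix: {list(missing)}")
        return idx


@dataclass
class QCReport:
    """Per-cell QC metrics plus per-sample means."""

    per_cell: pd.DataFrame
    per_sample: pd.DataFrame


def qc_metrics(m: CountMatrix) -> QCReport:
    """Per-cell genes detected, UMIs, and organellar UMI percentages.

    pct_mito / pct_chloro are 100 * (UMIs on mito / chloro genes) /
    (total UMIs); all-zero cells get 0 and a `zero_umis` flag.
    """
    counts = m.counts
    n_umis = np.asarray(counts.sum(axis=1)).ravel()
    n_genes = np.diff(counts.indptr)
    zero = n_umis == 0
    denom = np.where(zero, 1, n_umis)

    pct = {}
    for label in ("mito", "chloro"):
        mask = m.organelle_class == label
        organ = np.asarray(counts[:, mask].sum(axis=1)).ravel() if mask.any() else np.zeros(
            m.n_cells
        )
        pct[label] = np.where(zero, 0.0, 100.0 * organ / denom)

    per_cell = pd.DataFrame(
        {
            "sample": m.sample,
            "n_genes_detected": n_genes,
            "n_umis": n_umis,
            "pct_mito": pct["mito"],
            "pct_chloro": pct["chloro"],
            "zero_umis": zero,
        },
        index=pd.Index(m.barcodes, name="barcode"),
    )
    per_sample = (
        per_cell.groupby("sample", observed=True)[
            ["n_genes_detected", "n_umis", "pct_mito", "pct_chloro"]
        ]
        .mean()
        .rename_axis("sample")
    )
    return QCReport(per_cell=per_cell, per_sample=per_sample)


def filter_cells(m: CountMatrix, thresholds: QCThresholds | None = None) -> CountMatrix:
    """Drop low-quality cells; the gene axis is untouched.

    A cell is retained iff it has >= min_genes genes detected AND
    >= min_umis UMIs ("fewer than" is strict). Idempotent.
    """
    t = thresholds or QCThresholds()
    n_umis = np.asarray(m.counts.sum(axis=1)).ravel()
    n_genes = np.diff(m.counts.indptr)
    keep = (n_genes >= t.min_genes) & (n_umis >= t.min_umis)
    if not keep.any():
        raise ValueError(
            f"all {m.n_cells} cells fail QC (min_genes={t.min_genes}, min_umis={t.min_umis})"
        )
    return m.subset_cells(keep)


def normalize_log(m: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR) -> NormalizedMatrix:
    """value = ln(1 + scale_factor * count / cell_total).

    Sparsity is preserved (zero counts stay exactly zero). Cells with
    zero total counts are rejected; run :func:`filter_cells` first.
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(
            f"cell {m.barcodes[bad]!r} has zero counts; apply filter_cells before normalizing"
        )
    x = m.counts.astype(np.float64).tocsr(copy=True)
    row = np.repeat(np.arange(m.n_cells), np.diff(x.indptr))
    x.data = np.log1p(scale_factor * x.data / totals[row])
    return NormalizedMatrix(
        values=x,
        barcodes=m.barcodes.copy(),
        genes=m.genes.copy(),
        sample=m.sample.copy(),
        scale_factor=scale_factor,
    )


def select_variable_genes(n: NormalizedMatrix, n_top: int = 2000) -> np.ndarray:
    """Rank genes by mean-binned dispersion; return the top gene IDs.

    Genes with nonzero variance are placed into up to 20
    equal-frequency bins by mean expression and ranked by the residual
    of log variance around the bin median — a seed-free, leverage-
    robust variance-stabilized selection. Ties break by gene ID; zero-
    variance genes are excluded. If fewer than n_top genes qualify,
    all qualifying genes are returned.
    """
    values = n.values
    mean = np.asarray(values.sum(axis=0)).ravel() / n.n_cells
    sq = np.asarray(values.power(2).sum(axis=0)).ravel() / n.n_cells
    var = np.maximum(sq - mean**2, 0.0)
    ok = var > 1e-12
    if not ok.any():
        return np.array([], dtype=object)
    genes_ok = n.genes[ok]
    lv = np.log10(var[ok])
    k = ok.sum()
    n_mean_bins = max(1, min(20, k // 3))
    order_by_mean = np.lexsort((genes_ok, mean[ok]))
    ranks = np.empty(k, dtype=int)
    ranks[order_by_mean] = np.arange(k)
    bin_of = (ranks * n_mean_bins) // k
    resid = np.empty(k)
    for b in range(n_mean_bins):
        members = bin_of == b
        resid[members] = lv[members] - np.median(lv[members])
    order = np.lexsort((genes_ok, -resid))
    return genes_ok[order[: min(n_top, len(order))]]


def scale_center(
    n: NormalizedMatrix, genes: np.ndarray, clip: float = SCALE_CLIP
) -> tuple[np.ndarray, np.ndarray]:
    """Dense per-gene standardized matrix over the selected genes.

    Each kept column has mean 0 and unit (population) variance before
    clipping at +/-`clip`; zero-variance columns are dropped. Returns
    (matrix, kept gene IDs).
    """
    idx = n.gene_index(genes)
    x = np.asarray(n.values[:, idx].todense(), dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 1e-12
    x = (x[:, keep] - mu[keep]) / sd[keep]
    np.clip(x, -clip, clip, out=x)
    return x, np.asarray(genes, dtype=object)[keep]


def pca(scaled: np.ndarray, n_components: int = 20) -> np.ndarray:
    """Cell embedding from an exact (full-SVD) PCA of the scaled matrix.

    Deterministic; agrees with a dense SVD up to per-component sign
    conventions handled by scikit-learn's sign flipping.
    """
    n_cells, n_genes = scaled.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)="
            f"{min(n_cells, n_genes)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    return model.fit_transform(scaled)
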