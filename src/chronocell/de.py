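"""Differential expression: Wilcoxon rank-sum per gene + BH adjustment.

Tests run on log-normalized values, restricted to genes detected in at
least one cell of either group. The normal approximation with tie
correction is used when both groups have >= 20 cells, exact
enumeration below that. Significance is adjusted P < 0.05 after
Benjamini-Hochberg correction across all tested genes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

ADJ_P_CUTOFF = 0.05
ASYMPTOTIC_MIN_N = 20
_LFC_PSEUDOCOUNT = 1e-9


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_de(n: NormalizedMatrix, group_a, group_b) -> pd.DataFrame:
    """Two-sided rank-sum test per gene between two disjoint cell groups.

    `group_a` / `group_b` are boolean masks or index arrays over cells.
    Returns a DataFrame indexed by gene with mean_a, mean_b, log_fc
    (natural log of the expm1-mean ratio with a pseudocount), u_stat,
    p_value, adj_p and a significance flag; genes constant across both
    groups get p = 1 and a `constant` flag. Sorted by adj_p.
    """
    mask_a = _as_mask(group_a, n.n_cells)
    mask_b = _as_mask(group_b, n.n_cells)
    if (mask_a & mask_b).any():
        raise ValueError("groups must be disjoint")
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if min(n_a, n_b) < 3:
        raise ValueError("each group needs >= 3 cells")

    a = np.asarray(n.values[mask_a].todense(), dtype=float)
    b = np.asarray(n.values[mask_b].todense(), dtype=float)

    detected = ((a > 0).any(axis=0)) | ((b > 0).any(axis=0))
    a, b = a[:, detected], b[:, detected]
    genes = n.genes[detected]

    method = "asymptotic" if min(n_a, n_b) >= ASYMPTOTIC_MIN_N else "exact"
    constant = np.array([np.ptp(np.concatenate([a[:, j], b[:, j]])) == 0
                         for j in range(a.shape[1])])
    u = np.full(a.shape[1], np.nan)
    p = np.ones(a.shape[1])
    test_cols = np.flatnonzero(~constant)
    if test_cols.size:
        if method == "asymptotic":
            res = stats.mannwhitneyu(a[:, test_cols], b[:, test_cols], axis=0,
                                     method="asymptotic")
            u[test_cols], p[test_cols] = res.statistic, res.pvalue
        else:
            for j in test_cols:
                res = stats.mannwhitneyu(a[:, j], b[:, j], method="exact")
                u[j], p[j] = res.statistic, res.pvalue
    u[constant] = n_a * n_b / 2.0

    adj = bh_adjust(p)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    log_fc = np.log(
        (np.expm1(a).mean(axis=0) + _LFC_PSEUDOCOUNT)
        / (np.expm1(b).mean(axis=0) + _LFC_PSEUDOCOUNT)
    )
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log_fc": log_fc,
            "u_stat": u,
            "p_value": p,
            "adj_p": adj,
            "significant": adj < ADJ_P_CUTOFF,
            "constant": constant,
        },
        index=pd.Index(genes, name="gene"),
    )
    return out.sort_values("adj_p", kind="stable")


def _as_mask(group, n_cells):
    g = np.asarray(group)
    if g.dtype == bool:
        if g.size != n_cells:
            raise ValueError("boolean group mask has wrong length")
        return g
    mask = np.zeros(n_cells, dtype=bool)
    mask[g] = True
    return mask
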