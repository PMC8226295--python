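"""Independent reference implementations used only to check the package.

Everything here is deliberately written with dense arrays and explicit
loops, independent of the library's sparse/vectorized code paths.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np


def dense_module_score(values, genes, members, n_bins, n_ctrl, seed):
    """Brute-force module score: mean over set members minus mean over
    pooled bin-matched controls, following the published definition.

    Controls: all genes ranked by mean expression into n_bins
    equal-frequency bins (ties by gene ID); each member draws n_ctrl
    controls without replacement from its own bin (whole bin if
    smaller), pooled with multiplicity.
    """
    values = np.asarray(values, dtype=float)
    genes = np.asarray(genes, dtype=object)
    n_genes = values.shape[1]
    means = values.mean(axis=0)
    order = np.lexsort((genes, means))
    ranks = np.empty(n_genes, dtype=int)
    ranks[order] = np.arange(n_genes)
    bin_of = (ranks * n_bins) // n_genes

    pos = {g: i for i, g in enumerate(genes)}
    member_idx = [pos[m] for m in members if m in pos]
    rng = np.random.default_rng(seed)
    member_set = set(member_idx)
    pooled = []
    for gi in member_idx:
        cand = np.flatnonzero(bin_of == bin_of[gi])
        outside = np.array([j for j in cand if j not in member_set])
        if outside.size:
            cand = outside
        take = min(n_ctrl, cand.size)
        pooled.extend(rng.choice(cand, size=take, replace=False).tolist())

    n_cells = values.shape[0]
    out = np.empty(n_cells)
    for c in range(n_cells):
        set_mean = sum(values[c, g] for g in member_idx) / len(member_idx)
        ctrl_mean = sum(values[c, g] for g in pooled) / len(pooled)
        out[c] = set_mean - ctrl_mean
    return out


def dense_paired_module_score(values, genes, members, n_bins, n_ctrl, seed):
    """Variant: per-member paired control means, then averaged."""
    values = np.asarray(values, dtype=float)
    genes = np.asarray(genes, dtype=object)
    n_genes = values.shape[1]
    means = values.mean(axis=0)
    order = np.lexsort((genes, means))
    ranks = np.empty(n_genes, dtype=int)
    ranks[order] = np.arange(n_genes)
    bin_of = (ranks * n_bins) // n_genes
    pos = {g: i for i, g in enumerate(genes)}
    member_idx = [pos[m] for m in members if m in pos]
    rng = np.random.default_rng(seed)
    member_set = set(member_idx)
    diffs = []
    for gi in member_idx:
        cand = np.flatnonzero(bin_of == bin_of[gi])
        outside = np.array([j for j in cand if j not in member_set])
        if outside.size:
            cand = outside
        ctrl = rng.choice(cand, size=min(n_ctrl, cand.size), replace=False)
        diffs.append(values[:, gi] - values[:, ctrl].mean(axis=1))
    return np.mean(diffs, axis=0)


def cosinor_phase(y, theta_hours):
    """Least-squares cosinor: fit y ~ a + b cos + c sin of the known
    cell phases, return the fitted peak phase in hours [0, 24)."""
    ang = np.asarray(theta_hours, dtype=float) * 2 * np.pi / 24.0
    design = np.column_stack([np.ones_like(ang), np.cos(ang), np.sin(ang)])
    beta, *_ = np.linalg.lstsq(design, np.asarray(y, dtype=float), rcond=None)
    return (np.arctan2(beta[2], beta[1]) * 24.0 / (2 * np.pi)) % 24.0


def exact_mwu_two_sided(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of rank
    splits (assumes no ties; group sizes <= 8 keep this tractable)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled)
    ranks = np.empty(pooled.size)
    ranks[order] = np.arange(1, pooled.size + 1)
    n_a = a.size
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0

    us = []
    for idx in combinations(range(pooled.size), n_a):
        us.append(ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0)
    us = np.asarray(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


def bh_stepup(p_values):
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running = min(running, p[i] * m / (rank_from_top + 1))
        adj[i] = running
    return adj
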