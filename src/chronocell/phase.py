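"""Molecular-timetable diurnal phase inference for cells and clusters.

Rhythmic genes with known peak phases (hours after dawn, on a
half-hour grid up to 24.5 h) are collapsed into 13 non-overlapping
phase-bin gene sets centered every other hour: the bin at t hours
(t = 2, 4, ..., 24) holds genes peaking at t - 0.5, t, or t + 0.5,
while the dawn bin (0 h) holds only the 0 h and 0.5 h genes. Genes
peaking exactly on odd hours belong to no bin. Scoring every bin in
every cell yields a cells x 13 phase-score matrix; a cell's endogenous
phase is read off it either as the center of the best-scoring bin
(argmax) or as a score-weighted circular mean (the default), with the
0 h and 24 h bins merged into a single dawn direction so the turn of
the cycle is not double-weighted.

A permutation test on the absolute circular mean difference quantifies
phase shifts between two groups of cells (e.g. iron-replete vs
iron-deficient cultures).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import (
    PERIOD_H,
    circular_diff_hours,
    hours_to_angle,
)
from .io import GeneSet, PhaseTable
from .preprocess import NormalizedMatrix
from .score import DEFAULT_N_BINS, DEFAULT_N_CTRL, score as _module_score

logger = logging.getLogger(__name__)

BIN_CENTERS_H = tuple(range(0, 25, 2))  # 13 bins: 0, 2, ..., 24


@dataclass
class PhaseBinSets:
    """Ordered, pairwise-disjoint phase-bin gene sets."""

    bins: dict  # center (int hours) -> GeneSet

    def __post_init__(self):
        assert tuple(self.bins) == BIN_CENTERS_H

    def non_empty_centers(self):
        return [c for c, gs in self.bins.items() if len(gs) > 0]


def build_phase_bins(pt: PhaseTable) -> PhaseBinSets:
    """Collapse a gene -> phase table into the 13 phase-bin gene sets.

    Windows: {0.0, 0.5} for the 0 h bin; {t-0.5, t, t+0.5} for every
    other bin. Empty bins are permitted (logged).
    """
    genes = pt.genes
    phases = pt.phases
    bins = {}
    for c in BIN_CENTERS_H:
        window = (0.0, 0.5) if c == 0 else (c - 0.5, float(c), c + 0.5)
        mask = np.isin(phases, window)
        bins[c] = GeneSet(name=f"phase_{c:02d}h", members=list(genes[mask]))
        if not mask.any():
            logger.info("phase bin %d h is empty", c)
    return PhaseBinSets(bins=bins)


def phase_scores(
    n: NormalizedMatrix,
    bins: PhaseBinSets,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells x 13 matrix of phase-bin module scores.

    All bins share one control-sampling seed so columns are mutually
    comparable; empty bins yield all-NaN columns (logged).
    """
    centers = bins.non_empty_centers()
    if not centers:
        raise ValueError("all phase bins are empty")
    out = pd.DataFrame(
        np.nan, index=pd.Index(n.barcodes, name="barcode"), columns=list(BIN_CENTERS_H)
    )
    for c in BIN_CENTERS_H:
        gs = bins.bins[c]
        members = [g for g in gs.members if g in set(n.genes)]
        if not members:
            logger.warning("phase bin %d h has no genes in the matrix; column is NaN", c)
            continue
        res = _module_score(n, GeneSet(gs.name, members), n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        out[c] = res.scores
    return out


def aggregate_by_cluster(psm: pd.DataFrame, assignment) -> pd.DataFrame:
    """Per-cluster mean of each phase-bin score column."""
    labels = getattr(assignment, "labels", assignment)
    labels = np.asarray(labels)
    if len(labels) != len(psm):
        raise ValueError("cluster assignment must cover all cells")
    return psm.groupby(pd.Series(labels, index=psm.index, name="cluster")).mean()


def call_phase(psm: pd.DataFrame, method: str = "timetable") -> pd.DataFrame:
    """Infer the endogenous diurnal phase of each row of a score matrix.

    timetable (default): signed Fourier projection of each row's score
    profile onto the bin-center directions (0 h and 24 h averaged into
    one dawn direction), followed by a population-level recentering.
    Mean-matched control genes subtract the population-average rhythm
    from every profile, which translates the per-cell resultant
    vectors by the crowd's mean vector and inflates deviations from
    the crowd phase by 1/(1 - R) for a population of resultant length
    R; a Taubin least-squares circle fit across rows estimates that
    translation and the phase is the angle around the fitted center.
    Confidence is the radial distance relative to the mean fitted
    radius, capped at 1. Needs >= 8 rows.

    argmax: center of the best-scoring bin (ties -> earliest).

    circular_mean: atan2 of score-weighted unit vectors at the bin
    centers, weights max(score, 0), dawn bins merged; confidence is
    the weighted resultant length. Rows where every score is <= 0 (or
    fewer than 3 bins are non-missing) are NaN and flagged for
    circular_mean; argmax still answers with the earliest maximum.

    Returns a DataFrame with columns phase_hat, confidence, flagged.
    """
    if method not in ("timetable", "argmax", "circular_mean"):
        raise ValueError(f"unknown method {method!r}")
    centers = np.array(psm.columns, dtype=float)
    x = psm.to_numpy(dtype=float)
    n_valid = (~np.isnan(x)).sum(axis=1)
    too_few = n_valid < 3

    out = pd.DataFrame(index=psm.index, columns=["phase_hat", "confidence", "flagged"])
    if method == "timetable":
        if x.shape[0] < 8:
            raise ValueError(
                "timetable calls need >= 8 rows for the recentering fit; "
                "use method='circular_mean' for small matrices"
            )
        z = _signed_resultants(x, centers)
        center = _taubin_circle_center(z)
        w = z - center
        radius = np.abs(w)
        undefined = too_few | (radius < 1e-12)
        with np.errstate(invalid="ignore"):
            phase_hat = (np.angle(w) * PERIOD_H / (2 * np.pi)) % PERIOD_H
        mean_r = radius[~undefined].mean() if (~undefined).any() else 1.0
        conf = np.clip(radius / max(mean_r, 1e-12), 0.0, 1.0)
        out["phase_hat"] = np.where(undefined, np.nan, phase_hat)
        out["confidence"] = np.where(undefined, np.nan, conf)
        out["flagged"] = undefined
        return out

    if method == "argmax":
        safe = np.where(np.isnan(x), -np.inf, x)
        best = np.argmax(safe, axis=1)  # first (earliest) max on ties
        out["phase_hat"] = centers[best] % PERIOD_H
        out["confidence"] = np.nan
        out["flagged"] = too_few
        out.loc[too_few, "phase_hat"] = np.nan
        return out

    w = np.where(np.isnan(x), 0.0, np.clip(x, 0.0, None))
    # merge dawn: fold the 24 h column onto 0 h before the angular sum
    merged_centers = centers.copy()
    merged_centers[centers == 24.0] = 0.0
    z = (w * np.exp(1j * hours_to_angle(merged_centers))[None, :]).sum(axis=1)
    tot = w.sum(axis=1)
    undefined = too_few | (tot <= 0) | (np.abs(z) < 1e-12)
    with np.errstate(invalid="ignore"):
        phase_hat = (np.angle(z) * PERIOD_H / (2 * np.pi)) % PERIOD_H
        conf = np.where(tot > 0, np.abs(z) / np.where(tot > 0, tot, 1.0), 0.0)
    out["phase_hat"] = np.where(undefined, np.nan, phase_hat)
    out["confidence"] = np.where(undefined, np.nan, conf)
    out["flagged"] = undefined
    return out


def _signed_resultants(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Per-row complex resultant of the signed score profile.

    The 0 h and 24 h columns are averaged into a single dawn direction
    so the 12 remaining directions are uniform on the circle, making
    the projection an exact first-harmonic Fourier coefficient (a
    constant offset across bins projects to zero). NaN scores
    contribute nothing.
    """
    is_dawn = (centers == 0.0) | (centers == 24.0)
    with np.errstate(invalid="ignore"):
        dawn = np.nanmean(x[:, is_dawn], axis=1) if is_dawn.any() else np.zeros(x.shape[0])
    prof = np.column_stack([dawn, np.nan_to_num(x[:, ~is_dawn], nan=0.0)])
    prof[:, 0] = np.nan_to_num(prof[:, 0], nan=0.0)
    ang = hours_to_angle(np.concatenate([[0.0], centers[~is_dawn]]))
    return (prof * np.exp(1j * ang)[None, :]).sum(axis=1)


def _taubin_circle_center(z: np.ndarray) -> complex:
    """Taubin algebraic least-squares circle fit; returns the center."""
    x, y = z.real, z.imag
    xm, ym = x.mean(), y.mean()
    u, v = x - xm, y - ym
    zz = u * u + v * v
    zmean = zz.mean()
    if zmean < 1e-24:
        return complex(xm, ym)
    z0 = (zz - zmean) / (2.0 * np.sqrt(zmean))
    _, _, vt = np.linalg.svd(np.column_stack([z0, u, v]), full_matrices=False)
    a0, b, c = vt[2]
    a0 = a0 / (2.0 * np.sqrt(zmean))
    if abs(a0) < 1e-18:
        return complex(xm, ym)
    return complex(-b / (2 * a0) + xm, -c / (2 * a0) + ym)


def phase_shift(
    calls_a,
    calls_b,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Circular mean phase difference B - A with a permutation p-value.

    `calls_a` / `calls_b` are phase vectors in hours (NaN = undefined,
    excluded; a group with > 50% undefined is an error; >= 30 defined
    calls are required per group). delta_hours is wrapped to
    (-12, +12]; the p-value permutes group labels on the absolute
    circular mean difference.
    """
    a = _clean_calls(np.asarray(calls_a, dtype=float), "A")
    b = _clean_calls(np.asarray(calls_b, dtype=float), "B")

    za = np.exp(1j * hours_to_angle(a))
    zb = np.exp(1j * hours_to_angle(b))
    mean_a = np.angle(za.mean()) * PERIOD_H / (2 * np.pi)
    mean_b = np.angle(zb.mean()) * PERIOD_H / (2 * np.pi)
    delta = float(circular_diff_hours(mean_b, mean_a))

    pooled = np.concatenate([za, zb])
    n_a = a.size
    rng = np.random.default_rng(seed)
    obs = abs(delta)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.size)
        pa = pooled[perm[:n_a]].mean()
        pb = pooled[perm[n_a:]].mean()
        d = abs(circular_diff_hours(
            np.angle(pb) * PERIOD_H / (2 * np.pi), np.angle(pa) * PERIOD_H / (2 * np.pi)
        ))
        if d >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return {
        "delta_hours": delta,
        "p_value": float(p),
        "mean_a": float(mean_a % PERIOD_H),
        "mean_b": float(mean_b % PERIOD_H),
        "n_a": int(n_a),
        "n_b": int(b.size),
        "n_perm": int(n_perm),
    }


def _clean_calls(x: np.ndarray, label: str) -> np.ndarray:
    defined = x[~np.isnan(x)]
    if x.size and defined.size < 0.5 * x.size:
        raise ValueError(f"group {label}: more than 50% of phase calls are undefined")
    if defined.size < 30:
        raise ValueError(f"group {label}: need >= 30 defined phase calls, got {defined.size}")
    return defined
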