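"""Circular pseudo-time ordering of cells around the diurnal cycle.

Batch-cultured cells ordered by expression similarity organize on a
closed circle — a single trajectory without branches — so a circular
parameterization is the minimal sufficient structure. Cells are
projected onto the top-2 principal plane of either the 13-bin phase
score matrix (default, robust at low depth) or the filtered gene
expression matrix; pseudo-time is the angle of each cell around the
centroid, rescaled to [0, 24) hours. Two gauge freedoms remain and
are fixed deterministically: orientation (direction of travel) by
maximizing circular correlation with the molecular-timetable phase
calls, and the anchor (zero point) by rotating the division-program
signature (phase bins 12 and 14) onto the 12-14 h interval.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import PERIOD_H, circular_mean_hours, hours_to_angle
from .phase import _taubin_circle_center, call_phase
from .preprocess import NormalizedMatrix

DIVISION_ANCHOR_BINS = (12, 14)
DIVISION_ANCHOR_TARGET_H = 13.0


@dataclass
class Pseudotime:
    """Per-cell circular pseudo-time t in [0, 24) hours."""

    t: np.ndarray
    barcodes: np.ndarray
    space: str
    flipped: bool
    anchor_shift_h: float

    def to_series(self):
        return pd.Series(self.t, index=pd.Index(self.barcodes, name="barcode"), name="pseudotime")


def trajectory_gene_filter(n: NormalizedMatrix) -> np.ndarray:
    """Genes admissible for gene-space trajectory construction.

    Keeps genes with mean normalized expression strictly over 0.5 that
    are detected (nonzero) in strictly more than 10 cells.
    """
    mean = np.asarray(n.values.mean(axis=0)).ravel()
    detected = np.asarray((n.values > 0).sum(axis=0)).ravel()
    keep = (mean > 0.5) & (detected > 10)
    if not keep.any():
        raise ValueError("no genes pass the trajectory filter (mean > 0.5, detected in > 10 cells)")
    return n.genes[keep]


def circular_pseudotime(
    psm: pd.DataFrame,
    expression: np.ndarray | None = None,
    min_cells: int = 100,
) -> Pseudotime:
    """Order cells around the cycle from their phase-score profiles.

    `psm` is the cells x 13 phase-score matrix; it always supplies the
    orientation reference (phase calls) and the division-signature
    anchor. If `expression` (cells x genes, filtered and
    log-normalized, dense) is given, the principal plane is computed
    in gene space instead of bin-score space.
    """
    if len(psm) < min_cells:
        raise ValueError(f"need >= {min_cells} cells for a circular ordering, got {len(psm)}")
    data = expression if expression is not None else psm.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    data = np.nan_to_num(data, nan=0.0)
    x = data - data.mean(axis=0)

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s.size < 2 or s[1] < 1e-10 * max(1.0, s[0]):
        raise ValueError(
            "embedding is degenerate (collinear); try the phase-score-space input"
        )
    plane = u[:, :2] * s[:2]
    # under a concentrated phase distribution the ring of cells is
    # offset from the data centroid; recenter on the fitted circle so
    # the angle parameterizes position along the ring, not position
    # relative to the crowd
    center = _taubin_circle_center(plane[:, 0] + 1j * plane[:, 1])
    rel = plane[:, 0] - center.real + 1j * (plane[:, 1] - center.imag)
    t_raw = (np.angle(rel) * PERIOD_H / (2 * np.pi)) % PERIOD_H

    # orientation: travelling direction must agree with the timetable
    # calls. Rotation vs reflection resultants stay well defined even
    # for uniform phase distributions, unlike moment correlations.
    calls = call_phase(psm, method="timetable")["phase_hat"].to_numpy(dtype=float)
    ok = ~np.isnan(calls)
    a = hours_to_angle(t_raw[ok])
    b = hours_to_angle(calls[ok])
    r_rot = np.abs(np.exp(1j * (a - b)).mean())
    r_ref = np.abs(np.exp(1j * (a + b)).mean())
    flipped = bool(r_ref > r_rot)
    t = (-t_raw) % PERIOD_H if flipped else t_raw

    w = psm[list(DIVISION_ANCHOR_BINS)].to_numpy(dtype=float)
    w = np.clip(np.nan_to_num(w, nan=0.0), 0.0, None).mean(axis=1)
    center = circular_mean_hours(t, weights=w)
    shift = 0.0 if np.isnan(center) else (DIVISION_ANCHOR_TARGET_H - center) % PERIOD_H
    t = (t + shift) % PERIOD_H

    return Pseudotime(
        t=t,
        barcodes=np.asarray(psm.index, dtype=object),
        space="genes" if expression is not None else "bins",
        flipped=flipped,
        anchor_shift_h=float(shift),
    )


def pseudotime_heatmap_data(psm: pd.DataFrame, pt: Pseudotime) -> pd.DataFrame:
    """Bins x cells matrix with columns ordered by ascending pseudo-time.

    Values are the untransformed phase-bin scores; rows follow bin
    order. Stable under repeated application (sorting is idempotent).
    """
    order = np.argsort(pt.t, kind="stable")
    ordered = psm.iloc[order]
    if not np.array_equal(np.asarray(ordered.index, dtype=object), pt.barcodes[order]):
        raise ValueError("pseudotime and score matrix refer to different cells")
    return ordered.T
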