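"""Circular arithmetic on a 24-hour clock.

All public helpers take and return hours on the circle of period 24;
angles in radians are an internal detail. Phase differences are always
reported in the signed half-open interval (-12, +12].
"""
from __future__ import annotations

import numpy as np

PERIOD_H = 24.0
_RAD_PER_H = 2.0 * np.pi / PERIOD_H


def hours_to_angle(hours):
    """Map hours (mod 24) to radians (mod 2*pi)."""
    return np.asarray(hours, dtype=float) * _RAD_PER_H


def angle_to_hours(angle):
    """Map radians back to hours in [0, 24)."""
    h = (np.asarray(angle, dtype=float) / _RAD_PER_H) % PERIOD_H
    # float rounding can land the modulo exactly on the period
    return np.where(h >= PERIOD_H, 0.0, h)


def circular_mean_hours(hours, weights=None):
    """Weighted circular mean, in hours [0, 24).

    Returns ``nan`` if the resultant vector vanishes (e.g. antipodal
    equal weights) or total weight is zero.
    """
    a = hours_to_angle(hours)
    if weights is None:
        z = np.exp(1j * a).sum()
    else:
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            return np.nan
        z = (w * np.exp(1j * a)).sum()
    if np.abs(z) < 1e-12 * max(1.0, np.size(a)):
        return np.nan
    return float(angle_to_hours(np.angle(z)))


def resultant_length(hours, weights=None):
    """Mean resultant length R in [0, 1]; concentration of the sample."""
    a = hours_to_angle(hours)
    if weights is None:
        return float(np.abs(np.exp(1j * a).mean()))
    w = np.asarray(weights, dtype=float)
    tot = w.sum()
    if tot <= 0:
        return 0.0
    return float(np.abs((w * np.exp(1j * a)).sum()) / tot)


def circular_diff_hours(a, b):
    """Signed difference a - b wrapped to (-12, +12] hours."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % PERIOD_H
    return np.where(d > PERIOD_H / 2, d - PERIOD_H, d)


def circular_abs_error_hours(a, b):
    """Absolute circular distance |a - b| in [0, 12] hours."""
    return np.abs(circular_diff_hours(a, b))


def circular_mae_hours(estimated, truth):
    """Mean absolute circular error between two phase vectors, hours."""
    return float(np.mean(circular_abs_error_hours(estimated, truth)))


def circular_corr(hours_a, hours_b):
    """Jammalamadaka-SenGupta circular correlation coefficient.

    r = sum sin(a - abar) sin(b - bbar) /
        sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar))

    with abar, bbar the circular sample means. Returns nan for
    degenerate (zero-variance) inputs.
    """
    a = hours_to_angle(hours_a)
    b = hours_to_angle(hours_b)
    abar = np.angle(np.exp(1j * a).sum())
    bbar = np.angle(np.exp(1j * b).sum())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return np.nan
    return float((sa * sb).sum() / denom)


def circular_assoc(hours_a, hours_b):
    """Rotation-vs-reflection association of two circular samples.

    Returns r+^2 - r-^2 in [-1, 1], where r+ (r-) is the resultant
    length of the angle differences (sums): +1 iff b is a rotation of
    a, -1 iff a reflection. Unlike moment correlations this remains
    well defined for uniform marginals.
    """
    a = hours_to_angle(hours_a)
    b = hours_to_angle(hours_b)
    r_plus = np.abs(np.exp(1j * (a - b)).mean())
    r_minus = np.abs(np.exp(1j * (a + b)).mean())
    return float(r_plus**2 - r_minus**2)


def circular_rank_corr(hours_a, hours_b):
    """Circular association of the circular ranks of two samples.

    Each sample is replaced by uniform ranks mapped back onto the
    circle (ties broken by index, stably), so the statistic is
    invariant to any monotone circular reparameterization; +1 iff one
    ordering is a rotation of the other, -1 for a reflection.
    """
    a = np.asarray(hours_a, dtype=float)
    b = np.asarray(hours_b, dtype=float)
    n = a.size
    ra = np.empty(n)
    rb = np.empty(n)
    ra[np.argsort(a, kind="stable")] = np.arange(n)
    rb[np.argsort(b, kind="stable")] = np.arange(n)
    return circular_assoc(ra * PERIOD_H / n, rb * PERIOD_H / n)


def rayleigh_test(hours):
    """Rayleigh test of uniformity on the circle.

    Returns (R, p) where R is the mean resultant length and p the
    approximate p-value with the standard finite-n correction.
    """
    h = np.asarray(hours, dtype=float)
    n = h.size
    r = resultant_length(h)
    z = n * r * r
    p = np.exp(-z) * (
        1 + (2 * z - z * z) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n * n)
    )
    return r, float(np.clip(p, 0.0, 1.0))
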