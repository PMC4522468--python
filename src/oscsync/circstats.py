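"""Circular statistics for phase-reset analysis.

All angles are in radians. Degrees appear only at CLI/report boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AngleSample",
    "PairedAngleSample",
    "vector_strength",
    "circular_correlation",
    "hotelling_paired",
    "circular_mean_sem",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class AngleSample:
    """A set of angles (radians), one per stimulus repetition.

    Angles are reduced modulo 2*pi on construction.
    """

    angles: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("AngleSample requires at least one angle")
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "angles", np.mod(a, _TWO_PI))
        object.__setattr__(self, "n", int(a.size))


@dataclass(frozen=True)
class PairedAngleSample:
    """Equal-length paired angle samples (e.g. normal vs reversed polarity)."""

    angles_a: np.ndarray
    angles_b: np.ndarray
    n_pairs: int = field(init=False)

    def __post_init__(self) -> None:
        a = np.mod(np.asarray(self.angles_a, dtype=float), _TWO_PI)
        b = np.mod(np.asarray(self.angles_b, dtype=float), _TWO_PI)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired samples must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "angles_a", a)
        object.__setattr__(self, "angles_b", b)
        object.__setattr__(self, "n_pairs", int(a.size))


def vector_strength(sample: AngleSample) -> dict:
    """Resultant length r and mean angle of a set of angles.

    r = sqrt((sum cos(phi)/n)^2 + (sum sin(phi)/n)^2); equals 1 when all
    angles coincide and 0 when they are balanced around the circle.
    """
    phi = np.asarray(sample.angles, dtype=float)
    if phi.size == 0:
        raise ValueError("vector_strength: empty angle sample")
    c = np.sum(np.cos(phi)) / phi.size
    s = np.sum(np.sin(phi)) / phi.size
    r = float(np.hypot(c, s))
    return {"r": min(r, 1.0), "mean_angle": float(np.mod(np.arctan2(s, c), _TWO_PI))}


def _circular_mean(a: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))


def circular_correlation(a: AngleSample, b: AngleSample) -> float:
    """Circular correlation coefficient (sine-product estimator).

    r_cc = sum sin(a - abar) sin(b - bbar)
           / sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar))
    where abar/bbar are the circular means. When a sample's resultant length
    is ~0 the circular mean is undefined; the equivalent mean-free pairwise
    form sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) / sqrt(...) is used then.
    """
    x = np.asarray(a.angles, dtype=float)
    y = np.asarray(b.angles, dtype=float)
    if x.size != y.size:
        raise ValueError("circular_correlation: samples must have equal length")
    if x.size < 2:
        raise ValueError("circular_correlation: need at least 2 angles")
    res_x = np.hypot(np.mean(np.sin(x)), np.mean(np.cos(x)))
    res_y = np.hypot(np.mean(np.sin(y)), np.mean(np.cos(y)))
    if min(res_x, res_y) < 1e-10:
        dx = np.sin(x[:, None] - x[None, :])
        dy = np.sin(y[:, None] - y[None, :])
        den = np.sqrt(np.sum(dx**2) * np.sum(dy**2))
        if den == 0.0:
            raise ValueError("circular_correlation: degenerate input (zero angular variance)")
        return float(np.clip(np.sum(dx * dy) / den, -1.0, 1.0))
    sx = np.sin(x - _circular_mean(x))
    sy = np.sin(y - _circular_mean(y))
    den_x = np.sum(sx**2)
    den_y = np.sum(sy**2)
    if den_x == 0.0:
        raise ValueError("circular_correlation: first sample is degenerate (zero angular variance)")
    if den_y == 0.0:
        raise ValueError("circular_correlation: second sample is degenerate (zero angular variance)")
    r_cc = float(np.sum(sx * sy) / np.sqrt(den_x * den_y))
    return float(np.clip(r_cc, -1.0, 1.0))


def hotelling_paired(sample: PairedAngleSample, alpha: float = 0.05) -> dict:
    """Paired second-order Hotelling test for circular data.

    Per-pair rectangular differences X_j = cos(a_j) - cos(b_j),
    Y_j = sin(a_j) - sin(b_j) are tested against a zero mean vector:

        F = n (n - 2) / 2
            * (Xbar^2 Syy - 2 Xbar Ybar Sxy + Ybar^2 Sxx)
            / (Sxx Syy - Sxy^2)

    with Sxx = sum (X - Xbar)^2 etc., compared against the upper-alpha
    quantile of F(2, n - 2).
    """
    n = sample.n_pairs
    if n < 3:
        raise ValueError("hotelling_paired: need at least 3 pairs (df = n - 2 > 0)")
    X = np.cos(sample.angles_a) - np.cos(sample.angles_b)
    Y = np.sin(sample.angles_a) - np.sin(sample.angles_b)
    xbar, ybar = X.mean(), Y.mean()
    dx, dy = X - xbar, Y - ybar
    sxx = np.sum(dx * dx)
    syy = np.sum(dy * dy)
    sxy = np.sum(dx * dy)
    denom = sxx * syy - sxy**2
    if denom <= 0.0:
        # identical pairs everywhere: no dispersion, difference vector is 0
        F = 0.0 if (xbar == 0.0 and ybar == 0.0) else np.inf
    else:
        F = float(n * (n - 2) / 2.0 * (xbar**2 * syy - 2 * xbar * ybar * sxy + ybar**2 * sxx) / denom)
    F_crit = float(stats.f.ppf(1.0 - alpha, 2, n - 2))
    return {"F": F, "F_crit": F_crit, "significant": bool(F > F_crit)}


def circular_mean_sem(sample: AngleSample) -> dict:
    """Circular mean with a dispersion-based angular S.E.M.

    S.E.M. is the circular standard deviation sqrt(-2 ln r) divided by
    sqrt(n); undefined (error) when the mean direction is undefined (r = 0).
    """
    if sample.n < 2:
        raise ValueError("circular_mean_sem: need at least 2 angles")
    vs = vector_strength(sample)
    r = vs["r"]
    if r <= 1e-12:
        raise ValueError("circular_mean_sem: mean direction undefined (r = 0)")
    csd = np.sqrt(max(-2.0 * np.log(min(r, 1.0)), 0.0))
    return {"mean": vs["mean_angle"], "sem": float(csd / np.sqrt(sample.n))}
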