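"""Local dynamic stability via the local divergence exponent (LDE).

The trunk (T6) velocity series is delay-embedded, each embedded point's
nearest neighbor (outside a Theiler window) is found, and the mean
logarithm of the pairwise distance is tracked forward in time
(Rosenstein's method).  The LDE is the least-squares slope of this mean
log-divergence curve over the first half stride, with the time axis
normalized by stride duration; a larger exponent means neighboring
trajectories separate faster, i.e. less locally stable gait.

Defaults (embedding dimension 5, delay 10 samples = 0.1 stride at 100
samples/stride, Theiler window of half a stride) follow common practice
for treadmill-gait LDE analyses and are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InsufficientDataError, ParameterError, ValidationError

__all__ = ["DivergenceCurve", "three_point_velocity", "resample_strides",
           "rosenstein_divergence", "lde_slope", "lde_from_series"]


@dataclass
class DivergenceCurve:
    """Mean log divergence vs time (in strides) with its fitted slope."""

    time_strides: np.ndarray
    mean_log_divergence: np.ndarray
    samples_per_stride: int
    dim: int
    delay: int
    theiler: int
    n_pairs: int
    n_skipped: int = 0


def three_point_velocity(position: np.ndarray, rate: float) -> np.ndarray:
    """Velocity by three-point (central) differentiation.

    ``v[i] = (x[i+1] - x[i-1]) * rate / 2`` with one-sided differences
    at the endpoints.  Exact for linear signals.
    """
    x = np.asarray(position, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need at least 3 samples")
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * rate / 2.0
    v[0] = (x[1] - x[0]) * rate
    v[-1] = (x[-1] - x[-2]) * rate
    return v


def resample_strides(series: np.ndarray, rate: float, strikes: np.ndarray,
                     n_strides: int = 256,
                     samples_per_stride: int = 100) -> np.ndarray:
    """Time-normalize a series so each stride spans a fixed sample count.

    The span of the first ``n_strides`` strides is warped so stride k
    occupies samples ``[k*m, (k+1)*m)`` with ``m = samples_per_stride``;
    256 strides at 100 samples/stride yield exactly 25,600 samples.
    """
    strikes = np.asarray(strikes, dtype=float)
    if strikes.size < n_strides + 1:
        raise InsufficientDataError(
            f"need {n_strides} complete strides, have {strikes.size - 1}")
    t = np.arange(series.size) / rate
    out = np.empty(n_strides * samples_per_stride)
    frac = np.arange(samples_per_stride) / samples_per_stride
    for k in range(n_strides):
        tt = strikes[k] + frac * (strikes[k + 1] - strikes[k])
        out[k * samples_per_stride:(k + 1) * samples_per_stride] = \
            np.interp(tt, t, series)
    return out


def _embed(series: np.ndarray, dim: int, delay: int) -> np.ndarray:
    m = series.size - (dim - 1) * delay
    if m < 2:
        raise InsufficientDataError("series too short for this embedding")
    return np.stack([series[i * delay: i * delay + m] for i in range(dim)],
                    axis=1)


def rosenstein_divergence(series: np.ndarray, samples_per_stride: int,
                          dim: int = 5, delay: int = 10,
                          theiler: int | None = None,
                          horizon_strides: float = 1.0) -> DivergenceCurve:
    """Mean log-divergence curve of nearest-neighbor trajectories.

    The series is delay-embedded; for each point the nearest neighbor
    with ``|i - j| > theiler`` (default: half a stride) is found, and
    ``ln`` of the Euclidean distance between the two trajectories is
    averaged over pairs as both evolve forward over ``horizon_strides``.
    Points without an admissible neighbor are skipped and counted.
    """
    series = np.asarray(series, dtype=float)
    if np.ptp(series) == 0:
        raise ValidationError("degenerate (constant) series")
    if theiler is None:
        theiler = samples_per_stride // 2
    horizon = int(round(horizon_strides * samples_per_stride))
    emb = _embed(series, dim, delay)
    m_total = emb.shape[0]
    m_track = m_total - horizon          # points that can be tracked
    if m_track < 2 * theiler + 2:
        raise InsufficientDataError(
            "series too short for the requested horizon and Theiler window")
    pts = emb[:m_track]

    tree = cKDTree(pts)
    k_query = min(m_track, 2 * theiler + 8)
    dists, idxs = tree.query(pts, k=k_query, workers=-1)
    neighbor = np.full(m_track, -1)
    for j in range(m_track):
        admissible = np.abs(idxs[j] - j) > theiler
        cand = idxs[j][admissible]
        if cand.size:
            neighbor[j] = cand[0]
        else:
            # rare: all queried neighbors inside the Theiler window
            d = np.linalg.norm(pts - pts[j], axis=1)
            d[np.abs(np.arange(m_track) - j) <= theiler] = np.inf
            jj = int(np.argmin(d))
            if np.isfinite(d[jj]):
                neighbor[j] = jj
    valid = neighbor >= 0
    n_skipped = int((~valid).sum())
    j_idx = np.flatnonzero(valid)
    nb = neighbor[valid]

    curve = np.empty(horizon + 1)
    tiny = 1e-15 * max(np.ptp(series), 1.0)
    for i in range(horizon + 1):
        diff = emb[j_idx + i] - emb[nb + i]
        d = np.sqrt(np.sum(diff * diff, axis=1))
        curve[i] = np.mean(np.log(np.maximum(d, tiny)))
    time_strides = np.arange(horizon + 1) / samples_per_stride
    return DivergenceCurve(
        time_strides=time_strides, mean_log_divergence=curve,
        samples_per_stride=samples_per_stride, dim=dim, delay=delay,
        theiler=theiler, n_pairs=int(valid.sum()), n_skipped=n_skipped)


def lde_slope(curve: DivergenceCurve,
              window: tuple[float, float] = (0.0, 0.5)) -> float:
    """Least-squares slope (1/stride) of the curve over a stride window.

    The default window is the first half stride; later points do not
    influence the fit.
    """
    lo, hi = window
    mask = (curve.time_strides >= lo - 1e-12) & (curve.time_strides <= hi + 1e-12)
    if mask.sum() < 3:
        raise InsufficientDataError("fewer than 3 points in the fit window")
    if curve.time_strides[mask].max() < hi - 1e-9:
        raise InsufficientDataError(
            f"divergence curve does not cover {hi} strides")
    t = curve.time_strides[mask]
    y = curve.mean_log_divergence[mask]
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def lde_from_series(series: np.ndarray, samples_per_stride: int,
                    **kwargs) -> float:
    """Convenience: divergence curve then slope over 0-0.5 stride."""
    return lde_slope(rosenstein_divergence(series, samples_per_stride,
                                           **kwargs))
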