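"""Heel-strike / toe-off detection, stride times and step widths.

The primary detector thresholds each belt's vertical force: a heel
strike is the time the force rises through a small fraction of the
median peak stance force, and a toe-off is the matching falling
crossing.  This is precise on clean per-belt data, but fails when a
foot lands on the opposite belt (cross-stepping during narrow-base
walking).  In that case the detector falls back to the center of
pressure of the two belts combined: each foot contact produces a
posterior extremum of the summed anterior-posterior CoP excursion just
as weight transfer begins, which survives summed-belt data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import InsufficientDataError, NoContactError, ValidationError
from .synthetic_gait import TrialRecording

__all__ = ["GaitEvents", "compute_cop", "detect_heel_strikes",
           "compute_stride_times", "compute_step_widths"]


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) per foot, strictly increasing."""

    heel_strikes_left: np.ndarray
    heel_strikes_right: np.ndarray
    toe_offs_left: np.ndarray = field(default_factory=lambda: np.empty(0))
    toe_offs_right: np.ndarray = field(default_factory=lambda: np.empty(0))
    method: str = "per_belt"

    def __post_init__(self) -> None:
        for name in ("heel_strikes_left", "heel_strikes_right",
                     "toe_offs_left", "toe_offs_right"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValidationError(f"{name} must be strictly increasing")

    @property
    def n_strides_left(self) -> int:
        return max(0, self.heel_strikes_left.size - 1)

    @property
    def n_strides_right(self) -> int:
        return max(0, self.heel_strikes_right.size - 1)

    def check_alternation(self) -> None:
        """Raise unless left and right strikes strictly interleave."""
        merged = sorted([(t, "L") for t in self.heel_strikes_left]
                        + [(t, "R") for t in self.heel_strikes_right])
        feet = [f for _, f in merged]
        for a, b in zip(feet, feet[1:]):
            if a == b:
                raise ValidationError(
                    "heel strikes do not alternate between feet")


def compute_cop(fz: np.ndarray, mx: np.ndarray, my: np.ndarray,
                floor: float = 20.0) -> np.ndarray:
    """Center of pressure from vertical force and plate moments.

    ``cop_x = -My/Fz`` (mediolateral, rightward positive) and
    ``cop_y = Mx/Fz`` (anterior-posterior).  Samples where the vertical
    force does not exceed ``floor`` newtons are returned as NaN rather
    than interpolated.
    """
    fz = np.asarray(fz, dtype=float)
    loaded = fz > floor
    if not loaded.any():
        raise NoContactError(
            f"vertical force never exceeds the {floor} N contact floor")
    cop = np.full((fz.size, 2), np.nan)
    cop[loaded, 0] = -np.asarray(my, dtype=float)[loaded] / fz[loaded]
    cop[loaded, 1] = np.asarray(mx, dtype=float)[loaded] / fz[loaded]
    return cop


def _threshold_events(fz: np.ndarray, rate: float, threshold_frac: float,
                      refractory: float, floor: float = 20.0):
    """Rising/falling threshold crossings of one belt's vertical force."""
    loaded = fz > floor
    if not loaded.any():
        return np.empty(0), np.empty(0)
    # median peak stance force over contiguous loaded regions
    regions = []
    in_region = False
    start = 0
    for i, flag in enumerate(loaded):
        if flag and not in_region:
            in_region, start = True, i
        elif not flag and in_region:
            in_region = False
            regions.append((start, i))
    if in_region:
        regions.append((start, loaded.size))
    peaks = [fz[a:b].max() for a, b in regions if b - a > 3]
    if not peaks:
        return np.empty(0), np.empty(0)
    thr = threshold_frac * float(np.median(peaks))
    above = fz > thr
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    falls = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    min_gap = int(round(refractory * rate))

    def _dedup_interp(indices, rising):
        times, last = [], -min_gap - 1
        for i in indices:
            if i - last <= min_gap:
                continue
            last = i
            # sub-sample crossing time by linear interpolation
            f0, f1 = fz[i - 1], fz[i]
            frac = (thr - f0) / (f1 - f0) if f1 != f0 else 0.0
            times.append((i - 1 + frac) / rate)
        return np.asarray(times)

    return _dedup_interp(rises, True), _dedup_interp(falls, False)


def detect_heel_strikes(recording: TrialRecording,
                        threshold_frac: float = 0.05,
                        refractory: float = 0.2) -> GaitEvents:
    """Extract gait events from a trial's force-plate signals.

    Primary path: per-belt vertical-force threshold crossings (rising =
    heel strike, falling = toe-off, default threshold 5% of the median
    peak stance force with a 0.2 s refractory period).  If per-belt
    separation fails -- strikes do not alternate between feet, as
    happens with narrow-base cross-stepping -- the detector falls back
    to extrema of the summed-belt anterior-posterior CoP excursion.

    A trial with a constant (standing) load yields an explicit empty
    result; fewer than 2 detected strides on either foot raises
    :class:`InsufficientDataError`.
    """
    rate = recording.forces_left.rate
    if len(recording.evs) / rate < 3.0:
        raise InsufficientDataError("need at least 3 s of data")
    fz_l = recording.forces_left.force[:, 2]
    fz_r = recording.forces_right.force[:, 2]

    hs_l, to_l = _threshold_events(fz_l, rate, threshold_frac, refractory)
    hs_r, to_r = _threshold_events(fz_r, rate, threshold_frac, refractory)

    if hs_l.size == 0 and hs_r.size == 0:
        # constant load or quiet standing: no gait
        return GaitEvents(np.empty(0), np.empty(0), method="per_belt")

    events = GaitEvents(hs_l, hs_r, to_l, to_r, method="per_belt")
    try:
        events.check_alternation()
        ok = hs_l.size >= 3 and hs_r.size >= 3
        # cross-stepping merges stances on one belt: strikes go missing,
        # leaving implausibly long per-belt stride times
        for strikes in (hs_l, hs_r):
            st = np.diff(strikes)
            if st.size and np.max(st) > 1.5 * np.median(st):
                ok = False
    except ValidationError:
        ok = False
    if ok:
        if events.n_strides_left < 2 or events.n_strides_right < 2:
            raise InsufficientDataError(
                f"detected only {events.n_strides_left}/"
                f"{events.n_strides_right} strides (left/right)")
        return events
    return _cop_fallback(recording, rate)


def _cop_fallback(recording: TrialRecording, rate: float) -> GaitEvents:
    """Gait events from the summed-belt CoP (cross-stepping robust).

    Heel strikes appear as posterior extrema of the summed AP CoP: the
    landing foot is the most anterior point of support, so from the
    instant of contact the combined CoP reverses from its rearmost
    excursion and sweeps forward.  Feet are assigned by the mediolateral
    CoP during the following single-support window, with the global
    left/right parity chosen by majority vote (individual cross-steps
    may sit on the wrong side of the midline).
    """
    fz = recording.forces_left.force[:, 2] + recording.forces_right.force[:, 2]
    mx = recording.forces_left.moment[:, 0] + recording.forces_right.moment[:, 0]
    my = recording.forces_left.moment[:, 1] + recording.forces_right.moment[:, 1]
    cop = compute_cop(fz, mx, my)
    ap = cop[:, 1].copy()
    ml = cop[:, 0]
    # interpolate across unloaded gaps (rare for summed data)
    idx = np.arange(ap.size)
    good = np.isfinite(ap)
    if good.sum() < 10:
        raise InsufficientDataError("summed CoP almost never defined")
    ap = np.interp(idx, idx[good], ap[good])

    # step period from the dominant AP CoP frequency
    ap_d = ap - ap.mean()
    freqs, psd = _sig.welch(ap_d, fs=rate, nperseg=min(4096, ap_d.size))
    band = (freqs > 0.3) & (freqs < 3.0)
    f_step = freqs[band][np.argmax(psd[band])]
    step_period = 1.0 / f_step

    dist = max(2, int(0.7 * step_period * rate))
    prom = 0.25 * np.std(ap_d)
    minima, _ = _sig.find_peaks(-ap, distance=dist, prominence=prom)
    if minima.size < 5:
        raise InsufficientDataError(
            f"CoP fallback found only {minima.size} candidate contacts")
    strikes = minima / rate

    # foot assignment: ML CoP during the new foot's single support
    votes = np.zeros(strikes.size)
    for k, t in enumerate(strikes):
        a = int((t + 0.3 * step_period) * rate)
        b = int((t + 0.9 * step_period) * rate)
        seg = ml[a:min(b, ml.size)]
        seg = seg[np.isfinite(seg)]
        votes[k] = np.median(seg) if seg.size else 0.0
    # parity: even-indexed strikes all one foot, odd the other
    even_right = votes[0::2].sum() - votes[1::2].sum() > 0
    hs_r = strikes[0::2] if even_right else strikes[1::2]
    hs_l = strikes[1::2] if even_right else strikes[0::2]

    # anterior maxima mark completion of weight transfer ~= opposite
    # toe-off; assign each to the foot whose strike it does not follow
    maxima, _ = _sig.find_peaks(ap, distance=dist, prominence=prom)
    t_max = maxima / rate
    to_l, to_r = [], []
    for t in t_max:
        prev_l = hs_l[hs_l < t]
        prev_r = hs_r[hs_r < t]
        if prev_l.size == 0 and prev_r.size == 0:
            continue
        last_l = prev_l[-1] if prev_l.size else -np.inf
        last_r = prev_r[-1] if prev_r.size else -np.inf
        (to_r if last_l > last_r else to_l).append(t)
    ev = GaitEvents(hs_l, hs_r, np.asarray(to_l), np.asarray(to_r),
                    method="cop_fallback")
    if ev.n_strides_left < 2 or ev.n_strides_right < 2:
        raise InsufficientDataError("fallback recovered fewer than 2 strides")
    return ev


def compute_stride_times(events: GaitEvents) -> dict:
    """Stride durations per foot: first differences of same-foot strikes."""
    out = {}
    for foot, strikes in (("left", events.heel_strikes_left),
                          ("right", events.heel_strikes_right)):
        if strikes.size < 2:
            import warnings
            warnings.warn(f"only {strikes.size} strike(s) on the {foot} foot; "
                          "no stride times available")
            out[foot] = np.empty(0)
        else:
            out[foot] = np.diff(strikes)
    pooled = np.concatenate([out["left"], out["right"]])
    out["mean"] = float(pooled.mean()) if pooled.size else np.nan
    out["sd"] = float(pooled.std(ddof=1)) if pooled.size > 1 else np.nan
    return out


def compute_step_widths(events: GaitEvents, markers: dict,
                        marker_rate: float) -> pd.DataFrame:
    """Mediolateral distance between feet centroids at each heel strike.

    ``markers`` must contain ``heel_left`` and ``heel_right`` centroid
    traces ((n, 3), meters).  Widths are evaluated at the strike sample;
    a marker dropout (NaN) at a strike flags that step's width missing.
    """
    for key in ("heel_left", "heel_right"):
        if key not in markers:
            raise ValidationError(f"marker cluster {key!r} missing")
    n = markers["heel_left"].shape[0]
    t_m = np.arange(n) / marker_rate
    rows = []
    for foot, strikes in (("left", events.heel_strikes_left),
                          ("right", events.heel_strikes_right)):
        other = "right" if foot == "left" else "left"
        for t in strikes:
            i = int(round(t * marker_rate))
            if not 0 <= i < n:
                continue
            a = markers[f"heel_{foot}"][i, 0]
            b = markers[f"heel_{other}"][i, 0]
            width = abs(a - b) if np.isfinite(a) and np.isfinite(b) else np.nan
            rows.append((foot, t, width))
    df = pd.DataFrame(rows, columns=["foot", "time_s", "width_m"])
    return df.sort_values("time_s").reset_index(drop=True)
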