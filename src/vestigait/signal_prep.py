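"""Signal conditioning and stride-synchronized segmentation.

EMG envelopes: full-wave rectification, zero-phase 6th-order Butterworth
low-pass at 20 Hz, per-stride time normalization and averaging, with
study-level normalization to each channel's maximum across conditions.

Coherence inputs: (rectified) signals are zero-phase low-pass filtered
at 100 Hz and brought to a common 200 samples/s grid, then cut into
stride segments padded with half a stride of neighboring data on each
side so the wavelet transform's edge distortion falls outside the
analyzed stride.  Stride-to-stride duration differences are removed by
resampling each stride's time axis to the grand-average stride duration
(applied to the per-stride spectra downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .errors import InsufficientDataError, ParameterError, ValidationError

__all__ = ["StrideSegments", "emg_envelope", "normalize_envelopes",
           "prep_for_coherence", "segment_strides", "normalize_durations",
           "resample_axis"]

TARGET_RATE = 200.0
LP_ENVELOPE_HZ = 20.0
LP_COHERENCE_HZ = 100.0


@dataclass
class StrideSegments:
    """Padded stride-synchronized cuts of one conditioned channel.

    Each segment spans ``[strike_i - pad*T_i, strike_{i+1} + pad*T_i]``
    where ``T_i`` is that stride's duration.  Pad boundaries are stored
    per segment so post-transform cropping is exact, and the core
    samples concatenate back to the original signal bit-exactly.
    """

    segments: list = field(repr=False)      # list of 1-D arrays
    core_start: np.ndarray = field(repr=False)  # pad samples before core
    core_len: np.ndarray = field(repr=False)
    rate: float = TARGET_RATE
    pad_fraction: float = 0.5
    strike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dropped: int = 0

    @property
    def n_strides(self) -> int:
        return len(self.segments)

    @property
    def durations(self) -> np.ndarray:
        """Native stride durations in seconds."""
        return self.core_len / self.rate

    def cores(self) -> list:
        """Pad-free per-stride samples."""
        return [seg[p:p + n] for seg, p, n in
                zip(self.segments, self.core_start, self.core_len)]


def _butter_lp(x: np.ndarray, cutoff: float, rate: float, order: int) -> np.ndarray:
    sos = _sig.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return _sig.sosfiltfilt(sos, x)


def emg_envelope(emg: np.ndarray, rate: float, strikes: np.ndarray,
                 n_strides: int, grid: int = 1000) -> np.ndarray:
    """Average rectified-and-smoothed EMG over the stride cycle.

    Full-wave rectify, zero-phase 6th-order Butterworth low pass at
    20 Hz, resample each stride onto a fixed 0-100% grid and average
    the first ``n_strides`` strides.  Returns the mean envelope on the
    ``grid``-point cycle grid (not yet normalized across conditions;
    see :func:`normalize_envelopes`).
    """
    emg = np.asarray(emg, dtype=float)
    if rate < 200:
        raise ParameterError(f"EMG rate must be >= 200 samples/s, got {rate}")
    if strikes.size < n_strides + 1:
        raise InsufficientDataError(
            f"need {n_strides} complete strides, have {strikes.size - 1}")
    if np.ptp(emg) == 0:
        warnings.warn("degenerate EMG channel (constant signal)")
    env = _butter_lp(np.abs(emg), LP_ENVELOPE_HZ, rate, order=6)
    t = np.arange(emg.size) / rate
    phases = np.arange(grid) / grid
    out = np.empty((n_strides, grid))
    for k in range(n_strides):
        tt = strikes[k] + phases * (strikes[k + 1] - strikes[k])
        out[k] = np.interp(tt, t, env)
    return out.mean(axis=0)


def normalize_envelopes(per_condition: dict) -> dict:
    """Normalize envelopes by each channel's maximum across conditions.

    ``per_condition`` maps condition name -> {channel -> envelope}; the
    study-level maximum of each channel over all conditions becomes 1.
    """
    channels = {ch for envs in per_condition.values() for ch in envs}
    scale = {}
    for ch in channels:
        m = max(np.max(envs[ch]) for envs in per_condition.values() if ch in envs)
        scale[ch] = m if m > 0 else 1.0
    return {cond: {ch: env / scale[ch] for ch, env in envs.items()}
            for cond, envs in per_condition.items()}


def prep_for_coherence(x: np.ndarray, rate: float, kind: str = "evs",
                       target_rate: float = TARGET_RATE,
                       lp: float = LP_COHERENCE_HZ) -> np.ndarray:
    """Condition a signal for the wavelet coherence analysis.

    EMG (``kind='emg'``) is full-wave rectified first.  Signals above
    the target rate are zero-phase low-pass filtered at ``lp`` Hz
    (6th-order Butterworth) and decimated/resampled to exactly
    ``target_rate``.  Upsampling is refused: the conditioning pipeline
    only ever moves down to the force-plate rate.
    """
    x = np.asarray(x, dtype=float)
    if rate < target_rate:
        raise ParameterError(
            f"input rate {rate} below target {target_rate}; upsampling refused")
    if kind == "emg":
        x = np.abs(x)
    if rate == target_rate:
        return x.copy()
    x = _butter_lp(x, lp, rate, order=6)
    ratio = rate / target_rate
    if abs(ratio - round(ratio)) < 1e-9:
        return x[:: int(round(ratio))].copy()
    from fractions import Fraction
    frac = Fraction(int(round(target_rate * 1000)), int(round(rate * 1000)))
    return _sig.resample_poly(x, frac.numerator, frac.denominator)


def segment_strides(x: np.ndarray, rate: float, strikes: np.ndarray,
                    pad_fraction: float = 0.5) -> StrideSegments:
    """Cut a conditioned signal into padded stride segments.

    Strides whose padding would run past the ends of the recording are
    excluded and counted in ``n_dropped``.
    """
    if not 0.0 <= pad_fraction <= 1.0:
        raise ParameterError("pad_fraction must be in [0, 1]")
    strikes = np.asarray(strikes, dtype=float)
    if strikes.size < 2:
        raise InsufficientDataError("need at least 2 heel strikes")
    idx = np.round(strikes * rate).astype(int)
    segments, core_start, core_len, kept = [], [], [], []
    dropped = 0
    for k in range(strikes.size - 1):
        i0, i1 = idx[k], idx[k + 1]
        n = i1 - i0
        if n <= 0:
            raise ValidationError("zero-length stride")
        p = int(round(pad_fraction * n))
        if i0 - p < 0 or i1 + p > x.size:
            dropped += 1
            continue
        segments.append(x[i0 - p: i1 + p].copy())
        core_start.append(p)
        core_len.append(n)
        kept.append(strikes[k])
    if not segments:
        raise InsufficientDataError("no stride fits within the recording")
    return StrideSegments(
        segments=segments, core_start=np.asarray(core_start),
        core_len=np.asarray(core_len), rate=rate,
        pad_fraction=pad_fraction, strike_times=np.asarray(kept),
        n_dropped=dropped)


def resample_axis(arr: np.ndarray, n_out: int, axis: int = -1) -> np.ndarray:
    """Linear resampling of one axis onto ``n_out`` evenly spaced points.

    Endpoints map to endpoints; works on real or complex arrays.
    """
    arr = np.asarray(arr)
    n_in = arr.shape[axis]
    if n_in == 0:
        raise ParameterError("cannot resample an empty axis")
    if n_in == n_out:
        return arr.copy()
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = pos - lo
    a = np.take(arr, lo, axis=axis)
    b = np.take(arr, hi, axis=axis)
    shape = [1] * arr.ndim
    shape[axis] = n_out
    w = w.reshape(shape)
    return a * (1.0 - w) + b * w


def normalize_durations(segments: StrideSegments,
                        target_core: int | None = None) -> np.ndarray:
    """Resample padded stride segments to a common duration grid.

    The common core length is the rounded grand-average stride length
    in samples (or ``target_core``); pads scale proportionally.  The
    pad and core regions are resampled separately so the core boundary
    lands exactly on a grid point.  Returns an array of shape
    ``(n_strides, pad + core + pad)``; a zero-length stride raises.
    """
    if np.any(segments.core_len <= 0):
        raise ValidationError("zero-length stride")
    n_bar = int(round(segments.core_len.mean())) if target_core is None else target_core
    p_bar = int(round(segments.pad_fraction * n_bar))
    out = np.empty((segments.n_strides, 2 * p_bar + n_bar))
    for k, seg in enumerate(segments.segments):
        p, n = segments.core_start[k], segments.core_len[k]
        pre, core, post = seg[:p], seg[p:p + n], seg[p + n:]
        if p_bar == 0:
            out[k] = resample_axis(core, n_bar)
        else:
            out[k, :p_bar] = resample_axis(pre, p_bar) if p else 0.0
            out[k, p_bar:p_bar + n_bar] = resample_axis(core, n_bar)
            out[k, p_bar + n_bar:] = resample_axis(post, p_bar) if p else 0.0
    return out
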