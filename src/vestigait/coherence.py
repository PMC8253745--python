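"""Time-frequency coherence and gain over the gait cycle.

Stride segments of the stimulus and of each motor output are decomposed
with a continuous Morlet wavelet transform.  Per stride the products

    Pxx = |Wx|^2,   Pyy = |Wy|^2,   Pxy = Wx conj(Wy)

are formed on the padded segment, duration-normalized to the
grand-average stride, cropped to the core stride, and averaged across
strides.  Coherence and gain follow as

    C(tau, f) = |Pxy|^2 / (Pxx Pyy),      G(tau, f) = |Pxy / Pxx|

where tau is the stride phase (0-100%) and f the frequency in Hz.
Coherence lies in [0, 1] by the Cauchy-Schwarz inequality applied to
the stride average; no post-hoc clipping is performed.  The per-point
significance level for magnitude-squared coherence estimated from N
independent segments at confidence 1 - alpha is the standard bound
``1 - alpha**(1/(N-1))`` (0.018 for N = 256, alpha = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as _fft

from .errors import ParameterError, ValidationError
from .signal_prep import StrideSegments, resample_axis

__all__ = ["SpectraSet", "TFMap", "morlet_cwt", "stride_averaged_spectra",
           "coherence_map", "gain_map", "significance_threshold",
           "average_maps", "band_peak_phase", "DEFAULT_FREQS"]

#: Frequency grid for EVS-EMG and EVS-GRF maps: 0.5-25 Hz in 0.25 Hz
#: steps (significant EVS-EMG coupling spans roughly 0-25 Hz, EVS-GRF
#: roughly 0-10 Hz).
DEFAULT_FREQS = np.arange(0.5, 25.0 + 1e-9, 0.25)


@dataclass
class SpectraSet:
    """Stride-averaged time-dependent auto- and cross-spectra."""

    pxx: np.ndarray   # (nf, nt), real >= 0
    pyy: np.ndarray
    pxy: np.ndarray   # complex
    tau: np.ndarray   # stride phase, percent of stride
    freqs: np.ndarray  # Hz
    n_strides: int


@dataclass
class TFMap:
    """A coherence or gain map over (stride phase, frequency)."""

    values: np.ndarray          # (nf, nt)
    kind: str                   # 'coherence' | 'gain'
    tau: np.ndarray
    freqs: np.ndarray
    n_strides: int
    threshold: float | None = None
    defined: np.ndarray = field(default=None, repr=False)  # bool mask

    def __post_init__(self):
        if self.defined is None:
            self.defined = np.isfinite(self.values)


def _time_kernels(freqs: np.ndarray, rate: float,
                  omega0: float) -> tuple[np.ndarray, int]:
    """Time-domain CWT convolution kernels, one row per frequency.

    The analytic Morlet wavelet ``psi(t) = pi^(-1/4) exp(i w0 t - t^2/2)``
    is used with energy normalization ``1/sqrt(s)`` at scale
    ``s = w0 / (2 pi f)``; kernels are truncated at ``+-5 s`` of the
    largest scale.  Returns ``(kernels (nf, 2*half+1), half)``.
    """
    s_max = omega0 / (2.0 * np.pi * freqs.min())
    half = int(np.ceil(5.0 * s_max * rate))
    m = np.arange(-half, half + 1) / rate          # seconds
    K = np.empty((freqs.size, m.size), dtype=complex)
    for i, f in enumerate(freqs):
        s = omega0 / (2.0 * np.pi * f)
        u = m / s
        psi = (np.pi ** -0.25) * np.exp(1j * omega0 * u) * np.exp(-u**2 / 2.0)
        K[i] = psi / (np.sqrt(s) * rate)           # dt / sqrt(s) * psi
    return K, half


def _morlet_kernels(freqs: np.ndarray, rate: float, omega0: float,
                    n: int) -> tuple[np.ndarray, int, int]:
    """FFT of the CWT kernels sized for an n-sample input."""
    K, half = _time_kernels(freqs, rate, omega0)
    nfft = _fft.next_fast_len(n + 2 * half + 1)
    H = np.empty((freqs.size, nfft), dtype=complex)
    for i in range(freqs.size):
        h = np.roll(np.pad(K[i], (0, nfft - K.shape[1])), -half)
        H[i] = _fft.fft(h)
    return H, half, nfft


def morlet_cwt(x: np.ndarray, rate: float, freqs: Sequence[float],
               omega0: float = 6.0) -> np.ndarray:
    """Continuous Morlet wavelet transform at the requested frequencies.

    Returns complex coefficients of shape ``(len(freqs), len(x))``.
    The transform is linear, and a unit impulse at sample j produces the
    conjugated time-reversed wavelet centered on j at each scale.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("input contains non-finite samples")
    if np.any(freqs <= 0) or np.any(freqs >= rate / 2):
        raise ParameterError("analysis frequencies must lie in (0, rate/2)")
    H, half, nfft = _morlet_kernels(freqs, rate, omega0, x.size)
    X = _fft.fft(x, nfft)
    W = _fft.ifft(X[None, :] * H, axis=1)
    return W[:, : x.size]


class _CWTPlan:
    """Reusable kernel FFTs for repeated equal-rate transforms.

    FFT lengths are bucketed (multiples of 512) so the many slightly
    different segment lengths produced by stride-time jitter share a
    small number of precomputed kernel spectra.
    """

    def __init__(self, freqs, rate, omega0):
        self.freqs = np.asarray(freqs, dtype=float)
        self.rate = rate
        self.omega0 = omega0
        self._kernels, self._half = _time_kernels(self.freqs, rate, omega0)
        self._cache: dict[int, np.ndarray] = {}

    def transform(self, x: np.ndarray) -> np.ndarray:
        n = x.size
        need = n + 2 * self._half + 1
        nfft = _fft.next_fast_len(512 * ((need + 511) // 512))
        if nfft not in self._cache:
            nk = self._kernels.shape[1]
            H = np.empty((self.freqs.size, nfft), dtype=complex)
            for i in range(self.freqs.size):
                h = np.roll(np.pad(self._kernels[i], (0, nfft - nk)),
                            -self._half)
                H[i] = _fft.fft(h)
            self._cache[nfft] = H
        X = _fft.fft(x, nfft)
        return _fft.ifft(X[None, :] * self._cache[nfft], axis=1)[:, :n]


def stride_averaged_spectra(x_segments: StrideSegments,
                            y_segments: StrideSegments,
                            freqs: Sequence[float] = DEFAULT_FREQS,
                            omega0: float = 6.0,
                            target_core: int | None = None) -> SpectraSet:
    """Per-stride wavelet spectra, duration-normalized and averaged.

    ``x_segments`` holds the stimulus, ``y_segments`` the output; both
    must share the stride grid.  Per stride the padded segment is
    transformed, the spectral products are formed, their time axes are
    resampled to the grand-average stride duration (auto- and
    cross-spectra alike), the pads are cropped, and the result is
    averaged across strides.
    """
    if x_segments.n_strides != y_segments.n_strides:
        raise ValidationError(
            f"stride counts differ: {x_segments.n_strides} vs "
            f"{y_segments.n_strides}")
    if x_segments.rate != y_segments.rate:
        raise ValidationError("sampling rates differ between x and y")
    freqs = np.asarray(freqs, dtype=float)
    rate = x_segments.rate
    n_bar = (int(round(x_segments.core_len.mean()))
             if target_core is None else int(target_core))
    p_bar = int(round(x_segments.pad_fraction * n_bar))
    plan = _CWTPlan(freqs, rate, omega0)

    nt = n_bar
    pxx = np.zeros((freqs.size, nt))
    pyy = np.zeros((freqs.size, nt))
    pxy = np.zeros((freqs.size, nt), dtype=complex)
    n = x_segments.n_strides
    for k in range(n):
        sx, sy = x_segments.segments[k], y_segments.segments[k]
        if sx.size != sy.size:
            raise ValidationError("segment lengths differ between x and y")
        wx = plan.transform(sx)
        wy = plan.transform(sy)
        target = 2 * p_bar + n_bar
        axx = resample_axis(np.abs(wx) ** 2, target, axis=1)
        ayy = resample_axis(np.abs(wy) ** 2, target, axis=1)
        axy = resample_axis(wx * np.conj(wy), target, axis=1)
        sl = slice(p_bar, p_bar + n_bar)
        pxx += axx[:, sl]
        pyy += ayy[:, sl]
        pxy += axy[:, sl]
    pxx /= n
    pyy /= n
    pxy /= n
    tau = 100.0 * np.arange(nt) / nt
    return SpectraSet(pxx=pxx, pyy=pyy, pxy=pxy, tau=tau,
                      freqs=freqs, n_strides=n)


def coherence_map(spectra: SpectraSet) -> TFMap:
    """Magnitude-squared coherence ``|Pxy|^2 / (Pxx Pyy)``.

    Grid points where either auto-spectrum vanishes are flagged
    undefined (NaN), never zero-filled.
    """
    eps = 1e-300
    denom = spectra.pxx * spectra.pyy
    defined = denom > eps
    c = np.full(denom.shape, np.nan)
    c[defined] = np.abs(spectra.pxy[defined]) ** 2 / denom[defined]
    return TFMap(values=c, kind="coherence", tau=spectra.tau,
                 freqs=spectra.freqs, n_strides=spectra.n_strides,
                 defined=defined)


def gain_map(spectra: SpectraSet) -> TFMap:
    """Gain ``|Pxy / Pxx|``: output amplitude per unit input."""
    defined = spectra.pxx > 1e-300
    g = np.full(spectra.pxx.shape, np.nan)
    g[defined] = np.abs(spectra.pxy[defined]) / spectra.pxx[defined]
    return TFMap(values=g, kind="gain", tau=spectra.tau,
                 freqs=spectra.freqs, n_strides=spectra.n_strides,
                 defined=defined)


def significance_threshold(n_strides: int, alpha: float = 0.01) -> float:
    """Per-point significance level for coherence from N segments.

    ``1 - alpha**(1/(N-1))``, the standard confidence bound for
    magnitude-squared coherence estimated from N independent segments
    (0.0179... for N = 256 at alpha = 0.01).
    """
    if n_strides < 2:
        raise ParameterError(f"need at least 2 strides, got {n_strides}")
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    return 1.0 - alpha ** (1.0 / (n_strides - 1))


def average_maps(maps: Sequence[TFMap]) -> TFMap:
    """Average maps over limbs/channels (e.g. left/right pooling)."""
    if not maps:
        raise ParameterError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or m.kind != first.kind:
            raise ValidationError("maps have mismatched grids or kinds")
    stacked = np.stack([m.values for m in maps])
    return TFMap(values=np.nanmean(stacked, axis=0), kind=first.kind,
                 tau=first.tau, freqs=first.freqs,
                 n_strides=first.n_strides, threshold=first.threshold)


def band_peak_phase(tf: TFMap, f_lo: float = 0.0, f_hi: float = 25.0) -> float:
    """Stride fraction of the peak band-averaged map value."""
    band = (tf.freqs >= f_lo) & (tf.freqs <= f_hi)
    profile = np.nanmean(tf.values[band], axis=0)
    return float(tf.tau[np.nanargmax(profile)] / 100.0)
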