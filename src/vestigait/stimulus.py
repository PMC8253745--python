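"""Stochastic electrical vestibular stimulus (EVS) generation.

The stimulus is zero-mean Gaussian white noise, low-pass filtered with a
zero-phase (forward-backward) Butterworth filter and linearly rescaled so
that its largest absolute excursion equals a prescribed peak current.
With a 25 Hz cutoff and a 5.0 mA peak over an 8-minute trial the RMS
amplitude comes out near 1.2 mA; the peak is the binding constraint and
the RMS is emergent (only one of the two can be exact).

The waveform is deterministic for a fixed seed, which lets downstream
coherence analyses be replayed bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _sig

from .errors import AliasingError, ParameterError

__all__ = ["EVSSignal", "generate_evs", "write_evs", "read_evs"]


@dataclass(frozen=True)
class EVSSignal:
    """A band-limited stochastic vestibular current waveform.

    Attributes
    ----------
    samples : numpy.ndarray
        Current in mA, one dimensional.
    rate : float
        Sampling rate in samples/s.
    seed : int
        Seed of the white-noise source.
    cutoff : float
        Low-pass cutoff in Hz (design cutoff of the Butterworth filter,
        applied forward and backward).
    filter_order : int
        Order of the designed Butterworth filter (before the
        bidirectional pass doubles the effective roll-off).
    peak : float
        Peak absolute current in mA; ``max(|samples|) == peak``.
    """

    samples: np.ndarray = field(repr=False)
    rate: float
    seed: int
    cutoff: float
    filter_order: int
    peak: float

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate

    @property
    def rms(self) -> float:
        """Root-mean-square amplitude in mA."""
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate


def generate_evs(
    duration: float,
    rate: float = 200.0,
    cutoff: float = 25.0,
    order: int = 4,
    peak: float = 5.0,
    seed: int = 0,
) -> EVSSignal:
    """Generate a zero-mean, low-pass-filtered white-noise stimulus.

    Parameters
    ----------
    duration : float
        Length of the stimulus in seconds.
    rate : float
        Sampling rate in samples/s.  Must be at least ``2 * cutoff``
        (at least ``4 * cutoff`` is recommended for a clean stop band).
    cutoff : float
        Butterworth low-pass cutoff in Hz.
    order : int
        Filter order (the zero-phase pass applies it twice).
    peak : float
        Target peak absolute amplitude in mA.  Applied after filtering
        and mean removal by a single linear scale.
    seed : int
        Seed for the Gaussian white-noise source.

    Returns
    -------
    EVSSignal
    """
    if duration <= 0:
        raise ParameterError(f"duration must be positive, got {duration}")
    if peak <= 0:
        raise ParameterError(f"peak must be positive, got {peak}")
    if order < 1:
        raise ParameterError(f"filter order must be >= 1, got {order}")
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if rate < 2 * cutoff:
        raise AliasingError(
            f"rate {rate} samples/s cannot represent a {cutoff} Hz band "
            f"(need rate >= {2 * cutoff})"
        )

    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = _sig.butter(order, cutoff, btype="low", fs=rate, output="sos")
    filtered = _sig.sosfiltfilt(sos, white)
    filtered = filtered - filtered.mean()
    filtered *= peak / np.max(np.abs(filtered))
    return EVSSignal(
        samples=filtered, rate=float(rate), seed=int(seed),
        cutoff=float(cutoff), filter_order=int(order), peak=float(peak),
    )


def write_evs(sig: EVSSignal, path: str | Path) -> None:
    """Write an :class:`EVSSignal` as a commented CSV file."""
    path = Path(path)
    header = (
        "# vestigait evs v1\n"
        f"# rate_hz={sig.rate!r}\n"
        f"# seed={sig.seed}\n"
        f"# cutoff_hz={sig.cutoff!r}\n"
        f"# filter_order={sig.filter_order}\n"
        f"# peak_ma={sig.peak!r}\n"
        "current_ma\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, sig.samples, fmt="%.17g")


def read_evs(path: str | Path) -> EVSSignal:
    """Read an :class:`EVSSignal` written by :func:`write_evs`."""
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            n_header += 1
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
            else:
                break  # column-name row
    samples = np.loadtxt(path, skiprows=n_header)
    return EVSSignal(
        samples=np.atleast_1d(samples),
        rate=float(meta["rate_hz"]),
        seed=int(meta["seed"]),
        cutoff=float(meta["cutoff_hz"]),
        filter_order=int(meta["filter_order"]),
        peak=float(meta["peak_ma"]),
    )
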