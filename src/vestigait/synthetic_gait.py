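"""Synthetic walking trials with known vestibulo-motor coupling.

No raw recordings ship with this package, so every analysis stage is
exercised against a simulator that emulates a treadmill walking trial:
per-belt 3-axis forces and moments at 200 samples/s, surface-EMG-like
activity at 2000 samples/s, marker-cluster centroids at 100 samples/s,
and the applied vestibular current.  The simulator's job is not
anatomical realism; it is to provide streams whose ground truth (heel
strikes, step widths, coupling gains and phase gates, center-of-pressure
trajectories) is known exactly, so that the event detector, the
stride-synchronized coherence pipeline and the stability estimator can
be validated quantitatively.

Vestibulo-motor coupling is modeled as gated linear filtering: each
output channel receives ``gain * gate(phase) * (kernel * evs)(t - delay)``
on top of a phasic baseline, where the raised-cosine gate localizes the
response to a window of the stride cycle.  Trunk (T6) kinematics come
from a noise-driven limit-cycle oscillator whose divergence grows with
the dynamical noise level, giving a tunable local divergence exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy import signal as _sig

from .errors import InsufficientDataError, LengthError, ParameterError
from .stimulus import EVSSignal

__all__ = [
    "FORCE_RATE", "EMG_RATE", "MARKER_RATE",
    "ChannelCoupling", "CouplingConfig", "ForcePlate", "TrialTruth",
    "TrialRecording", "phase_gate", "stride_phase", "simulate_trial",
    "simulate_t6_series", "emg_coupling_kernel", "grf_coupling_kernel",
    "default_coupling", "condition_preset", "EMG_CHANNELS",
]

FORCE_RATE = 200.0    # samples/s, force plates
EMG_RATE = 2000.0     # samples/s, surface EMG
MARKER_RATE = 100.0   # samples/s, marker clusters

#: EMG channel names: three muscles relevant to frontal-plane gait
#: stability, both sides.
EMG_CHANNELS = (
    "gastrocnemius_medialis_l", "gastrocnemius_medialis_r",
    "gluteus_medius_l", "gluteus_medius_r",
    "erector_spinae_l", "erector_spinae_r",
)


# ---------------------------------------------------------------------------
# coupling configuration
# ---------------------------------------------------------------------------

def emg_coupling_kernel(rate: float = FORCE_RATE, sigma: float = 0.035,
                        support: float = 0.1) -> np.ndarray:
    """Default EVS->EMG impulse response: a biphasic (odd) pulse.

    ``k(t) = -t * exp(-t^2 / (2 sigma^2))`` truncated at ``+-support``
    seconds and normalized so the peak of its frequency-response
    magnitude is 1 (the channel ``gain`` is then the peak transfer
    magnitude in output units per mA).  The response is band limited to
    roughly 0-20 Hz with ~200 ms total support.
    """
    half = int(round(support * rate))
    t = np.arange(-half, half + 1) / rate
    k = -t * np.exp(-(t**2) / (2 * sigma**2))
    h = np.fft.rfft(k, 8192)
    return k / np.max(np.abs(h))


def grf_coupling_kernel(rate: float = FORCE_RATE, sigma: float = 0.03,
                        support: float = 0.1) -> np.ndarray:
    """Default EVS->GRF impulse response: a Gaussian low-pass (<= ~10 Hz)."""
    half = int(round(support * rate))
    t = np.arange(-half, half + 1) / rate
    k = np.exp(-(t**2) / (2 * sigma**2))
    h = np.fft.rfft(k, 8192)
    return k / np.max(np.abs(h))


@dataclass
class ChannelCoupling:
    """Phase-gated linear coupling of the EVS to one output channel."""

    gate_center: float = 0.5   # stride fraction in [0, 1)
    gate_width: float = 0.25   # stride fraction in (0, 1]
    gain: float = 0.0          # peak transfer magnitude, units per mA
    delay: float = 0.01        # s
    kernel: Optional[np.ndarray] = None  # FIR at FORCE_RATE; None -> default
    noise_sd: float = 0.0      # additive white noise, output units

    def __post_init__(self) -> None:
        if not 0.0 <= self.gate_center < 1.0:
            raise ParameterError(f"gate_center must be in [0,1), got {self.gate_center}")
        if not 0.0 < self.gate_width <= 1.0:
            raise ParameterError(f"gate_width must be in (0,1], got {self.gate_width}")
        if self.gain < 0:
            raise ParameterError("gain must be >= 0")
        if self.delay < 0:
            raise ParameterError("delay must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.kernel is not None and not np.all(np.isfinite(self.kernel)):
            raise ParameterError("kernel must have finite energy")


@dataclass
class CouplingConfig:
    """Per-channel coupling settings for one simulated trial."""

    channels: Dict[str, ChannelCoupling] = field(default_factory=dict)

    def get(self, name: str) -> ChannelCoupling:
        return self.channels.get(name, ChannelCoupling())


def default_coupling(gain_scale: float = 1.0,
                     overrides: Optional[Dict[str, float]] = None) -> CouplingConfig:
    """Coupling defaults imitating phase- and muscle-specific responses.

    Gastrocnemius couples most strongly in late stance (push-off),
    gluteus medius before/around early stance (foot placement), erector
    spinae at heel strike (trunk control); the net mediolateral GRF
    channel carries a low-pass coupled component.  ``overrides`` maps a
    muscle base name (or ``grf_ml``) to a multiplicative gain factor.
    """
    overrides = overrides or {}
    base_gain = 0.04  # a.u. per mA against a 0.1 a.u. envelope peak
    spec = {
        "gastrocnemius_medialis": (0.45, 0.25),
        "gluteus_medius": (0.12, 0.25),
        "erector_spinae": (0.02, 0.2),
    }
    channels: Dict[str, ChannelCoupling] = {}
    for muscle, (center, width) in spec.items():
        factor = overrides.get(muscle, 1.0)
        for side in ("l", "r"):
            channels[f"{muscle}_{side}"] = ChannelCoupling(
                gate_center=center, gate_width=width,
                gain=base_gain * gain_scale * factor,
                delay=0.01, noise_sd=0.01,
            )
    channels["grf_ml"] = ChannelCoupling(
        gate_center=0.3, gate_width=0.5,
        gain=1.5 * gain_scale * overrides.get("grf_ml", 1.0),
        delay=0.01, kernel=grf_coupling_kernel(), noise_sd=0.5,
    )
    return CouplingConfig(channels=channels)


def condition_preset(name: str) -> tuple[CouplingConfig, dict]:
    """Simulator settings for the four study conditions.

    Returns a ``(CouplingConfig, simulate_trial keyword dict)`` pair.
    The presets encode the intended direction of each manipulation:
    external stabilization reduces trunk noise, step width and coupling
    gains; wide-base walking widens steps and reduces gains; narrow-base
    walking narrows steps, adds cross-stepping onto the opposite belt,
    and redistributes gains across muscles (trunk up, ankle down).
    """
    presets = {
        "normal": (default_coupling(1.0), dict(
            step_width_mean=0.27, step_width_sd=0.02, t6_noise_sd=0.08)),
        "stabilized": (default_coupling(0.4), dict(
            step_width_mean=0.09, step_width_sd=0.01, t6_noise_sd=0.03)),
        "wide": (default_coupling(0.6), dict(
            step_width_mean=0.35, step_width_sd=0.025, t6_noise_sd=0.09)),
        "narrow": (default_coupling(1.0, {"gastrocnemius_medialis": 0.6,
                                          "gluteus_medius": 1.0,
                                          "erector_spinae": 1.8,
                                          "grf_ml": 1.5}),
                   dict(step_width_mean=0.16, step_width_sd=0.015,
                        t6_noise_sd=0.05, cross_step_prob=0.25)),
    }
    if name not in presets:
        raise ParameterError(f"unknown condition {name!r}; choose from {sorted(presets)}")
    config, kwargs = presets[name]
    kwargs["condition"] = name
    return config, kwargs


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ForcePlate:
    """3-axis force (N) and moment (N m) signals of one treadmill belt.

    Axes: x = mediolateral (rightward positive), y = anterior-posterior
    (forward positive), z = vertical (upward positive).  Moments are
    about the plate origin, so the center of pressure follows from
    ``cop_x = -My/Fz``, ``cop_y = Mx/Fz``.
    """

    force: np.ndarray   # (n, 3)
    moment: np.ndarray  # (n, 3)
    rate: float = FORCE_RATE


@dataclass
class TrialTruth:
    """Ground truth stored alongside a simulated trial."""

    config: CouplingConfig
    heel_strikes_left: np.ndarray
    heel_strikes_right: np.ndarray
    toe_offs_left: np.ndarray
    toe_offs_right: np.ndarray
    step_width_times: np.ndarray
    step_width_feet: np.ndarray      # array of 'left'/'right'
    step_widths: np.ndarray          # m
    cop_left: Optional[np.ndarray] = None   # (n, 2), nan when unloaded
    cop_right: Optional[np.ndarray] = None
    cop_sum: Optional[np.ndarray] = None


@dataclass
class TrialRecording:
    """Synchronized multirate container for one walking condition."""

    evs: EVSSignal
    forces_left: ForcePlate
    forces_right: ForcePlate
    emg: Dict[str, np.ndarray]
    markers: Dict[str, np.ndarray]   # cluster name -> (n, 3) positions, m
    condition: str = "normal"
    stride_period: float = 120.0 / 78.0
    emg_rate: float = EMG_RATE
    marker_rate: float = MARKER_RATE
    truth: Optional[TrialTruth] = None

    @property
    def duration(self) -> float:
        return self.evs.duration


# ---------------------------------------------------------------------------
# phase machinery
# ---------------------------------------------------------------------------

def stride_phase(t: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Stride fraction in [0, 1) of each time relative to event times.

    Phase is 0 at each event and grows linearly to 1 at the next event.
    Outside the event span the phase clamps to the nearest edge.
    """
    events = np.asarray(events, dtype=float)
    if events.size < 2:
        raise InsufficientDataError("need at least 2 events to define a phase")
    if np.any(np.diff(events) <= 0):
        raise ParameterError("event times must be strictly increasing")
    idx = np.interp(t, events, np.arange(events.size, dtype=float))
    return np.mod(idx, 1.0)


def phase_gate(t: np.ndarray, events: np.ndarray, center: float,
               width: float) -> np.ndarray:
    """Raised-cosine stride-phase window, periodic with the stride.

    Equals 1 at ``center`` (a stride fraction), falls to 0 at
    ``center +- width/2`` and is 0 elsewhere.  Its integral over one
    stride of duration T is ``width/2 * T``.
    """
    phi = stride_phase(t, events)
    d = np.mod(phi - center + 0.5, 1.0) - 0.5
    out = np.zeros_like(d)
    inside = np.abs(d) < width / 2
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * d[inside] / width))
    return out


def _extended(events: np.ndarray) -> np.ndarray:
    """Pad an event series by one period on each side for clean phase."""
    first = events[0] - (events[1] - events[0])
    last = events[-1] + (events[-1] - events[-2])
    return np.concatenate([[first], events, [last]])


# ---------------------------------------------------------------------------
# trunk kinematics
# ---------------------------------------------------------------------------

def simulate_t6_series(n_strides: int, samples_per_stride: int,
                       noise_sd: float, seed: int, *,
                       contraction: float = 4.0,
                       amplitude: float = 1.0) -> np.ndarray:
    """Trunk velocity from a noise-driven stable limit-cycle oscillator.

    A radial Ornstein-Uhlenbeck amplitude (attracted to 1 at rate
    ``contraction`` per stride) and a diffusing phase drive
    ``v = A (r cos(theta) + 0.35 r cos(2 theta + 0.8))``, one stride per
    ``2 pi`` of phase.  With ``noise_sd = 0`` the orbit is exactly
    periodic, so the local divergence exponent is ~0; increasing
    ``noise_sd`` increases the divergence of neighboring trajectories.
    """
    if n_strides < 10:
        raise ParameterError(f"need n_strides >= 10, got {n_strides}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    n = int(n_strides) * int(samples_per_stride)
    dt = 1.0 / samples_per_stride          # time unit: strides
    rng = np.random.default_rng(seed)
    xi_r = rng.standard_normal(n)
    xi_th = rng.standard_normal(n)
    # r - 1 follows an AR(1): u[k] = (1 - contraction dt) u[k-1] + sigma sqrt(dt) xi
    a = 1.0 - contraction * dt
    u = _sig.lfilter([1.0], [1.0, -a], noise_sd * math.sqrt(dt) * xi_r)
    r = 1.0 + u
    # deterministic ramp built from the wrapped sample index so the
    # noise-free orbit is bitwise periodic (exactly repeating samples)
    theta = (2.0 * np.pi / samples_per_stride) * (np.arange(n) % samples_per_stride)
    if noise_sd > 0:
        theta = theta + np.cumsum(noise_sd * math.sqrt(dt) * xi_th)
    return amplitude * (r * np.cos(theta) + 0.35 * r * np.cos(2.0 * theta + 0.8))


# ---------------------------------------------------------------------------
# vertical force profile
# ---------------------------------------------------------------------------

def _stance_profile(s: np.ndarray) -> np.ndarray:
    """Normalized vertical force over stance fraction s in [0, 1].

    Double-bump shape (loading and push-off peaks near 22% and 78% of
    stance with a mid-stance valley), multiplied by fast onset/offset
    ramps so contact begins and ends with a high loading rate.
    """
    base = (0.4 * np.sin(np.pi * s)
            + 0.75 * (np.exp(-((s - 0.22) / 0.14) ** 2)
                      + np.exp(-((s - 0.78) / 0.14) ** 2)))
    ramp = np.clip(s / 0.01, 0.0, 1.0) * np.clip((1.0 - s) / 0.01, 0.0, 1.0)
    return base * ramp


# ---------------------------------------------------------------------------
# main simulator
# ---------------------------------------------------------------------------

def simulate_trial(
    evs: EVSSignal,
    config: CouplingConfig,
    n_strides: int,
    cadence: float = 78.0,
    step_width_mean: float = 0.27,
    step_width_sd: float = 0.02,
    t6_noise_sd: float = 0.08,
    seed: int = 0,
    *,
    stride_jitter_cv: float = 0.02,
    cross_step_prob: float = 0.0,
    stance_fraction: float = 0.6,
    body_weight: float = 700.0,
    belt_speed: float = 0.8,
    condition: str = "normal",
    channels: Optional[tuple[str, ...]] = None,
    keep_cop_truth: bool = True,
) -> TrialRecording:
    """Simulate one walking trial with known ground truth.

    Parameters
    ----------
    evs : EVSSignal
        The stimulus driving all coupled channels; must be sampled at
        the force-plate rate (200 samples/s) and long enough to cover
        ``n_strides`` strides plus a 2 s lead-in.
    config : CouplingConfig
        Per-channel gate/gain/kernel/noise settings.
    n_strides : int
        Number of complete strides to simulate (>= 2).
    cadence : float
        Metronome cadence in steps/min; the stride period is
        ``2 * 60 / cadence`` seconds (1.538 s at 78 steps/min).
    step_width_mean, step_width_sd : float
        Target step-width distribution in meters.
    t6_noise_sd : float
        Dynamical noise of the trunk oscillator (per-stride units);
        larger values yield a larger local divergence exponent.
    seed : int
        Global seed; fanned out into independent per-stream substreams.
    stride_jitter_cv : float
        Coefficient of variation of stride-period timing jitter.
    cross_step_prob : float
        Probability that a step lands across the belt midline (onto the
        opposite belt), as happens in narrow-base walking.
    channels : tuple of str, optional
        Subset of EMG channels to synthesize (default: all six).
    """
    if n_strides < 2:
        raise ParameterError(f"need n_strides >= 2, got {n_strides}")
    if cadence <= 0:
        raise ParameterError("cadence must be positive")
    if evs.rate != FORCE_RATE:
        raise ParameterError(
            f"evs must be sampled at {FORCE_RATE} samples/s, got {evs.rate}")

    stride_t = 2.0 * 60.0 / cadence
    t0 = 2.0
    needed = t0 + (n_strides + 1) * stride_t * (1 + 4 * stride_jitter_cv) + 0.5
    if evs.duration < needed:
        raise LengthError(
            f"evs covers {evs.duration:.1f} s but {needed:.1f} s are needed "
            f"for {n_strides} strides at {cadence} steps/min")

    ss = np.random.SeedSequence(seed)
    keys = ["events", "widths", "t6", "forces"] + list(channels or EMG_CHANNELS)
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    # --- gait events -------------------------------------------------------
    rng_ev = rngs["events"]
    periods = stride_t * (1.0 + stride_jitter_cv * rng_ev.standard_normal(n_strides + 1))
    periods = np.clip(periods, 0.7 * stride_t, 1.3 * stride_t)
    hs_l = t0 + np.concatenate([[0.0], np.cumsum(periods[:-1])])
    hs_r = hs_l + 0.5 * periods * (1.0 + 0.5 * stride_jitter_cv
                                   * rng_ev.standard_normal(n_strides + 1))
    to_l = hs_l + stance_fraction * periods
    to_r = hs_r + stance_fraction * periods

    # --- foot placements ---------------------------------------------------
    rng_w = rngs["widths"]
    strikes = sorted(
        [(t, "left", i) for i, t in enumerate(hs_l)]
        + [(t, "right", i) for i, t in enumerate(hs_r)])
    ml_land = {"left": np.empty(n_strides + 1), "right": np.empty(n_strides + 1)}
    cur = {"left": -step_width_mean / 2.0, "right": step_width_mean / 2.0}
    w_times, w_feet, w_vals = [], [], []
    for t_ev, foot, idx in strikes:
        other = "right" if foot == "left" else "left"
        sign = -1.0 if foot == "left" else 1.0
        if rng_w.random() < cross_step_prob:
            # landing crosses the midline onto the opposite belt
            ml = -sign * (0.02 + abs(0.01 * rng_w.standard_normal()))
        else:
            w = max(0.01, rng_w.normal(step_width_mean, step_width_sd))
            ml = sign * w / 2.0 + rng_w.normal(0.0, 0.005)
        ml_land[foot][idx] = ml
        cur[foot] = ml
        w_times.append(t_ev)
        w_feet.append(foot)
        w_vals.append(abs(cur[foot] - cur[other]))

    # --- time bases --------------------------------------------------------
    duration = evs.duration
    n_f = len(evs)
    t_f = np.arange(n_f) / FORCE_RATE
    n_e = int(round(duration * EMG_RATE))
    t_e = np.arange(n_e) / EMG_RATE
    n_m = int(round(duration * MARKER_RATE))
    t_m = np.arange(n_m) / MARKER_RATE

    # --- vertical forces and moments per belt ------------------------------
    rng_f = rngs["forces"]
    fz = {"left": np.zeros(n_f), "right": np.zeros(n_f)}
    mx = {"left": np.zeros(n_f), "right": np.zeros(n_f)}
    my = {"left": np.zeros(n_f), "right": np.zeros(n_f)}
    all_stances = (
        [(hs_l[i], to_l[i], ml_land["left"][i]) for i in range(n_strides + 1)]
        + [(hs_r[i], to_r[i], ml_land["right"][i]) for i in range(n_strides + 1)])
    for hs, to, ml in all_stances:
        belt = "left" if ml < 0 else "right"
        i0 = max(0, int(math.ceil(hs * FORCE_RATE)))
        i1 = min(n_f, int(math.floor(to * FORCE_RATE)) + 1)
        if i1 <= i0:
            continue
        s = (t_f[i0:i1] - hs) / (to - hs)
        f = body_weight * _stance_profile(s)
        ap = 0.3 - belt_speed * (t_f[i0:i1] - hs)
        fz[belt][i0:i1] += f
        my[belt][i0:i1] += -ml * f
        mx[belt][i0:i1] += ap * f

    cop = {}
    for belt in ("left", "right"):
        c = np.full((n_f, 2), np.nan)
        loaded = fz[belt] > 20.0
        c[loaded, 0] = -my[belt][loaded] / fz[belt][loaded]
        c[loaded, 1] = mx[belt][loaded] / fz[belt][loaded]
        cop[belt] = c
    fz_sum = fz["left"] + fz["right"]
    cop_sum = np.full((n_f, 2), np.nan)
    loaded = fz_sum > 20.0
    cop_sum[loaded, 0] = -(my["left"] + my["right"])[loaded] / fz_sum[loaded]
    cop_sum[loaded, 1] = (mx["left"] + mx["right"])[loaded] / fz_sum[loaded]

    # measurement noise on forces/moments (truth CoP kept noiseless);
    # moment noise of 0.3 N m gives the few-mm CoP resolution typical
    # of instrumented treadmills at stance loads
    for belt in ("left", "right"):
        fz[belt] = fz[belt] + rng_f.normal(0.0, 2.0, n_f)
        mx[belt] = mx[belt] + rng_f.normal(0.0, 0.3, n_f)
        my[belt] = my[belt] + rng_f.normal(0.0, 0.3, n_f)

    # --- mediolateral force: phasic baseline + gated coupled EVS -----------
    hs_l_ext = _extended(hs_l)
    hs_r_ext = _extended(hs_r)
    grf_cfg = config.get("grf_ml")
    k_grf = grf_cfg.kernel if grf_cfg.kernel is not None else grf_coupling_kernel()
    coupled_grf = _sig.fftconvolve(evs.samples, k_grf, mode="same")
    gate_grf = phase_gate(t_f, hs_l_ext, grf_cfg.gate_center, grf_cfg.gate_width)
    phi_l_f = stride_phase(t_f, hs_l_ext)
    fml_sum = (25.0 * np.sin(2.0 * np.pi * phi_l_f)
               + grf_cfg.gain * gate_grf
               * np.interp(t_f - grf_cfg.delay, t_f, coupled_grf))
    share = np.divide(fz["left"], fz_sum, out=np.full(n_f, 0.5),
                      where=fz_sum > 1.0)
    fml = {"left": fml_sum * share, "right": fml_sum * (1.0 - share)}
    for belt in ("left", "right"):
        fml[belt] = fml[belt] + rng_f.normal(0.0, grf_cfg.noise_sd / math.sqrt(2), n_f)

    plates = {}
    for belt in ("left", "right"):
        force = np.column_stack([fml[belt],
                                 rng_f.normal(0.0, 1.0, n_f),
                                 fz[belt]])
        moment = np.column_stack([mx[belt], my[belt], np.zeros(n_f)])
        plates[belt] = ForcePlate(force=force, moment=moment)

    # --- EMG ---------------------------------------------------------------
    k_emg_default = emg_coupling_kernel()
    emg: Dict[str, np.ndarray] = {}
    for name in (channels or EMG_CHANNELS):
        cfg = config.get(name)
        rng_c = rngs[name]
        events = hs_l_ext if name.endswith("_l") else hs_r_ext
        phi = stride_phase(t_e, events)
        base = 0.1 * _baseline_envelope(name, phi)
        slow = _sig.sosfiltfilt(_sig.butter(2, 2.0, fs=EMG_RATE, output="sos"),
                                rng_c.standard_normal(n_e))
        slow *= 0.2 / max(np.std(slow), 1e-12)
        kern = cfg.kernel if cfg.kernel is not None else k_emg_default
        coupled = _sig.fftconvolve(evs.samples, kern, mode="same")
        coupled_e = np.interp(t_e - cfg.delay, t_f, coupled)
        gate = phase_gate(t_e, events, cfg.gate_center, cfg.gate_width)
        x = (base * (1.0 + slow) + cfg.gain * gate * coupled_e
             + rng_c.normal(0.0, cfg.noise_sd, n_e))
        emg[name] = np.maximum(x, 0.0)

    # --- markers -----------------------------------------------------------
    markers: Dict[str, np.ndarray] = {}
    for foot, hs, to in (("left", hs_l, to_l), ("right", hs_r, to_r)):
        knot_t = np.empty(2 * (n_strides + 1))
        knot_ml = np.empty_like(knot_t)
        knot_ap = np.empty_like(knot_t)
        knot_t[0::2], knot_t[1::2] = hs, to
        knot_ml[0::2] = knot_ml[1::2] = ml_land[foot]
        knot_ap[0::2] = 0.3
        knot_ap[1::2] = 0.3 - belt_speed * (to - hs)
        ml_tr = np.interp(t_m, knot_t, knot_ml)
        ap_tr = np.interp(t_m, knot_t, knot_ap)
        markers[f"heel_{foot}"] = np.column_stack(
            [ml_tr, ap_tr, np.full(n_m, 0.03)])

    spp6 = int(round(stride_t * MARKER_RATE))
    n_cover = max(10, int(math.ceil(n_m / spp6)) + 2)
    v6 = 0.05 * simulate_t6_series(n_cover, spp6, t6_noise_sd,
                                   seed=rngs["t6"].integers(2**31))
    pos6 = np.cumsum(v6[:n_m]) / MARKER_RATE
    markers["t6"] = np.column_stack(
        [pos6, np.full(n_m, -0.1), np.full(n_m, 1.40)])
    markers["pelvis"] = np.column_stack(
        [0.8 * pos6, np.full(n_m, -0.15), np.full(n_m, 1.0)])

    truth = TrialTruth(
        config=config,
        heel_strikes_left=hs_l, heel_strikes_right=hs_r,
        toe_offs_left=to_l, toe_offs_right=to_r,
        step_width_times=np.asarray(w_times),
        step_width_feet=np.asarray(w_feet),
        step_widths=np.asarray(w_vals),
        cop_left=cop["left"] if keep_cop_truth else None,
        cop_right=cop["right"] if keep_cop_truth else None,
        cop_sum=cop_sum if keep_cop_truth else None,
    )
    return TrialRecording(
        evs=evs, forces_left=plates["left"], forces_right=plates["right"],
        emg=emg, markers=markers, condition=condition,
        stride_period=stride_t, truth=truth,
    )


def _baseline_envelope(name: str, phi: np.ndarray) -> np.ndarray:
    """Phasic EMG baseline envelope as a function of own-limb stride phase.

    Shapes imitate the qualitative activity patterns of the three
    muscles during treadmill walking: a late-stance gastrocnemius burst,
    an early-stance gluteus medius burst, and a bimodal erector spinae
    pattern with bursts around both heel strikes.
    """
    def bump(c, w):
        d = np.mod(phi - c + 0.5, 1.0) - 0.5
        return np.exp(-(d / w) ** 2)

    if name.startswith("gastrocnemius"):
        env = 0.15 + bump(0.45, 0.10)
    elif name.startswith("gluteus"):
        env = 0.15 + bump(0.12, 0.10)
    elif name.startswith("erector"):
        env = 0.2 + 0.8 * bump(0.02, 0.06) + 0.8 * bump(0.52, 0.06)
    else:
        env = np.ones_like(phi)
    return env
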