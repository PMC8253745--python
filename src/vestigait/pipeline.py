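"""End-to-end study orchestration and trial I/O.

``run_pipeline`` simulates (or loads) the four walking conditions for a
cohort of synthetic subjects, extracts gait events, computes stride
times, step widths, EMG envelopes, stride-synchronized EVS-EMG and
EVS-GRF coherence maps and the local divergence exponent, and compares
conditions with repeated-measures ANOVA and cluster-based permutation
tests.  Every artifact carries provenance (config echo, seed, content
hash) and the run is deterministic for a fixed configuration.

Trials interchange as one directory per trial: per-stream CSV files
plus a JSON sidecar holding rates, condition, seed and (for synthetic
data) the ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import coherence as coh
from . import gait_events as ge
from . import signal_prep as sp
from . import stability as st
from . import stats as vstats
from . import synthetic_gait as sg
from .errors import InsufficientDataError, ValidationError
from .stimulus import EVSSignal, generate_evs, read_evs, write_evs

__all__ = ["StudyConfig", "run_pipeline", "analyze_trial", "save_trial",
           "load_recording", "write_tfmap", "read_tfmap"]

log = logging.getLogger("vestigait")

MUSCLES = ("gastrocnemius_medialis", "gluteus_medius", "erector_spinae")


@dataclass
class StudyConfig:
    """All knobs of a full study run."""

    conditions: Sequence[str] = ("normal", "stabilized", "wide", "narrow")
    n_subjects: int = 11
    n_strides: int = 256
    seed: int = 0
    freq_lo: float = 0.5
    freq_hi: float = 25.0
    freq_step: float = 0.25
    omega0: float = 6.0
    pad_fraction: float = 0.5
    coherence_alpha: float = 0.01
    n_permutations: int = 5000
    cluster_alpha: float = 0.05
    lde_dim: int = 5
    lde_delay: int = 10
    lde_samples_per_stride: int = 100
    lde_theiler: Optional[int] = None

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 1e-9, self.freq_step)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# trial I/O
# ---------------------------------------------------------------------------

_FMT = "%.17g"  # round-trips float64 exactly


def save_trial(rec: sg.TrialRecording, path: str | Path) -> None:
    """Write a trial as per-stream CSVs plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_evs(rec.evs, path / "evs.csv")
    for belt in ("left", "right"):
        plate: sg.ForcePlate = getattr(rec, f"forces_{belt}")
        arr = np.hstack([plate.force, plate.moment])
        np.savetxt(path / f"forces_{belt}.csv", arr, fmt=_FMT, delimiter=",",
                   header="fx,fy,fz,mx,my,mz", comments="")
    emg_names = sorted(rec.emg)
    if emg_names:
        arr = np.column_stack([rec.emg[n] for n in emg_names])
        np.savetxt(path / "emg.csv", arr, fmt=_FMT, delimiter=",",
                   header=",".join(emg_names), comments="")
    marker_names = sorted(rec.markers)
    cols = [f"{n}_{ax}" for n in marker_names for ax in "xyz"]
    arr = np.hstack([rec.markers[n] for n in marker_names])
    np.savetxt(path / "markers.csv", arr, fmt=_FMT, delimiter=",",
               header=",".join(cols), comments="")
    sidecar = {
        "condition": rec.condition,
        "stride_period": rec.stride_period,
        "rates": {"force": rec.forces_left.rate, "emg": rec.emg_rate,
                  "marker": rec.marker_rate, "evs": rec.evs.rate},
        "emg_channels": emg_names,
        "marker_clusters": marker_names,
    }
    if rec.truth is not None:
        tr = rec.truth
        sidecar["truth"] = {
            "heel_strikes_left": tr.heel_strikes_left.tolist(),
            "heel_strikes_right": tr.heel_strikes_right.tolist(),
            "toe_offs_left": tr.toe_offs_left.tolist(),
            "toe_offs_right": tr.toe_offs_right.tolist(),
            "step_width_times": tr.step_width_times.tolist(),
            "step_width_feet": tr.step_width_feet.tolist(),
            "step_widths": tr.step_widths.tolist(),
            "config": {
                name: {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in dataclasses.asdict(c).items()}
                for name, c in tr.config.channels.items()
            },
        }
    (path / "trial.json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path: str | Path) -> sg.TrialRecording:
    """Load a trial directory, validating streams against the sidecar."""
    path = Path(path)
    problems = []
    sidecar_path = path / "trial.json"
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    rates = meta["rates"]
    for fname in ("evs.csv", "forces_left.csv", "forces_right.csv",
                  "markers.csv"):
        if not (path / fname).exists():
            problems.append(f"missing stream file {fname}")
    if problems:
        raise ValidationError("; ".join(problems))

    evs = read_evs(path / "evs.csv")
    duration = evs.duration
    if evs.rate != rates["evs"]:
        problems.append(f"evs rate {evs.rate} != sidecar {rates['evs']}")

    plates = {}
    for belt in ("left", "right"):
        arr = np.loadtxt(path / f"forces_{belt}.csv", delimiter=",",
                         skiprows=1, ndmin=2)
        plates[belt] = sg.ForcePlate(force=arr[:, :3], moment=arr[:, 3:6],
                                     rate=rates["force"])
        expected = round(duration * rates["force"])
        if abs(arr.shape[0] - expected) > 1:
            problems.append(
                f"forces_{belt} has {arr.shape[0]} samples, expected "
                f"~{expected} at {rates['force']} samples/s")

    emg: Dict[str, np.ndarray] = {}
    if (path / "emg.csv").exists() and meta.get("emg_channels"):
        arr = np.loadtxt(path / "emg.csv", delimiter=",", skiprows=1, ndmin=2)
        for i, name in enumerate(meta["emg_channels"]):
            emg[name] = arr[:, i]
        expected = round(duration * rates["emg"])
        if abs(arr.shape[0] - expected) > 1:
            problems.append(
                f"emg has {arr.shape[0]} samples, expected ~{expected}")

    arr = np.loadtxt(path / "markers.csv", delimiter=",", skiprows=1, ndmin=2)
    markers = {name: arr[:, 3 * i: 3 * i + 3]
               for i, name in enumerate(meta["marker_clusters"])}
    expected = round(duration * rates["marker"])
    if abs(arr.shape[0] - expected) > 1:
        problems.append(f"markers have {arr.shape[0]} samples, expected "
                        f"~{expected}")
    if problems:
        raise ValidationError("; ".join(problems))

    truth = None
    if "truth" in meta:
        tr = meta["truth"]
        channels = {
            name: sg.ChannelCoupling(
                gate_center=c["gate_center"], gate_width=c["gate_width"],
                gain=c["gain"], delay=c["delay"],
                kernel=None if c["kernel"] is None else np.asarray(c["kernel"]),
                noise_sd=c["noise_sd"])
            for name, c in tr["config"].items()}
        truth = sg.TrialTruth(
            config=sg.CouplingConfig(channels=channels),
            heel_strikes_left=np.asarray(tr["heel_strikes_left"]),
            heel_strikes_right=np.asarray(tr["heel_strikes_right"]),
            toe_offs_left=np.asarray(tr["toe_offs_left"]),
            toe_offs_right=np.asarray(tr["toe_offs_right"]),
            step_width_times=np.asarray(tr["step_width_times"]),
            step_width_feet=np.asarray(tr["step_width_feet"]),
            step_widths=np.asarray(tr["step_widths"]))
    return sg.TrialRecording(
        evs=evs, forces_left=plates["left"], forces_right=plates["right"],
        emg=emg, markers=markers, condition=meta["condition"],
        stride_period=meta["stride_period"], emg_rate=rates["emg"],
        marker_rate=rates["marker"], truth=truth)


def write_tfmap(tf: coh.TFMap, path: str | Path) -> None:
    """Write a time-frequency map as long-format CSV + JSON metadata."""
    path = Path(path)
    df = pd.DataFrame({
        "tau_pct": np.repeat(tf.tau, tf.freqs.size),
        "freq_hz": np.tile(tf.freqs, tf.tau.size),
        "value": tf.values.T.ravel(),
        "defined": tf.defined.T.ravel().astype(int),
    })
    df.to_csv(path, index=False)
    meta = {"kind": tf.kind, "n_strides": tf.n_strides,
            "threshold": tf.threshold}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_tfmap(path: str | Path) -> coh.TFMap:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    tau = np.unique(df["tau_pct"].to_numpy())
    freqs = np.unique(df["freq_hz"].to_numpy())
    values = df["value"].to_numpy().reshape(tau.size, freqs.size).T
    defined = df["defined"].to_numpy().reshape(tau.size, freqs.size).T.astype(bool)
    return coh.TFMap(values=values, kind=meta["kind"], tau=tau, freqs=freqs,
                     n_strides=meta["n_strides"],
                     threshold=meta["threshold"], defined=defined)


# ---------------------------------------------------------------------------
# per-trial analysis
# ---------------------------------------------------------------------------

def analyze_trial(rec: sg.TrialRecording, config: StudyConfig) -> dict:
    """Run the full single-trial analysis chain.

    Returns a dict with gait events, stride times, step widths, EMG
    envelopes (unnormalized), pooled EVS-EMG coherence maps per muscle,
    the EVS-GRF coherence map and the local divergence exponent.
    """
    events = ge.detect_heel_strikes(rec)
    n_avail = min(events.n_strides_left, events.n_strides_right)
    if n_avail < config.n_strides:
        raise InsufficientDataError(
            f"trial provides {n_avail} complete strides but the analysis "
            f"requires {config.n_strides} (short by {config.n_strides - n_avail})")
    log.info("events: %d/%d strides (method=%s)",
             events.n_strides_left, events.n_strides_right, events.method)

    stride_times = ge.compute_stride_times(events)
    widths = ge.compute_step_widths(events, rec.markers, rec.marker_rate)
    freqs = config.freqs

    evs_p = sp.prep_for_coherence(rec.evs.samples, rec.evs.rate, kind="evs")

    strikes = {"l": events.heel_strikes_left[: config.n_strides + 1],
               "r": events.heel_strikes_right[: config.n_strides + 1]}
    x_segs = {side: sp.segment_strides(evs_p, sg.FORCE_RATE, strikes[side],
                                       config.pad_fraction)
              for side in ("l", "r")}
    threshold = coh.significance_threshold(config.n_strides,
                                           config.coherence_alpha)
    # common duration-normalized grid (nominal stride length) so left/
    # right limbs, channels and subjects can be pooled and compared
    target_core = int(round(rec.stride_period * sg.FORCE_RATE))

    envelopes: Dict[str, np.ndarray] = {}
    coh_maps: Dict[str, coh.TFMap] = {}
    for muscle in MUSCLES:
        per_side = []
        for side in ("l", "r"):
            name = f"{muscle}_{side}"
            if name not in rec.emg:
                continue
            envelopes[name] = sp.emg_envelope(
                rec.emg[name], rec.emg_rate, strikes[side], config.n_strides)
            y = sp.prep_for_coherence(rec.emg[name], rec.emg_rate, kind="emg")
            y_segs = sp.segment_strides(y, sg.FORCE_RATE, strikes[side],
                                        config.pad_fraction)
            spectra = coh.stride_averaged_spectra(x_segs[side], y_segs,
                                                  freqs, config.omega0,
                                                  target_core=target_core)
            per_side.append(coh.coherence_map(spectra))
        if per_side:
            pooled = coh.average_maps(per_side)
            pooled.threshold = threshold
            coh_maps[muscle] = pooled

    # net mediolateral GRF: both belts summed before conditioning
    ml_sum = rec.forces_left.force[:, 0] + rec.forces_right.force[:, 0]
    grf_p = sp.prep_for_coherence(ml_sum, rec.forces_left.rate, kind="grf")
    grf_segs = sp.segment_strides(grf_p, sg.FORCE_RATE, strikes["l"],
                                  config.pad_fraction)
    spectra = coh.stride_averaged_spectra(x_segs["l"], grf_segs, freqs,
                                          config.omega0,
                                          target_core=target_core)
    grf_map = coh.coherence_map(spectra)
    grf_map.threshold = threshold
    coh_maps["grf_ml"] = grf_map

    # local dynamic stability from T6 mediolateral velocity
    t6_ml = rec.markers["t6"][:, 0]
    vel = st.three_point_velocity(t6_ml, rec.marker_rate)
    fixed = st.resample_strides(vel, rec.marker_rate,
                                events.heel_strikes_left,
                                n_strides=config.n_strides,
                                samples_per_stride=config.lde_samples_per_stride)
    curve = st.rosenstein_divergence(
        fixed, config.lde_samples_per_stride, dim=config.lde_dim,
        delay=config.lde_delay, theiler=config.lde_theiler)
    lde = st.lde_slope(curve)

    return {"events": events, "stride_times": stride_times,
            "step_widths": widths, "envelopes": envelopes,
            "coherence": coh_maps, "lde": lde, "divergence_curve": curve,
            "threshold": threshold}


# ---------------------------------------------------------------------------
# study pipeline
# ---------------------------------------------------------------------------

def _subject_seed(base: int, subject: int, cond_idx: int) -> int:
    ss = np.random.SeedSequence([base, subject, cond_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_condition_trial(config: StudyConfig, condition: str,
                             subject: int) -> sg.TrialRecording:
    """Simulate one subject's trial in one condition (seed fan-out)."""
    ci = ("normal", "stabilized", "wide", "narrow").index(condition)
    seed = _subject_seed(config.seed, subject, ci)
    cpl, kwargs = sg.condition_preset(condition)
    stride_t = 120.0 / 78.0
    duration = 2.0 + (config.n_strides + 2) * stride_t * 1.1 + 1.0
    evs = generate_evs(duration, rate=sg.FORCE_RATE, seed=seed)
    return sg.simulate_trial(evs, cpl, n_strides=config.n_strides,
                             seed=seed + 1, **kwargs)


def run_pipeline(config: StudyConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic study and write its report.

    Produces, per condition: group-mean coherence maps for the net GRF
    and each muscle; across conditions: a gait-parameter table (stride
    time, step width, LDE per subject), repeated-measures ANOVAs with
    planned comparisons against normal walking, and cluster-based
    permutation tests of each modified condition's coherence against
    normal.  A manifest records the configuration, seed and a content
    hash so reruns can be verified bit-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = list(config.conditions)
    rows = []
    maps: Dict[str, Dict[str, list]] = {c: {} for c in conditions}

    for subject in range(config.n_subjects):
        for cond in conditions:
            log.info("subject %d condition %s", subject, cond)
            rec = simulate_condition_trial(config, cond, subject)
            res = analyze_trial(rec, config)
            rows.append({
                "subject": subject, "condition": cond,
                "stride_time_mean_s": res["stride_times"]["mean"],
                "stride_time_sd_s": res["stride_times"]["sd"],
                "step_width_mean_m": float(np.nanmean(
                    res["step_widths"]["width_m"])),
                "lde_per_stride": res["lde"],
            })
            for ch, tf in res["coherence"].items():
                maps[cond].setdefault(ch, []).append(tf)

    params = pd.DataFrame(rows)
    params.to_csv(out / "gait_parameters.csv", index=False)

    anovas = {}
    for metric in ("stride_time_mean_s", "step_width_mean_m", "lde_per_stride"):
        table = params.pivot(index="subject", columns="condition",
                             values=metric)[conditions].to_numpy()
        k = len(conditions)
        res = vstats.rm_anova_planned(
            table, planned_contrasts=[(0, j) for j in range(1, k)],
            condition_names=conditions)
        anovas[metric] = {
            "F": res.F, "df": list(res.df), "p": res.p_value,
            "eta_squared": res.eta_squared,
            "partial_eta_squared": res.partial_eta_squared,
            "pairwise": [dataclasses.asdict(p) for p in res.pairwise],
        }
    (out / "anova.json").write_text(json.dumps(anovas, indent=1))

    channels = sorted({ch for c in conditions for ch in maps[c]})
    for cond in conditions:
        for ch in channels:
            if ch in maps[cond]:
                mean_map = coh.average_maps(maps[cond][ch])
                write_tfmap(mean_map, out / f"coherence_{cond}_{ch}.csv")

    cluster_report = {}
    if "normal" in conditions:
        for cond in conditions:
            if cond == "normal":
                continue
            for ch in channels:
                if ch not in maps["normal"] or ch not in maps[cond]:
                    continue
                a = np.stack([m.values for m in maps["normal"][ch]])
                b = np.stack([m.values for m in maps[cond][ch]])
                res = vstats.cluster_permutation_test(
                    a, b, n_permutations=config.n_permutations,
                    cluster_alpha=config.cluster_alpha, seed=config.seed)
                cluster_report[f"normal_vs_{cond}:{ch}"] = [
                    {"sign": c.sign, "mass": c.mass, "p": c.p_value,
                     "size": c.size} for c in res.clusters]
        (out / "clusters.json").write_text(json.dumps(cluster_report, indent=1))

    payload = {"gait_parameters": rows, "anova": anovas,
               "clusters": cluster_report}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    manifest = {"config": json.loads(config.to_json()), "seed": config.seed,
                "content_sha256": digest}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"gait_parameters": params, "anova": anovas,
            "clusters": cluster_report, "manifest": manifest}
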