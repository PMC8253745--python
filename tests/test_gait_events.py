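"""Gait events: CoP arithmetic, detection accuracy, stride/width metrics."""

import numpy as np
import pytest

import vestigait as vg
from vestigait import gait_events as ge
from vestigait import synthetic_gait as sg
from vestigait.errors import NoContactError, ValidationError


class TestCoP:
    def test_point_load(self):
        fz = np.full(10, 700.0)
        # moments of a point load at (0.1, -0.05): Mx = y*Fz, My = -x*Fz
        mx = -0.05 * fz
        my = -0.1 * fz
        cop = ge.compute_cop(fz, mx, my)
        assert np.allclose(cop[:, 0], 0.1)
        assert np.allclose(cop[:, 1], -0.05)

    def test_two_symmetric_loads_cancel(self):
        fz = np.full(5, 350.0)
        my = -0.1 * fz + 0.1 * fz   # loads at x = +-0.1 m
        cop = ge.compute_cop(2 * fz, np.zeros(5), my)
        assert np.allclose(cop[:, 0], 0.0)

    def test_unloaded_samples_flagged_nan(self):
        fz = np.array([0.0, 700.0, 5.0])
        cop = ge.compute_cop(fz, np.zeros(3), np.zeros(3))
        assert np.isnan(cop[0, 0]) and np.isnan(cop[2, 0])
        assert np.isfinite(cop[1, 0])

    def test_never_loaded_raises(self):
        with pytest.raises(NoContactError):
            ge.compute_cop(np.full(10, 1.0), np.zeros(10), np.zeros(10))

    def test_cop_matches_simulator_truth_within_5mm(self, normal_trial):
        plate = normal_trial.forces_left
        cop = ge.compute_cop(plate.force[:, 2], plate.moment[:, 0],
                             plate.moment[:, 1])
        truth = normal_trial.truth.cop_left
        both = np.isfinite(cop[:, 0]) & np.isfinite(truth[:, 0])
        rmse = np.sqrt(np.nanmean((cop[both] - truth[both]) ** 2))
        assert rmse < 0.005


class TestDetection:
    def test_clean_trial_strikes_within_10ms(self, normal_trial):
        ev = ge.detect_heel_strikes(normal_trial)
        assert ev.method == "per_belt"
        for side in ("left", "right"):
            det = getattr(ev, f"heel_strikes_{side}")
            true = getattr(normal_trial.truth, f"heel_strikes_{side}")
            errs = [np.min(np.abs(det - t)) for t in true]
            assert np.max(errs) < 0.010

    def test_standing_load_yields_empty_events(self):
        evs = vg.generate_evs(10.0, seed=0)
        n = len(evs)
        const = sg.ForcePlate(
            force=np.column_stack([np.zeros(n), np.zeros(n),
                                   np.full(n, 700.0)]),
            moment=np.zeros((n, 3)))
        rec = sg.TrialRecording(evs=evs, forces_left=const,
                                forces_right=const, emg={}, markers={})
        ev = ge.detect_heel_strikes(rec)
        assert ev.heel_strikes_left.size == 0
        assert ev.heel_strikes_right.size == 0

    def test_cross_stepping_falls_back_to_cop(self, narrow_trial):
        """Summed-CoP fallback recovers >= 95% of strikes within 20 ms."""
        ev = ge.detect_heel_strikes(narrow_trial)
        assert ev.method == "cop_fallback"
        det = np.sort(np.concatenate([ev.heel_strikes_left,
                                      ev.heel_strikes_right]))
        true = np.sort(np.concatenate([
            narrow_trial.truth.heel_strikes_left,
            narrow_trial.truth.heel_strikes_right]))
        hits = np.array([np.min(np.abs(det - t)) for t in true])
        assert np.mean(hits < 0.020) >= 0.95

    def test_interleaving_violation_raises_not_reorders(self):
        with pytest.raises(ValidationError):
            ge.GaitEvents(np.array([0.0, 1.0]),
                          np.array([0.5, 0.4])).check_alternation()
        ev = ge.GaitEvents(np.array([0.0, 1.0, 2.0]),
                           np.array([0.5, 0.7, 2.5]))
        with pytest.raises(ValidationError):
            ev.check_alternation()


class TestStrideTimes:
    def test_first_differences(self):
        ev = ge.GaitEvents(np.array([0.0, 1.5, 3.0]),
                           np.array([0.75, 2.25, 3.75]))
        st = ge.compute_stride_times(ev)
        assert np.allclose(st["left"], [1.5, 1.5])

    def test_single_strike_warns_empty(self):
        ev = ge.GaitEvents(np.array([0.0]), np.array([0.5, 2.0, 3.5]))
        with pytest.warns(UserWarning):
            st = ge.compute_stride_times(ev)
        assert st["left"].size == 0

    def test_metronome_cadence_recovered(self, normal_trial):
        """78 steps/min -> mean stride time 60/78*2 ~ 1.538 s."""
        ev = ge.detect_heel_strikes(normal_trial)
        st = ge.compute_stride_times(ev)
        assert st["mean"] == pytest.approx(120.0 / 78.0, rel=0.01)


class TestStepWidths:
    def _events_markers(self, ml_left, ml_right):
        n = 200
        markers = {
            "heel_left": np.column_stack([np.full(n, ml_left),
                                          np.zeros(n), np.zeros(n)]),
            "heel_right": np.column_stack([np.full(n, ml_right),
                                           np.zeros(n), np.zeros(n)])}
        ev = ge.GaitEvents(np.array([0.2, 1.0]), np.array([0.6, 1.4]))
        return ev, markers

    def test_simple_width(self):
        ev, markers = self._events_markers(-0.06, 0.06)
        df = ge.compute_step_widths(ev, markers, 100.0)
        assert np.allclose(df["width_m"], 0.12)

    def test_degenerate_same_position(self):
        ev, markers = self._events_markers(0.03, 0.03)
        df = ge.compute_step_widths(ev, markers, 100.0)
        assert np.allclose(df["width_m"], 0.0)

    def test_dropout_flags_missing(self):
        ev, markers = self._events_markers(-0.06, 0.06)
        markers["heel_left"][:, 0] = np.nan
        df = ge.compute_step_widths(ev, markers, 100.0)
        assert df["width_m"].isna().all()

    def test_monte_carlo_mean_width(self):
        evs = vg.generate_evs(440.0, seed=8)
        rec = sg.simulate_trial(evs, sg.default_coupling(), n_strides=256,
                                seed=21, step_width_mean=0.18,
                                step_width_sd=0.02, channels=())
        ev = ge.detect_heel_strikes(rec)
        df = ge.compute_step_widths(ev, rec.markers, rec.marker_rate)
        assert abs(np.nanmean(df["width_m"]) - 0.18) < 0.005
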