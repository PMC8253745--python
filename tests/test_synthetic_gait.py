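"""Simulator: phase gates, stream consistency and injected ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import signal as sig

import vestigait as vg
from vestigait import synthetic_gait as sg
from vestigait.errors import InsufficientDataError, LengthError, ParameterError


class TestPhaseGate:
    events = np.array([0.0, 1.5, 3.0, 4.5])

    def test_unity_at_center(self):
        # phase 0.5 of the second stride
        assert sg.phase_gate(np.array([2.25]), self.events, 0.5, 0.2)[0] \
            == pytest.approx(1.0)

    def test_zero_opposite_the_gate(self):
        assert sg.phase_gate(np.array([1.5]), self.events, 0.5, 0.2)[0] == 0.0

    def test_integral_over_one_stride(self):
        # closed form: integral of the raised cosine = width/2 * T
        t = np.linspace(1.5, 3.0, 20001)
        for width in (0.2, 0.5, 1.0):
            g = sg.phase_gate(t, self.events, 0.4, width)
            integral = np.trapezoid(g, t)
            assert integral == pytest.approx(width / 2 * 1.5, rel=1e-3)

    def test_too_few_events(self):
        with pytest.raises(InsufficientDataError):
            sg.phase_gate(np.array([0.5]), np.array([1.0]), 0.5, 0.2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(center=hst.floats(0.0, 0.999), width=hst.floats(0.01, 1.0),
           t=hst.floats(0.0, 4.5))
    def test_gate_bounded_in_unit_interval(self, center, width, t):
        g = sg.phase_gate(np.array([t]), self.events, center, width)[0]
        assert 0.0 <= g <= 1.0


class TestTrialStreams:
    def test_stream_lengths_match_rates(self, normal_trial):
        dur = normal_trial.duration
        assert normal_trial.forces_left.force.shape[0] == round(dur * 200)
        for ch in normal_trial.emg.values():
            assert ch.size == round(dur * 2000)
        for m in normal_trial.markers.values():
            assert m.shape[0] == round(dur * 100)

    def test_vertical_forces_nonnegative_when_loaded(self, normal_trial):
        # noise floor aside, belt loads never go meaningfully negative
        for plate in (normal_trial.forces_left, normal_trial.forces_right):
            assert plate.force[:, 2].min() > -15.0

    def test_emg_nonnegative(self, normal_trial):
        for ch in normal_trial.emg.values():
            assert ch.min() >= 0.0

    def test_same_seed_identical_trial(self):
        evs = vg.generate_evs(20.0, seed=3)
        cfg = sg.default_coupling()
        a = sg.simulate_trial(evs, cfg, n_strides=8, seed=9)
        b = sg.simulate_trial(evs, cfg, n_strides=8, seed=9)
        assert np.array_equal(a.forces_left.force, b.forces_left.force)
        for k in a.emg:
            assert np.array_equal(a.emg[k], b.emg[k])
        for k in a.markers:
            assert np.array_equal(a.markers[k], b.markers[k])

    def test_evs_too_short_raises(self):
        evs = vg.generate_evs(5.0, seed=0)
        with pytest.raises(LengthError):
            sg.simulate_trial(evs, sg.default_coupling(), n_strides=64)

    def test_step_width_mean_converges(self):
        evs = vg.generate_evs(440.0, seed=4)
        cfg = sg.default_coupling()
        rec = sg.simulate_trial(evs, cfg, n_strides=256, seed=11,
                                step_width_mean=0.18, step_width_sd=0.02,
                                channels=())
        widths = rec.truth.step_widths[2:]
        assert abs(widths.mean() - 0.18) < 0.005

    def test_regressing_emg_on_gated_evs_recovers_gain(self):
        """At high SNR the injected coupling gain is identified within 10%."""
        evs = vg.generate_evs(120.0, seed=5)
        gain = 0.02
        cfg = sg.CouplingConfig({"erector_spinae_l": sg.ChannelCoupling(
            gate_center=0.5, gate_width=0.3, gain=gain, delay=0.0,
            noise_sd=0.0)})
        rec = sg.simulate_trial(evs, cfg, n_strides=64, seed=6,
                                channels=("erector_spinae_l",),
                                stride_jitter_cv=0.0)
        t_e = np.arange(rec.emg["erector_spinae_l"].size) / 2000.0
        t_f = np.arange(len(evs)) / 200.0
        kern = sg.emg_coupling_kernel()
        coupled = np.interp(t_e, t_f, sig.fftconvolve(evs.samples, kern,
                                                      mode="same"))
        hs = np.concatenate([
            rec.truth.heel_strikes_left,
            [2 * rec.truth.heel_strikes_left[-1]
             - rec.truth.heel_strikes_left[-2]]])
        gate = sg.phase_gate(t_e, hs, 0.5, 0.3)
        x = gate * coupled
        y = rec.emg["erector_spinae_l"]
        mask = gate > 0.2
        beta = np.polyfit(x[mask], y[mask], 1)[0]
        assert abs(beta - gain) / gain < 0.10


class TestT6Series:
    def test_output_length(self):
        v = sg.simulate_t6_series(12, 80, 0.05, seed=0)
        assert v.size == 12 * 80

    def test_zero_noise_is_exactly_periodic(self):
        v = sg.simulate_t6_series(12, 100, 0.0, seed=0)
        assert np.array_equal(v[100:], v[:-100])

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            sg.simulate_t6_series(12, 100, -0.1, seed=0)

    def test_too_few_strides_rejected(self):
        with pytest.raises(ParameterError):
            sg.simulate_t6_series(5, 100, 0.1, seed=0)


def test_condition_presets_cover_study_conditions():
    for name in ("normal", "stabilized", "wide", "narrow"):
        config, kwargs = sg.condition_preset(name)
        assert "grf_ml" in config.channels
        assert kwargs["condition"] == name
    _, normal = sg.condition_preset("normal")
    _, wide = sg.condition_preset("wide")
    _, narrow = sg.condition_preset("narrow")
    assert wide["step_width_mean"] - normal["step_width_mean"] \
        == pytest.approx(0.08)
    assert normal["step_width_mean"] - narrow["step_width_mean"] \
        == pytest.approx(0.11)
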