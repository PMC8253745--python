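"""Wavelet transform and coherence/gain estimators."""

import numpy as np
import pytest
from scipy import signal as sig

from vestigait import coherence as coh
from vestigait import signal_prep as sp
from vestigait.errors import ParameterError, ValidationError

RATE = 200.0


def _strikes(n_strides=64, stride_s=1.5, t0=2.0):
    return t0 + stride_s * np.arange(n_strides + 1)


def _maps(x, y, n_strides=64):
    strikes = _strikes(n_strides)
    xs = sp.segment_strides(x, RATE, strikes)
    ys = sp.segment_strides(y, RATE, strikes)
    s = coh.stride_averaged_spectra(xs, ys)
    return s, coh.coherence_map(s), coh.gain_map(s)


@pytest.fixture(scope="module")
def white_x():
    n = int((2.0 + 1.5 * 67) * RATE)
    return np.random.default_rng(0).standard_normal(n)


class TestMorletCWT:
    def test_sinusoid_ridge_at_its_frequency(self):
        t = np.arange(4000) / RATE
        x = np.sin(2 * np.pi * 8.0 * t)
        freqs = np.arange(2.0, 20.1, 1.0)
        W = coh.morlet_cwt(x, RATE, freqs)
        power = np.abs(W[:, 500:-500]).mean(axis=1)
        assert freqs[np.argmax(power)] == 8.0
        ridge = np.abs(W[np.argmax(power), 500:-500])
        assert ridge.std() / ridge.mean() < 0.01  # flat away from edges

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 1000))
        freqs = [2.0, 5.0, 10.0]
        Wx = coh.morlet_cwt(x, RATE, freqs)
        Wy = coh.morlet_cwt(y, RATE, freqs)
        Wxy = coh.morlet_cwt(x + y, RATE, freqs)
        assert np.allclose(Wxy, Wx + Wy, atol=1e-10)

    def test_impulse_reproduces_wavelet(self):
        """A unit impulse yields the conjugated time-reversed wavelet."""
        n, j = 800, 400
        x = np.zeros(n)
        x[j] = 1.0
        f0, w0 = 5.0, 6.0
        W = coh.morlet_cwt(x, RATE, [f0], omega0=w0)
        s = w0 / (2 * np.pi * f0)
        t = (np.arange(n) - j) / RATE
        expect = ((np.pi ** -0.25) * np.exp(1j * w0 * t / s)
                  * np.exp(-(t / s) ** 2 / 2) / (np.sqrt(s) * RATE))
        assert np.max(np.abs(W[0] - expect)) < 1e-7

    def test_frequencies_beyond_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            coh.morlet_cwt(np.zeros(100), RATE, [150.0])


class TestSpectraAndMaps:
    def test_identity_signal_gives_unit_coherence(self, white_x):
        s, C, G = _maps(white_x, white_x.copy())
        assert np.allclose(s.pxy, s.pxx)
        assert np.nanmin(C.values) == pytest.approx(1.0, abs=1e-9)

    def test_single_stride_degeneracy(self, white_x):
        strikes = _strikes(1)
        xs = sp.segment_strides(white_x, RATE, strikes)
        ys = sp.segment_strides(np.roll(white_x, 7), RATE, strikes)
        s = coh.stride_averaged_spectra(xs, ys)
        assert np.allclose(np.abs(s.pxy) ** 2, s.pxx * s.pyy, rtol=1e-9)

    def test_independent_noise_bias_is_one_over_n(self, white_x):
        y = np.random.default_rng(9).standard_normal(white_x.size)
        s, C, G = _maps(white_x, y)
        assert np.nanmean(C.values) == pytest.approx(1 / 64, rel=0.35)

    def test_scalar_gain_of_two(self, white_x):
        _, C, G = _maps(white_x, 2.0 * white_x)
        assert np.nanmax(np.abs(G.values - 2.0)) < 1e-9

    def test_pure_delay_has_unit_gain_in_band(self, white_x):
        _, C, G = _maps(white_x, np.roll(white_x, 3))
        band = (G.freqs > 3) & (G.freqs < 20)
        assert np.nanmean(G.values[band]) == pytest.approx(1.0, abs=0.05)

    def test_fir_gain_matches_transfer_magnitude(self, white_x):
        from vestigait.synthetic_gait import grf_coupling_kernel
        h = grf_coupling_kernel()
        y = sig.fftconvolve(white_x, h, mode="same")
        _, C, G = _maps(white_x, y)
        _, H = sig.freqz(h, worN=G.freqs, fs=RATE)
        prof = np.nanmean(G.values, axis=1)
        band = (G.freqs >= 1.0) & (G.freqs <= 8.0)
        rel = np.abs(prof[band] - np.abs(H[band])) / np.abs(H[band])
        assert rel.max() < 0.05

    def test_snr_closed_form(self, white_x):
        """y = ax + independent noise -> C ~ s/(1+s) with s = a^2."""
        rng = np.random.default_rng(5)
        for a, snr in ((1.0, 1.0), (2.0, 4.0)):
            y = a * white_x + rng.standard_normal(white_x.size)
            _, C, _ = _maps(white_x, y)
            band = (C.freqs > 3) & (C.freqs < 20)
            assert np.nanmean(C.values[band]) \
                == pytest.approx(snr / (1 + snr), rel=0.05)

    def test_coherence_invariant_gain_equivariant_to_scaling(self, white_x):
        rng = np.random.default_rng(6)
        y = white_x + rng.standard_normal(white_x.size)
        _, C1, G1 = _maps(white_x, y)
        _, C2, G2 = _maps(3.0 * white_x, 0.5 * y)
        assert np.allclose(C1.values, C2.values, atol=1e-9)
        assert np.allclose(G2.values, G1.values * 0.5 / 3.0, rtol=1e-6)

    def test_coherence_bounded_in_unit_interval(self, white_x):
        rng = np.random.default_rng(7)
        y = 0.3 * white_x + rng.standard_normal(white_x.size)
        _, C, _ = _maps(white_x, y)
        vals = C.values[np.isfinite(C.values)]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_mismatched_stride_counts_rejected(self, white_x):
        xs = sp.segment_strides(white_x, RATE, _strikes(8))
        ys = sp.segment_strides(white_x, RATE, _strikes(6))
        with pytest.raises(ValidationError):
            coh.stride_averaged_spectra(xs, ys)


class TestSignificanceThreshold:
    @pytest.mark.parametrize("n, alpha, expected, tol", [
        (256, 0.01, 0.018, 5e-4),   # the published level for 256 strides
        (2, 0.05, 0.95, 1e-12),
        (100, 0.05, 1 - 0.05 ** (1 / 99), 1e-12),
    ])
    def test_closed_form(self, n, alpha, expected, tol):
        assert coh.significance_threshold(n, alpha) \
            == pytest.approx(expected, abs=tol)

    def test_requires_two_strides(self):
        with pytest.raises(ParameterError):
            coh.significance_threshold(1, 0.05)
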