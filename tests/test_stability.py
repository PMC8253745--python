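"""Local divergence exponent: differentiation, resampling, Rosenstein."""

import numpy as np
import pytest

from vestigait import stability as st
from vestigait import synthetic_gait as sg
from vestigait.errors import InsufficientDataError, ValidationError


class TestThreePointVelocity:
    def test_linear_ramp_exact(self):
        x = 3.0 * np.arange(100) / 50.0
        v = st.three_point_velocity(x, 50.0)
        assert np.allclose(v, 3.0)

    def test_constant_zero(self):
        assert np.allclose(st.three_point_velocity(np.full(50, 2.0), 100.0), 0.0)

    def test_sinusoid_amplitude_matches_transfer_function(self):
        # central difference gain: rate*sin(2*pi*f/rate) vs exact 2*pi*f
        rate, f, A = 1000.0, 5.0, 1.3
        t = np.arange(5000) / rate
        v = st.three_point_velocity(A * np.sin(2 * np.pi * f * t), rate)
        measured = np.max(np.abs(v[100:-100]))
        assert measured == pytest.approx(2 * np.pi * f * A, rel=0.01)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            st.three_point_velocity(np.array([1.0, 2.0]), 10.0)


class TestResampleStrides:
    def test_256_strides_give_25600_samples(self):
        strikes = 1.5 * np.arange(257) + 2.0
        series = np.random.default_rng(0).standard_normal(
            int((strikes[-1] + 2) * 100))
        out = st.resample_strides(series, 100.0, strikes, 256, 100)
        assert out.size == 25_600

    @pytest.mark.parametrize("n, m", [(10, 100), (16, 64), (37, 50)])
    def test_length_is_product(self, n, m):
        strikes = 1.5 * np.arange(n + 1)
        series = np.random.default_rng(1).standard_normal(
            int((strikes[-1] + 1) * 100))
        assert st.resample_strides(series, 100.0, strikes, n, m).size == n * m

    def test_uniform_strides_identity(self):
        # strides already uniform at 100 samples: warp is the identity
        strikes = np.arange(11, dtype=float)
        t = np.arange(1200) / 100.0
        series = np.sin(2 * np.pi * 1.0 * t)
        out = st.resample_strides(series, 100.0, strikes, 10, 100)
        assert np.allclose(out, series[:1000], atol=1e-9)

    def test_too_few_strides_reports_count(self):
        with pytest.raises(InsufficientDataError, match="have 4"):
            st.resample_strides(np.zeros(1000), 100.0,
                                1.5 * np.arange(5), 256, 100)


def brute_force_divergence(series, samples_per_stride, dim, delay,
                           theiler, horizon_strides):
    """All-pairs nearest-neighbor reference implementation."""
    horizon = int(round(horizon_strides * samples_per_stride))
    m_total = series.size - (dim - 1) * delay
    emb = np.stack([series[i * delay: i * delay + m_total]
                    for i in range(dim)], axis=1)
    m_track = m_total - horizon
    pts = emb[:m_track]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    ii, jj = np.meshgrid(np.arange(m_track), np.arange(m_track),
                         indexing="ij")
    d2[np.abs(ii - jj) <= theiler] = np.inf
    nn = np.argmin(d2, axis=1)
    tiny = 1e-15 * max(np.ptp(series), 1.0)
    curve = np.empty(horizon + 1)
    idx = np.arange(m_track)
    for i in range(horizon + 1):
        d = np.linalg.norm(emb[idx + i] - emb[nn + i], axis=1)
        curve[i] = np.mean(np.log(np.maximum(d, tiny)))
    return curve


class TestRosenstein:
    def test_matches_brute_force_oracle(self):
        series = sg.simulate_t6_series(18, 100, 0.05, seed=3)  # 1800 samples
        fast = st.rosenstein_divergence(series, 100, dim=5, delay=10,
                                        theiler=50, horizon_strides=1.0)
        slow = brute_force_divergence(series, 100, dim=5, delay=10,
                                      theiler=50, horizon_strides=1.0)
        assert np.allclose(fast.mean_log_divergence, slow, atol=1e-10)

    def test_noiseless_orbit_has_flat_curve(self):
        series = sg.simulate_t6_series(64, 100, 0.0, seed=0)
        lde = st.lde_from_series(series, 100)
        assert abs(lde) <= 0.05

    def test_lde_increases_with_dynamical_noise(self):
        medians = []
        for sd in (0.01, 0.05, 0.2):
            vals = [st.lde_from_series(
                sg.simulate_t6_series(64, 100, sd, seed=s), 100)
                for s in range(10)]
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_amplitude_scaling_invariance(self):
        series = sg.simulate_t6_series(32, 100, 0.05, seed=5)
        a = st.lde_from_series(series, 100)
        b = st.lde_from_series(3.0 * series, 100)
        assert abs(a - b) < 1e-10

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError):
            st.rosenstein_divergence(np.ones(2000), 100)


class TestLdeSlope:
    def _curve(self, y, spp=100):
        t = np.arange(y.size) / spp
        return st.DivergenceCurve(time_strides=t, mean_log_divergence=y,
                                  samples_per_stride=spp, dim=5, delay=10,
                                  theiler=50, n_pairs=1)

    def test_exact_line(self):
        t = np.arange(101) / 100.0
        assert st.lde_slope(self._curve(0.8 * t - 2.0)) \
            == pytest.approx(0.8, abs=1e-12)

    def test_flat_curve_zero(self):
        assert st.lde_slope(self._curve(np.full(101, -3.0))) \
            == pytest.approx(0.0, abs=1e-12)

    def test_window_ignores_later_points(self):
        t = np.arange(101) / 100.0
        y = np.where(t <= 0.5, 2.0 * t, 1.0)   # steep then flat
        assert st.lde_slope(self._curve(y)) == pytest.approx(2.0, abs=1e-9)

    def test_short_curve_rejected(self):
        t = np.arange(30) / 100.0   # covers only 0.3 stride
        with pytest.raises(InsufficientDataError):
            st.lde_slope(self._curve(np.zeros(30)))
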