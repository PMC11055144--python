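"""Cumulative-velocity time warping."""

import numpy as np
import pytest

import actimage as ai
from actimage.segmentation import VelocitySeries
from actimage.warp import build_warp_map, resample_profile, warp_profile


def _vel(values, fs=1.0):
    return VelocitySeries(fs, np.asarray(values, dtype=float))


class TestWarpMap:
    @pytest.mark.parametrize("mode", ["expand_fast", "literal_eq7"])
    def test_constant_velocity_is_identity(self, mode):
        vel = _vel(np.full(11, 3.0), fs=10.0)
        wmap = build_warp_map(vel, mode=mode)
        src = wmap.source_times(11)
        np.testing.assert_allclose(src, vel.times, atol=1e-9)

    @pytest.mark.parametrize("mode", ["expand_fast", "literal_eq7"])
    @pytest.mark.parametrize("rule", ["trapezoid", "left_riemann"])
    def test_endpoints_preserved(self, mode, rule):
        rng = np.random.default_rng(8)
        vel = _vel(rng.uniform(0, 5, 50), fs=240.0)
        wmap = build_warp_map(vel, integration_rule=rule, mode=mode)
        src = wmap.source_times(32)
        assert src[0] == pytest.approx(0.0, abs=1e-12)
        assert src[-1] == pytest.approx(vel.duration, abs=1e-9)

    def test_quadrature_matches_bruteforce(self):
        """Cumulative integral of V_rep = [1,1,1,9] on a unit-spaced grid
        against independently computed quadratures."""
        v = np.array([1.0, 1.0, 1.0, 9.0])
        vel = _vel(v, fs=1.0)
        # trapezoid: manual cumulative sums of interval means
        trap = np.array([0.0, 1.0, 2.0, 7.0])
        wmap = build_warp_map(vel, integration_rule="trapezoid")
        np.testing.assert_allclose(wmap.cumulative, trap / trap[-1], atol=1e-12)
        # left Riemann: cumulative sums of left endpoints
        left = np.array([0.0, 1.0, 2.0, 3.0])
        wmap = build_warp_map(vel, integration_rule="left_riemann")
        np.testing.assert_allclose(wmap.cumulative, left / left[-1], atol=1e-12)

    def test_monotone_source_times(self):
        rng = np.random.default_rng(15)
        vel = _vel(np.abs(rng.normal(0, 1, 200)) * (rng.uniform(size=200) > 0.3),
                   fs=240.0)
        for mode in ("expand_fast", "literal_eq7"):
            wmap = build_warp_map(vel, mode=mode)
            src = wmap.source_times(77)
            assert np.all(np.diff(src) >= 0)

    def test_zero_velocity_degrades_to_identity(self):
        vel = _vel(np.zeros(20), fs=10.0)
        wmap = build_warp_map(vel)
        np.testing.assert_allclose(wmap.source_times(20), vel.times, atol=1e-12)

    def test_negative_velocity_rejected(self):
        with pytest.raises(ai.ValidationError):
            VelocitySeries(240.0, np.array([1.0, -0.5, 2.0]))

    def test_invalid_mode_rejected(self):
        vel = _vel(np.ones(5))
        with pytest.raises(ai.ValidationError):
            build_warp_map(vel, mode="sideways")


class TestWarpProfile:
    def test_identity_map_equals_uniform_resampling(self, segment_a6):
        vel = ai.representative_velocity(segment_a6)
        const = VelocitySeries(vel.sample_rate, np.ones(vel.n_frames))
        wmap = build_warp_map(const)
        warped = warp_profile(segment_a6, wmap, 80)
        uniform = resample_profile(segment_a6, 80)
        np.testing.assert_allclose(warped.values, uniform.values, atol=1e-6)

    def test_literal_eq7_on_ramp_returns_warp_series(self):
        """With p(t) = t, composing p with the warp map must reproduce the
        warped-time series itself."""
        rng = np.random.default_rng(2)
        T = 60
        v = np.abs(rng.normal(1, 0.5, T))
        vel = _vel(v, fs=60.0)
        values = np.zeros((T, 1, 6, 3))
        values[:, 0, 0, 0] = vel.times  # ramp channel
        profile = ai.MotionProfile(values, 60.0, ("right_hand",))
        wmap = build_warp_map(vel, mode="literal_eq7")
        warped = warp_profile(profile, wmap, T)
        t_warp = np.interp(np.linspace(0, vel.duration, T), vel.times,
                           wmap.cumulative) * wmap.t_f
        np.testing.assert_allclose(warped.values[:, 0, 0, 0], t_warp, atol=1e-4)

    def test_expand_fast_allocates_rows_by_velocity_share(self):
        """Rows land in the fast interval in proportion to its share of the
        cumulative velocity, within 1/n_rows."""
        fs, T = 240.0, 480
        v = np.ones(T)
        lo, hi = 200, 280
        v[lo:hi] = 9.0
        vel = _vel(v, fs=fs)
        wmap = build_warp_map(vel)
        n_rows = 100
        src = wmap.source_times(n_rows)
        t0, t1 = lo / fs, hi / fs
        from scipy.integrate import cumulative_trapezoid
        cum = cumulative_trapezoid(v, dx=1 / fs, initial=0.0)
        share = (np.interp(t1, vel.times, cum) - np.interp(t0, vel.times, cum)) / cum[-1]
        got = np.mean((src >= t0) & (src <= t1))
        assert abs(got - share) <= 1.0 / n_rows + 1e-9

    def test_modes_are_inverse_reparameterizations(self):
        """Applying the literal composition to the expand_fast source-time
        map recovers the uniform grid."""
        rng = np.random.default_rng(4)
        vel = _vel(np.abs(rng.normal(1, 0.6, 120)) + 0.05, fs=120.0)
        n = 120
        expand = build_warp_map(vel, mode="expand_fast").source_times(n)
        literal = build_warp_map(vel, mode="literal_eq7")
        # s(expand(u)) * t_f should be the uniform grid
        recovered = np.interp(expand, literal.grid, literal.cumulative) * literal.t_f
        np.testing.assert_allclose(recovered, np.linspace(0, vel.duration, n), atol=1e-4)

    def test_source_times_within_segment(self, segment_a6):
        vel = ai.representative_velocity(segment_a6)
        warped = warp_profile(segment_a6, build_warp_map(vel), 64)
        assert warped.source_times.min() >= 0
        assert warped.source_times.max() <= segment_a6.duration + 1e-12

    def test_n_rows_too_small_rejected(self, segment_a6):
        vel = ai.representative_velocity(segment_a6)
        with pytest.raises(ai.ValidationError):
            warp_profile(segment_a6, build_warp_map(vel), 1)
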