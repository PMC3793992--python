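"""Feature extraction: time/spectral features, energy, gravity filtering,
and the composed 152/12-feature extractors."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlahar import (
    GravityFilterSpec,
    IntegrityError,
    ParameterError,
    energy,
    extract_generic,
    extract_rest,
    generic_feature_names,
    gravity_component,
    rest_feature_names,
    spectral_features,
    time_features,
)
from dlahar.features import _generic_block

RATE = 204.8


class TestTimeFeatures:
    def test_hand_arithmetic(self):
        assert time_features([1, 2, 3, 4]) == (1.0, 4.0, 2.5, 1.25)

    def test_constant_window(self):
        assert time_features(np.full(100, 7.5)) == (7.5, 7.5, 7.5, 0.0)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=1024)
        mn, mx, mean, var = time_features(x)
        # brute-force loops
        o_mn, o_mx, acc = x[0], x[0], 0.0
        for v in x:
            o_mn, o_mx, acc = min(o_mn, v), max(o_mx, v), acc + v
        o_mean = acc / len(x)
        o_var = sum((v - o_mean) ** 2 for v in x) / len(x)  # population
        assert mn == pytest.approx(o_mn, abs=1e-12)
        assert mx == pytest.approx(o_mx, abs=1e-12)
        assert mean == pytest.approx(o_mean, abs=1e-12)
        assert var == pytest.approx(o_var, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            time_features([])


class TestSpectralFeatures:
    def test_constant_window_is_zero_by_convention(self):
        assert spectral_features(np.full(1024, 2.0), RATE) == (0.0, 0.0)

    def test_single_bin_sinusoid(self):
        # bin 10 of a 1024-sample window at 204.8 Hz is exactly 2.0 Hz
        f0 = 10 * RATE / 1024
        t = np.arange(1024) / RATE
        c, bw = spectral_features(np.sin(2 * np.pi * f0 * t), RATE)
        assert c == pytest.approx(2.0, abs=1e-9)
        # bandwidth amplifies numerical leakage via sqrt of (f - c)^2-weighted
        # residuals; ~1e-5 Hz is the float64 leakage floor here
        assert bw == pytest.approx(0.0, abs=1e-4)

    def test_two_bin_sinusoids(self):
        f1, f2 = 10 * RATE / 1024, 30 * RATE / 1024  # 2.0 and 6.0 Hz
        t = np.arange(1024) / RATE
        x = np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t + 0.7)
        c, bw = spectral_features(x, RATE)
        assert c == pytest.approx((f1 + f2) / 2, abs=1e-9)
        assert bw == pytest.approx((f2 - f1) / 2, abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_centroid_within_nyquist_bandwidth_nonnegative(self, seed):
        x = np.random.default_rng(seed).normal(size=256)
        c, bw = spectral_features(x, RATE)
        assert 0.0 <= c <= RATE / 2
        assert bw >= 0.0


class TestEnergy:
    def test_all_twos_gives_four(self):
        assert energy(np.full((3, 128), 2.0)) == pytest.approx(4.0)

    def test_zeros(self):
        assert energy(np.zeros((3, 16))) == 0.0

    def test_matches_nested_loop_oracle(self, rng):
        w = rng.normal(size=(3, 1024))
        acc = 0.0
        for axis in w:
            s = 0.0
            for v in axis:
                s += v * v
            acc += s
        assert energy(w) == pytest.approx(acc / (3 * 1024), abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(c=st.floats(-10, 10), seed=st.integers(0, 1000))
    def test_quadratic_homogeneity(self, c, seed):
        w = np.random.default_rng(seed).normal(size=(3, 64))
        assert energy(c * w) == pytest.approx(c * c * energy(w), rel=1e-9, abs=1e-9)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(IntegrityError):
            energy([np.ones(10), np.ones(10), np.ones(9)])
        with pytest.raises(IntegrityError):
            energy(np.ones((2, 10)))


class TestGravityFilter:
    def test_dc_gain_unity(self):
        x = np.ones(int(30 * RATE))
        y = gravity_component(x, RATE)
        ripple = 10 ** (-0.01 / 20)  # passband ripple bound
        assert np.abs(y[-1024:] - 1.0).max() < (1 - ripple) + 1e-6

    def test_5hz_oscillation_strongly_attenuated(self):
        t = np.arange(int(30 * RATE)) / RATE
        x = 1.0 + 0.5 * np.sin(2 * np.pi * 5.0 * t)
        y = gravity_component(x, RATE)
        tail = y[-2048:]
        assert abs(tail.mean() - 1.0) < 0.01
        # residual oscillation far below the stopband spec applied to 0.5 g
        assert (tail - tail.mean()).std() < 0.5 * 10 ** (-60 / 20)

    def test_in_band_sinusoid_passes(self):
        f0 = 0.05
        t = np.arange(int(120 * RATE)) / RATE
        x = np.sin(2 * np.pi * f0 * t)
        y = gravity_component(x, RATE)
        # steady-state amplitude over the last two full periods
        tail = y[-int(2 / f0 * RATE) :]
        amp = (tail.max() - tail.min()) / 2
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            gravity_component(np.ones(4), RATE)

    def test_invalid_rate_for_cutoff(self):
        with pytest.raises(ParameterError):
            GravityFilterSpec().sos(0.4)


class TestComposedExtractors:
    def test_generic_has_152_stable_named_features(self, rng):
        w = rng.normal(size=(24, 1024))
        fv = extract_generic(w, RATE)
        assert len(fv.values) == 152
        assert fv.names == generic_feature_names()
        assert len(set(fv.names)) == 152
        fv2 = extract_generic(w, RATE)
        np.testing.assert_array_equal(fv.values, fv2.values)

    def test_rest_has_12_features(self, rng):
        fv = extract_rest(rng.normal(size=(12, 1024)))
        assert len(fv.values) == 12
        assert fv.names == rest_feature_names()

    def test_all_zero_window(self):
        fv = extract_generic(np.zeros((24, 256)), RATE)
        assert np.all(fv.values == 0.0)

    def test_generic_composition_matches_standalone_ops(self, rng):
        """Each of the 152 entries equals the elementary operation applied
        to the corresponding channel slice."""
        w = rng.normal(size=(24, 512))
        fv = extract_generic(w, RATE)
        values = dict(zip(fv.names, fv.values))
        from dlahar.imu_data import CHANNEL_NAMES, NODE_ORDER

        for ci, chan in enumerate(CHANNEL_NAMES):
            mn, mx, mean, var = time_features(w[ci])
            c, bw = spectral_features(w[ci], RATE)
            for feat, expected in zip(
                ("min", "max", "mean", "variance", "centroid", "bandwidth"),
                (mn, mx, mean, var, c, bw),
            ):
                assert values[f"{chan}.{feat}"] == pytest.approx(expected, abs=1e-10)
        for ni, node in enumerate(NODE_ORDER):
            accel = energy(w[ni * 6 : ni * 6 + 3])
            gyro = energy(w[ni * 6 + 3 : ni * 6 + 6])
            assert values[f"{node}.accel.energy"] == pytest.approx(accel, abs=1e-10)
            assert values[f"{node}.gyro.energy"] == pytest.approx(gyro, abs=1e-10)

    def test_static_posture_rest_vector(self):
        """A hip sensor aligned with gravity yields ~1 g on hip.az and ~0
        elsewhere after gravity filtering."""
        n = int(30 * RATE)
        signals = np.zeros((24, n))
        from dlahar.imu_data import channel_index

        signals[channel_index("HIP", "az")] = 1.0
        filtered = np.stack(
            [
                gravity_component(signals[i], RATE)
                for i in range(24)
                if i % 6 < 3  # accelerometer rows
            ]
        )
        fv = extract_rest(filtered[:, -1024:])
        values = dict(zip(fv.names, fv.values))
        assert values["HIP.az.gravity"] == pytest.approx(1.0, abs=1e-3)
        others = [v for k, v in values.items() if k != "HIP.az.gravity"]
        assert np.abs(others).max() < 1e-3

    def test_wrong_channel_count_rejected(self, rng):
        with pytest.raises(IntegrityError):
            extract_generic(rng.normal(size=(23, 128)), RATE)
        with pytest.raises(IntegrityError):
            extract_rest(rng.normal(size=(11, 128)))

    def test_vectorized_block_matches_single_window_path(self, rng):
        windows = rng.normal(size=(5, 24, 256))
        block = _generic_block(windows, RATE)
        for k in range(5):
            np.testing.assert_allclose(
                block[k], extract_generic(windows[k], RATE).values, atol=1e-10
            )
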