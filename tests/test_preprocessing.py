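"""Gaussian filtering and arm-axis calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skitech.io import ImuSeries
from skitech.preprocessing import (
    DETECTION_FILTER,
    FEATURE_FILTER,
    CalibrationRotation,
    CalibrationWarning,
    FilterSpec,
    calibrate_arm,
    gaussian_filter,
    gaussian_smooth,
)


def _gyro(samples, rate=20.0):
    n = len(samples)
    return ImuSeries(np.arange(n) / rate, samples, "arm_right", "gyroscope", rate)


class TestGaussianFilter:
    def test_constant_signal_unchanged(self):
        out = gaussian_smooth(np.full(200, 3.7), 5.0)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_impulse_response_is_normalized_gaussian(self):
        sigma = 5.0
        x = np.zeros(401)
        x[200] = 1.0
        out = gaussian_smooth(x, sigma)
        k = np.arange(-20, 21)
        kernel = np.exp(-0.5 * (k / sigma) ** 2)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out[180:221], kernel, atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        # continuous Gaussian transfer: gain = exp(-(2*pi*f*sigma_t)^2 / 2)
        fs, f, sigma_s = 20.0, 0.5, 0.25
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * f * t)
        out = gaussian_smooth(x, sigma_s * fs)
        mid = slice(200, 1000)
        gain = np.sqrt(2 * np.mean(out[mid] ** 2))
        expected = np.exp(-0.5 * (2 * np.pi * f * sigma_s) ** 2)
        assert gain == pytest.approx(expected, rel=0.02)

    def test_output_length_equals_input_length(self):
        s = _gyro(np.random.default_rng(0).normal(size=(120, 3)))
        out = gaussian_filter(s, DETECTION_FILTER)
        assert out.n == s.n

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="kernel support"):
            gaussian_smooth(np.zeros(10), 5.0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 100))
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        s1, s2 = rng.normal(size=(2, 100))
        lhs = gaussian_smooth(a * s1 + b * s2, 3.0)
        rhs = a * gaussian_smooth(s1, 3.0) + b * gaussian_smooth(s2, 3.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_default_specs_match_pipeline_constants(self):
        assert DETECTION_FILTER.sigma_samples(20.0) == pytest.approx(5.0)
        assert FEATURE_FILTER.sigma_samples(20.0) == pytest.approx(1.75)


def _swing_signal(n=600, rate=20.0, period_s=1.4, rng=None):
    """Positively skewed arm-swing-like angular rate about one axis."""
    t = np.arange(n) / rate
    w = 2 * np.pi / period_s
    x = 120 * np.cos(w * t) + 45 * np.cos(2 * w * t)  # peaks taller than troughs
    if rng is not None:
        x = x + 3 * rng.standard_normal(n)
    return x


class TestCalibration:
    def test_recovers_tilted_axis_within_one_degree(self, rng):
        axis = np.array([0.0, np.cos(np.radians(30)), np.sin(np.radians(30))])
        omega = _swing_signal(rng=rng)
        samples = np.outer(omega, axis) + 0.5 * rng.standard_normal((len(omega), 3))
        series = _gyro(samples)
        calibrated, rot = calibrate_arm(series)
        recovered = rot.matrix[1]  # calibrated y in raw coordinates
        angle = np.degrees(np.arccos(abs(np.clip(recovered @ axis, -1, 1))))
        assert angle < 1.0
        # dominant peaks of the calibrated y must be positive
        assert calibrated.y.max() > -calibrated.y.min()

    def test_aligned_input_gives_identity_up_to_sign(self, rng):
        omega = _swing_signal(rng=rng)
        samples = np.column_stack([
            0.3 * rng.standard_normal(len(omega)),
            omega,
            0.1 * rng.standard_normal(len(omega)),
        ])
        _, rot = calibrate_arm(_gyro(samples))
        np.testing.assert_allclose(np.abs(rot.matrix), np.eye(3), atol=0.05)
        assert rot.matrix[1, 1] > 0  # sign resolved toward the true axis

    def test_isotropic_motion_warns_and_returns_identity(self, rng):
        samples = rng.standard_normal((600, 3))
        with pytest.warns(CalibrationWarning):
            _, rot = calibrate_arm(_gyro(samples))
        assert rot.is_identity
        assert rot.dominant_variance_fraction < 0.5

    def test_rotation_preserves_sample_norms(self, rng):
        omega = _swing_signal(rng=rng)
        samples = np.outer(omega, [0.2, 0.9, 0.4]) + rng.standard_normal((len(omega), 3))
        series = _gyro(samples)
        calibrated, _ = calibrate_arm(series)
        np.testing.assert_allclose(
            np.linalg.norm(calibrated.samples, axis=1),
            np.linalg.norm(series.samples, axis=1),
            atol=1e-9,
        )

    def test_rotation_matrix_is_proper(self, rng):
        omega = _swing_signal(rng=rng)
        samples = np.outer(omega, [0.1, 0.8, 0.6]) + rng.standard_normal((len(omega), 3))
        _, rot = calibrate_arm(_gyro(samples))
        np.testing.assert_allclose(rot.matrix @ rot.matrix.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(rot.matrix) == pytest.approx(1.0, abs=1e-9)

    def test_improper_matrix_rejected(self):
        m = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper rotation"):
            CalibrationRotation(m, 0.9)

    def test_chest_modality_rejected(self, rng):
        chest = ImuSeries(np.arange(100) / 20.0, rng.normal(size=(100, 3)),
                          "chest", "accelerometer", 20.0)
        with pytest.raises(ValueError, match="gyroscope"):
            calibrate_arm(chest)
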