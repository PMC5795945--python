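"""Arm-sensor axis calibration and Gaussian low-pass filtering.

Two Gaussian filters are used in the pipeline, specified by their standard
deviation in the time domain: a heavy 0.25 s (5 samples at 20 Hz) filter
that reduces the arm-gyroscope y-axis to a near-sinusoidal signal for cycle
detection, and a light 0.0875 s (1.75 samples) filter that removes
high-frequency noise from the chest accelerometer before feature
extraction.

Arm-sensor mounting misalignment is compensated by a principal-axes
calibration: the skier's arm swing is assumed to rotate predominantly about
the axis perpendicular to the sagittal plane, so the gyro axis with maximal
angular-motion variance is taken as the calibrated y-axis.  The chest
sensor is never calibrated; its mounting is assumed robust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .io import ImuSeries

__all__ = [
    "FilterSpec",
    "DETECTION_FILTER",
    "FEATURE_FILTER",
    "CalibrationRotation",
    "gaussian_smooth",
    "gaussian_filter",
    "calibrate_arm",
    "CalibrationWarning",
]


@dataclass(frozen=True)
class FilterSpec:
    """Gaussian low-pass filter given by its time-domain standard deviation."""

    sigma_seconds: float

    def __post_init__(self) -> None:
        if self.sigma_seconds <= 0:
            raise ValueError("sigma_seconds must be positive")

    def sigma_samples(self, sample_rate_hz: float) -> float:
        return self.sigma_seconds * sample_rate_hz


#: Heavy smoothing for cycle detection (0.25 s; 5 samples at 20 Hz).
DETECTION_FILTER = FilterSpec(0.25)
#: Light smoothing before feature extraction (0.0875 s; 1.75 samples at 20 Hz).
FEATURE_FILTER = FilterSpec(0.0875)

_TRUNCATE = 4.0  # kernel truncated at 4 sigma


class CalibrationWarning(UserWarning):
    """Raised (as a warning) when arm motion is too isotropic to calibrate."""


def gaussian_smooth(values: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Convolve along axis 0 with a normalized Gaussian kernel.

    Boundary handling is reflection, which avoids the edge transients that
    constant padding would turn into spurious peaks.  NaNs (missing
    samples) are linearly interpolated before filtering so they do not
    propagate; cycles overlapping missing spans are excluded downstream
    regardless.
    """
    values = np.asarray(values, dtype=float)
    if sigma_samples <= 0:
        raise ValueError("sigma_samples must be positive")
    n = values.shape[0]
    if n <= int(_TRUNCATE * sigma_samples):
        raise ValueError(
            f"series of length {n} is shorter than the filter kernel support "
            f"({int(_TRUNCATE * sigma_samples) + 1} samples)"
        )
    work = values.copy()
    cols = work.reshape(n, -1)
    for j in range(cols.shape[1]):
        col = cols[:, j]
        bad = np.isnan(col)
        if bad.any():
            if bad.all():
                col[:] = 0.0
            else:
                idx = np.arange(n)
                col[bad] = np.interp(idx[bad], idx[~bad], col[~bad])
    out = ndimage.gaussian_filter1d(
        work, sigma=sigma_samples, axis=0, mode="reflect", truncate=_TRUNCATE
    )
    return out.reshape(values.shape)


def gaussian_filter(series: ImuSeries, spec: FilterSpec) -> ImuSeries:
    """Return a copy of ``series`` with each axis Gaussian low-pass filtered."""
    sigma = spec.sigma_samples(series.sample_rate_hz)
    return series.with_samples(gaussian_smooth(series.samples, sigma))


@dataclass(frozen=True)
class CalibrationRotation:
    """Rotation mapping raw arm-sensor axes to calibrated axes.

    ``matrix`` rows are the calibrated x/y/z directions expressed in raw
    sensor coordinates; applying it as ``samples @ matrix.T`` puts the axis
    of maximal angular motion on the second (y) component.
    ``dominant_variance_fraction`` is the share of total angular-rate
    variance carried by that axis; values below 0.5 indicate near-isotropic
    motion for which calibration is unreliable.
    """

    matrix: np.ndarray
    dominant_variance_fraction: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("rotation matrix must be 3x3")
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise ValueError("matrix must be orthonormal")
        if not np.isclose(np.linalg.det(m), 1.0, atol=1e-9):
            raise ValueError("matrix must be a proper rotation (det +1)")
        object.__setattr__(self, "matrix", m)

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=1e-12))


def calibrate_arm(
    gyro: ImuSeries,
    detection_filter: FilterSpec = DETECTION_FILTER,
    min_dominant_fraction: float = 0.5,
) -> tuple[ImuSeries, CalibrationRotation]:
    """Principal-axes calibration of the arm gyroscope.

    The zero-meaned angular-rate covariance is eigen-decomposed; the
    dominant eigenvector becomes the calibrated y-axis (the arm-swing
    axis), the second most energetic the x-axis and the least the z-axis,
    with signs fixed so the matrix is a proper rotation.  The sign of the
    y-axis is disambiguated so that the dominant peaks of the heavily
    filtered y signal are positive (arm extended behind = maximum): the
    skewness of the filtered projection decides, falling back to comparing
    the magnitudes of its extrema.

    If the dominant axis carries less than ``min_dominant_fraction`` of the
    variance the motion is too isotropic to orient reliably: a
    ``CalibrationWarning`` is emitted and the identity rotation returned.
    """
    if gyro.modality != "gyroscope":
        raise ValueError("calibration applies to gyroscope streams only")
    finite = ~np.any(np.isnan(gyro.samples), axis=1)
    X = gyro.samples[finite]
    if X.shape[0] < 3:
        warnings.warn("too few samples to calibrate", CalibrationWarning)
        return gyro.with_samples(gyro.samples), CalibrationRotation(np.eye(3), 0.0)
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / Xc.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    total = float(evals.sum())
    frac = float(evals[2] / total) if total > 0 else 0.0
    if frac < min_dominant_fraction:
        warnings.warn(
            f"arm motion near-isotropic (dominant-axis variance fraction "
            f"{frac:.2f} < {min_dominant_fraction}); returning identity rotation",
            CalibrationWarning,
        )
        return gyro.with_samples(gyro.samples), CalibrationRotation(np.eye(3), frac)

    y_axis = evecs[:, 2]
    x_axis = evecs[:, 1]
    z_axis = evecs[:, 0]

    # Orient y so that deep arm extensions come out as positive peaks.
    proj = Xc @ y_axis
    sigma = detection_filter.sigma_samples(gyro.sample_rate_hz)
    if proj.shape[0] > int(_TRUNCATE * sigma):
        proj_f = gaussian_smooth(proj, sigma)
    else:
        proj_f = proj
    sk = float(stats.skew(proj_f)) if proj_f.std() > 0 else 0.0
    if abs(sk) > 1e-9:
        flip = sk < 0
    else:
        extrema = float(proj_f.max() + proj_f.min())
        flip = extrema < -1e-12
    if flip:
        y_axis = -y_axis
        x_axis = -x_axis  # keep handedness

    R = np.vstack([x_axis, y_axis, z_axis])
    if np.linalg.det(R) < 0:
        R[2] = -R[2]
    rotation = CalibrationRotation(R, frac)
    rotated = gyro.samples @ R.T
    return gyro.with_samples(rotated), rotation
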