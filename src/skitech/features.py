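"""Per-cycle feature vectors from the chest accelerometer, and mirror
augmentation.

Each cycle's chest-accelerometer segment (lightly filtered, 0.0875 s
Gaussian) is resampled to 30 points per axis by linear interpolation over
30 equally spaced positions spanning the cycle; decimation of long cycles
is the same interpolation.  The resampled x, y and z blocks are
concatenated and four scalars appended: the original cycle length in
samples and the per-axis normalized sums (sum of samples divided by cycle
length, i.e. the per-axis mean — the division removes the duration
dependence, which element 91 already carries).  Total length: 94.

Mirror augmentation makes the classifier robust to whether the left or the
right arm delimited the cycles: the lateral (y) axis flips sign under that
choice while x and z do not, so each training cycle is cloned with the
resampled y block and the normalized y-sum negated.  This doubles the
training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Cycle, ImuSeries, LabeledCycle, SubTechnique

__all__ = [
    "FeatureVector",
    "FEATURE_LENGTH",
    "N_RESAMPLED",
    "extract_features",
    "mirror_values",
    "augment_mirror",
    "feature_matrix",
]

N_RESAMPLED = 30
FEATURE_LENGTH = 3 * N_RESAMPLED + 4  # 94

# Layout of the 94-vector (0-based slices/indices).
X_SLICE = slice(0, 30)
Y_SLICE = slice(30, 60)
Z_SLICE = slice(60, 90)
LENGTH_INDEX = 90
X_MEAN_INDEX, Y_MEAN_INDEX, Z_MEAN_INDEX = 91, 92, 93


@dataclass(frozen=True)
class FeatureVector:
    """The 94-element per-cycle encoding.

    Elements 0-29 resampled x-axis, 30-59 resampled y-axis, 60-89
    resampled z-axis, 90 the original cycle length in samples, 91-93 the
    per-axis normalized sums.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).reshape(-1)
        if v.shape[0] != FEATURE_LENGTH:
            raise ValueError(f"feature vector must have length {FEATURE_LENGTH}, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        if v[LENGTH_INDEX] < 2:
            raise ValueError("cycle length element must be >= 2 samples")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return FEATURE_LENGTH

    @property
    def cycle_length(self) -> int:
        return int(self.values[LENGTH_INDEX])


def _resample(segment: np.ndarray, n_points: int) -> np.ndarray:
    """Linear interpolation of a 1-D segment onto n equally spaced points
    spanning [0, len-1]; endpoints are preserved exactly."""
    m = segment.shape[0]
    positions = np.linspace(0.0, m - 1.0, n_points)
    return np.interp(positions, np.arange(m), segment)


def extract_features(chest_accel: ImuSeries, cycle: Cycle) -> FeatureVector:
    """Encode one cycle of the (filtered) chest accelerometer as a 94-vector.

    The cycle must not be excluded, must span at least 2 samples and lie
    within the series bounds.
    """
    if cycle.excluded:
        raise ValueError("cannot extract features from an excluded cycle")
    if cycle.duration_samples < 2:
        raise ValueError("cycle shorter than 2 samples")
    if cycle.end > chest_accel.n:
        raise ValueError(
            f"cycle [{cycle.start}, {cycle.end}) outside series of length {chest_accel.n}"
        )
    seg = chest_accel.samples[cycle.start:cycle.end]
    if np.any(np.isnan(seg)):
        raise ValueError("cycle overlaps missing chest data; mark it excluded")
    blocks = [_resample(seg[:, axis], N_RESAMPLED) for axis in range(3)]
    means = seg.sum(axis=0) / cycle.duration_samples
    values = np.concatenate(blocks + [[float(cycle.duration_samples)], means])
    return FeatureVector(values)


def mirror_values(values: np.ndarray) -> np.ndarray:
    """The left/right mirror transform: negate the resampled y block and the
    normalized y-sum; everything else unchanged.  An involution."""
    out = np.asarray(values, dtype=float).copy()
    out[Y_SLICE] = -out[Y_SLICE]
    out[Y_MEAN_INDEX] = -out[Y_MEAN_INDEX]
    return out


def augment_mirror(dataset: Sequence[LabeledCycle]) -> list[LabeledCycle]:
    """Mirror-augment a featurized dataset; output size is exactly 2x input.

    Each clone keeps its cycle boundaries and label; only the y-dependent
    feature elements are negated.
    """
    out: list[LabeledCycle] = []
    for lc in dataset:
        if lc.feature is None:
            raise ValueError("augmentation requires extracted features")
        out.append(lc)
    for lc in list(dataset):
        mirrored = FeatureVector(mirror_values(lc.feature.values))
        out.append(LabeledCycle(cycle=lc.cycle, label=lc.label, feature=mirrored))
    return out


def feature_matrix(
    dataset: Sequence[LabeledCycle],
) -> tuple[np.ndarray, list[SubTechnique]]:
    """Stack a featurized dataset into an (n, 94) design matrix + labels."""
    X = np.vstack([lc.feature.values for lc in dataset])
    y = [lc.label for lc in dataset]
    return X, y
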