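"""Movement-cycle segmentation from the filtered arm-gyroscope y-axis.

A cycle starts and ends when the arm is extended all the way behind the
skier, which appears as a peak of the heavily filtered (0.25 s Gaussian)
arm-gyro y signal; the minima between peaks correspond to pole plants.
Cycles therefore tile the peak-to-peak region exactly.  Sub-techniques in
which the arms barely move (tuck, some turns) produce no interior peaks,
so their cycles come out much longer — the cycle duration itself is a
classification feature, and no maximum duration is imposed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .io import Cycle, merge_spans

__all__ = ["detect_cycles", "detect_peaks", "mark_excluded"]

log = logging.getLogger(__name__)

#: Minimum separation between cycle-delimiting peaks; no skiing cycle is
#: shorter than half a second.
MIN_PEAK_SEPARATION_S = 0.5
#: Peak prominence threshold as a fraction of the signal's amplitude scale
#: (90th percentile of |signal - median|, so detection is invariant to a
#: constant offset).
PROMINENCE_FRACTION = 0.25


def detect_peaks(
    signal: np.ndarray,
    sample_rate_hz: float,
    prominence_fraction: float = PROMINENCE_FRACTION,
    min_separation_s: float = MIN_PEAK_SEPARATION_S,
) -> np.ndarray:
    """Indices of cycle-delimiting peaks in a filtered 1-D signal."""
    x = np.asarray(signal, dtype=float).reshape(-1)
    if x.size < 3:
        return np.empty(0, dtype=int)
    scale = float(np.percentile(np.abs(x - np.median(x)), 90))
    prominence = max(prominence_fraction * scale, 1e-12)
    distance = max(1, int(round(min_separation_s * sample_rate_hz)))
    peaks, _ = find_peaks(x, prominence=prominence, distance=distance)
    return peaks


def detect_cycles(
    filtered_gyro_y: np.ndarray,
    sample_rate_hz: float,
    prominence_fraction: float = PROMINENCE_FRACTION,
    min_separation_s: float = MIN_PEAK_SEPARATION_S,
) -> list[Cycle]:
    """Segment a session into cycles delimited by successive gyro peaks.

    Returns complete cycles [peak_k, peak_{k+1}) in order, preceded /
    followed by the partial leading and trailing segments (flagged
    ``partial``) when the first peak is not at the first sample or the last
    peak not at the last.  With fewer than two peaks no cycle is defined
    and an empty list is returned.
    """
    x = np.asarray(filtered_gyro_y, dtype=float).reshape(-1)
    peaks = detect_peaks(x, sample_rate_hz, prominence_fraction, min_separation_s)
    if peaks.size < 2:
        log.info("cycle detection: %d peak(s) found; no cycles defined", peaks.size)
        return []
    cycles: list[Cycle] = []
    if peaks[0] > 0:
        cycles.append(Cycle(0, int(peaks[0]), partial=True))
    for a, b in zip(peaks[:-1], peaks[1:]):
        cycles.append(Cycle(int(a), int(b)))
    if peaks[-1] < x.size - 1:
        cycles.append(Cycle(int(peaks[-1]), x.size, partial=True))
    return cycles


def mark_excluded(
    cycles: Sequence[Cycle],
    missing_spans_arm: Sequence[tuple[int, int]] = (),
    missing_spans_chest: Sequence[tuple[int, int]] = (),
) -> list[Cycle]:
    """Flag cycles overlapping missing-data spans of either sensor as excluded.

    Spans are half-open sample intervals in the (shared) session sample
    coordinates.  Returns new ``Cycle`` objects; the input is not mutated.
    """
    spans = merge_spans(list(missing_spans_arm) + list(missing_spans_chest))
    out: list[Cycle] = []
    for c in cycles:
        excluded = c.excluded or any(c.overlaps_span(s) for s in spans)
        out.append(Cycle(c.start, c.end, excluded=excluded, partial=c.partial))
    return out
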