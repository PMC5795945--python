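"""Synchronizing classified cycles with a GNSS/heart-rate track.

Each (nominally 1 Hz) trackpoint is assigned the sub-technique of the
cycle covering its timestamp; the IMU and GNSS clocks are aligned by a
single constant offset.  A point exactly on a cycle boundary takes the
later cycle's class (the half-open cycle convention).  Per-class
aggregates — moving time, distance, mean speed and mean heart rate —
summarize how each sub-technique was used over the course.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    Cycle,
    GnssTrack,
    SubTechnique,
    _parse_gpx,
    haversine_m,
    write_gpx,
)

__all__ = ["AnnotatedTrack", "annotate", "export_annotated", "read_annotated"]


@dataclass
class AnnotatedTrack:
    """A GNSS track with per-point sub-technique annotation.

    ``classes[i]`` is the SubTechnique covering trackpoint ``i`` (EXC for
    excluded cycles, None outside any cycle).  ``summary`` holds the
    per-class aggregates with columns ``time_s``, ``distance_m``,
    ``mean_speed_mps`` and ``mean_heart_rate_bpm``.
    """

    track: GnssTrack
    classes: list[SubTechnique | None]
    summary: pd.DataFrame

    @property
    def n_annotated(self) -> int:
        return sum(c is not None for c in self.classes)


def _point_durations(timestamps: np.ndarray) -> np.ndarray:
    """Duration attributed to each trackpoint: the step to the next point;
    the last point gets the median step (1 s for a nominal track)."""
    n = timestamps.shape[0]
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([1.0])
    d = np.diff(timestamps)
    return np.concatenate([d, [float(np.median(d))]])


def _aggregate(track: GnssTrack, classes: Sequence[SubTechnique | None]) -> pd.DataFrame:
    durations = _point_durations(track.timestamps)
    seg_dist = np.zeros(track.n)
    if track.n > 1:
        seg_dist[:-1] = haversine_m(
            track.latitude[:-1], track.longitude[:-1],
            track.latitude[1:], track.longitude[1:],
        )
    rows = []
    present = []
    for c in classes:
        if c is not None and c not in present:
            present.append(c)
    for cls in present:
        mask = np.asarray([c is cls for c in classes])
        time_s = float(durations[mask].sum())
        dist = float(seg_dist[mask].sum())
        hr = np.nan
        if track.heart_rate is not None:
            vals = track.heart_rate[mask]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                hr = float(vals.mean())
        rows.append({
            "class": cls.value,
            "time_s": time_s,
            "distance_m": dist,
            "mean_speed_mps": dist / time_s if time_s > 0 else np.nan,
            "mean_heart_rate_bpm": hr,
        })
    return pd.DataFrame(rows, columns=[
        "class", "time_s", "distance_m", "mean_speed_mps", "mean_heart_rate_bpm",
    ])


def annotate(
    track: GnssTrack,
    classified: Sequence[tuple[Cycle, SubTechnique]],
    sample_rate_hz: float,
    offset_s: float = 0.0,
) -> AnnotatedTrack:
    """Assign each trackpoint the class of the cycle covering its time.

    Cycle sample indices are converted to session seconds via
    ``sample_rate_hz``; ``offset_s`` is the constant GNSS-minus-IMU clock
    offset (a trackpoint at GNSS time t falls at IMU time t - offset_s).
    Raises when the track and the cycles do not overlap in time at all.
    """
    if track.n == 0 or not classified:
        return AnnotatedTrack(track, [None] * track.n, _aggregate(track, []))
    starts = np.asarray([c.start for c, _ in classified]) / sample_rate_hz
    ends = np.asarray([c.end for c, _ in classified]) / sample_rate_hz
    imu_times = track.timestamps - offset_s
    if imu_times[-1] < starts[0] or imu_times[0] >= ends[-1]:
        raise ValueError(
            "track and classified cycles cover disjoint time ranges; "
            "check the clock offset"
        )
    classes: list[SubTechnique | None] = []
    for t in imu_times:
        j = int(np.searchsorted(starts, t, side="right")) - 1
        if 0 <= j < len(classified) and t < ends[j]:
            classes.append(classified[j][1])
        else:
            classes.append(None)
    return AnnotatedTrack(track, classes, _aggregate(track, classes))


def export_annotated(
    annotated: AnnotatedTrack,
    gpx_path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write the annotated track as GPX (per-point ``subtechnique``
    extension tag) and, optionally, the per-class summary as CSV."""
    tokens = [c.value if c is not None else None for c in annotated.classes]
    write_gpx(annotated.track, gpx_path, classes=tokens)
    if summary_path is not None:
        annotated.summary.to_csv(summary_path, index=False)


def read_annotated(gpx_path: str | Path) -> AnnotatedTrack:
    """Read back a GPX written by :func:`export_annotated`; aggregates are
    recomputed from the points."""
    from .io import read_gpx

    raw = _parse_gpx(gpx_path)
    track = read_gpx(gpx_path)
    classes = [
        SubTechnique.parse(tok) if tok else None
        for tok in raw["classes"]
    ]
    return AnnotatedTrack(track, classes, _aggregate(track, classes))
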