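"""Domain types and file I/O for IMU streams, GNSS tracks, cycles and labels.

The on-disk dialects are deliberately plain text:

* IMU streams: a CSV with header ``time,x,y,z`` (time in seconds as float)
  plus a JSON/YAML sidecar (``<file>.meta.json``) declaring placement,
  modality, units and nominal sample rate.
* GNSS tracks: GPX 1.1, optionally carrying a heart-rate extension and a
  per-point ``subtechnique`` extension written by :mod:`skitech.track`.
* Cycle labels: a CSV of ``cycle,label`` rows.

IMU streams are stored internally on the uniform nominal-rate time grid;
samples that are absent in the input (gaps wider than twice the nominal
interval, or dropouts injected by the synthesizer) appear as NaN rows and
are tracked explicitly as half-open index spans in ``missing_spans``.
Cycles that overlap such spans are later excluded from classification.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET

import numpy as np

__all__ = [
    "SubTechnique",
    "CLASSES",
    "ImuSeries",
    "Cycle",
    "LabeledCycle",
    "GnssTrack",
    "ImuParseError",
    "ImuValidationError",
    "read_imu_csv",
    "write_imu_csv",
    "read_gpx",
    "write_gpx",
    "read_labels",
    "write_labels",
    "read_cycles_csv",
    "write_cycles_csv",
    "haversine_m",
    "merge_spans",
]


class ImuParseError(ValueError):
    """Malformed sensor file (bad row, missing column, empty file)."""


class ImuValidationError(ValueError):
    """Structurally parseable input that violates a stream invariant."""


class SubTechnique(enum.Enum):
    """Classical-style sub-technique classes, plus the EXC exclusion sentinel.

    DIA: diagonal stride; DK: double poling with kick; DP: double poling;
    TCK: tuck (downhill); HRB: herringbone; TRN: turn; tDIA / fDIA:
    transition cycles into / out of diagonal stride.  EXC marks cycles
    excluded from classification because of lost sensor data; it is never
    a training target.
    """

    DIA = "DIA"
    DK = "DK"
    DP = "DP"
    TCK = "TCK"
    HRB = "HRB"
    TRN = "TRN"
    TDIA = "tDIA"
    FDIA = "fDIA"
    EXC = "EXC"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value

    @classmethod
    def parse(cls, token: str) -> "SubTechnique":
        """Parse a class token case-insensitively. Unknown tokens raise."""
        key = token.strip().upper()
        try:
            return _TOKEN_MAP[key]
        except KeyError:
            raise ValueError(f"unknown sub-technique token: {token!r}") from None


_TOKEN_MAP = {m.value.upper(): m for m in SubTechnique}

#: Canonical ordering of the eight trainable classes (EXC excluded).
CLASSES: tuple[SubTechnique, ...] = (
    SubTechnique.DIA,
    SubTechnique.DK,
    SubTechnique.DP,
    SubTechnique.TCK,
    SubTechnique.HRB,
    SubTechnique.TRN,
    SubTechnique.TDIA,
    SubTechnique.FDIA,
)

PLACEMENTS = ("chest", "arm_left", "arm_right")
MODALITIES = ("accelerometer", "gyroscope")


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open index spans."""
    out: list[tuple[int, int]] = []
    for a, b in sorted((int(a), int(b)) for a, b in spans):
        if b <= a:
            continue
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


@dataclass
class ImuSeries:
    """A uniformly sampled 3-axis sensor stream.

    ``timestamps`` are seconds since session start on the nominal grid,
    ``samples`` an (n, 3) array in canonical units (accelerometer m/s^2,
    gyroscope deg/s).  Missing samples are NaN rows listed in
    ``missing_spans`` as half-open index intervals.
    """

    timestamps: np.ndarray
    samples: np.ndarray
    placement: str
    modality: str
    sample_rate_hz: float
    missing_spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float).reshape(-1)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ImuValidationError("samples must be an (n, 3) array")
        if self.samples.shape[0] != self.timestamps.shape[0]:
            raise ImuValidationError("samples count must equal timestamps count")
        if self.placement not in PLACEMENTS:
            raise ImuValidationError(f"placement must be one of {PLACEMENTS}")
        if self.modality not in MODALITIES:
            raise ImuValidationError(f"modality must be one of {MODALITIES}")
        if self.sample_rate_hz <= 0:
            raise ImuValidationError("sample_rate_hz must be positive")
        if self.n > 1:
            dts = np.diff(self.timestamps)
            if np.any(dts <= 0):
                raise ImuValidationError("timestamps must be strictly increasing")
            nominal = 1.0 / self.sample_rate_hz
            med = float(np.median(dts))
            if abs(med - nominal) > 0.1 * nominal:
                raise ImuValidationError(
                    f"median sample interval {med:.4f}s deviates >10% from "
                    f"nominal {nominal:.4f}s"
                )
        self.missing_spans = merge_spans(self.missing_spans)
        for a, b in self.missing_spans:
            if a < 0 or b > self.n:
                raise ImuValidationError("missing span outside series bounds")

    @property
    def n(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if self.n else 0.0

    @property
    def x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.samples[:, 2]

    def with_samples(self, samples: np.ndarray) -> "ImuSeries":
        """Copy of this series with replaced sample values."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       missing_spans=list(self.missing_spans))


@dataclass
class Cycle:
    """One movement cycle as a half-open sample interval [start, end).

    Cycles are delimited by successive instants at which the arm is fully
    extended behind the skier (peaks of the filtered arm-gyro y-axis), so
    consecutive cycles tile without overlap.  ``partial`` marks the
    leading/trailing segments before the first / after the last peak.
    """

    start: int
    end: int
    excluded: bool = False
    partial: bool = False

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid cycle interval [{self.start}, {self.end})")

    @property
    def duration_samples(self) -> int:
        return self.end - self.start

    def overlaps_span(self, span: tuple[int, int]) -> bool:
        a, b = span
        return max(self.start, a) < min(self.end, b)


@dataclass
class LabeledCycle:
    """A cycle with its expert (or ground-truth) label and optional feature."""

    cycle: Cycle
    label: SubTechnique
    feature: "object | None" = None  # FeatureVector; kept loose to avoid cycles

    def __post_init__(self) -> None:
        if self.cycle.excluded and self.label is not SubTechnique.EXC:
            raise ValueError("excluded cycles must carry label EXC")
        if self.label is SubTechnique.EXC and self.feature is not None:
            raise ValueError("EXC cycles carry no feature")


@dataclass
class GnssTrack:
    """A 1 Hz (nominal) GNSS track with optional heart rate.

    ``timestamps`` are seconds since track start; ``speed`` is in m/s and is
    derived by finite differences of haversine distance when the source file
    does not carry it.
    """

    timestamps: np.ndarray
    latitude: np.ndarray
    longitude: np.ndarray
    altitude: np.ndarray
    speed: np.ndarray
    heart_rate: np.ndarray | None = None
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        for name in ("timestamps", "latitude", "longitude", "altitude", "speed"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(-1))
        n = self.timestamps.shape[0]
        for name in ("latitude", "longitude", "altitude", "speed"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length must match timestamps")
        if self.heart_rate is not None:
            self.heart_rate = np.asarray(self.heart_rate, dtype=float).reshape(-1)
            if self.heart_rate.shape[0] != n:
                raise ValueError("heart_rate length must match timestamps")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("track timestamps must be strictly increasing")
        if np.any((self.latitude < -90) | (self.latitude > 90)):
            raise ValueError("latitude out of [-90, 90]")
        if np.any((self.longitude < -180) | (self.longitude > 180)):
            raise ValueError("longitude out of [-180, 180]")

    @property
    def n(self) -> int:
        return int(self.timestamps.shape[0])


# ---------------------------------------------------------------------------
# IMU CSV
# ---------------------------------------------------------------------------

_UNIT_FACTORS = {
    ("accelerometer", "m/s2"): 1.0,
    ("accelerometer", "m/s^2"): 1.0,
    ("accelerometer", "g"): 9.80665,
    ("gyroscope", "deg/s"): 1.0,
    ("gyroscope", "rad/s"): 180.0 / math.pi,
}


def _load_sidecar(path: Path) -> dict:
    for suffix, loader in ((".meta.json", json.loads), (".meta.yaml", None)):
        side = Path(str(path) + suffix)
        if side.exists():
            text = side.read_text()
            if loader is not None:
                return loader(text)
            import yaml  # lazy; only needed for YAML sidecars

            return yaml.safe_load(text)
    raise ImuParseError(f"no metadata given and no sidecar found for {path}")


def read_imu_csv(path: str | Path, metadata: dict | None = None) -> ImuSeries:
    """Read an IMU stream from ``time,x,y,z`` CSV onto the uniform grid.

    ``metadata`` must declare ``placement``, ``modality``, ``units`` and
    ``sample_rate_hz``; if omitted, a ``<path>.meta.json``/``.meta.yaml``
    sidecar is read.  Values are converted to canonical units.  Gaps wider
    than twice the nominal interval become NaN rows recorded as missing
    spans.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = dict(metadata) if metadata is not None else _load_sidecar(path)
    for key in ("placement", "modality", "units", "sample_rate_hz"):
        if key not in meta:
            raise ImuParseError(f"metadata missing required key {key!r}")
    modality = meta["modality"]
    factor = _UNIT_FACTORS.get((modality, meta["units"]))
    if factor is None:
        raise ImuParseError(
            f"unsupported units {meta['units']!r} for modality {modality!r}"
        )
    rate = float(meta["sample_rate_hz"])

    times: list[float] = []
    rows: list[tuple[float, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ImuParseError(f"{path}: empty file")
        cols = [c.strip().lower() for c in header]
        try:
            it, ix, iy, iz = (cols.index(c) for c in ("time", "x", "y", "z"))
        except ValueError:
            raise ImuParseError(
                f"{path}: header must contain time,x,y,z (got {header})"
            ) from None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                times.append(float(row[it]))
                rows.append((float(row[ix]), float(row[iy]), float(row[iz])))
            except (ValueError, IndexError):
                raise ImuParseError(f"{path}: malformed row at line {lineno}") from None
    if not rows:
        raise ImuParseError(f"{path}: no data rows")

    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise ImuValidationError(f"{path}: time column not strictly increasing")
    vals = np.asarray(rows) * factor

    # Snap observations onto the uniform nominal grid; unfilled grid rows
    # are the missing-data spans.
    idx = np.rint((t - t[0]) * rate).astype(int)
    if np.any(np.diff(idx) < 1):
        raise ImuValidationError(f"{path}: samples collide on the nominal grid")
    n = int(idx[-1]) + 1
    samples = np.full((n, 3), np.nan)
    samples[idx] = vals
    grid_t = t[0] + np.arange(n) / rate
    missing = _nan_spans(samples)
    return ImuSeries(
        timestamps=grid_t,
        samples=samples,
        placement=meta["placement"],
        modality=modality,
        sample_rate_hz=rate,
        missing_spans=missing,
    )


def _nan_spans(samples: np.ndarray) -> list[tuple[int, int]]:
    bad = np.any(np.isnan(samples), axis=1)
    spans = []
    i = 0
    n = len(bad)
    while i < n:
        if bad[i]:
            j = i
            while j < n and bad[j]:
                j += 1
            spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def write_imu_csv(series: ImuSeries, path: str | Path, units: str | None = None) -> None:
    """Write a stream as ``time,x,y,z`` CSV plus a JSON metadata sidecar.

    Missing (NaN) rows are omitted, so a round-trip regenerates the same
    missing spans.
    """
    path = Path(path)
    if units is None:
        units = "m/s2" if series.modality == "accelerometer" else "deg/s"
    factor = _UNIT_FACTORS[(series.modality, units)]
    keep = ~np.any(np.isnan(series.samples), axis=1)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "x", "y", "z"])
        for t, (x, y, z) in zip(series.timestamps[keep], series.samples[keep] / factor):
            w.writerow([f"{t:.6f}", repr(float(x)), repr(float(y)), repr(float(z))])
    meta = {
        "placement": series.placement,
        "modality": series.modality,
        "units": units,
        "sample_rate_hz": series.sample_rate_hz,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# GPX
# ---------------------------------------------------------------------------

_EARTH_RADIUS_M = 6371000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between points in degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_gpx(path: str | Path) -> dict:
    tree = ET.parse(str(path))
    pts = [el for el in tree.iter() if _localname(el.tag) == "trkpt"]
    if not pts:
        raise ValueError(f"{path}: GPX file contains no trackpoints")
    lat, lon, ele, times, hrs, speeds, classes = [], [], [], [], [], [], []
    for pt in pts:
        lat.append(float(pt.attrib["lat"]))
        lon.append(float(pt.attrib["lon"]))
        e = t = None
        hr = sp = np.nan
        cls = None
        for el in pt.iter():
            name = _localname(el.tag)
            if name == "ele":
                e = float(el.text)
            elif name == "time":
                t = datetime.fromisoformat(el.text.replace("Z", "+00:00"))
            elif name == "hr":
                hr = float(el.text)
            elif name == "speed":
                sp = float(el.text)
            elif name == "subtechnique":
                cls = el.text.strip() if el.text else None
        ele.append(e if e is not None else np.nan)
        times.append(t)
        hrs.append(hr)
        speeds.append(sp)
        classes.append(cls)
    return {
        "lat": np.asarray(lat),
        "lon": np.asarray(lon),
        "ele": np.asarray(ele),
        "times": times,
        "hr": np.asarray(hrs),
        "speed": np.asarray(speeds),
        "classes": classes,
    }


def read_gpx(path: str | Path) -> GnssTrack:
    """Read a GPX 1.1 track.

    Speed is taken from a per-point ``speed`` extension if present and
    otherwise derived by finite differences of haversine distance over the
    time steps (0 for a single-point track).  A heart-rate extension
    (``hr`` under any namespace) populates ``heart_rate``.
    """
    raw = _parse_gpx(path)
    n = len(raw["lat"])
    if all(t is not None for t in raw["times"]):
        t0 = raw["times"][0]
        ts = np.asarray([(t - t0).total_seconds() for t in raw["times"]])
        start = t0
    else:
        ts = np.arange(n, dtype=float)
        start = None
    speed = raw["speed"]
    if np.all(np.isnan(speed)):
        speed = np.zeros(n)
        if n > 1:
            d = haversine_m(raw["lat"][:-1], raw["lon"][:-1], raw["lat"][1:], raw["lon"][1:])
            dt = np.diff(ts)
            speed[1:] = d / np.where(dt > 0, dt, np.nan)
            speed[0] = speed[1]
    hr = None if np.all(np.isnan(raw["hr"])) else raw["hr"]
    ele = raw["ele"]
    ele = np.where(np.isnan(ele), 0.0, ele)
    return GnssTrack(ts, raw["lat"], raw["lon"], ele, speed, hr, start)


_GPX_EPOCH = datetime(2024, 1, 6, 10, 0, 0, tzinfo=timezone.utc)


def write_gpx(
    track: GnssTrack,
    path: str | Path,
    classes: Sequence[str | None] | None = None,
) -> None:
    """Write a track as GPX 1.1; per-point class labels go into an
    ``extensions/subtechnique`` tag, heart rate into ``extensions/hr``."""
    gpx = ET.Element("gpx", attrib={
        "version": "1.1",
        "creator": "skitech",
        "xmlns": "http://www.topografix.com/GPX/1/1",
    })
    seg = ET.SubElement(ET.SubElement(gpx, "trk"), "trkseg")
    t0 = track.start_time or _GPX_EPOCH
    for i in range(track.n):
        pt = ET.SubElement(seg, "trkpt", attrib={
            "lat": f"{track.latitude[i]:.7f}",
            "lon": f"{track.longitude[i]:.7f}",
        })
        ET.SubElement(pt, "ele").text = f"{track.altitude[i]:.2f}"
        stamp = t0 + timedelta(seconds=float(track.timestamps[i]))
        ET.SubElement(pt, "time").text = stamp.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"
        ext = ET.SubElement(pt, "extensions")
        ET.SubElement(ext, "speed").text = repr(float(track.speed[i]))
        if track.heart_rate is not None and np.isfinite(track.heart_rate[i]):
            ET.SubElement(ext, "hr").text = f"{track.heart_rate[i]:.0f}"
        if classes is not None and classes[i]:
            ET.SubElement(ext, "subtechnique").text = str(classes[i])
    ET.indent(gpx)
    ET.ElementTree(gpx).write(str(path), encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# Labels and cycles CSV
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> list[tuple[int, SubTechnique]]:
    """Read per-cycle labels from ``cycle,label`` CSV (header optional).

    Tokens are matched case-insensitively; unknown tokens and duplicate
    cycle ordinals raise ``ValueError``.
    """
    out: list[tuple[int, SubTechnique]] = []
    seen: set[int] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and not row[0].strip().lstrip("-").isdigit():
                continue  # header
            try:
                ordinal = int(row[0])
            except ValueError:
                raise ValueError(f"{path}: bad cycle ordinal at line {lineno}") from None
            if ordinal in seen:
                raise ValueError(f"{path}: duplicate cycle ordinal {ordinal}")
            seen.add(ordinal)
            out.append((ordinal, SubTechnique.parse(row[1])))
    return out


def write_labels(pairs: Iterable[tuple[int, SubTechnique]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cycle", "label"])
        for ordinal, label in pairs:
            w.writerow([ordinal, label.value])


def write_cycles_csv(cycles: Sequence[Cycle], path: str | Path,
                     labels: Sequence[SubTechnique] | None = None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["cycle", "start", "end", "duration", "excluded", "partial"]
        if labels is not None:
            header.append("label")
        w.writerow(header)
        for i, c in enumerate(cycles):
            row = [i, c.start, c.end, c.duration_samples, int(c.excluded), int(c.partial)]
            if labels is not None:
                row.append(labels[i].value)
            w.writerow(row)


def read_cycles_csv(path: str | Path) -> tuple[list[Cycle], list[SubTechnique] | None]:
    cycles: list[Cycle] = []
    labels: list[SubTechnique] = []
    has_labels = False
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            cycles.append(Cycle(
                start=int(row["start"]), end=int(row["end"]),
                excluded=bool(int(row.get("excluded", 0))),
                partial=bool(int(row.get("partial", 0))),
            ))
            if row.get("label"):
                has_labels = True
                labels.append(SubTechnique.parse(row["label"]))
    return cycles, (labels if has_labels else None)
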