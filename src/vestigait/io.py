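"""Sensor-recording containers, CSV round trip, synchronization, calibration.

One shank sensor produces a uniformly sampled (50 Hz) 3-axis angular-velocity
stream: x = antigravity, y = walking direction, z = to the subject's right
(the pitch axis of the shank).  Recordings are stored as plain CSV with a
``t,gx,gy,gz`` header (seconds and deg/s) plus an optional YAML sidecar for
walk-level metadata.  Sensors are synchronized by a deliberate shake at the
start of each recording, which shows up as a jump in angular velocity far
larger than anything walking produces between consecutive 20 ms samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (FormatError, NotStationaryError, ParameterError,
                     SyncNotFoundError)

log = logging.getLogger(__name__)

SPACING_TOL = 1e-6  # tolerated timestamp jitter, s
NOMINAL_DT = 0.02   # acquisition interval, s


@dataclass
class AngularVelocitySeries:
    """One sensor's timestamped 3-axis angular-velocity stream."""

    timestamps: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    leg: str
    sensor_id: str = ""

    def __post_init__(self) -> None:
        for name in ("timestamps", "gx", "gy", "gz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.leg not in ("left", "right"):
            raise ParameterError(f"leg must be 'left' or 'right', "
                                 f"got {self.leg!r}")
        n = len(self.timestamps)
        if n < 2:
            raise FormatError("series needs at least 2 samples")
        if any(len(getattr(self, c)) != n for c in ("gx", "gy", "gz")):
            raise FormatError("channel lengths differ")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            raise FormatError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - np.median(dt))) > SPACING_TOL:
            bad = int(np.argmax(np.abs(dt - np.median(dt)))) + 1
            raise FormatError(f"irregular sample spacing at row {bad}")

    @property
    def n(self) -> int:
        return len(self.timestamps)

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.timestamps)))

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def slice_time(self, t0: float, t1: float) -> "AngularVelocitySeries":
        """Samples with t0 ≤ t ≤ t1 (inclusive, grid tolerance 1e-9)."""
        m = (self.timestamps >= t0 - 1e-9) & (self.timestamps <= t1 + 1e-9)
        return AngularVelocitySeries(self.timestamps[m], self.gx[m],
                                     self.gy[m], self.gz[m],
                                     leg=self.leg, sensor_id=self.sensor_id)

    def shifted(self, delta: float) -> "AngularVelocitySeries":
        return AngularVelocitySeries(self.timestamps + delta, self.gx,
                                     self.gy, self.gz, leg=self.leg,
                                     sensor_id=self.sensor_id)


@dataclass
class WalkRecording:
    """Both legs of one corridor walk plus walk-level metadata."""

    left: AngularVelocitySeries
    right: AngularVelocitySeries
    group: str
    lesion_side: str
    corridor_length: float
    subject_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left.leg != "left" or self.right.leg != "right":
            raise ParameterError("leg labels do not match recording slots")
        if self.corridor_length <= 0:
            raise ParameterError("corridor_length must be positive")

    def series(self, leg: str) -> AngularVelocitySeries:
        return self.left if leg == "left" else self.right


def write_series(series: AngularVelocitySeries, path) -> None:
    """Write one sensor stream as ``t,gx,gy,gz`` CSV (full precision)."""
    df = pd.DataFrame({"t": series.timestamps, "gx": series.gx,
                       "gy": series.gy, "gz": series.gz})
    df.to_csv(path, index=False, float_format="%.12g")


def read_series(path, leg: str, sensor_id: str = "",
                ) -> AngularVelocitySeries:
    """Parse a ``t,gx,gy,gz`` CSV (any column order) into a series.

    Timestamp jitter within 1e-6 s is accepted and re-gridded onto a uniform
    axis; anything larger is rejected with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = {"t", "gx", "gy", "gz"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) < 2:
        raise FormatError(f"{path}: fewer than 2 rows")
    for col in ("t", "gx", "gy", "gz"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2  # 1-based incl. header
            raise FormatError(f"{path}: non-numeric value in column "
                              f"{col!r} at line {row}")
        df[col] = vals
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise FormatError(f"{path}: timestamps not increasing")
    dev = np.abs(dt - med)
    if np.any(dev > SPACING_TOL):
        row = int(np.argmax(dev > SPACING_TOL)) + 2
        raise FormatError(f"{path}: irregular sample spacing at line {row}")
    if np.any(dev > 0):
        t = t[0] + np.arange(len(t)) * med  # re-grid sub-µs jitter
    if abs(med - NOMINAL_DT) > SPACING_TOL:
        log.warning("%s: sampling interval %.6f s differs from the nominal "
                    "0.02 s; re-gridding by linear interpolation", path, med)
        new_t = np.arange(t[0], t[-1] + 1e-12, NOMINAL_DT)
        df = pd.DataFrame({c: np.interp(new_t, t, df[c].to_numpy(float))
                           for c in ("gx", "gy", "gz")})
        t = new_t
    return AngularVelocitySeries(t, df["gx"].to_numpy(float),
                                 df["gy"].to_numpy(float),
                                 df["gz"].to_numpy(float),
                                 leg=leg, sensor_id=sensor_id or path.stem)


def detect_sync_start(series: AngularVelocitySeries,
                      jerk_threshold: float = 150.0) -> float:
    """Time of the synchronization shake.

    Returns the timestamp of the first sample whose angular-velocity change
    from the previous sample exceeds ``jerk_threshold`` (deg/s per sample)
    on any axis.  Walking at 50 Hz stays well below the default threshold;
    a deliberate shake exceeds it.
    """
    jumps = np.max(np.abs(np.diff(
        np.column_stack([series.gx, series.gy, series.gz]), axis=0)), axis=1)
    idx = np.flatnonzero(jumps > jerk_threshold)
    if idx.size == 0:
        raise SyncNotFoundError(
            f"no inter-sample change exceeds {jerk_threshold} deg/s "
            f"on sensor {series.sensor_id!r}")
    return float(series.timestamps[idx[0] + 1])


def estimate_offsets(series: AngularVelocitySeries,
                     window: tuple[float, float],
                     max_sd: float = 10.0) -> tuple[float, float, float]:
    """Per-axis stationary zero offsets over a standing-still window.

    The window must last at least 1 s and each axis must be quiet
    (SD < ``max_sd`` deg/s); otherwise the window contains movement and is
    rejected.
    """
    t0, t1 = window
    if t1 - t0 < 1.0:
        raise ParameterError("calibration window must span at least 1 s")
    if t0 < series.timestamps[0] - 1e-9 or t1 > series.timestamps[-1] + 1e-9:
        raise ParameterError("calibration window outside the recording")
    sub = series.slice_time(t0, t1)
    offs = []
    for name in ("gx", "gy", "gz"):
        ch = getattr(sub, name)
        sd = float(np.std(ch))
        if sd >= max_sd:
            raise NotStationaryError(
                f"axis {name} SD {sd:.1f} deg/s in [{t0:.2f}, {t1:.2f}] s "
                f"exceeds {max_sd} deg/s; window is not stationary")
        offs.append(float(np.mean(ch)))
    return tuple(offs)


def align_pair(left: AngularVelocitySeries, right: AngularVelocitySeries,
               jerk_threshold: float = 150.0, group: str = "control",
               lesion_side: str = "none", corridor_length: float = 88.8,
               subject_meta: dict | None = None) -> WalkRecording:
    """Synchronize two sensors on their shake spikes.

    Each series is shifted so its spike time maps to t = 0, then both are
    trimmed to the overlapping span.  Idempotent: aligning an aligned pair
    changes nothing.
    """
    t0_l = detect_sync_start(left, jerk_threshold)
    t0_r = detect_sync_start(right, jerk_threshold)
    left = left.shifted(-t0_l)
    right = right.shifted(-t0_r)
    lo = max(left.timestamps[0], right.timestamps[0])
    hi = min(left.timestamps[-1], right.timestamps[-1])
    if hi - lo <= 0:
        raise ParameterError("aligned series do not overlap")
    return WalkRecording(left=left.slice_time(lo, hi),
                         right=right.slice_time(lo, hi),
                         group=group, lesion_side=lesion_side,
                         corridor_length=corridor_length,
                         subject_meta=subject_meta or {})


def write_recording(recording: WalkRecording, directory) -> None:
    """Write ``left.csv``, ``right.csv`` and a ``meta.yaml`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_series(recording.left, directory / "left.csv")
    write_series(recording.right, directory / "right.csv")
    meta = {
        "group": recording.group,
        "lesion_side": recording.lesion_side,
        "corridor_length_m": float(recording.corridor_length),
        "subject_meta": dict(recording.subject_meta),
        "sensors": {"left": recording.left.sensor_id,
                    "right": recording.right.sensor_id},
    }
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_recording(directory) -> WalkRecording:
    """Read a recording directory written by :func:`write_recording`."""
    directory = Path(directory)
    meta_path = directory / "meta.yaml"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    sensors = meta.get("sensors", {})
    left = read_series(directory / "left.csv", "left",
                       sensors.get("left", ""))
    right = read_series(directory / "right.csv", "right",
                        sensors.get("right", ""))
    return WalkRecording(left=left, right=right,
                         group=meta.get("group", "control"),
                         lesion_side=meta.get("lesion_side", "none"),
                         corridor_length=meta.get("corridor_length_m", 88.8),
                         subject_meta=meta.get("subject_meta", {}) or {})
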