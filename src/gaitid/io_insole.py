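"""Reading, writing and validation of insole recordings.

An insole recording is one participant's raw two-foot sensor stream: per
foot, 8 plantar-pressure channels quantized to levels {0, 1, 2}, a 3-axis
accelerometer and a 3-axis gyroscope, all sampled at a common rate (100 Hz
for the FootLogger-class hardware this package models). On disk a recording
is a pair of CSV files (one per foot) with columns
``time,p1..p8,ax,ay,az,gx,gy,gz``; a dataset manifest is a CSV with columns
``participant_id,left_file,right_file`` whose paths are resolved relative to
the manifest's directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

PRESSURE_LEVELS = (0, 1, 2)
IMU_MIN, IMU_MAX = -32768, 32768

PRESSURE_COLS = [f"p{i}" for i in range(1, 9)]
ACCEL_COLS = ["ax", "ay", "az"]
ROTATION_COLS = ["gx", "gy", "gz"]
ALL_COLS = ["time"] + PRESSURE_COLS + ACCEL_COLS + ROTATION_COLS


class FormatError(ValueError):
    """Raised when a file does not have the expected column layout."""


class ValidationError(ValueError):
    """Raised when sensor values violate the data model ranges."""


@dataclass
class FootChannels:
    """One foot's channel block: pressure (n, 8), accel (n, 3), rotation (n, 3)."""

    pressure: np.ndarray
    accel: np.ndarray
    rotation: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.pressure.shape[0]

    def validate(self, foot: str = "") -> None:
        tag = f"{foot} " if foot else ""
        if self.pressure.ndim != 2 or self.pressure.shape[1] != 8:
            raise ValidationError(f"{tag}pressure must have 8 channels")
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValidationError(f"{tag}accel must have 3 channels")
        if self.rotation.ndim != 2 or self.rotation.shape[1] != 3:
            raise ValidationError(f"{tag}rotation must have 3 channels")
        n = self.pressure.shape[0]
        if n < 1:
            raise ValidationError(f"{tag}recording must contain at least one sample")
        if self.accel.shape[0] != n or self.rotation.shape[0] != n:
            raise ValidationError(f"{tag}channel blocks differ in length")
        bad = ~np.isin(self.pressure, PRESSURE_LEVELS)
        if bad.any():
            row, ch = np.argwhere(bad)[0]
            raise ValidationError(
                f"{tag}pressure channel p{ch + 1} row {row}: value "
                f"{self.pressure[row, ch]} not in {{0, 1, 2}}"
            )
        for name, block, cols in (
            ("accel", self.accel, ACCEL_COLS),
            ("rotation", self.rotation, ROTATION_COLS),
        ):
            bad = (block < IMU_MIN) | (block > IMU_MAX)
            if bad.any():
                row, ch = np.argwhere(bad)[0]
                raise ValidationError(
                    f"{tag}{name} channel {cols[ch]} row {row}: value "
                    f"{block[row, ch]} outside [{IMU_MIN}, {IMU_MAX}]"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FootChannels):
            return NotImplemented
        return (
            np.array_equal(self.pressure, other.pressure)
            and np.array_equal(self.accel, other.accel)
            and np.array_equal(self.rotation, other.rotation)
        )


@dataclass
class InsoleRecording:
    """A participant's validated two-foot multichannel time series."""

    participant_id: str
    sampling_rate_hz: float
    left: FootChannels
    right: FootChannels

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        self.left.validate("left")
        self.right.validate("right")

    def foot(self, foot: str) -> FootChannels:
        if foot not in ("left", "right"):
            raise ValueError(f"foot must be 'left' or 'right', got {foot!r}")
        return self.left if foot == "left" else self.right

    def __eq__(self, other) -> bool:
        if not isinstance(other, InsoleRecording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.left == other.left
            and self.right == other.right
        )


@dataclass(frozen=True)
class ManifestEntry:
    participant_id: str
    left_file: Path
    right_file: Path


def _read_foot_csv(path: Path, fs: float) -> FootChannels:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in ALL_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if not np.issubdtype(df[ALL_COLS[1:]].to_numpy().dtype, np.number):
        raise FormatError(f"{path}: non-numeric sensor values")
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    return FootChannels(
        pressure=df[PRESSURE_COLS].to_numpy(dtype=np.int64),
        accel=df[ACCEL_COLS].to_numpy(dtype=np.int64),
        rotation=df[ROTATION_COLS].to_numpy(dtype=np.int64),
    )


def read_recording(
    left_path: str | Path,
    right_path: str | Path,
    participant_id: str,
    sampling_rate_hz: float = 100.0,
) -> InsoleRecording:
    """Read one participant's left/right foot CSV files into a validated recording.

    Rows are ordered by the ``time`` column; the two feet may have different
    lengths (segmentation treats feet independently).
    """
    left_path, right_path = Path(left_path), Path(right_path)
    for p in (left_path, right_path):
        if not p.exists():
            raise FileNotFoundError(p)
    return InsoleRecording(
        participant_id=participant_id,
        sampling_rate_hz=sampling_rate_hz,
        left=_read_foot_csv(left_path, sampling_rate_hz),
        right=_read_foot_csv(right_path, sampling_rate_hz),
    )


def _write_foot_csv(block: FootChannels, path: Path, fs: float) -> None:
    n = block.n_samples
    df = pd.DataFrame({"time": np.arange(n) / fs})
    for j, c in enumerate(PRESSURE_COLS):
        df[c] = block.pressure[:, j]
    for j, c in enumerate(ACCEL_COLS):
        df[c] = block.accel[:, j]
    for j, c in enumerate(ROTATION_COLS):
        df[c] = block.rotation[:, j]
    df.to_csv(path, index=False)


def write_recording(
    rec: InsoleRecording, left_path: str | Path, right_path: str | Path
) -> tuple[Path, Path]:
    """Write a recording as two per-foot CSV files; round-trips value-exactly."""
    left_path, right_path = Path(left_path), Path(right_path)
    for p in (left_path, right_path):
        p.parent.mkdir(parents=True, exist_ok=True)
    _write_foot_csv(rec.left, left_path, rec.sampling_rate_hz)
    _write_foot_csv(rec.right, right_path, rec.sampling_rate_hz)
    return left_path, right_path


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a dataset manifest CSV and check every referenced file exists."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = ["participant_id", "left_file", "right_file"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    entries: list[ManifestEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for _, row in df.iterrows():
        key = (str(row.participant_id), str(row.left_file), str(row.right_file))
        if key in seen:
            raise FormatError(f"{path}: duplicate manifest entry {key}")
        seen.add(key)
        left = path.parent / str(row.left_file)
        right = path.parent / str(row.right_file)
        for p in (left, right):
            if not p.exists():
                raise FileNotFoundError(f"{path}: referenced file missing: {p}")
        entries.append(ManifestEntry(str(row.participant_id), left, right))
    return entries


def write_manifest(entries: Iterable[ManifestEntry], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "participant_id": e.participant_id,
            "left_file": Path(e.left_file).name,
            "right_file": Path(e.right_file).name,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_dataset(manifest_path: str | Path, sampling_rate_hz: float = 100.0):
    """Read every recording listed in a manifest, in manifest order."""
    return [
        read_recording(e.left_file, e.right_file, e.participant_id, sampling_rate_hz)
        for e in read_manifest(manifest_path)
    ]
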