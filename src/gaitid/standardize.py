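"""Standardization of unit steps into fixed-size training samples.

Detected steps vary in length with cadence; the models need fixed-size
inputs. Every step is resampled to the standard length d — the minimum
step length observed across both feet of all participants (87 in the
cohort this package models) — by cubic-spline interpolation, the two feet
are concatenated column-wise per modality, and optionally k consecutive
steps of a participant are stacked row-wise into one longer sample.

Channel scaling for modelling: pressure levels {0,1,2} map to [0,1] by /2;
accelerometer/gyroscope integers map to [-1,1] by /32768.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .io_insole import IMU_MAX
from .segmentation import UnitStep

MODALITY_WIDTH = {"p": 8, "a": 3, "r": 3}
MODALITIES = ("p", "a", "r")

DEFAULT_STANDARD_LENGTH = 87


@dataclass
class StandardSample:
    """Fixed-format sample: per-modality (k*d) x (w*2) matrices plus label."""

    participant_id: str
    k: int
    d: int
    pressure: np.ndarray | None = None
    accel: np.ndarray | None = None
    rotation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if all(m is None for m in (self.pressure, self.accel, self.rotation)):
            raise ValueError("at least one modality must be present")
        rows = self.k * self.d
        for name, mat, w in (
            ("pressure", self.pressure, 8),
            ("accel", self.accel, 3),
            ("rotation", self.rotation, 3),
        ):
            if mat is None:
                continue
            if mat.shape != (rows, 2 * w):
                raise ValueError(
                    f"{name} must have shape ({rows}, {2 * w}), got {mat.shape}"
                )

    def modality(self, m: str) -> np.ndarray:
        mat = {"p": self.pressure, "a": self.accel, "r": self.rotation}[m]
        if mat is None:
            raise ValueError(f"modality {m!r} absent from sample")
        return mat


def standard_length(steps: list[UnitStep]) -> int:
    """Minimum step length across all provided steps (both feet, everyone)."""
    if not steps:
        raise ValueError("cannot take the standard length of an empty step list")
    return min(len(s) for s in steps)


def resize_channels(values: np.ndarray, d: int) -> np.ndarray:
    """Resample an (n, c) block to d rows via a natural cubic spline.

    Each channel is interpolated independently on evenly spaced positions
    over [0, n-1]; endpoints are reproduced exactly. Blocks shorter than 4
    samples fall back to linear interpolation (a cubic needs 4 knots).
    """
    values = np.asarray(values, dtype=float)
    if d < 2:
        raise ValueError("standard length d must be at least 2")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to resize")
    x_new = np.linspace(0.0, n - 1, d)
    if n < 4:
        x = np.arange(n)
        return np.stack(
            [np.interp(x_new, x, values[:, c]) for c in range(values.shape[1])],
            axis=1,
        )
    spline = CubicSpline(np.arange(n), values, axis=0, bc_type="natural")
    return spline(x_new)


def resize_step(step: UnitStep, d: int) -> dict[str, np.ndarray]:
    """Resample every modality of one step to the standard length."""
    return {
        "p": resize_channels(step.pressure, d),
        "a": resize_channels(step.accel, d),
        "r": resize_channels(step.rotation, d),
    }


def concat_feet(
    left_steps: list[np.ndarray], right_steps: list[np.ndarray]
) -> list[np.ndarray]:
    """Column-concatenate per-step matrices of the two feet: [left | right].

    Lists are paired by index; both sides must share d. Pressure yields 16
    columns, accelerometer/gyroscope 6.
    """
    if len(left_steps) != len(right_steps):
        raise ValueError("left/right step lists must be paired (equal length)")
    out = []
    for lhs, rhs in zip(left_steps, right_steps):
        if lhs.shape[0] != rhs.shape[0]:
            raise ValueError("left/right steps differ in standard length d")
        out.append(np.hstack([lhs, rhs]))
    return out


def pair_feet(
    left: list[UnitStep], right: list[UnitStep]
) -> list[tuple[UnitStep, UnitStep]]:
    """Pair the i-th left step with the i-th right step; drop the remainder."""
    n = min(len(left), len(right))
    return list(zip(left[:n], right[:n]))


def build_standard_samples(
    steps_by_participant: dict[str, dict[str, list[UnitStep]]],
    d: int | None = None,
) -> list[StandardSample]:
    """Resize, concatenate feet, and emit k=1 samples for a whole cohort.

    ``steps_by_participant`` maps participant -> {"left": [...], "right":
    [...]} in temporal order. If ``d`` is None it is taken as the minimum
    step length over the cohort (the standard-length rule).
    """
    if d is None:
        all_steps = [
            s
            for feet in steps_by_participant.values()
            for steps in feet.values()
            for s in steps
        ]
        d = standard_length(all_steps)
    samples: list[StandardSample] = []
    for pid, feet in steps_by_participant.items():
        for lhs, rhs in pair_feet(feet["left"], feet["right"]):
            lres, rres = resize_step(lhs, d), resize_step(rhs, d)
            samples.append(
                StandardSample(
                    participant_id=pid,
                    k=1,
                    d=d,
                    pressure=np.hstack([lres["p"], rres["p"]]),
                    accel=np.hstack([lres["a"], rres["a"]]),
                    rotation=np.hstack([lres["r"], rres["r"]]),
                )
            )
    return samples


def group_k_steps(samples: list[StandardSample], k: int) -> list[StandardSample]:
    """Stack k consecutive k=1 samples per participant into one sample.

    Groups are non-overlapping and in temporal order; a trailing remainder
    of fewer than k steps is discarded. k=1 is the identity.
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    if k == 1:
        return list(samples)
    by_pid: dict[str, list[StandardSample]] = {}
    for s in samples:
        if s.k != 1:
            raise ValueError("group_k_steps expects k=1 input samples")
        by_pid.setdefault(s.participant_id, []).append(s)
    grouped: list[StandardSample] = []
    for pid, seq in by_pid.items():
        for i in range(0, len(seq) - k + 1, k):
            chunk = seq[i : i + k]

            def _stack(m: str) -> np.ndarray | None:
                mats = [getattr(c, m) for c in chunk]
                return None if mats[0] is None else np.vstack(mats)

            grouped.append(
                StandardSample(
                    participant_id=pid,
                    k=k,
                    d=chunk[0].d,
                    pressure=_stack("pressure"),
                    accel=_stack("accel"),
                    rotation=_stack("rotation"),
                )
            )
    return grouped


def scale_modality(mat: np.ndarray, modality: str) -> np.ndarray:
    """Map raw sensor units onto model ranges: p/2 -> [0,1]; IMU/32768 -> [-1,1]."""
    if modality == "p":
        return np.asarray(mat, dtype=np.float32) / 2.0
    return np.asarray(mat, dtype=np.float32) / float(IMU_MAX)
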