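"""Straight-line ablation profiles: data model, kinematics, device validation.

An ablation profile is an ordered, piecewise-constant schedule of probe
position, translation velocity and generator power along a straight
trajectory.  Positions are measured in mm from the entry point (x = 0,
increasing towards the far end of the trajectory), times in seconds, power
in watts.  Pauses are encoded as zero-power segments; stationary dwells as
zero-velocity segments with an explicit dwell time.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DeviceModel",
    "ProfileSegment",
    "AblationProfile",
    "Violation",
    "validate_profile",
    "position_at_time",
    "total_energy",
]

_POS_TOL = 1e-9  # mm; tolerance for contiguity checks


@dataclass(frozen=True)
class DeviceModel:
    """Operating constraints of a microwave ablation generator + drive.

    Defaults describe a generator with 60-140 W output in 20 W increments
    and a maximum of 6 minutes of continuous energy delivery per cycle,
    driven by a robot limited to translation velocities of 0.01-1.0 mm/s.
    """

    allowed_powers: tuple[float, ...] = (60.0, 80.0, 100.0, 120.0, 140.0)
    power_increment: float = 20.0
    max_cycle_duration: float = 360.0
    v_min: float = 0.01
    v_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.allowed_powers:
            raise ValueError("allowed_powers must be non-empty")
        if any(p <= 0 for p in self.allowed_powers):
            raise ValueError("allowed powers must be positive")
        if self.max_cycle_duration <= 0:
            raise ValueError("max_cycle_duration must be positive")
        if not (0 < self.v_min < self.v_max):
            raise ValueError("require 0 < v_min < v_max")
        object.__setattr__(
            self, "allowed_powers", tuple(sorted(float(p) for p in self.allowed_powers))
        )

    def to_dict(self) -> dict:
        return {
            "allowed_powers": list(self.allowed_powers),
            "power_increment": self.power_increment,
            "max_cycle_duration": self.max_cycle_duration,
            "v_min": self.v_min,
            "v_max": self.v_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceModel":
        return cls(
            allowed_powers=tuple(d["allowed_powers"]),
            power_increment=d.get("power_increment", 20.0),
            max_cycle_duration=d.get("max_cycle_duration", 360.0),
            v_min=d.get("v_min", 0.01),
            v_max=d.get("v_max", 1.0),
        )


@dataclass(frozen=True)
class ProfileSegment:
    """One piecewise-constant leg of an ablation profile.

    ``velocity == 0`` marks a stationary dwell: the probe stays at
    ``x_start == x_end`` for ``dwell_time`` seconds.  ``power == 0`` marks a
    pause in energy delivery (moving or stationary).
    """

    x_start: float
    x_end: float
    power: float
    velocity: float
    dwell_time: float = 0.0

    @property
    def is_dwell(self) -> bool:
        return self.velocity == 0.0

    @property
    def is_active(self) -> bool:
        return self.power > 0.0

    @property
    def length(self) -> float:
        return self.x_end - self.x_start

    @property
    def duration(self) -> float:
        if self.is_dwell:
            return self.dwell_time
        return (self.x_end - self.x_start) / self.velocity


@dataclass
class AblationProfile:
    """Ordered, contiguous sequence of :class:`ProfileSegment`.

    ``metadata`` is free-form provenance (planner options, seed, target
    name); it travels through serialization untouched.
    """

    segments: list[ProfileSegment]
    trajectory_length: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segments = list(self.segments)
        if self.trajectory_length is None:
            self.trajectory_length = self.segments[-1].x_end if self.segments else 0.0

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def segment_start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def active_segments(self) -> list[ProfileSegment]:
        return [s for s in self.segments if s.is_active]

    def cycles(self) -> list[list[ProfileSegment]]:
        """Maximal runs of active (nonzero-power) segments."""
        runs: list[list[ProfileSegment]] = []
        current: list[ProfileSegment] = []
        for seg in self.segments:
            if seg.is_active:
                current.append(seg)
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
        return runs

    # ---------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "x_start_mm": s.x_start,
                    "x_end_mm": s.x_end,
                    "power_w": s.power,
                    "velocity_mm_s": s.velocity,
                    "dwell_s": s.dwell_time,
                }
                for s in self.segments
            ],
            "trajectory_length_mm": self.trajectory_length,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AblationProfile":
        segs = [
            ProfileSegment(
                x_start=s["x_start_mm"],
                x_end=s["x_end_mm"],
                power=s["power_w"],
                velocity=s["velocity_mm_s"],
                dwell_time=s.get("dwell_s", 0.0),
            )
            for s in d["segments"]
        ]
        return cls(
            segments=segs,
            trajectory_length=d.get("trajectory_length_mm"),
            metadata=d.get("metadata", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "AblationProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x_start_mm", "x_end_mm", "power_w", "velocity_mm_s", "dwell_s"])
            for s in self.segments:
                writer.writerow([s.x_start, s.x_end, s.power, s.velocity, s.dwell_time])

    @classmethod
    def from_csv(cls, path: str | Path) -> "AblationProfile":
        segs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                segs.append(
                    ProfileSegment(
                        x_start=float(row["x_start_mm"]),
                        x_end=float(row["x_end_mm"]),
                        power=float(row["power_w"]),
                        velocity=float(row["velocity_mm_s"]),
                        dwell_time=float(row.get("dwell_s", 0.0) or 0.0),
                    )
                )
        return cls(segments=segs)


@dataclass(frozen=True)
class Violation:
    """One broken rule, reported (never raised) by :func:`validate_profile`."""

    segment_index: int | None
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = "profile" if self.segment_index is None else f"segment {self.segment_index}"
        return f"[{self.rule}] {where}: {self.message}"


def validate_profile(profile: AblationProfile, device: DeviceModel) -> list[Violation]:
    """Check a profile against structural invariants and device constraints.

    Returns an empty list iff the profile is executable on ``device``.
    Violations name the offending segment index (or ``None`` for
    profile-level rules) and the broken rule.
    """
    out: list[Violation] = []
    allowed = set(device.allowed_powers) | {0.0}
    for i, s in enumerate(profile.segments):
        if s.x_end < s.x_start - _POS_TOL:
            out.append(Violation(i, "position-order", f"x_end {s.x_end} < x_start {s.x_start}"))
        if s.velocity < 0:
            out.append(Violation(i, "velocity-sign", f"negative velocity {s.velocity}"))
        if s.velocity == 0.0:
            if abs(s.x_end - s.x_start) > _POS_TOL:
                out.append(Violation(i, "dwell-motion", "dwell segment must not move"))
            if s.dwell_time <= 0:
                out.append(Violation(i, "dwell-time", "dwell segment needs dwell_time > 0"))
        else:
            if abs(s.x_end - s.x_start) <= _POS_TOL:
                out.append(
                    Violation(i, "zero-length-move", "moving segment must cover distance > 0")
                )
            if s.is_active and not (device.v_min - 1e-12 <= s.velocity <= device.v_max + 1e-12):
                out.append(
                    Violation(
                        i,
                        "velocity-range",
                        f"velocity {s.velocity} outside [{device.v_min}, {device.v_max}]",
                    )
                )
        if s.power < 0:
            out.append(Violation(i, "power-sign", f"negative power {s.power}"))
        elif s.power not in allowed:
            out.append(
                Violation(
                    i,
                    "power-not-allowed",
                    f"power {s.power} W not in allowed set {sorted(allowed)}",
                )
            )
    for i in range(len(profile.segments) - 1):
        a, b = profile.segments[i], profile.segments[i + 1]
        if abs(a.x_end - b.x_start) > _POS_TOL:
            out.append(
                Violation(
                    i + 1,
                    "contiguity",
                    f"x_start {b.x_start} does not continue previous x_end {a.x_end}",
                )
            )
    for j, cycle in enumerate(profile.cycles()):
        active_time = sum(s.duration for s in cycle)
        if active_time > device.max_cycle_duration + 1e-9:
            out.append(
                Violation(
                    None,
                    "max_cycle_duration",
                    f"cycle {j} active time {active_time:.1f} s exceeds "
                    f"{device.max_cycle_duration:.0f} s",
                )
            )
    return out


def position_at_time(profile: AblationProfile, t: float) -> float:
    """Probe position (mm from entry point) at time ``t`` seconds.

    Piecewise linear within moving segments, constant within dwells;
    ``position_at_time(profile, 0) == x_start`` of the first segment.
    """
    total = profile.total_duration
    if not (0.0 <= t <= total + 1e-9):
        raise ValueError(f"t = {t} outside profile duration [0, {total}]")
    elapsed = 0.0
    for s in profile.segments:
        d = s.duration
        if t <= elapsed + d or s is profile.segments[-1]:
            if s.is_dwell or d == 0:
                return s.x_start
            frac = min(max((t - elapsed) / d, 0.0), 1.0)
            return s.x_start + frac * (s.x_end - s.x_start)
        elapsed += d
    return profile.segments[-1].x_end  # pragma: no cover


def total_energy(profile: AblationProfile) -> float:
    """Total delivered energy in kJ; pauses contribute zero."""
    return float(sum(s.power * s.duration for s in profile.segments)) / 1000.0


def split_segment(profile: AblationProfile, index: int, x: float) -> AblationProfile:
    """Split a moving segment at interior position ``x``; kinematics unchanged."""
    s = profile.segments[index]
    if s.is_dwell:
        raise ValueError("cannot split a dwell segment by position")
    if not (s.x_start < x < s.x_end):
        raise ValueError(f"x = {x} not interior to segment {index}")
    left = replace(s, x_end=x)
    right = replace(s, x_start=x)
    segs = profile.segments[:index] + [left, right] + profile.segments[index + 1 :]
    return AblationProfile(segs, profile.trajectory_length, dict(profile.metadata))
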