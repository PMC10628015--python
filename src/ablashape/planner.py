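"""Inverse planning: turn a target axial width function into a device-
constrained power/velocity profile.

The calibrated width model has two degrees of freedom (power, velocity) for
one output (width), so a selection policy resolves the redundancy:

- ``boundary-accuracy`` uses the lowest allowed power whose required
  velocity stays within device limits inside a configurable boundary zone
  at the shape ends (low power + low speed where accuracy matters most)
  and the highest such power in the interior;
- ``max-throughput`` uses the highest feasible power everywhere.

After a power is chosen and snapped to the device's discrete levels, the
velocity is re-solved exactly for the snapped power, so the planned mean
width matches the target up to velocity clamping.  Targets whose active
travel span collapses to a point (spherical targets) are planned as
stationary dwells via an equivalent-velocity model: a dwell of duration
``t`` at power ``P`` is assumed to produce the width of a pass at velocity
``d_ref / t`` (``d_ref`` defaults to 6 mm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ablashape.profiles import AblationProfile, DeviceModel, ProfileSegment
from ablashape.width_model import CalibrationCoefficients, width_mean, width_sd

__all__ = [
    "TargetShape",
    "PlanOptions",
    "PlanResult",
    "PlanInfeasibleError",
    "invert_width",
    "snap_power",
    "dwell_for_width",
    "achievable_envelope",
    "plan_profile",
    "insert_pauses",
    "plan_multi_trajectory",
    "archetype_target",
]


class PlanInfeasibleError(ValueError):
    """Target widths outside the achievable envelope; carries offending
    positions and the envelope."""

    def __init__(self, positions, envelope):
        self.positions = list(positions)
        self.envelope = envelope
        super().__init__(
            f"target width unachievable at x = {self.positions} mm; "
            f"achievable width envelope is [{envelope[0]:.2f}, {envelope[1]:.2f}] mm"
        )


@dataclass
class TargetShape:
    """Desired rotationally symmetric ablation: width vs. axial position.

    ``x`` must be strictly increasing; widths strictly positive.
    ``required_margin`` is carried for downstream margin verification.
    """

    x: np.ndarray
    width: np.ndarray
    required_margin: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.width.shape:
            raise ValueError("x and width must be matching 1-D arrays")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x grid must be strictly increasing")
        if np.any(self.width <= 0):
            raise ValueError("target widths must be strictly positive")
        if self.required_margin < 0:
            raise ValueError("required margin must be >= 0")

    @property
    def length(self) -> float:
        return float(self.x[-1] - self.x[0])

    def width_at(self, x) -> np.ndarray | float:
        out = np.interp(x, self.x, self.width)
        return float(out) if np.ndim(x) == 0 else out


@dataclass(frozen=True)
class PlanOptions:
    """Planner configuration.

    ``policy`` selects the power-redundancy policy; ``boundary_zone_mm``
    the extent of the low-power zone at the target ends under
    ``boundary-accuracy``; ``pause_s`` the duration of inserted zero-power
    pauses; ``trajectory_power_offset`` the power adjustment applied to
    trajectories after the first (the specimen is already heated);
    ``d_ref`` the dwell equivalent-velocity reference length.
    """

    policy: str = "boundary-accuracy"
    boundary_zone_mm: float = 10.0
    insert_pauses: bool = True
    pause_s: float = 30.0
    trajectory_power_offset: float = -20.0
    d_ref: float = 6.0
    grid_mm: float = 1.0
    tol_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.policy not in ("boundary-accuracy", "max-throughput"):
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass
class PlanResult:
    """Planned profile with its per-sample forward predictions."""

    profile: AblationProfile
    x: np.ndarray
    target_width: np.ndarray
    predicted_width: np.ndarray
    predicted_sd: np.ndarray
    power: np.ndarray
    velocity: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def max_abs_error(self) -> float:
        return float(np.max(np.abs(self.predicted_width - self.target_width)))


def invert_width(coeffs: CalibrationCoefficients, w_target: float, power: float) -> float:
    """Velocity [mm/s] at which a pass at ``power`` produces ``w_target``.

    Exact inversion of the log-linear mean model:
    ``v = exp((w - alpha - beta_power*ln P) / beta_velocity)``.
    """
    if coeffs.beta_velocity == 0:
        raise ZeroDivisionError("beta_velocity = 0: width cannot be controlled by velocity")
    if power <= 0:
        raise ValueError("power must be positive")
    return math.exp(
        (w_target - coeffs.alpha - coeffs.beta_power * math.log(power)) / coeffs.beta_velocity
    )


def snap_power(p_continuous: float, device: DeviceModel) -> float:
    """Nearest allowed power level; exact midpoint ties break downward
    (lower power favours boundary accuracy), out-of-range values clamp."""
    if p_continuous <= 0:
        raise ValueError("power must be positive")
    levels = device.allowed_powers
    if p_continuous <= levels[0]:
        return levels[0]
    if p_continuous >= levels[-1]:
        return levels[-1]
    best = levels[0]
    best_d = abs(p_continuous - best)
    for lv in levels[1:]:
        d = abs(p_continuous - lv)
        if d < best_d - 1e-12:  # strictly closer only: ties keep the lower level
            best, best_d = lv, d
    return best


def dwell_for_width(
    coeffs: CalibrationCoefficients,
    power: float,
    w_target: float,
    d_ref: float = 6.0,
    device: DeviceModel | None = None,
) -> float:
    """Stationary dwell time [s] producing ``w_target`` at ``power``.

    Uses the equivalent-velocity model ``v_eq = d_ref / t``: the dwell that
    makes ``v_eq`` equal the inverted velocity.  Capped (with a warning) at
    the device's maximum cycle duration.
    """
    if power <= 0 or w_target <= 0 or d_ref <= 0:
        raise ValueError("power, w_target and d_ref must be positive")
    t = d_ref / invert_width(coeffs, w_target, power)
    if device is not None and t > device.max_cycle_duration:
        warnings.warn(
            f"dwell of {t:.0f} s capped at max cycle duration "
            f"{device.max_cycle_duration:.0f} s",
            stacklevel=2,
        )
        t = device.max_cycle_duration
    return t


def achievable_envelope(
    coeffs: CalibrationCoefficients, device: DeviceModel
) -> tuple[float, float]:
    """(min, max) mean width achievable over allowed powers x [v_min, v_max]."""
    widths = [
        width_mean(coeffs, p, v)
        for p in device.allowed_powers
        for v in (device.v_min, device.v_max)
    ]
    return float(min(widths)), float(max(widths))


def _feasible_power(
    coeffs: CalibrationCoefficients,
    device: DeviceModel,
    w_target: float,
    prefer_low: bool,
    preferred: float | None = None,
) -> tuple[float, float] | None:
    """First allowed power (in policy order) whose exact velocity is within
    device limits; returns (power, velocity) or None."""
    levels = list(device.allowed_powers)
    if not prefer_low:
        levels = levels[::-1]
    if preferred is not None and preferred in levels:
        levels = [preferred] + [lv for lv in levels if lv != preferred]
    for p in levels:
        v = invert_width(coeffs, w_target, p)
        if device.v_min - 1e-12 <= v <= device.v_max + 1e-12:
            return p, float(np.clip(v, device.v_min, device.v_max))
    return None


def _active_span(target: TargetShape, max_iter: int = 100) -> tuple[float, float]:
    """Travel span [x0, x1] such that hemispherical end caps of radius
    w(x0)/2 and w(x1)/2 extend the synthesized shape to the target ends.

    Solved by fixed-point iteration of ``x0 = left + w(x0)/2`` (and
    mirrored on the right)."""
    left, right = float(target.x[0]), float(target.x[-1])
    x0 = left + target.width_at(left) / 2
    x1 = right - target.width_at(right) / 2
    for _ in range(max_iter):
        x0_new = left + target.width_at(min(x0, right)) / 2
        x1_new = right - target.width_at(max(x1, left)) / 2
        if abs(x0_new - x0) < 1e-9 and abs(x1_new - x1) < 1e-9:
            break
        x0, x1 = x0_new, x1_new
    return x0, x1


def _split_into_cycles(
    segments: list[ProfileSegment], device: DeviceModel, pause_s: float
) -> list[ProfileSegment]:
    """Insert zero-power pauses so no active run exceeds the cycle limit.

    Moving segments are split at the position reached when the cycle budget
    runs out."""
    out: list[ProfileSegment] = []
    budget = device.max_cycle_duration
    for seg in segments:
        if not seg.is_active:
            out.append(seg)
            budget = device.max_cycle_duration
            continue
        remaining = seg
        while remaining.duration > budget + 1e-9:
            if remaining.is_dwell:
                first = replace(remaining, dwell_time=budget)
                rest = replace(remaining, dwell_time=remaining.dwell_time - budget)
            else:
                x_split = remaining.x_start + remaining.velocity * budget
                first = replace(remaining, x_end=x_split)
                rest = replace(remaining, x_start=x_split)
            out.append(first)
            out.append(
                ProfileSegment(
                    x_start=first.x_end, x_end=first.x_end, power=0.0,
                    velocity=0.0, dwell_time=pause_s,
                )
            )
            budget = device.max_cycle_duration
            remaining = rest
        out.append(remaining)
        budget -= remaining.duration
    return out


def _merge_segments(segments: list[ProfileSegment]) -> list[ProfileSegment]:
    """Merge adjacent moving segments with identical (P, v) within 1e-6."""
    out: list[ProfileSegment] = []
    for seg in segments:
        if (
            out
            and not seg.is_dwell
            and not out[-1].is_dwell
            and abs(out[-1].power - seg.power) < 1e-6
            and abs(out[-1].velocity - seg.velocity) < 1e-6
            and abs(out[-1].x_end - seg.x_start) < 1e-9
        ):
            out[-1] = replace(out[-1], x_end=seg.x_end)
        else:
            out.append(seg)
    return out


def plan_profile(
    target: TargetShape,
    coeffs: CalibrationCoefficients,
    device: DeviceModel | None = None,
    opts: PlanOptions | None = None,
    _power_offset: float = 0.0,
) -> PlanResult:
    """Plan a device-constrained profile whose forward-simulated mean width
    matches ``target`` at every grid sample within ``opts.tol_mm``.

    Raises :class:`PlanInfeasibleError`, listing the offending positions
    and the achievable envelope, when some sample cannot be met.
    """
    device = device or DeviceModel()
    opts = opts or PlanOptions()
    envelope = achievable_envelope(coeffs, device)
    x0, x1 = _active_span(target)
    prefer_low_everywhere = False

    if x1 - x0 < opts.grid_mm / 2:
        # Spherical/degenerate target: a single stationary dwell at the center
        center = 0.5 * (x0 + x1)
        w_t = float(np.max(target.width))
        choice = _dwell_choice(coeffs, device, opts, w_t, _power_offset)
        if choice is None:
            raise PlanInfeasibleError([center], envelope)
        p, t, v_eq = choice
        seg = ProfileSegment(x_start=center, x_end=center, power=p, velocity=0.0, dwell_time=t)
        profile = AblationProfile(
            [seg], trajectory_length=target.length,
            metadata={"target": target.name, "policy": opts.policy,
                      "power_offset": _power_offset},
        )
        w_pred = width_mean(coeffs, p, v_eq)
        return PlanResult(
            profile=profile,
            x=np.array([center]),
            target_width=np.array([w_t]),
            predicted_width=np.array([w_pred]),
            predicted_sd=np.array([width_sd(coeffs, p, v_eq)]),
            power=np.array([p]),
            velocity=np.array([v_eq]),
            flags=["stationary-dwell"],
        )

    n = int(round((x1 - x0) / opts.grid_mm)) + 1
    xs = np.linspace(x0, x1, max(n, 2))
    half = opts.grid_mm / 2
    powers = np.empty_like(xs)
    vels = np.empty_like(xs)
    flags: list[str] = []
    infeasible_x: list[float] = []
    for i, x in enumerate(xs):
        w_t = float(target.width_at(x))
        near_boundary = (x - x0 <= opts.boundary_zone_mm) or (x1 - x <= opts.boundary_zone_mm)
        prefer_low = opts.policy == "boundary-accuracy" and near_boundary
        choice = _feasible_power(coeffs, device, w_t, prefer_low)
        if choice is None:
            # clamp velocity at the nearest-feasible power; accept within tol
            best = None
            for p in device.allowed_powers:
                v = float(np.clip(invert_width(coeffs, w_t, p), device.v_min, device.v_max))
                err = abs(width_mean(coeffs, p, v) - w_t)
                if best is None or err < best[2]:
                    best = (p, v, err)
            p, v, err = best
            if err > opts.tol_mm:
                infeasible_x.append(float(x))
            else:
                flags.append(f"velocity-clamped at x = {x:.1f} mm (error {err:.2f} mm)")
            choice = (p, v)
        p, v = choice
        if _power_offset:
            p_off = snap_power(max(p + _power_offset, device.allowed_powers[0]), device)
            v_off = invert_width(coeffs, w_t, p_off)
            if device.v_min - 1e-12 <= v_off <= device.v_max + 1e-12:
                p, v = p_off, float(np.clip(v_off, device.v_min, device.v_max))
            else:
                flags.append(f"power offset infeasible at x = {x:.1f} mm, kept {p:g} W")
        powers[i] = p
        vels[i] = v
    if infeasible_x:
        raise PlanInfeasibleError(infeasible_x, envelope)

    # one cell per sample, breakpoints at inter-sample midpoints
    edges = np.concatenate([[x0], 0.5 * (xs[1:] + xs[:-1]), [x1]])
    segs = [
        ProfileSegment(x_start=float(edges[i]), x_end=float(edges[i + 1]),
                       power=float(powers[i]), velocity=float(vels[i]))
        for i in range(len(xs))
        if edges[i + 1] > edges[i] + 1e-12
    ]
    segs = _merge_segments(segs)
    if opts.insert_pauses:
        segs = _split_into_cycles(segs, device, opts.pause_s)
    profile = AblationProfile(
        segs, trajectory_length=target.length,
        metadata={"target": target.name, "policy": opts.policy, "power_offset": _power_offset},
    )
    return PlanResult(
        profile=profile,
        x=xs,
        target_width=target.width_at(xs),
        predicted_width=width_mean(coeffs, powers, vels),
        predicted_sd=width_sd(coeffs, powers, vels),
        power=powers,
        velocity=vels,
        flags=flags,
    )


def _dwell_choice(coeffs, device, opts, w_target, power_offset):
    """Pick (power, dwell_time, v_eq) for a stationary plan under policy."""
    levels = list(device.allowed_powers)
    if opts.policy == "boundary-accuracy":
        levels = levels  # a dwell is all boundary: lowest power first
    else:
        levels = levels[::-1]
    chosen = None
    for p in levels:
        v_eq = invert_width(coeffs, w_target, p)
        t = opts.d_ref / v_eq
        if 0 < t <= device.max_cycle_duration and v_eq <= device.v_max:
            chosen = p
            break
    if chosen is None:
        return None
    if power_offset:
        p_off = snap_power(max(chosen + power_offset, device.allowed_powers[0]), device)
        v_eq = invert_width(coeffs, w_target, p_off)
        t = opts.d_ref / v_eq
        if 0 < t <= device.max_cycle_duration and v_eq <= device.v_max:
            chosen = p_off
    v_eq = invert_width(coeffs, w_target, chosen)
    return chosen, opts.d_ref / v_eq, v_eq


def insert_pauses(
    profile: AblationProfile, boundaries: Sequence[float], pause_s: float = 30.0
) -> AblationProfile:
    """Insert zero-power dwell pauses at the given positions.

    Segments spanning a boundary are split there; active content is
    unchanged, so total energy and the position-time law (up to inserted
    holds) are preserved."""
    if not profile.segments:
        raise ValueError("empty profile")
    lo = profile.segments[0].x_start
    hi = profile.segments[-1].x_end
    segs = list(profile.segments)
    for b in sorted(boundaries):
        if not (lo <= b <= hi):
            raise ValueError(f"boundary {b} outside trajectory span [{lo}, {hi}]")
        new_segs: list[ProfileSegment] = []
        inserted = False
        for seg in segs:
            if not inserted and not seg.is_dwell and seg.x_start < b < seg.x_end:
                new_segs.append(replace(seg, x_end=b))
                new_segs.append(ProfileSegment(b, b, 0.0, 0.0, pause_s))
                new_segs.append(replace(seg, x_start=b))
                inserted = True
            elif not inserted and seg.x_end == b and seg.is_active:
                new_segs.append(seg)
                new_segs.append(ProfileSegment(b, b, 0.0, 0.0, pause_s))
                inserted = True
            else:
                new_segs.append(seg)
        segs = new_segs
    return AblationProfile(segs, profile.trajectory_length, dict(profile.metadata))


def plan_multi_trajectory(
    targets: Sequence[TargetShape],
    coeffs: CalibrationCoefficients,
    device: DeviceModel | None = None,
    opts: PlanOptions | None = None,
) -> list[PlanResult]:
    """Plan one profile per target; trajectories after the first get their
    powers offset by ``opts.trajectory_power_offset`` (default -20 W, the
    specimen being pre-heated), then snapped, wherever feasible."""
    if not targets:
        raise ValueError("need at least one target")
    opts = opts or PlanOptions()
    device = device or DeviceModel()
    results = []
    for k, target in enumerate(targets):
        offset = opts.trajectory_power_offset if k > 0 else 0.0
        results.append(plan_profile(target, coeffs, device, opts, _power_offset=offset))
    return results


def archetype_target(name: str, grid_mm: float = 1.0, **dims) -> TargetShape:
    """Parametric target shapes for typical liver-tumor configurations.

    - ``elongated``: constant-width cylinder (``length``, ``width``);
    - ``dumbbell``: two bulges with a waist (``length``, ``lobe_widths``,
      ``waist_width``);
    - ``teardrop``: monotone taper (``length``, ``width_start``,
      ``width_end``);
    - ``connected_spheres``: two equal spherical lobes at the span ends
      joined by a neck (``length``, ``lobe_width``, ``neck_width``).
    """
    if name == "elongated":
        length = float(dims.get("length", 75.0))
        width = float(dims.get("width", 20.0))
        x = np.arange(0.0, length + grid_mm / 2, grid_mm)
        return TargetShape(x, np.full_like(x, width), name="elongated")
    if name == "dumbbell":
        length = float(dims.get("length", 63.0))
        w1, w2 = dims.get("lobe_widths", (26.0, 26.0))
        waist = float(dims.get("waist_width", 9.0))
        x = np.arange(0.0, length + grid_mm / 2, grid_mm)
        h = length / 4.0
        c1, c2 = length / 4.0, 3.0 * length / 4.0

        def bump(c):
            u = np.clip(np.abs(x - c) / h, 0.0, 1.0)
            return np.cos(np.pi * u / 2.0) ** 2

        w = waist + np.maximum((w1 - waist) * bump(c1), (w2 - waist) * bump(c2))
        return TargetShape(x, w, name="dumbbell")
    if name == "teardrop":
        length = float(dims.get("length", 68.0))
        w_start = float(dims.get("width_start", 25.0))
        w_end = float(dims.get("width_end", 17.0))
        x = np.arange(0.0, length + grid_mm / 2, grid_mm)
        w = w_start + (w_end - w_start) * x / length
        return TargetShape(x, w, name="teardrop")
    if name == "connected_spheres":
        length = float(dims.get("length", 91.0))
        lobe = float(dims.get("lobe_width", 22.0))
        neck = float(dims.get("neck_width", 8.0))
        r = lobe / 2.0
        c1, c2 = r, length - r
        x = np.arange(0.0, length + grid_mm / 2, grid_mm)

        def sphere(c):
            d2 = r**2 - (x - c) ** 2
            return 2.0 * np.sqrt(np.maximum(d2, 0.0))

        w = np.maximum(sphere(c1), sphere(c2))
        w = np.where((x >= c1) & (x <= c2), np.maximum(w, neck), w)
        w = np.maximum(w, 1e-3)  # strictly positive at the very tips
        return TargetShape(x, w, name="connected_spheres")
    raise ValueError(f"unknown archetype {name!r}")
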