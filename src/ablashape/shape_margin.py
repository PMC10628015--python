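"""Forward shape synthesis, voxelization and ablation-margin metrics.

The ablation produced by a straight-line profile is modelled as a
rotationally symmetric solid around the trajectory axis: at each axial
position inside the active travel span the transverse diameter is the
calibrated mean width for the (power, velocity) in force when the probe
passes, and hemispherical end caps with the local half-width radius close
the span ends.  Voxel masks of such shapes (and their unions, for
multi-trajectory plans) are compared against tumor masks by
distance-transform margin metrics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ablashape.profiles import AblationProfile
from ablashape.width_model import CalibrationCoefficients, width_mean, width_sd

__all__ = [
    "AblationShape",
    "RasterMask",
    "MarginReport",
    "synthesize_shape",
    "rasterize",
    "union_masks",
    "margin_metrics",
]


class EmptyShapeError(ValueError):
    pass


@dataclass
class AblationShape:
    """Axial width function of a rotationally symmetric ablation.

    ``x`` spans the active travel span; ``width``/``sd`` are the mean and
    sd of the transverse diameter there.  ``cap_model`` describes how the
    span ends are closed (hemispherical caps of radius width/2 by default),
    so the full shape extends ``width[0]/2`` before ``x[0]`` and
    ``width[-1]/2`` past ``x[-1]``.
    """

    x: np.ndarray
    width: np.ndarray
    sd: np.ndarray
    cap_model: str = "hemispherical"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.width <= 0):
            raise ValueError("widths must be positive on the active span")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")

    @property
    def cap_radii(self) -> tuple[float, float]:
        return float(self.width[0] / 2), float(self.width[-1] / 2)

    @property
    def total_length(self) -> float:
        r0, r1 = self.cap_radii
        return float(self.x[-1] - self.x[0]) + r0 + r1

    @property
    def max_width(self) -> float:
        return float(np.max(self.width))

    def width_at(self, x) -> np.ndarray | float:
        out = np.interp(x, self.x, self.width)
        return float(out) if np.ndim(x) == 0 else out


@dataclass
class RasterMask:
    """Boolean voxel mask with isotropic spacing and a physical origin.

    ``volume`` is indexed (x, y, z) with the trajectory along axis 0;
    ``slice2d`` is the z = 0 plane.
    """

    volume: np.ndarray
    spacing: float
    origin: tuple[float, float, float]

    @property
    def slice2d(self) -> np.ndarray:
        return self.volume[:, :, self.volume.shape[2] // 2]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.volume.sum()) * self.spacing**3

    def same_grid(self, other: "RasterMask") -> bool:
        return (
            self.volume.shape == other.volume.shape
            and abs(self.spacing - other.spacing) < 1e-12
            and np.allclose(self.origin, other.origin)
        )


def synthesize_shape(
    profile: AblationProfile,
    coeffs: CalibrationCoefficients,
    grid_mm: float = 0.5,
    d_ref: float = 6.0,
) -> AblationShape:
    """Forward-simulate the mean ablation shape of a profile.

    Each axial sample takes the width of the (power, velocity) in force
    when the probe passes it; dwells use the equivalent velocity
    ``d_ref / dwell_time``.  Where several active passes cover a sample
    the envelope (pointwise maximum width) wins.  Pauses contribute
    nothing.
    """
    active = profile.active_segments()
    if not active:
        raise EmptyShapeError("profile has no active (nonzero-power) segments")
    lo = min(s.x_start for s in active)
    hi = max(s.x_end for s in active)
    n = max(int(round((hi - lo) / grid_mm)) + 1, 1)
    xs = np.linspace(lo, hi, n)
    w = np.zeros_like(xs)
    sd = np.zeros_like(xs)
    for s in active:
        if s.is_dwell:
            v_eff = d_ref / s.dwell_time
            mask = np.abs(xs - s.x_start) <= grid_mm / 2 + 1e-12
            if not mask.any():
                mask = np.abs(xs - s.x_start) == np.min(np.abs(xs - s.x_start))
        else:
            v_eff = s.velocity
            mask = (xs >= s.x_start - 1e-12) & (xs <= s.x_end + 1e-12)
        wi = width_mean(coeffs, s.power, v_eff)
        si = width_sd(coeffs, s.power, v_eff)
        upd = mask & (wi > w)
        w[upd] = wi
        sd[upd] = si
    keep = w > 0
    if not keep.any():
        raise EmptyShapeError("no axial sample received positive width")
    return AblationShape(x=xs[keep], width=w[keep], sd=sd[keep])


def rasterize(shape: AblationShape, spacing: float = 0.5, pad_mm: float = 2.0) -> RasterMask:
    """Voxelize the rotational sweep of an :class:`AblationShape`.

    A voxel center is inside iff its radial distance from the axis is at
    most the local half-width (within the active span) or it lies within a
    hemispherical end cap.  The grid is isotropic and symmetric about the
    axis so the z = 0 slice is an exact axial cross-section.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > np.min(shape.width) / 2:
        warnings.warn(
            f"spacing {spacing} mm exceeds half the minimum width "
            f"{np.min(shape.width):.2f} mm; mask will be poorly resolved",
            stacklevel=2,
        )
    r0, r1 = shape.cap_radii
    x_lo = shape.x[0] - r0 - pad_mm
    x_hi = shape.x[-1] + r1 + pad_mm
    r_max = shape.max_width / 2 + pad_mm
    xs = np.arange(x_lo, x_hi + spacing / 2, spacing)
    half = int(np.ceil(r_max / spacing))
    ys = np.arange(-half, half + 1) * spacing
    zs = ys.copy()
    rho2 = ys[:, None] ** 2 + zs[None, :] ** 2
    half_w = np.interp(xs, shape.x, shape.width) / 2.0
    in_span = (xs >= shape.x[0]) & (xs <= shape.x[-1])
    vol = in_span[:, None, None] & (rho2[None, :, :] <= half_w[:, None, None] ** 2)
    for cap_x, cap_r, side in ((shape.x[0], r0, -1), (shape.x[-1], r1, +1)):
        ax = side * (xs - cap_x)
        outside = ax > 0
        cap = outside[:, None, None] & (
            (xs - cap_x)[:, None, None] ** 2 + rho2[None, :, :] <= cap_r**2
        )
        vol |= cap
    return RasterMask(volume=vol, spacing=spacing, origin=(float(xs[0]), float(ys[0]), float(zs[0])))


def union_masks(masks: list[RasterMask]) -> RasterMask:
    """Voxelwise OR of co-registered masks (multi-trajectory superposition)."""
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    out = first.volume.copy()
    for m in masks[1:]:
        if not first.same_grid(m):
            raise ValueError("masks are not on the same grid")
        out |= m.volume
    return RasterMask(volume=out, spacing=first.spacing, origin=first.origin)


@dataclass
class MarginReport:
    """Quantitative ablation-margin verification result.

    ``minimal_margin_mm`` is the signed distance from the ablation boundary
    at the worst tumor voxel: positive when the whole tumor sits strictly
    inside the ablation, negative when tumor tissue remains outside.
    ``over_ablation_ratio`` is the fraction of ablated volume beyond the
    tumor grown by the required margin.
    """

    minimal_margin_mm: float
    coverage: float
    over_ablation_ratio: float
    dice: float
    required_margin_mm: float = 0.0
    tumor_volume_mm3: float = 0.0
    ablation_volume_mm3: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def margin_metrics(
    ablation: np.ndarray | RasterMask,
    tumor: np.ndarray | RasterMask,
    spacing: float | None = None,
    required_margin: float = 0.0,
) -> MarginReport:
    """Compare an ablation mask against a tumor mask.

    The signed margin at a voxel is ``edt_inside - spacing`` inside the
    ablation (zero exactly at ablation-boundary voxels) and ``-edt_outside``
    beyond it, evaluated at every tumor voxel; the minimum is reported.
    Coverage is the ablated fraction of tumor voxels; Dice compares the
    ablation with the tumor grown by ``required_margin``.
    """
    if isinstance(ablation, RasterMask):
        if spacing is None:
            spacing = ablation.spacing
        ablation = ablation.volume
    if isinstance(tumor, RasterMask):
        tumor = tumor.volume
    if spacing is None:
        raise ValueError("spacing must be given for raw arrays")
    ablation = np.asarray(ablation, dtype=bool)
    tumor = np.asarray(tumor, dtype=bool)
    if ablation.shape != tumor.shape:
        raise ValueError("ablation and tumor masks must share one grid")
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("tumor mask is empty")
    n_abl = int(ablation.sum())
    coverage = float((tumor & ablation).sum()) / n_tumor

    if n_abl == 0:
        diag = float(np.linalg.norm(np.array(tumor.shape) * spacing))
        minimal_margin = -diag
        over = 0.0
        dice = 0.0
    else:
        d_in = ndimage.distance_transform_edt(ablation, sampling=spacing)
        d_out = ndimage.distance_transform_edt(~ablation, sampling=spacing)
        signed = np.where(ablation, d_in - spacing, -d_out)
        minimal_margin = float(signed[tumor].min())
        dist_to_tumor = ndimage.distance_transform_edt(~tumor, sampling=spacing)
        tumor_plus = tumor | (dist_to_tumor <= required_margin + 1e-9)
        over_vox = int((ablation & ~tumor_plus).sum())
        over = over_vox / n_abl
        inter = int((ablation & tumor_plus).sum())
        dice = 2.0 * inter / (n_abl + int(tumor_plus.sum()))
    return MarginReport(
        minimal_margin_mm=minimal_margin,
        coverage=coverage,
        over_ablation_ratio=over,
        dice=dice,
        required_margin_mm=required_margin,
        tumor_volume_mm3=n_tumor * spacing**3,
        ablation_volume_mm3=n_abl * spacing**3,
    )
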