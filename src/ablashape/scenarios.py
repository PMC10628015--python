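"""Seeded end-to-end demo scenarios and run provenance.

Each scenario plans, simulates, rasterizes, margin-checks, renders and
re-measures one representative treatment configuration:

- ``cylinder``: constant velocity and power (elongated/cylindrical target);
- ``dumbbell``: dumbbell target (wide lobes with a narrow waist, pauses
  between active cycles);
- ``teardrop``: teardrop target (tapering width, power decreasing towards the
  narrow end under the boundary-accuracy policy);
- ``spheres``: multi-trajectory plan of two spherical lobes as sequential
  stationary ablations, the second at 20 W less because the specimen is
  already heated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import ablashape
from ablashape.planner import (
    PlanOptions,
    archetype_target,
    plan_multi_trajectory,
    plan_profile,
)
from ablashape.phantom_imaging import DEFAULT_NOISE, measure_specimen, render_specimen, save_image
from ablashape.profiles import DeviceModel, validate_profile
from ablashape.shape_margin import margin_metrics, rasterize, synthesize_shape, union_masks
from ablashape.width_model import DEFAULT_COEFFS, CalibrationCoefficients

__all__ = ["RunConfig", "SCENARIOS", "run_scenario", "version_manifest"]

SCENARIOS = ("cylinder", "dumbbell", "teardrop", "spheres")


@dataclass
class RunConfig:
    """Configuration of a scenario run; all randomness flows from ``seed``."""

    coeffs: CalibrationCoefficients = DEFAULT_COEFFS
    device: DeviceModel = field(default_factory=DeviceModel)
    raster_spacing: float = 1.0
    image_spacing: float = 0.25
    marker_side: float = 10.0
    noise: float = DEFAULT_NOISE
    seed: int = 0
    out_dir: str | Path | None = None

    def to_dict(self) -> dict:
        return {
            "coeffs": {n: getattr(self.coeffs, n) for n in
                       ("alpha", "beta_power", "beta_velocity", "eps", "eps_power",
                        "eps_velocity")},
            "device": self.device.to_dict(),
            "raster_spacing": self.raster_spacing,
            "image_spacing": self.image_spacing,
            "marker_side": self.marker_side,
            "noise": self.noise,
            "seed": self.seed,
        }


def version_manifest(config: RunConfig) -> dict:
    """Deterministic provenance record: package version, config hash, seed."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return {
        "package": "ablashape",
        "version": ablashape.__version__,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
    }


def _scenario_plans(name: str, config: RunConfig):
    coeffs, device = config.coeffs, config.device
    if name == "cylinder":
        target = archetype_target("elongated")
        opts = PlanOptions(policy="max-throughput")
        return [plan_profile(target, coeffs, device, opts)], [target]
    if name == "dumbbell":
        target = archetype_target("dumbbell")
        opts = PlanOptions(policy="boundary-accuracy")
        return [plan_profile(target, coeffs, device, opts)], [target]
    if name == "teardrop":
        target = archetype_target("teardrop")
        opts = PlanOptions(policy="boundary-accuracy")
        return [plan_profile(target, coeffs, device, opts)], [target]
    if name == "spheres":
        full = archetype_target("connected_spheres")
        lobe = float(full.width.max())
        r = lobe / 2.0
        length = full.length
        sphere1 = archetype_target("connected_spheres", length=lobe, lobe_width=lobe,
                                   neck_width=1e-3)
        sphere1.name = "spheres-lobe1"
        sphere2 = archetype_target("connected_spheres", length=lobe, lobe_width=lobe,
                                   neck_width=1e-3)
        sphere2.name = "spheres-lobe2"
        # second lobe sits at the far end of the common trajectory
        sphere2.x = sphere2.x + (length - lobe)
        opts = PlanOptions(policy="max-throughput")
        results = plan_multi_trajectory([sphere1, sphere2], coeffs, device, opts)
        return results, [sphere1, sphere2]
    raise ValueError(f"unknown scenario {name!r}; choose one of {SCENARIOS}")


def run_scenario(name: str, config: RunConfig | None = None) -> dict:
    """Run one end-to-end scenario; returns (and optionally writes) the bundle.

    The bundle holds the planned profile(s), synthesized shape(s), union
    voxel mask, margin report against the target's own rasterization, a
    rendered synthetic specimen of the first shape, and its re-measured
    width profile, plus a provenance manifest.
    """
    config = config or RunConfig()
    plans, targets = _scenario_plans(name, config)
    coeffs = config.coeffs
    shapes = [synthesize_shape(p.profile, coeffs, grid_mm=min(config.raster_spacing, 1.0))
              for p in plans]
    masks = [rasterize(s, spacing=config.raster_spacing) for s in shapes]

    # reference tumor mask: the target's own rotational rasterization
    from ablashape.shape_margin import AblationShape

    from ablashape.planner import _active_span

    target_shapes = []
    for t in targets:
        x0, x1 = _active_span(t)
        if x1 - x0 < 0.5:
            c = 0.5 * (t.x[0] + t.x[-1])
            w = float(t.width.max())
            target_shapes.append(AblationShape(np.array([c]), np.array([w]), np.array([0.0])))
        else:
            xs = np.linspace(x0, x1, max(int(round(x1 - x0)) + 1, 2))
            target_shapes.append(
                AblationShape(xs, np.asarray(t.width_at(xs)), np.zeros_like(xs))
            )
    t_masks = [rasterize(s, spacing=config.raster_spacing) for s in target_shapes]

    embedded = _common_grid(masks + t_masks)
    masks = embedded[: len(masks)]
    t_masks = embedded[len(masks) :]
    ablation = union_masks(masks)
    tumor = union_masks(t_masks)
    report = margin_metrics(ablation, tumor, spacing=config.raster_spacing)

    specimen = render_specimen(
        shapes[0], spacing=config.image_spacing, marker_side=config.marker_side,
        noise=config.noise, seed=config.seed,
    )
    measurement = measure_specimen(specimen)
    manifest = version_manifest(config)
    manifest["scenario"] = name

    bundle = {
        "name": name,
        "plans": plans,
        "shapes": shapes,
        "ablation_mask": ablation,
        "tumor_mask": tumor,
        "margin_report": report,
        "specimen": specimen,
        "measurement": measurement,
        "manifest": manifest,
    }
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir), config)
    return bundle


def _common_grid(masks):
    """Embed co-axial masks into one shared grid (axial extent and
    transverse half-size are the union over all masks)."""
    from ablashape.shape_margin import RasterMask

    s = masks[0].spacing
    lo = min(m.origin[0] for m in masks)
    hi = max(m.origin[0] + (m.volume.shape[0] - 1) * s for m in masks)
    nx = int(round((hi - lo) / s)) + 1
    half = max(m.volume.shape[1] // 2 for m in masks)
    ny = 2 * half + 1
    out = []
    for m in masks:
        vol = np.zeros((nx, ny, ny), dtype=bool)
        x_off = int(round((m.origin[0] - lo) / s))
        t_off = half - m.volume.shape[1] // 2
        vol[
            x_off : x_off + m.volume.shape[0],
            t_off : t_off + m.volume.shape[1],
            t_off : t_off + m.volume.shape[2],
        ] = m.volume
        out.append(
            RasterMask(volume=vol, spacing=s, origin=(lo, -half * s, -half * s))
        )
    return out


def _write_bundle(bundle: dict, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    name = bundle["name"]
    for i, plan in enumerate(bundle["plans"]):
        plan.profile.to_json(out_dir / f"{name}_profile_{i}.json")
        plan.profile.to_csv(out_dir / f"{name}_profile_{i}.csv")
    for i, shape in enumerate(bundle["shapes"]):
        arr = np.column_stack([shape.x, shape.width, shape.sd])
        header = "x_mm,width_mm,sd_mm"
        np.savetxt(out_dir / f"{name}_shape_{i}.csv", arr, delimiter=",",
                   header=header, comments="", fmt="%.6f")
    bundle["margin_report"].to_json(out_dir / f"{name}_margin.json")
    save_image(bundle["specimen"], out_dir / f"{name}_specimen.png")
    save_image(bundle["measurement"].mask, out_dir / f"{name}_segmentation.png")
    m = bundle["measurement"]
    np.savetxt(out_dir / f"{name}_widths.csv",
               np.column_stack([m.x_mm, m.width_mm]), delimiter=",",
               header="x_mm,width_mm", comments="", fmt="%.6f")
    (out_dir / f"{name}_manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2, sort_keys=True)
    )
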