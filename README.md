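# ablashape

Planning and analysis toolkit for **dynamic energy delivery** in thermal
tumor ablation: shaping the coagulation volume by translating a microwave
ablation probe along a straight trajectory while modulating generator power
and translation velocity.

Standard microwave ablation produces roughly ellipsoidal volumes whose radii
cannot be controlled independently, which forces a "nearest fit" for the
irregular tumor shapes common in the liver. If instead the probe is pulled
back along its trajectory at velocity `v(x)` while the generator runs at
power `P(x)`, the coagulated zone becomes an elongated, rotationally
symmetric solid whose local transverse diameter (the *ablation width*) can
be steered point by point. This package provides the computational side of
that workflow for researchers prototyping such systems:

- **Width model.** The calibrated log-linear model
  `width = α + β_power·ln P + β_velocity·ln v` with heteroscedastic
  observation noise `σ = ε + ε_power·P + ε_velocity·v`, alongside the
  physical reference model `width ∝ √(P/v)`.
- **Calibration.** Bayesian fitting of all six coefficients from
  `(power, velocity, width)` observations by ensemble MCMC with R-hat/ESS
  diagnostics, plus a simulator of calibration experiments and a
  scikit-learn-compatible estimator (`WidthRegressor`).
- **Inverse planning.** Device-constrained power/velocity profiles for
  target axial width functions (discrete power levels, velocity limits,
  per-cycle duration limits, pauses, stationary dwells, multi-trajectory
  plans with a reduced-power second pass).
- **Shape synthesis and margins.** Forward simulation of the rotationally
  symmetric ablation shape, voxelization with hemispherical end caps, mask
  unions, and distance-transform margin metrics (minimal signed margin,
  coverage, over-ablation ratio, Dice).
- **Phantom imaging.** Synthetic photographs of cut thermochromic-phantom
  specimens (magenta ablation zone, square fiducial markers) and the
  measurement chain: fiducial-based pixel spacing, color segmentation, and
  principal-axis width-profile extraction.

## Worked example

Plan a teardrop-shaped ablation (68 mm long, tapering from 25 mm to 17 mm
width) and check the plan by forward simulation:

```python
from ablashape import (DEFAULT_COEFFS, DeviceModel, PlanOptions,
                       archetype_target, plan_profile, synthesize_shape)

target = archetype_target("teardrop", length=68.0, width_start=25.0, width_end=17.0)
plan = plan_profile(target, DEFAULT_COEFFS, DeviceModel(), PlanOptions())
print(f"segments: {len(plan.profile.segments)}")
print(f"powers used: {sorted(set(plan.power.tolist()))} W")
print(f"velocity range: {plan.velocity.min():.3f}-{plan.velocity.max():.3f} mm/s")
print(f"max planned width error: {plan.max_abs_error:.2e} mm")
shape = synthesize_shape(plan.profile, DEFAULT_COEFFS)
print(f"simulated shape: length {shape.total_length:.1f} mm, "
      f"widths {shape.width.min():.1f}-{shape.width.max():.1f} mm")
```

```
segments: 52
powers used: [60.0, 140.0] W
velocity range: 0.013-0.258 mm/s
max planned width error: 3.55e-15 mm
simulated shape: length 68.0 mm, widths 18.1-23.6 mm
```

The planner runs the low-power setting (60 W, slow motion) inside the
10 mm boundary zones where placement accuracy matters most and the
high-power setting (140 W) in the interior, re-solving the velocity exactly
after snapping power to the generator's 20 W increments — hence the
numerically zero planned-width error. The simulated active span is shorter
than 68 mm because hemispherical end caps (radius = local width/2) close
the shape to the full target length; widths at the very ends are carried by
the caps.

The same operations are available from a CLI
(`ablashape synth | calibrate | predict | plan | simulate | margin |
segment | scenario`), e.g.:

```sh
ablashape synth --out obs.csv --seed 1
ablashape calibrate --in obs.csv --out posterior.json --chains 4 --draws 1000 --seed 1
ablashape plan --target target.json --coeffs posterior.json --out profile.json
```

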