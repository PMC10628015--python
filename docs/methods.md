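# Methods

## The width model

The package treats the coagulation zone created by a moving microwave
probe as a rotationally symmetric solid around the (straight) trajectory.
Its local transverse diameter — the *ablation width*, in mm — is modelled
as a function of the generator power `P` [W] and the probe translation
velocity `v` [mm/s] at the moment the probe passes that position.

Two model families are exposed:

- **Physical reference model.**
  `width = (1/√(β_device·β_tissue)) · √(P/v)`, where `β_device` captures
  the device's energy-delivery efficiency and `β_tissue` how much width the
  tissue produces per unit of deposited energy. Because the interaction
  between tissue and applied energy is not predictable from imaging or
  biopsy, this model is kept as a reference only — note that
  `ln(width)` is affine in `(ln P, ln v)` with slopes ±1/2, the same
  functional form the calibrated model generalizes.
- **Calibrated model** (used for everything else):

  ```
  μ(P, v) = α + β_power·ln P + β_velocity·ln v
  σ(P, v) = ε + ε_power·P + ε_velocity·v
  width ~ Normal(μ, σ)
  ```

  Logarithms are natural throughout (a module-level constant in the sense
  that every consumer of coefficients uses the same convention, so a
  calibration is self-consistent by construction). The noise model is
  heteroscedastic: wider ablations made at high power are also more
  variable, which is exactly why the planner prefers low power near shape
  boundaries.

*Width* always means the full diameter; rasterization uses radius =
width/2.

## Calibration

`simulate_calibration` draws observations from the generative model over a
factorial design; the default design is four power levels (60, 80, 100,
120 W) crossed with eight velocities evenly spaced in [0.05, 0.12] mm/s,
run over 35 mm of travel. Widths that would sample ≤ 0 are resampled
(truncation at zero, logged) — irrelevant in practice because widths in
the design range sit far from zero.

`fit_calibration` samples the six-coefficient posterior with an
affine-invariant ensemble sampler (emcee), vectorized over walkers.
Priors are Normal(0, scale) on (α, β_power, β_velocity) with scales 50,
10, 10 mm and Exponential(rate 1) on the non-negative noise coefficients —
weakly informative at the mm scale of the data and dominated by even one
replicate of the default design. Each chain (default 4) is an independent
16-walker ensemble, started in a tight ball around the MAP estimate
(Nelder–Mead on the log posterior from an OLS start) and run for a warmup
period (default 500 steps) before draws are retained. Split-R-hat and
effective sample size are computed with ArviZ; R-hat > 1.05 sets a
non-convergence flag on the result rather than raising. All randomness is
controlled by a single seed via spawned `SeedSequence`s, including emcee's
internal move RNG, so fits are exactly reproducible.

Numerical choices:

- A likelihood floor `σ ≥ 1e-6` mm keeps the Gaussian log-density finite
  on noise-free data, where the posterior concentrates at the least-squares
  solution (the package's zero-noise oracle check).
- Credible intervals are central quantile intervals; reported summaries are
  posterior means, sds and central intervals per coefficient.
- An optional `fix_intercept_zero` mode pins α at 0 for the intercept-free
  variant of the model; the default keeps α free.

The scikit-learn estimator `WidthRegressor` wraps the same fit with
`fit(X, y)` on `X = [[power, velocity], ...]`, `predict` (posterior-mean
width) and `predict_interval` (posterior-predictive central intervals, an
equal-weight Gaussian mixture over draws inverted on a 4097-point grid with
root-polishing; a seeded Monte-Carlo path is available).

### Default planning coefficients

No fitted mean-model coefficients ship with any device, so the package
carries one set of defaults chosen once to be clinically plausible for a
60–140 W water-cooled probe in a tissue-mimicking phantom: α = −30.657,
β_power = 9 mm per ln W, β_velocity = −4 mm per ln(mm/s). These put
20 mm width at 100 W / 0.1 mm/s and span roughly 6–32 mm over the full
device envelope (8–26 mm over the calibration design), matching the size
range of liver ablations. The noise slopes are ε = 0.5 mm,
ε_power = 0.03 mm/W and ε_velocity = 0.85 mm/(mm/s); the two slopes are
the levels a calibrated system of this type exhibits and are also the
recovery targets of the synthetic-calibration checks. Real deployments
must replace these defaults with their own calibration — the coefficients
are device- and tissue-specific by construction.

## Inverse planning

A target is a width-vs-position function `w(x)` on a strictly increasing
grid (default 1 mm, matching typical CT voxel resolution). Because both
`P` and `v` control the width, the planner resolves the redundancy by
policy:

- `boundary-accuracy` (default): within a configurable boundary zone
  (default 10 mm) of the shape ends, the *lowest* allowed power whose
  exact velocity lies within device limits — low power and low speed where
  the shape boundary must be accurate, because σ grows with power — and
  the highest such power in the interior;
- `max-throughput`: the highest feasible power everywhere (shortest
  procedure, appropriate for large uniform regions).

For the chosen power the velocity is solved in closed form,
`v = exp((w − α − β_power·ln P)/β_velocity)`, *after* snapping the power to
the generator's discrete levels (nearest level, exact midpoints snapped
down — the lower-power side is the accurate one; out-of-range clamps).
Re-solving after snapping means the planned mean width is exact wherever
the velocity does not hit its limits; velocity clamping is flagged, and
samples whose best achievable width misses the target by more than the
tolerance (default 1 mm) raise an infeasibility error listing the
offending positions and the achievable width envelope.

Other planner behaviors:

- **End caps.** The active travel span is shortened at both ends by the
  local half-width, found by fixed-point iteration of `x₀ = w(x₀)/2`, so
  that hemispherical caps complete the shape to the full target length.
- **Stationary dwells.** A target whose active span collapses to a point
  (a sphere) is planned as a single dwell. Since the width model is
  undefined at `v = 0`, a dwell of duration `t` is assigned the width of a
  pass at the equivalent velocity `v_eq = d_ref/t` with `d_ref = 6 mm` by
  default. This equivalence is a modelling assumption, not a calibrated
  law; `d_ref` is configurable and should be tuned per device.
- **Cycles and pauses.** A cycle is a maximal run of nonzero-power
  segments; active time per cycle is capped (default 360 s). Plans that
  exceed the cap are split by inserted zero-power pauses (default 30 s),
  which also give the sharp shape boundaries that continuous delivery
  blurs by heat propagation.
- **Multi-trajectory plans.** Trajectory k ≥ 2 is planned with its powers
  offset by −20 W (configurable) wherever feasible, because the specimen
  is pre-heated by the earlier pass; volumes combine by geometric union
  with no further thermal-interaction model.
- Adjacent samples with identical (P, v) merge into single segments, so
  profiles stay executable.

Archetype targets cover four representative liver-tumor configurations:
constant-width cylinder (75 × 20 mm), dumbbell (63 mm, 26 mm lobes over a
9 mm waist, cosine-squared bulges), teardrop (68 mm tapering 25 → 17 mm),
and connected spheres (91 mm, 22 mm lobes joined by an 8 mm neck — the
neck floor keeps the target inside the achievable envelope, since a true
sphere pair's zero-width neck is unplannable).

## Shape synthesis, rasterization and margins

`synthesize_shape` assigns each axial sample the width of the (P, v) in
force when the probe passes it (dwells via `v_eq`), taking the pointwise
maximum over overlapping passes. `rasterize` sweeps the width function
around the axis on an isotropic grid (default 0.5 mm): a voxel is inside
iff its radial distance is at most the local half-width, plus
hemispherical caps at the span ends. Cap geometry is isolated behind a
`cap_model` descriptor so alternatives (e.g. ellipsoidal) can be swapped.

`margin_metrics` compares co-registered ablation and tumor masks. The
signed margin at a voxel is `EDT_inside − spacing` within the ablation
(zero exactly at ablation-boundary voxels) and `−EDT_outside` beyond it;
the minimum over tumor voxels is the **minimal margin**, so
coverage = 1 ⟺ minimal margin ≥ 0 holds exactly, and an ablation that
equals the tumor scores a margin of 0. Coverage is the ablated fraction of
tumor voxels; the over-ablation ratio is the ablated volume beyond the
tumor grown by the required margin, as a fraction of the ablation; Dice
compares the ablation with the grown tumor. Positive margins mean fully
covered with spare margin (the clinical sign convention). No default
required margin is asserted; it is a parameter of the report.

## Phantom imaging

The renderer emulates photographs of specimens cut along the probe axis in
an acrylamide phantom with thermochromic ink (irreversibly magenta above
60 °C): an off-white canvas, the magenta axial cross-section of the shape,
and four dark square fiducials of known side length (default 10 mm) near
the corners. Optional Gaussian color noise (default sd 0.02 on the [0,1]
scale) with a slight blur is seeded and bit-reproducible. The render is
fronto-parallel; no lens or perspective model.

The measurement chain mirrors what one does with real photos:

- **Pixel spacing** = marker side [mm] / mean detected marker side [px],
  detecting markers as dark, square-ish connected components (fill ratio
  ≥ 0.8, aspect ≤ 1.3).
- **Segmentation**: an HSV window around magenta (hue 300° ± 40°,
  saturation ≥ 0.3, value ≥ 0.15 — configurable, since real thresholds are
  device- and lighting-specific), 3 × 3 morphological opening and closing,
  largest connected component. An empty result is flagged, not raised.
- **Width profile**: the mask's principal axis from its second moments;
  width per axial station is the perpendicular pixel extent × spacing.

What the synthetic loop does *not* capture about real photographs:
perspective and lens distortion, specular highlights and shading, cutting
misalignment relative to the probe axis, diffuse color boundaries from
partial heating, and marker occlusion. Passing round-trip tests therefore
validate the measurement chain's geometry and color logic, not its
robustness to real acquisition artifacts.

## Problem sizes and checks

The test suite and the acceptance script work at deliberately moderate
sizes: calibration fits use 2–4 chains × 1000 retained draws on designs of
32–192 observations; parameter-recovery coverage uses 20 seeded
repetitions; rasterization oracles use 0.5 mm grids (~10⁶ voxels); imaging
round trips use 10–20 seeded specimens at 0.2–0.25 mm/px. Every expected
value asserted in the tests is computed by an independent oracle (ordinary
least squares, adaptive quadrature, analytic volumes, distance-transform
constructions, Gaussian quantiles) rather than by the code path under
test.

## Known limitations

- No biophysical heat-transfer simulation: the calibrated model *replaces*
  the bioheat equation, so perfusion cooling, vessel heat sinks and
  inter-trajectory thermal interaction (beyond the constant −20 W offset)
  are out of scope.
- The dwell equivalence (`v_eq = d_ref/t`) and the hemispherical caps are
  modelling choices, validated only for self-consistency.
- The −20 W second-pass offset is an operational heuristic, not a
  validated thermal model.
- Trajectory direction/entry-point optimization against anatomy, needle
  bending, and registration to clinical imaging are not modelled; targets
  are given in trajectory coordinates.
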