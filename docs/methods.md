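# Methods

This note records the model, its numerical treatment, the synthetic
geometries, and the design choices that were genuinely open.

## Neutron equivalent-dose model

Stray neutron equivalent dose per prescribed proton dose (H/D, mSv/Gy) is
evaluated pointwise as the product of

1. a plan-level isocenter calibration `hd_iso` (mSv/Gy), optionally
   computed from a proton energy-bin spectrum as
   `(1/n_max) * sum_j hd_iso_j * n_j` with `n_max` the proton count of the
   maximum-**energy** bin (a `max_count` convention is exposed for the
   alternative reading of "maximum bin");
2. a power-law divergence factor `(d/d_iso)^(-p)` in the geometric distance
   `d` from the virtual neutron source, which sits on the central axis at
   the downstream face of the patient collimator (33 cm upstream of the
   isocenter in the default geometries);
3. a four-component mixture over the neutron populations
   (intranuclear-cascade, evaporation, epithermal, thermal), each with an
   exponential water attenuation `exp(-alpha_i (d' - d'_iso))` along the
   ray-traced water-equivalent pathlength `d'`, and a lateral Gaussian
   `exp(-(x^2+y^2) d_iso^2 / (2 sigma_i^2 z^2))` whose width is specified
   at the isocenter plane and grows linearly with the axial distance `z`
   (the `d_iso^2/z^2` scaling); and
4. a scalar field-size factor in [0, 1] — the blocked-to-total collimator
   area ratio — because the calibration condition is a fully closed
   collimator. It is a multiplier on `hd_iso`, not a spatial reshaping.

Assumptions worth keeping in mind: all neutrons emanate from a single
virtual point (real treatment heads also produce neutrons upstream, which
Monte Carlo models resolve and this model does not); tissues are treated as
water of varying density, so elemental composition effects (notably in
air-filled regions, where hydrogen is scarce) are not modelled; the model
covers nozzle-produced neutrons only, not neutrons produced inside the
patient, so it is not applicable to scanned-beam delivery without
modification.

### Parameters and defaults

| parameter | units | default | origin |
| --- | --- | --- | --- |
| `hd_iso` | mSv/Gy | 3.68 | plan-level calibration value; replace per plan/spectrum |
| `p` | – | 1.3 | illustrative |
| `d_iso` | cm | 33 | virtual source to isocenter |
| `d'_iso` | cm | traced per plan | ray trace source→isocenter through the anatomy (overridable for water-tank work) |
| `C_i` | – | 0.72 / 0.20 / 0.05 / 0.03 | illustrative |
| `alpha_i` | 1/cm | 0.03 / 0.08 / 0.11 / 0.14 | illustrative |
| `sigma_i` | cm | 18 / 28 / 40 / 55 | illustrative |

The component defaults are a **physically plausible, non-clinical stand-in**
chosen once from qualitative physics — cascade neutrons penetrating and
forward-peaked, evaporation intermediate, epithermal/thermal strongly
attenuated and laterally broad — so that the shipped pipeline produces
out-of-field doses in the sub-1 % band reported for passive scattering. A
clinical deployment replaces every number with a fitted set for its own
treatment head via the TOML model file.

Validation warns (rather than errors) when the component weights do not sum
to 1, because at the isocenter the model reduces to `hd_iso * sum(C_i)` and
a sum far from 1 makes `hd_iso` inconsistent with the model's own value
there; whether fitted weight sets are normalized is a property of the fit,
not of the model.

### Numerical treatment

* Exponents are clipped to ±700 before exponentiation; arguments at or
  below the clip are flushed to exactly zero (they are below double
  underflow anyway), so extreme off-axis points give 0, never NaN/Inf.
* Points at or behind the virtual source plane are outside the model's
  forward half-space. `z_min` = 0.1 cm: the pointwise evaluator raises,
  the grid evaluator writes zero and logs the voxel count. The lateral term
  diverges as z→0, so some cut is mandatory; 0.1 cm is far upstream of any
  anatomy in practice.
* Grids are evaluated at voxel centers, no sub-voxel averaging.
* The grid path and the pointwise path share one vectorized evaluation
  routine and one traversal kernel, so they agree bit-for-bit.

## Ray tracing

Water-equivalent pathlength uses an exact parametric (Siddon-style)
traversal: per-voxel chord length × relative density, voxel boxes half-open
`[origin + i·s, origin + (i+1)·s)`, 0-based indices, world units cm. Chord
lengths sum to the geometric in-grid length by construction (the traversal
marches a single parameter, so no length is created or lost); boundary and
corner hits advance all tied axes at once, producing the deterministic
zero-length-chord behaviour standard for this algorithm. Segments outside
the grid contribute with a configurable outside density, default 0.001
(air): the source sits in air upstream of the patient, and air gaps enter
`d'` at their near-zero water equivalence. The kernels are JIT-compiled
(numba), which is what makes whole-grid evaluation (~0.5 M voxels) a matter
of seconds on one CPU.

HU→density conversion is a clamped piecewise-linear table; the packaged
4-point curve (−1000→0.001, 0→1.0, 100→1.05, 1500→1.6) is a documented
stand-in for a clinic-calibrated curve. Phantom grids carry relative
densities directly; the HU path is exercised by HU-kind grids in the tests.

## Passive-scattering proton surrogate

The target of this package is the *neutron* engine; the proton engine only
needs to reproduce the qualitative in-field/out-of-field behaviour of a
passively scattered SOBP plan, so a scanned-beam optimizer is replaced by a
closed form:

* **Aperture**: beam's-eye-view projection of the PTV voxel footprints onto
  the collimator plane through the divergent geometry (point source 233 cm
  upstream of the isocenter, collimator plane at 200 cm), no margin. Voxel
  footprints are projected as per-voxel corner bounding boxes — exact for
  grid-axis-aligned beams, slightly conservative for oblique ones.
* **Modulation width**: deepest distal radiological edge minus shallowest
  proximal radiological edge over all rays intersecting the PTV (the
  conservative global-envelope reading; a per-ray option exists because the
  phrase "maximal difference between radiological depths of the proximal
  and distal edges" admits both readings). Voxel edges include a half
  water-equivalent chord so a d-cm sphere in water yields exactly d cm.
* **PTV_PS**: a voxel belongs iff its BEV ray is in the open aperture and
  its distal water-equivalent edge lies in the half-open band
  `(distal_edge − M, distal_edge]` on its ray. The half-open lower bound
  with a closed top is the only rule consistent with the degenerate cases
  (zero modulation → the distal shell; a single-voxel PTV → itself) while
  guaranteeing PTV ⊆ PTV_PS in homogeneous media.
* **Dose**: `prescription × SOBP(depth) × P(lateral)` per voxel. The SOBP
  is flat (=1) across the modulation band ending at the per-ray distal
  PTV_PS edge (conformal distal coverage rather than beam-energy
  modelling), ramps linearly from an entrance plateau (default 0.75) and
  falls distally as cos² over 0.6 cm, hence exactly zero beyond 1 cm. The
  penumbra `P` is `0.5·erfc((s − m)/(σ√2))` in the signed distance `s` to
  the projected aperture edge, with the 50 % point offset `m` = 0.8 cm
  outside the edge (the surrogate's stand-in for the aperture margin a
  planner adds so the field edge clears the PTV) and σ = 0.4 cm at the
  isocenter plane, both diverging linearly with z, and a hard cutoff 3 cm
  outside the aperture at collimator scale. The (m, σ) pair was chosen
  together so that simultaneously: the isocenter dose equals the
  prescription to <0.5 %, the mean target dose sits within 1 % of
  prescription despite rim voxels, and the dose 3 cm outside the field edge
  is below 10⁻⁵ of prescription with an order-of-magnitude margin against
  voxel-quantization effects (a 0.5 cm σ without margin leaves that last
  bound with almost no headroom).

## Phantoms

* **Water box**: 30 × 15 × 15 cm³ of water (beam along the 30 cm axis,
  +z), 5-cm spherical target centred 7.5 cm deep, isocenter at the target
  centre, default 0.25 cm isotropic voxels. At that spacing the voxelized
  sphere volume is within 1 % of the analytic volume; 0.25 cm balances
  discretization error against desk-scale runtime.
* **Thorax**: an elliptical soft-tissue (ρ=1.0) torso with a neck, two lung
  ellipsoids (ρ=0.26), a spine-like bone column (ρ=1.4), a 6-cm mediastinal
  spherical target at the isocenter, a thyroid-like ellipsoid (ρ=1.05)
  ~15.5 cm superior of the target centroid, and anterior breast-like bulges
  so the beam crosses an oblique, irregular surface. Densities are standard
  tissue-table values. The beam is a single anterior–posterior field.
  Default spacing 0.4 cm.

Both are deterministic given their spec; optional Gaussian density noise is
seed-controlled and off by default.

What these phantoms do **not** emulate: true CT texture and noise, elemental
composition, organ shapes beyond quadrics, setup uncertainty. Passing tests
therefore demonstrate the engine's geometric/heterogeneity behaviour
(lung-deepened isodoses, sub-1 % far-field band, source divergence), not
agreement with any specific patient's numbers.

## Reporting conventions

* Proton equivalent dose = absorbed dose × 1 (radiation weighting factor 1
  for protons); combined dose is the voxelwise sum with the neutron
  equivalent dose in Sv.
* Percentages are relative to the prescription at the isocenter, never to
  the maximum dose.
* Structure "±" is the population SD over structure voxels (`sample`
  convention available); the choice is configurable because the convention
  behind published "±" values is usually unstated.
* DVHs are cumulative at 1 % bins; isodose contours are marching squares
  per slice, exported as world-coordinate polylines.
* The pipeline logs per-stage wall time so the relative cost of the neutron
  stage can be inspected; it is not asserted in tests.

## Verification design

* Traversal is checked against an independent fine-step midpoint-sampling
  integrator on heterogeneous grids (the oracle's own error is linear in
  its step; the step is chosen so that error sits well inside the 10⁻³ cm
  comparison tolerance), and against exact closed forms in homogeneous and
  outside-grid cases; symmetry, translation invariance, collinear
  additivity and length conservation are property-tested.
* The grid H/D evaluator is compared bit-for-bit with the pointwise closed
  form at random voxels, and the model's parameters (p, C_i, alpha_i,
  sigma_i) are recovered to ≪1 % by relative-residual least squares from a
  noiseless engine-generated grid in an identifiable configuration
  (well-separated alphas and sigmas, heterogeneous medium so d' varies
  independently of d).
* The water-box plan reproduces uniform target coverage (mean within 1 % of
  prescription) with near-zero dose 3 cm outside the field edge and <10⁻⁵
  of prescription 1 cm beyond the distal edge.

## Known limitations

* Aperture footprint projection is a bounding-box rasterization: exact for
  axis-aligned beams, up to ~half a voxel conservative for oblique beams.
* Per-ray distal range is taken from voxel-center binning on the aperture
  raster; columns at the target rim can straddle two beam's-eye pixels.
* The proton surrogate has no nozzle model, no MU calibration, no
  range-modulator weighting, single field only.
* Neutron model limitations inherited from its form: single virtual source,
  water-equivalent attenuation only, no energy dependence of the component
  parameters.
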