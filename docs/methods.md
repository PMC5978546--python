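# Methods

## The problem

A temporary breast tissue expander contains a magnetic injection port — a
neodymium-magnet disk in a thin titanium casing — that sits inside the
radiation field during postmastectomy radiotherapy (PMRT). Commercial
treatment planning systems model it poorly: contouring it on
artifact-ridden kV CT images and converting CT numbers through a
saturating density table underestimates its attenuation, while overriding
generously drawn contours with nominal component densities overestimates
it. This package implements a radiologically calibrated alternative: the
port is a single homogeneous tilted disk whose diameter, thickness and
bulk density are chosen so that calculated depth doses match depth-dose
measurements under the port in both the parallel and the perpendicular
orientation, across beam energies. The calibrated defaults are 17.5 mm
diameter, 5 mm thickness and 7.5 g/cm^3 — deliberately different from the
physical magnet (21 mm x 3.5 mm, 7.4 g/cm^3) because they are *effective*
parameters of a density-override model, not component specifications.

## Port geometry

`geometry.PortModel` is a finite cylinder: center (mm, LPS-like world
frame: +x left, +y posterior, +z superior), diameter, thickness, density,
and two tilt angles in degrees. The disk axis starts anterior–posterior,
(0, 1, 0); the sagittal tilt (rotation about x) is applied first, then the
transverse tilt (rotation about z), right-hand rule. No convention for
these angles is standard, so this order is a documented package choice.
The thin Ti shell (35 mm x 0.4 mm, 4.2 g/cm^3) contributes less than
0.2 g/cm^2 of areal density (`areal_density(0.04, 4.5) = 0.18`) and is
excluded from the default model; an optional `ShellSpec` can represent it.

Ray–disk chords are computed analytically (slab interval intersected with
the lateral quadric interval, clipped to t >= 0). Slice contours are
extracted per axial plane as the zero level of the signed boundary
function on a 0.25 mm lattice (sub-pixel linear interpolation via
marching squares), resampled to <= 0.5 mm vertex spacing,
counter-clockwise, closed only on serialization. Rasterization is a
voxel-center inclusion test with *closed* boundaries; voxel centers that
lie exactly on the boundary are inside the analytic mask but may fall on
either side of a traced contour, which is why contour-based and analytic
masks are compared on occupied-voxel fractions, not voxel-by-voxel.

## Phantoms

`phantoms` generates every geometry the evaluation needs, all seeded and
deterministic:

* **Ion-chamber tank** — water, port top face 50 mm below the surface,
  SSD 850 mm, isocenter at 150 mm depth, 10 x 10 cm^2 field, sample
  depths 70–150 mm; `parallel` and `perpendicular` port orientations.
* **Anthropomorphic slabs** — layered along the lateral beam direction:
  lung slab (0.30 g/cm^3; the physical phantom uses wood and states no
  value, so 0.30 is a configurable package choice), 1 cm bolus as chest
  wall, and a water-equivalent block of 63 mm (inflated expander) or
  20 mm (deflated). The port center sits 20 mm below the block surface;
  SSD 907 mm (inflated) / 950 mm (deflated); isocenter at the
  lung/chest-wall interface aligned with the port. TLD points 1, 2, 4 lie
  25 mm from the port center (lateral, superior, inferior); point 3 is on
  the beam-side axis directly under the port. The axial placement of
  points 1/2/4 is only specified laterally in the source setup, so their
  in-plane placement here is a documented choice.
* **Patient-like chest** — a half-cylindrical body with an embedded water
  expander, the port at its anterior face with small seeded tilts, a PTV
  covering the chest-wall shell plus expander on port-bearing slices, and
  four evaluation points (two skin points deeper than 1 cm, two
  chest-wall points). It is a synthetic stand-in for a patient CT: sizes
  and jitter are seeded, nothing anatomical beyond slab/half-cylinder
  realism is claimed.

Metal artifacts are simulated as eight alternating bright/dark angular
streaks (±300 HU default) emanating from the per-slice port centroid,
decaying linearly to zero at 8 cm; deterministic per seed, defined on HU
volumes only. This emulates the *contouring hazard* of streaks, not CT
reconstruction physics.

HU↔density conversion is piecewise linear. The extended table reaches
10 g/cm^3; the non-extended clinical table saturates at 3.0 g/cm^3 (a
typical clinical cap, chosen here to reproduce the saturating-table
underestimation of the `clinical2` policy). Override policies: `clinical1`
(magnet 7.4, shell 4.2, artifacts water), `clinical2` (port contour
dilated 3 mm keeps CT-derived saturated densities, artifacts water),
`new` (disk 7.5, artifacts water), `nodisk` (everything water — the
homogeneous baseline). Overlaps resolve port > shell > artifact >
background.

## Dose engine

The engine is a desk-scale stand-in for a commissioned convolution
algorithm and is documented as such — it reproduces the transmission
physics the port model rests on, not a clinical beam model. Per voxel:

    D = fluence(u, v) * wedge(u) * (1000 / r)^2 * PDD(d) * exp(-mu/rho * max(0, t_rad - d/10))

where `r` is the source distance (mm), `d` the geometric depth (mm) below
the surface along the ray (density >= 0.05 g/cm^3 counts as material),
and `t_rad` the Siddon-traced radiological depth (g/cm^2). Evaluating the
PDD at the geometric depth and carrying heterogeneity entirely in the
excess-attenuation factor makes the homogeneous-water limit *exactly*
`fluence x inverse-square x PDD` and makes the with/without-port dose
ratio exactly `exp(-mu/rho (rho - 1) chord)` in primary-only mode — the
two anchors the test suite checks at 1 % and 3 %. The `max(0, .)` means
sub-water densities (lung) do not boost the primary; this asymmetry is a
known simplification.

* PDD: `(1 - exp(-a d)) exp(-b (d - dmax))`, normalized to 1 at dmax.
  Defaults (a 1/cm, b 1/cm, dmax mm): 6 MV (2.6, 0.0493, 15),
  10 MV (1.6, 0.0382, 23), 15 MV (1.35, 0.0327, 28); `b` is mildly
  reduced for fields larger than 10 x 10 cm^2 (factor `(Feq/100)^-0.08`).
* Effective mass attenuation mu/rho: 0.0493, 0.0382, 0.0327 cm^2/g for
  6/10/15 MV; the port uses the water coefficient scaled by density,
  consistent with a density-override model.
* Scatter: the primary is mixed with a laterally Gaussian-blurred copy
  (fraction 0.15), with sigma(d) = 3 mm + 0.05 d applied slab-by-slab
  along the dominant beam axis. `primary_only=True` disables it for
  closed-form comparisons.
* Field edges get a 4 mm linear penumbra ramp; fluence maps (for
  IMRT-style beams) are fixed inputs on the 100 cm plane — there is no
  inverse optimization.
* Wedges: linear transmission gradient across the crossline direction,
  unity at the center, clipped to (0, 1]. The gradient is
  `(b + 0.02 cm^-1) tan(angle)` per cm; the second term is the
  inverse-square contribution to the axial dose gradient at the reference
  distance, so the nominal angle equals the isodose tilt at 10 cm depth
  measured near the axis on the attenuated side (the clip makes the heel
  side flat). Verified numerically to ±1 degree at 20 degrees.
* Plans are weighted beam sums normalized so the prescription dose is
  delivered at the normalization point (isocenter by default). Arcs are
  discretized at 10 degrees by default, endpoints inclusive.

Siddon traversal is exact per voxel (numba-compiled); surface entry for
SSD setups is located by nearest-voxel sampling at 0.05 mm along the
central axis, so the effective SSD is accurate to the sampling step.

## Calibration

`calibration` fits the port density — optionally jointly with diameter
and thickness — by minimizing the RMS of relative differences
`(calc - meas)/meas` over all depths, setups and energies, equally
weighted (the source procedure says only that differences were
minimized; RMS with equal weights is the package's choice). The forward
model is the engine's primary term on the central axis with the chord
computed analytically for the candidate geometry, which keeps a full
three-parameter grid search in seconds. A coarse-to-fine grid search
(two x10 refinements, e.g. density 0.5 → 0.005 g/cm^3) is used instead
of gradient descent because a voxelized forward model would make the
objective non-smooth; exact ties break toward the smaller density
(conservative attenuation), then smaller diameter and thickness.

**Identifiability.** On-axis depth doses under the port determine exactly
two quantities: the excess areal densities `(rho - 1) x thickness`
(perpendicular) and `(rho - 1) x diameter` (parallel). The three
parameters are therefore only identifiable up to a one-parameter ridge,
which is the quantitative form of the observation that a density fitted
to the parallel setup alone fails the perpendicular measurements (the
joint-fit diagnostics report this cross-setup RMS). Recovery studies
consequently draw ground truths on the search grid and exclude the rare
combinations whose ridge passes exactly through a smaller-density lattice
point (`sample_identifiable_ports`); for those aliases the tie-break
rule returns the alias, correctly, because the data cannot distinguish
them. Synthetic measurements are engine-generated, optionally with
multiplicative Gaussian noise of stated relative width; with 0.5 % noise
the median fitted density over 20 replicates recovers the truth well
within 2 %, because ~54 depth points average the noise down.

`PortCalibration` / `PortCalibrationResult` expose this as a
model/results pair with a `summary()` table.

## Evaluation

* Percent differences are `(calc - ref)/ref x 100`, rounded
  half-away-from-zero (1 decimal for the phantom table, 2 for the patient
  table — the convention that reproduces the printed values). The two
  shipped fixture CSVs carry the printed dose and difference columns of
  the phantom-validation and patient comparison tables; recomputing every
  difference from the dose columns must agree within one unit in the last
  printed digit, the slack implied by the dose columns themselves being
  rounded (0.1 cGy on ~90 cGy propagates up to ±0.11 percentage points).
  The patient table (~5000 cGy doses) reproduces exactly.
* Cumulative DVHs: V(0) = 100 %, non-increasing, 0 beyond the maximum;
  default bin width 0.01 Gy for phantom doses, 0.5 Gy recommended for
  patient-scale doses.
* Reduced PTV: the PTV restricted to axial slices containing the port,
  minus expander and port — the tissue-only target used for DVH
  comparison.
* FWHM dimensioning: the width at half the extremum of a projection
  profile, baseline taken as the median of the outer 20 % of samples (no
  baseline rule exists in the source; this one is robust to tilted
  backgrounds), crossings linearly interpolated. A perpendicular
  projection estimates the diameter, a parallel projection the thickness;
  on box-like profiles the estimator is unbiased to within one pixel.
* TLD calibration: ordinary least squares of reading on delivered dose
  (slope, intercept, residuals, standard errors); `tld_dose` inverts the
  line.

## What the synthetic data do and do not show

The phantom factory reproduces the *geometry and design* of the
measurement campaigns — layer thicknesses, SSDs, point layouts, the
28-packet TLD inventory (24 measurement + 1 background + 3 calibration) —
but its "measurements" are engine-generated. Passing tests therefore
demonstrate internal consistency (the calibration recovers what the
engine produced; the table arithmetic matches what was printed), not
agreement with ion-chamber or TLD data, which would require the
commissioned beam model and convolution dose algorithm that are
explicitly out of scope. Reported dosimetric agreements recomputed here
(e.g. the 5.0 % phantom-validation bound, the skin-dose reductions) come
from the fixture dose columns, exactly as printed.

## Numerical choices and problem sizes

Default test/analysis grids are 2 mm (1 mm along the beam where the
voxelized chord must be exact; 0.25 mm for geometry convergence checks),
chosen as the package's standard desk-scale configuration. The engine's
dose grid contract follows the 1 mm^3 clinical grid where affordable.
Degenerate inputs are errors, not warnings: empty masks, flat profiles,
zero measured doses, single-depth records, degenerate arcs and
zero-weight plans all raise `ValueError`.

## Known limitations

* No convolution/superposition or Monte Carlo transport; no electron
  contamination; scatter is a two-parameter Gaussian mix.
* Sub-water heterogeneity does not increase the primary (the `max(0, .)`
  clip); lung-transit doses are water-like.
* The wedge model is linear with a hard clip at unity; large wedge
  angles and far-off-axis points deviate from the nominal tilt.
* Clinical model #2's in-TPS per-voxel densities are unknowable; only
  the saturating-table mechanism is emulated.
* The patient-like phantom is geometric, not anatomical; RT-STRUCT
  export is minimal (one ROI contour sequence per structure, closed
  planar contours) and not a full DICOM-RT implementation.
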