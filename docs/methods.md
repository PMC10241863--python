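# Methods

## Drop-shape model of the yolk puddle

The yolk is treated as a uniform incompressible fluid of density ρ enclosed
by a structureless membrane under uniform isotropic tension γ, resting on a
rigid horizontal non-adhesive plate in a massless exterior. Mechanical
equilibrium of the axisymmetric interface is the Young–Laplace balance
γ(κ₁ + κ₂) = p₀ − ρgz with hydrostatic interior pressure and apex
overpressure p₀. Because the membrane wraps the yolk completely, the
meridian meets the plate tangentially (contact angle π). The model has no
bending stiffness, no strain-dependent (elastic) constitutive response, no
contact adhesion and no albumen buoyancy; it maps one observed shape to one
tension value and says nothing about the kinetics of membrane weakening.

Written in arc length s from the apex, the meridian obeys

    dr/ds = cos φ,   dz/ds = −sin φ,
    dφ/ds = (p₀ − ρgz)/γ − sin φ / r,

with the L'Hôpital limit dφ/ds = p₀/2γ at r = 0. The single dimensionless
control parameter is the Bond number Bo = ρgV^(2/3)/γ. The solver supports
Bo ∈ [10⁻³, 10⁴] and raises a domain error outside it.

### Numerical scheme

All computation is nondimensionalized by V^(1/3) (lengths) and γ/V^(1/3)
(pressures), so the state stays O(1) across the Bond range. The meridian is
solved as a two-point boundary-value problem in normalized arc length with
`scipy.integrate.solve_bvp` (4th-order collocation): four states (r, depth
below apex, φ, accumulated volume), two unknown parameters (apex
overpressure, total arc length), six boundary conditions (apex regularity,
φ = π at contact, enclosed volume = V). Collocation was chosen over single
shooting deliberately: the flat film that develops across the puddle
interior at large Bo carries exponential growing/decaying modes with rate
√Bo per unit V^(1/3)-length, which makes apex-initialized shooting
ill-conditioned beyond Bo ≈ 30 while the two-point formulation remains
stable.

Solutions are obtained by continuation along a *fixed ladder* of Bond
numbers (steps of 1/8 decade from Bo = 1), each ladder solution warm-started
from the previous and cached, with one final collocation step from the
nearest ladder point to the requested Bo. The ladder makes every solve a
pure function of (Bo, tolerance) — results do not depend on call history —
while repeated nearby solves (as inside an inversion) cost one collocation
call each. Collocation tolerance is min(rtol, 10⁻⁶); the volume boundary
condition is satisfied to Newton precision, and every returned profile is
checked against |V_enclosed − V|/V ≤ rtol (default rtol 10⁻⁶).

Beyond Bo ≈ 1.5×10³ the apex overpressure that distinguishes admissible
solutions shrinks below what double precision can represent (its window
closes like e^(−√Bo)), so no floating-point ODE/BVP formulation with a
global pressure unknown can converge there. In that regime the profile is
built instead from the exact planar-puddle edge solution: the translationally
invariant membrane puddle with contact angle π admits the first integral
1 − cos φ = u²/2λ² (u depth below the flat top, λ = √(γ/ρg) the capillary
length), giving u(φ) = 2λ sin(φ/2) and the horizontal coordinate by the
closed-form quadrature r(φ) = R + λ[F(φ) − F(π/2)] with
F(t) = ln tan(t/4) + 2cos(t/2). The puddle radius R is root-found so the
volume of revolution matches V exactly; the neglected azimuthal curvature
contributes a relative error O(λ/R) < 1% at the switch, where the two
branches were verified to agree to 1% after removing the Bo^(−1/2) height
trend. Puddle height in this branch is exactly 2λ.

The reported diameter D is the maximum horizontal extent of the meridian
(what a side photograph measures), refined by locating the φ = π/2 crossing
on the collocation dense output; it exceeds the contact diameter because
the membrane tucks under the bulge at contact angle π.

### Inversion

The yolk index H/D is strictly increasing in γ at fixed (ρ, V, g) — asserted
as a property test on a 10-point tension grid — so tension is recovered with
Brent root finding on yolk_index(γ) − observed over a bracket (default
10⁻³–10 N/m, which spans both solver branches for bench-scale yolks). A
missing sign change raises a bracket error; the noiseless round trip
recovers γ to better than 0.1%.

### Energy-minimization cross-check

An independent route to the same shape minimizes
E = γ(side area + wetted disc area) + ρg∫z dV at fixed volume, the wetted
disc term encoding the contact angle π. The meridian is discretized as
single-valued r(z) on a sine-spaced grid (dense toward the apex to resolve
the √-type tip) and minimized with SLSQP under an equality volume
constraint, 160 segments by default. It shares no code with the collocation
solver and agrees with it in height and diameter to well under 1% at
Bo ∈ {0.5, 5, 50}; tests require 2%. It is ~100× slower and used only for
validation.

## Scale tensiometry

Tensions follow from the closed-form weight differences
γ = |Δm|·g/L with masses in kg and L the strip width (default 0.02 m,
g = 9.8 m/s²). Differences are taken in absolute value: the formula as
printed with the stated sign of the reading change would yield a negative
number, and tension is non-negative by definition.

Event detection works on a 0.5-s rolling-median smoothing of the reading:
steps larger than `jump_tol` within 0.5 s mark the cut (first downward) and
rupture (last upward); plateau weights are means of stable stretches
(spread within 4× `plateau_tol` = 0.05 g) of at least 2 s, skipping a 1-s
settle after each step. `jump_tol` defaults to 0.3 g — weak late-stage
membranes produce ~0.5 g cut steps on a 2-cm strip, while gram-scale sensor
noise (0.02 g) leaves 0.3 g a ≈20σ threshold. The detached weight is read
from the post-rupture terminal plateau; for traces that end before rupture
it falls back to the pre-cut plateau (the full weight rests on the balance
in both states), the native tension remains computable and the maximum
tension is undefined. The breaking weight is the extremal pre-rupture
reading estimated by fitting a line to the last 2 s of the ramp and
evaluating it at the final pre-rupture sample — unbiased under both the
descending ramp and the sensor noise, where a raw minimum would be biased
low by noise extremes and a smoothed minimum biased high by the ramp slope.

## Probe indentation

Traces (time, probe position, force; 100 Hz nominal, 0.1 mm/s push) are
processed in a fixed order: (1) baseline correction — the mean force over
the pre-movement stretch (≥ 2 s required) is subtracted per trace;
(2) averaging to one value per second, timestamps at bin centers (bin means
preserve the slope of a linear signal exactly and shrink white noise by
√n); (3) QC — `early_rupture` if force drops by more than 0.05 mN between
consecutive seconds during the push, `holder_hit` if force exceeds 50 mN or
the per-second slope jumps by more than 5× its established push-phase
median, `no_contact` if force never clears the contact threshold;
(4) slope extraction. Contact is the first 1-Hz sample where force exceeds
3× the baseline residual SD for 3 consecutive samples. Among all contiguous
20-s windows after contact the one maximizing the R² of a straight-line fit
is selected (earliest wins ties within 10⁻⁹), and its fitted slope (mN/s)
is the stiffness metric; selecting by R² rather than by a fixed offset from
contact keeps soft-contact curvature out of the fitted span without
hand-tuning a delay. The slope is not converted to an elastic modulus —
that would require a contact-mechanics model of the membrane–probe geometry
that is deliberately out of scope.

## Morphometrics

Speeds are least-squares slopes over all frames (not endpoint differences):
elongation from the Euclidean distance between a fixed reference somite and
the posterior end (µm/h, negative = shortening), convergence as minus the
slope of the posterior-neural-tube width between the outer wall boundaries
(µm/h, negative = widening), segmentation from the somite-pair count
(pairs/h). Regression is exact on noiseless linear series and unbiased
under per-frame Gaussian landmark noise (verified by Monte-Carlo mean
within 2 SE).

Fibre density: the stain image (inverted first if fibres are dark) is
binarized with Otsu's threshold — parameter-free where manual thresholding
would not be reproducible — and `n_rois` axis-aligned square ROIs (default
10 × 128 px) are placed uniformly at random fully inside the image with a
recorded seed; the density is the mean white fraction across ROIs. A
constant image has no threshold and reports density 0 with a degenerate
flag. An ROI spanning the whole image makes the result seed-independent.

## Synthetic data

Generators are pure functions of their arguments and seed (byte-identical
reruns, hash-checked in tests) and write truth sidecars for every output.
Default conditions: 17 mL yolk at 1.035 g/cm³; group tensions 0.8 (day 0)
and 0.32 N/m (day 2), i.e. a 40% retained fraction; geometry noise 0.3 mm;
20 samples per group for geometry, 15/19 for scale traces and 15/16 for
probe traces (figure-style cohort sizes); scale readings at 10 Hz with
0.02 g noise around a 10 g clip weight; probe traces at 100 Hz with 0.01 mN
noise, 5 s stationary baseline, contact at 10 s, 40 s push; landmark series
of 8 h at 2 frames/h with 5 µm landmark noise, elongation 80 vs 30 µm/h,
convergence 30 vs 5 µm/h, segmentation 0.667 vs 0.4 pairs/h for
control-like vs tension-maintained-like groups; fibre coverages 5–40% as
random dilated line segments with Gaussian intensity noise.

What the generators deliberately do *not* emulate: viscoelastic relaxation
during the scale ramp, probe–membrane contact mechanics (force is linear by
construction after a quadratic onset), landmark tracking failures, image
vignetting/uneven illumination, and integer quantization of somite counts
(counts are kept fractional-linear so the generating slope is exact; as a
consequence synthetic segmentation speeds have near-zero within-group
variance and their group tests are degenerate by construction). Passing
recovery tests therefore demonstrate estimator correctness under the
assumed noise model, not robustness to these real-data effects.

## Statistics

Two-tailed t-tests compare metric values between groups of distinct
samples; Welch's unequal-variance form is the default (group SDs plainly
differ between days), with a pooled equal-variance switch. One-way ANOVA
serves multi-group panels; identical constant groups are flagged degenerate
rather than returning a spurious F. Both match explicit sums-of-squares
oracles to 10⁻¹⁰ in tests, and their simulated null type-I error at
α = 0.05 is verified within the binomial confidence interval at 1000
replicates. No multiple-testing correction is applied; the assembled report
records the number of comparisons made.

## Problem sizes

Tests and the analysis pipeline run at the study-condition sizes above
(≤ 20 samples per group, 1000-replicate null calibrations, 256–512 px
images); the collocation meshes adapt from ~100 to ~4×10⁴ nodes across the
Bond range, and profiles are reported on an 801-point meridian.

## Known limitations

- The shape model is a one-parameter (tension-only) membrane: if the real
  VM stores elastic strain energy or the yolk density is stratified, the
  inverted γ is an effective tension, and the tension *ratio* between two
  shapes is more trustworthy than either absolute value.
- Whether a measured yolk index or an absolute height at fixed volume is
  inverted changes the estimate under volume uncertainty; both entry points
  are provided (`invert_tension` accepts an index or an (H, D) pair).
- Scale-trace event detection assumes the protocol's plateau–ramp–rupture
  structure; traces that deviate (double ruptures, drifting baselines) fail
  QC rather than being rescued.
- The 20-s stiffness window is chosen per trace by fit quality; per-trace
  window placement can differ from a fixed-offset convention on strongly
  nonlinear force curves.
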