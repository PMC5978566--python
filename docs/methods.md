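# Methods

## The measurement chain being emulated

A linac delivers one field per fraction; the EPID integrates the exit dose
into a 2D image; QA software compares each fraction's image against a
baseline fraction with user-chosen dose-difference (DD),
distance-to-agreement (DTA) or gamma criteria and flags fields whose
passing rate drops below a preset. `episense` replaces the hardware with
an analytic renderer so that the comparison chain's detection limits can
be measured under exactly known conditions.

## Image formation model

`render_image` evaluates, at every pixel centre,

    dose(p) = MU · output_scale · A_σ(p) · T_scene(p) · (1 + ε_p).

**Aperture.** The field is the intersection of the jaw rectangle with the
MLC opening. The MLC is modelled as 60 leaf pairs with the standard
120-leaf layout (10 outer pairs of 10 mm, 40 central pairs of 5 mm at
isocenter — vendor convention, configurable). The opening decomposes into
disjoint per-leaf rectangles, and the Gaussian penumbra is applied as the
*exact* convolution of that union: each rectangle contributes a separable
product of error-function edge profiles. A collimator rotation is an exact
rotation of the aperture about the central axis (the isotropic kernel
commutes with rotation). Consequences relied on elsewhere:

* edge positions are continuous — induced sub-pixel shifts are exact;
* the 50% isodose line sits on the projected geometric edge independently
  of σ, so detection thresholds are penumbra-width-independent;
* isocenter-plane coordinates are magnified by exactly `SDD/SAD`.

**Penumbra width.** σ = 1.5 mm at the detector plane by default. No
published beam model exists for this chain; the value is a typical 6 MV
in-air penumbra scale, and nothing downstream depends on it because edge
detection uses the σ-independent 50% level.

**Scene.** Transmission factors multiply: a water-equivalent slab
`exp(−μ_eff·t)` with μ_eff = 0.0475 /cm (6 MV narrow-beam ballpark); a
couch top as a lateral strip pattern (5 mm wide strips every 30 mm,
transmission 0.97 — geometry from the physical couch insert, transmission
an assumption, configurable); a rail as a 30 mm attenuating band
(transmission 0.92) present only when "in". Strip and band edges get the
same erf smoothing as the aperture. Scatter is not modelled: for this
comparison chain it perturbs detection thresholds by well under the sweep
step, and a wide additive kernel would not change any conclusion drawn
here. Rail attenuation values are assumptions, so rail results are
qualitative by construction (in-vs-out produces failing pixels; the static
field shows a larger maximum DD than an MU-weighted arc composite in which
the rail shades only a subset of control points).

**Head phantom.** `make_head_phantom(seed)` builds a water-equivalent
path-length map (cm) on a 0.5–1 mm isocenter grid: an elliptical head
(~12 × 16 cm) with an ellipsoidal-chord thickness profile (~16 cm), a
skull-like dense rim, one bone blob, two air cavities, and a hard
tissue–air external contour (path length is zero strictly outside,
≥ 0.4 cm inside). Pose errors are rigid: lateral/longitudinal shifts plus
a roll. The roll pivots about a point 10 cm from the beam axis on the
support side — a phantom on a leveling plate rotates about its support,
not about the beam axis — so a roll also translates the anatomy laterally
(1° ≈ 1.7 mm at the field centre). This pivot is what makes a 1° roll a
more severe image perturbation than a 1 mm shift, reproducing the severity
ordering such setup-error studies observe; shifts and roll are applied in
reinforcing orientations. The phantom is synthetic: absolute passing rates
are anatomy-dependent and are *not* comparable to any measured head, so
tests assert only orderings (rates fall with severity, rise with criteria
looseness), averaged over 20 phantom seeds for the severity direction
(individual random anatomies can swap adjacent severity levels by a few
tenths of a percent).

**Noise.** Multiplicative i.i.d. Gaussian per pixel, σ = 0 by default
(geometry studies are noise-free), with an explicit integer seed;
`(configuration, seed) → image` is a pure function. The repeated-delivery
constancy check uses σ = 0.1% by default; emulating a panel whose
pairwise images agree within 0.2% requires σ ≈ 0.025% (the maximum
pairwise DD over ~10⁴ evaluated pixels is ≈ 6.7·σ), and the constancy
report flags its 0.2% bound accordingly.

## Comparison engine

All three tests evaluate a fraction image against the baseline on the
same grid, normalized to the baseline maximum `N` (global normalization;
the per-pixel alternative is a documented hook, not implemented). Pixels
with baseline dose below the threshold (default 10% of `N`) are excluded
from both classification and the passing rate. Equality passes
everywhere: |DD| = ΔD, DTA = Δd and γ = 1 are passes. A pure-geometry
test is mode `dta_only` (not a zero dose-denominator in γ), a pure-dose
test is `dd_only`.

**DTA.** For pixel `p` with dose `v`, the engine extracts the iso-level
line `D_ref = v` of the bilinearly interpolated baseline with marching
squares on a window covering the search radius, then refines the nearest
point by Newton projection onto the bilinear level set (the marching
chord is exact on straight edges but errs on tightly curved contours).
The search radius is `max(3·Δd, 5 mm)`; beyond it "no agreement" is a
failure (DTA = +∞). Two numerical tolerances are intrinsic to searching a
*sampled* baseline:

* *Dose matching tolerance.* A level can graze a grid extremum (e.g. the
  bottom of a couch-strip dip) and then genuinely not exist in the
  bilinear surface even though the continuous distribution attains it.
  Each node therefore matches doses within its own bilinear
  interpolation-error bound (local second differences / 8), floored at a
  dose-resolution of `N/2¹⁶` (16-bit digitization). Without this, such
  pixels would report infinite DTA and the descent would trigger at its
  starting tolerance.
* *Distance allowance.* The interpolated level lines sit within
  `O(pitch²·curvature/gradient)` of the continuum's, in either direction,
  so the pass test fires only when DTA exceeds the tolerance by more than
  `pitch/8` (configurable). This makes geometric flags conservative
  against interpolation artefacts — the measured behaviour of such
  systems, where failing pixels appear only at tolerances *below* the
  induced error — and preserves the exact one-step-below descent result
  at both the native (0.39 mm) and half (0.78 mm) pitch.

In low-gradient regions (profile tails) the level-matching problem is
intrinsically ill-conditioned and DTA can exceed the induced translation;
this is visible in the couch-shift scenario, where the strip-dip contrast
is only 3% and detection can occur at or slightly above the induced shift
— the same anomaly reported for measured couch shifts.

**Gamma.** Exhaustive minimisation over a refinement lattice of step
≤ 0.1·Δd within the capped radius, baseline interpolated bilinearly,
visiting offsets in order of increasing distance and retiring pixels once
the distance term alone exceeds their current best (an exact early
termination). Verified against an independent full-lattice brute-force
minimiser to machine precision, and the DTA search against an independent
dense-grid crossing scan to < 0.05 mm, on seeded smooth fields.

## Tolerance descent

`sweep_dta` / `sweep_dd` descend from a starting tolerance above the
expected error in fixed steps (default 0.1 mm / 0.1%) and stop at the
first tolerance with ≥ `min_fail_pixels` failing pixels (default 1, the
strictest reading of "failing pixels begin to appear"; a larger cluster
criterion is configurable). Thresholds are reported on the grid, never
interpolated; if the floor is reached without failures the result is "not
detected", not an exception. Sensitivity is the absolute difference
between the induced error and the threshold. The DTA metric map does not
depend on the tolerance, so the sweep computes it once at the largest
radius and re-thresholds — tolerance-for-tolerance identical to
re-running the comparison, since an agreement found within radius `r` is
found within any larger radius.

Closed forms provided alongside: a collimator rotation θ of a square
field of side L deviates the edges by at most `(L/2)·tanθ`; a vertical
couch error `v` under SAD `s` changes a region of diameter `D` by
`D·v/s` (edge shift half that); an oblique beam at angle α sees `v·sinα`
of a vertical error. Vertical-couch effects are treated analytically
only, not rendered.

## Experiment runner

`run_experiment` renders the baseline once per scenario, one errant image
per magnitude, applies the scenario's analysis, and emits one report row
per magnitude with provenance (config hash, seed, version); re-running a
spec is bit-identical. Default problem sizes are chosen for a desk-scale
suite: a 2× downsampled panel (0.78125 mm pitch, 384 × 512) for the
machine-error scenarios — detection thresholds are pitch-stable because
edges are continuous, asserted by running the jaw sweep at both pitches —
and a 2 mm grid for the head-phantom study, whose synthetic anatomy has
no sub-millimetre structure. The pseudo-IMRT scenario synthesises 5–10
seeded rectangular MLC segments as an MU-weighted composite, then
perturbs every 4th leaf; the arc (VMAT-proxy) scenario is an MU-weighted
sum of 8 static renders with the rail band present for 3 of them. Email
alerting is reduced to a non-zero exit code and log line in the CLI when
the passing rate misses the preset (default 95%, an example value, not a
recommendation).

`three_way_comparison` resamples coarse representations (e.g. a 5 mm
diode-array grid) to the finest pitch present, runs gamma per pair and
reports the passing-rate spread; the synthetic analogue of cross-checking
a portal image against an array measurement and a planning-system
calculation, with a 3% default spread bound.

## What the synthetic study does and does not show

The generator reproduces the geometric structure of transit images
(magnified apertures, penumbra, attenuation patterns, rigid anatomy
motion) with exact, continuous edge positions, and the statistical
structure only as uncorrelated multiplicative noise. It does not model
scatter kernels, panel glare/ghosting, beam-profile flatness, cine
acquisition, or real anatomy. Passing tests therefore demonstrate the
*comparison chain's* sensitivity — that the DD/DTA/gamma logic, the
boundary conventions and the descent procedure resolve errors down to one
sweep step under noise-free conditions, and degrade gracefully with noise
— not the absolute sensitivity of any physical EPID system, which is
additionally limited by measurement noise of order a few tenths of a
millimetre and 0.2% in dose. Absolute rail dose errors and head-phantom
passing rates depend on unmodelled composition and anatomy and are
asserted only as orderings and bounded relationships.

## Degenerate inputs and edge cases

Apertures entirely outside the panel render as zeros with a warning.
All-zero baselines raise (normalization undefined), as does a passing
rate over zero evaluated pixels. Gamma with a zero tolerance raises and
points to the single-criterion modes. Zero-magnitude error injections are
bit-identical to the nominal rendering. DD classification carries a 1e-9
(percent) absolute guard so exact-ratio scalings land on the pass side of
the boundary regardless of floating-point rounding direction.
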