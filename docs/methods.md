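# Methods

`lvphantom` builds a fully synthetic, ground-truth-known analogue of a
flexible-walled left-ventricle (LV) bench model and the four measurement
chains used to characterize it: stereo-photogrammetry (SP) of surface
markers, short-axis cine segmentation (CMR-like), transvalvular flow
integration (inline probes and PC-CMR-like sampling), and planar particle
image velocimetry (PIV).  Because every observation is generated from a
known deforming geometry, each reconstruction can be validated by recovery
of the true volume waveform rather than by agreement with another imperfect
modality.

## The phantom

**Geometry.** The cavity is a stack of concentric ellipses along the long
axis (z, apex at z = 0): an ellipsoidal apex-to-base profile with equal
default semi-axes (21 mm before scaling) over an 80 mm long axis, truncated
by one oblique basal cut plane.  The cut plane passes through the axis at
z = 64 mm with its normal tilted 35° from the long axis, i.e. the dihedral
angle between the plane and the axis is 125° on the outflow side; the tilt
lies inside the x = 0 plane so the cut respects the left/right mirror
symmetry the SP reconstruction assumes.  Cross-section areas, including
sections clipped by the cut, are evaluated with the closed-form
elliptical-segment formula, and cavity volume is the trapezoidal integral of
area over z (200 sections by default; the discretization error against the
closed-form ellipsoid volume is below 0.5 %, and halving the spacing moves
the result by < 0.2 %).  The reference geometry is scaled so the
end-diastolic cavity volume is exactly 65 mL.

**Wall.** The 1.59 mm silicone wall is represented as a constant *in-plane*
offset of the cavity ellipses (outer semi-axes a + t, b + t), not a true 3-D
normal offset.  The SP wall-offset correction subtracts the same in-plane t,
so generator and reconstruction are exactly consistent; the difference from
a true normal offset is concentrated at the apex and is far below the 2 %
volume tolerances used throughout.

**Volume waveform.** V(t) is piecewise smooth over the 60/70 s cycle:
isovolumic contraction (40 ms), a raised-cosine ejection lobe, isovolumic
relaxation (40 ms), a raised-cosine filling lobe, and diastasis.  Filling is
monophasic (single E-wave; no A-wave).  Lobe durations are solved so each
lobe integral equals the stroke volume (65 − 31 = 34 mL) at the configured
peak flows (aortic 20 L/min, mitral 17.5 L/min), which makes the printed
volume extremes and peak flow rates hold simultaneously.  Note the
parameterization is stroke-volume-driven: 34 mL at 70 bpm implies a cardiac
output of 2.4 L/min, which is what the generator produces; a 3.5 L/min
output cannot coexist with these volume extremes at this heart rate, and no
attempt is made to reconcile the two.

**Deformation and wall speed.** Each phase scales the short-axis semi-axes;
since the cut plane transforms as a material surface, volume scales exactly
as the in-plane area factor and the scale solve is closed-form (a bisection
polish guards non-exact cases at 0.1 %).  In the default *uneven
contraction* mode the x/y semi-axis ratio k(t) builds to 1.10 with ejection
(area-preserving, so volumes are untouched) and returns to 1 at filling
onset as an underdamped elastic recoil (decay constant 30 ms, oscillation
period 50 ms).  The recoil is the mechanism by which the flexible wall
produces a burst of wall speed at early diastole; together with the
peak-systolic excursion it determines which cine frames blur.  Wall speed is
the maximum over a fixed parametric grid of outer-surface points of
|dp/dt| by periodic central differences.

**Markers and pin.** A 4 mm grid of 2 mm markers covers one lateral half
(x > 0) of the outer surface: rows at equal meridional arc spacing, columns
at equal circumferential arc spacing, nothing printed within 1 mm of the cut
edge.  Marker identity is the (row, column) parameter pair, which is
material — the same marker is re-evaluated on every deformed geometry.  A
fiducial pin sits at the apex on the long axis; in-plane scaling leaves it
fixed, so it is stationary in every frame of both cameras.

**Cameras and distortion.** Two 1280 × 1024 px pinhole cameras sit 600 mm
from the chamber at ±14° azimuth on the marker side.  Imaging through
air/acrylic/water-glycerin is emulated as a smooth image-space displacement
(quadratic polynomial of normalized world position, scaled to a 2 px
maximum) applied after projection — deliberately the kind of spatially
varying bias a localized calibration can absorb and a single global DLT
cannot; ray-level refraction is not traced.  Pixel noise is i.i.d. Gaussian
(0.5 px default), independent across the 15 cycles.

**Cine stack.** Fifteen contiguous 6 mm slices at 1.2 × 1.2 mm in-plane
resolution (64 px images) cover the long axis; lumen/wall/background render
at 0.85/0.35/0.15 with 3 × 3 supersampled edges and additive Gaussian noise
(sigma 0.03).  Phases whose wall speed exceeds a threshold are convolved
with a 45° line kernel of length speed x 0.1 s; the threshold is calibrated
as the midpoint between the 7th and 8th fastest of the 128 phases, so
exactly 7 phases — clustered at peak systole and early diastole — carry blur
flags (121/128 = 94.5 % ≈ 95 % usable).

**Flow sampling.** Probe-like flows are the waveform's exact derivative
split into mitral (dV/dt > 0) and aortic (−dV/dt > 0) channels in L/min on
the dense 214-point grid.  PC-CMR-like flows sample 20 phases/cycle and add
5 % regurgitant lobes (reverse mitral flow during ejection, reverse aortic
flow during filling); the leak is subtracted from both channels equally so
q_mv − q_av, and hence the integrated volume, is unchanged.

**PIV field.** Early diastole is an analytic field: a central jet with
Gaussian cross-stream profile (FWHM = the 19.5 mm equivalent diameter of the
3.0 cm² valveless mitral annulus) arrested smoothly at the vortex depth,
plus a counter-rotating Lamb–Oseen pair (±11 mm off-axis, 5 mm cores,
0.55 strength ratio); the whole field is rescaled so its peak speed is
exactly the configured 1.15 m/s.  Particle pairs are Gaussian spots advected
through the field by the midpoint rule over dt = 1 ms at 0.167 mm/px, giving
~7 px jet displacement (the 5–8 px design band).

## The reconstructions

**Stereo-photogrammetry.** Calibration uses a 1 cm grid sheet traversed
along x (7 planes, 63 points each).  Global calibration is the standard
11-parameter DLT solved by normalized linear least squares; localized DLT
(LDLT) tiles the calibration volume into 3 × 3 × 3 cells and fits 11
parameters per cell per camera, sharing points across a 35 % cell margin so
every cell stays over-determined.  Triangulation intersects the two DLT rays
in least squares; in localized mode the cell is re-selected from the current
solution until it contains it (≤ 5 rounds; a boundary oscillation settles on
the nearest cell centre; otherwise the global fit is the fallback).  Pixel
tracks are ensemble-averaged over the 15 trigger-synchronized cycles before
triangulation, the half-cloud is mirrored across the x = 0 plane through the
triangulated pin, and volume is extracted slicewise: points are clustered
into rings by their z gaps, an ellipse is least-squares fit per ring
(free fits are trusted only when the arc covers ≥ 180°; sparser rings
inherit shape parameters extrapolated in z, and rings with neither are
dropped), rings truncated by the basal cut are clipped at the chord of the
missing arc after extending each arc end by the expected 3 mm printing
shortfall (cut margin + half the grid pitch — without this correction the
base is systematically under-counted by ~2 %), semi-axes are shrunk by the
wall thickness to convert the outer surface to the cavity, and area is
integrated over z with linear extrapolation to zero at apex and base.  A
convex-hull volume is available as a cross-check.  Noiseless end-to-end
recovery is within 2 % of EDV at all 214 phases; with 0.5 px noise the error
stays ~1 %.

**Cine volumetry.** Each slice image is segmented by the piecewise-constant
(Chan–Vese) region-based active contour as implemented in scikit-image,
wrapped with: Otsu-threshold level-set initialization for cold starts
(a centred-circle init is available but converges slowly for small apex
lumens), warm starts from the previous usable phase within a slice and from
the neighbouring slice at the first phase (mid-ventricle outward), budgets
of 120/40 iterations (cold/warm; full budget again after a rejected-phase
gap) at tolerance 1e-3, brighter-region selection, largest-component/
hole-fill post-processing, and a final local re-threshold at the midpoint of
the lumen mean and the adjacent wall-ring mean.  That last step matters: the
two-region model pools wall and background into one mean, which parks the
contour a fraction of a pixel outside the lumen and biases small-volume
phases by up to +5 %; re-centering the boundary on the lumen–wall edge
brings noiseless recovery within 2.5 % per phase and EF to 52.0–52.1 %
(truth 52.3 %).  Blurred phases are excluded either by the stack's flags or
by a sharpness criterion (per-phase mean gradient energy below 0.75 of its
cyclic rolling-median baseline), which identifies the same 7 phases; volume
is lumen pixel area × slice thickness summed over slices, with no
interpolation across gaps.

**Flow integration.** V(t) = ESV + ∫(q_mv − q_av) dt from the detected
end-systolic instant (mitral upcrossing), trapezoidal, with L/min → mL/s
conversion.  The integrand sign is the physically correct one: filling
raises volume.  The 20-phase sampling is resampled to the dense grid by a
periodic cubic spline before integration.  Round-trip recovery (derive flows
→ integrate) is within 0.05 % of EDV at probe sampling and ~3 % at 20-phase
sampling.

**Comparison.** Each modality's volume curve is divided by its own cycle
maximum and mapped to cycle fraction; the coarser curve is periodically
spline-resampled onto the finer curve's samples (so cine gap phases are
simply absent from the grid), and the statistic is the pointwise
100·|V̄_a − V̄_b| summarized as mean ± population sd plus the maximum and
its phase.  Three pairs are reported: CMR vs SP, SP vs probes, CMR vs
PC-CMR.  The ESV constant for probe integration comes from the SP minimum
and for PC-CMR from the cine minimum.

**PIV.** Sliding-minimum background subtraction (5 px box; a sliding-mean
variant is configurable), dual-pass FFT correlation (64 → 32 px, 50 %
overlap) with integer predictor shifting of the second tile, 3-point
Gaussian sub-pixel peak fit (parabolic fallback at non-positive samples),
peak-ratio Q with a 3 px exclusion zone, Q < 1.2 deletion, linear
(nearest-neighbour at edges) hole filling, and node-wise ensemble averaging
with valid-sample counts.  Windows whose second tile would be gathered
outside the frame are clamped and carry the usual frame-edge wrap bias;
quantitative assertions therefore address interior vectors.  A 50-pair
ensemble recovers the analytic field with ~1.3 % RMS of peak speed, the peak
itself within 3 % (the residual attenuation is window averaging across the
jet profile), and both vortices with correct signs and positions.

## What the generator does and does not emulate

The phantom reproduces the *structure* of the bench data — sampling rates,
marker layout, slice geometry, blur counts, flow discretizations, seeding
densities — with simple noise models (Gaussian pixel/intensity/position
noise, polynomial distortion, linear motion blur).  It does not emulate MR
physics (SSFP contrast, k-space artefacts), valve leaflet kinematics,
pressure dynamics, biphasic filling, or real refraction; and its noise
amplitudes are small and well-behaved compared with a physical rig.
Consequently the cross-modality discrepancies measured here (≈ 0.2–0.7 %
mean) are floor values set by the reconstruction algorithms themselves, not
reproductions of bench-level discrepancies (≈ 5–8 %), which are dominated by
apparatus effects the phantom deliberately omits.  Passing tests demonstrate
the correctness of the measurement chains, not field accuracy on real data.

## Problem sizes and numerical choices

Default runs use the full SP configuration (214 phases × 15 cycles) and a
64-phase cine stack; the blur statistics are always computed on the full
128-phase stack (the blur calibration is defined there), and segmentation of
the full 128-phase stack is available by configuration.  The PIV ensemble
default is 50 pairs (200 behind a parameter).  These sizes keep a complete
analysis run in the low minutes on one core.  Other numerics: ellipse-stack
sections 200/geometry; ellipse fits require 5 points; ring clustering gap =
half the band height; LDLT cell-boundary ties resolve to the nearest cell
centre (lowest index on exact ties); normalization ties take the first
maximum; comparison sd is population (ddof 0); degenerate inputs (zero
contrast, coplanar calibration points, collinear rings, empty cells,
< 4 spline samples) raise errors naming the defect.
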