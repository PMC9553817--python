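# Methods

## Problem

Freely diffusible ¹⁵O-water equilibrates with tissue water within a minute, so a
cardiac perfusion scan holds no late-uptake contrast from which ventricular
anatomy could be read. Kinetic modelling of the dynamic data, however, yields a
voxel-wise *perfusable tissue fraction* (PTF, mL of water-perfusable tissue per
mL of voxel) alongside myocardial blood flow. PTF is an intrinsic
partial-volume correction and, as an image, a high-contrast structural map of
the time-averaged left ventricle. `ptfmass` measures left-ventricular mass
(LVM) and mid-septal wall thickness (WT) by contouring that PTF map, and
classifies LV hypertrophy from the results.

## Kinetic model

Each voxel's decay-corrected activity is modelled as

    C_PET(t) = PTF · F e^(−F t / p) ⊗ C_A(t) + V_A · C_A(t) + V_RV · C_RV(t)

with F the tissue flow (mL·min⁻¹·mL⁻¹), p = 0.91 mL/mL the water partition
coefficient, C_A and C_RV the arterial and right-ventricular blood curves, and
V_A, V_RV spill-over blood fractions. Fitting uses the basis-function method:
F is discretised on a 50-point logarithmic grid over [0.05, 5] mL·min⁻¹·mL⁻¹;
for each candidate flow the three linear coefficients are found by
non-negative weighted least squares (weights = frame durations) and the flow
with minimal weighted residual wins, ties resolving to the lower flow. The
3-variable NNLS is solved exactly by enumerating all support subsets, which
vectorises over voxels; the full-volume fit of a 64³×22 study takes seconds on
one core. The basis convolution is computed in closed form per time step
(exact for a piecewise-linear input on the 0.5 s grid), so noise-free
parameters at grid flows are recovered to machine precision.

Input curves come either from a 3-column CSV or as mean time-activity curves
of LV-cavity and RV ROIs, interpolated linearly at frame midpoints onto the
fine grid. Midpoint interpolation cannot resolve the first-pass ramp (the one
or two frames around bolus arrival); this biases absolute PTF/MBF slightly but
leaves the geometry pipeline untouched, because contouring is invariant to a
global rescaling of the PTF map.

## Wall delineation and measurement

The PTF volume is rotated to short-axis orientation (long axis = principal
axis of voxels above 50% of the robust maximum, or explicit angles) and
resampled isotropically. Per slice, the cavity centre is the centroid of the
myocardial ring (PTF ≥ 50% of slice max) with one radially re-weighted pass;
36 rays at 10° increments are sampled at 0.5 mm steps out to 80 mm by bilinear
interpolation. On each profile the inner and outer contours sit where the
profile crosses a fixed fraction — 67% by default, 80% as the low-resolution
alternative — of its own maximum (per-slice maximum available as an option),
with sub-sample linear interpolation. A profile already above threshold at the
centre marks a slice through solid myocardium (apical/basal cap): its inner
contour collapses to the centre so cap mass is retained; without this the
closed-shell caps (~20% of shell mass) would be lost and end-to-end mass
recovery would be impossible. Slices qualify only if their robust (99th
percentile) peak reaches half the volume's robust maximum, and a plausibility
pass removes cap slices that are not contiguous with the ring block or are
wider than their adjacent ring slice — the ventricle tapers, so such disks can
only be noise in the surroundings.

LVM is the raster volume fully enclosed between the contour polygons
(all four in-plane cell corners inside the outer and outside the inner
polygon; cell-centre rule available) times 1.05 g/mL. The raster pitch is the
in-plane spacing divided by 16, at which the strict corner rule is within ~1%
of its limiting ring area; the membership test uses the star-shape property of
radial contours and is exact. WT is the mean contour gap over the 5 profiles
(nearest ±2 at 10° spacing) closest to the line joining the LV centre and the
intensity-weighted RV blood-volume centroid, on the middle contoured slice.
Indexed LVM uses Du Bois body-surface area; hypertrophy labels use strict
cutoffs of 81 (women) / 85 (men) g/m², and WT bands normal < 12 mm ≤ increased
≤ 15 mm < severe.

## Digital phantom

The phantom is an ellipsoidal LV shell (default epicardial semi-axes
45×30×30 mm, endocardial 36×21×21 mm: 9 mm wall, 108.3 g — a typical adult
heart), optionally with a septal wedge (endocardium pulled inward over an
angular span facing the RV), a long-axis tilt, an RV blood crescent (clipped
cylinder abutting the septum), and a thoracic background with PTF
0.25 mL/mL — lungs and mediastinum are perfusable, and this floor is what
keeps epicardial edge detection realistic; a heart in vacuum is the wrong
test. Wall kinetics default to PTF 0.70, flow 0.9 (rest) with 15% arterial
blood volume; cavities are pure blood. Blood curves are gamma variates
(arterial arrival 11 s, RV 5 s) shaped like a standardised 400 MBq bolus.
Truth is analytic: closed-form shell volume (wedge volume by 2-D quadrature,
Monte-Carlo checked) and the epi–endo gap along the LV→RV line.

Simulation evaluates the kinetic forward model per label (tissue fractions by
3³ sub-voxel sampling), blurs each frame with an isotropic Gaussian PSF
(default FWHM 5 mm, emulating contemporary scanners; 8 mm approximates an
older device) and adds seeded Gaussian noise with per-frame SD
`noise_scale·sqrt(mean activity / frame duration)` — image-domain noise,
because reconstructed images are the observable; the default `noise_scale`
of 1.5 yields ~9% voxel-wise PTF coefficient of variation in the wall at
default settings, a typical clinical parametric-map noise level. What the
phantom does *not* emulate: respiratory/cardiac motion, papillary and
trabecular tissue, attenuation/scatter residuals, non-Gaussian reconstruction
textures, recirculation tails in the input functions. Passing phantom tests
therefore demonstrates correctness of the measurement chain under controlled
degradation, not clinical accuracy.

## Validation statistics

Paired agreement uses OLS regression (scipy), Bland–Altman bias with
1.96·SD limits and a proportional-bias trend; reproducibility uses ICC(2,1)
(two-way random effects, absolute agreement, single measure) from the ANOVA
mean squares with McGraw–Wong F-based 95% intervals, plus the repeatability
coefficient 1.96·SD of differences (percent of the grand mean). ROC analysis
uses the Mann–Whitney rank AUC (ties ½), a Youden-J operating point (ties to
the lowest cutoff, positive test = score strictly above cutoff), Clopper–
Pearson intervals for proportions and DeLong intervals for AUC. The rank AUC
and the ANOVA ICC are verified in tests against brute-force pairwise counting
and independent implementations.

## Known behaviour and limitations

The fraction-of-maximum criterion is resolution-coupled. On an edge ramp one
voxel wide, the 67% crossing sits ~0.3 voxel inside the true surface on the
cavity side; under a 5 mm FWHM PSF the blurred peak of a 9 mm wall drops to
~0.96 of plateau and the cavity-side contour moves ~0.9 mm inward, while the
epicardial side is stabilised by the lung-background floor. Measured on the
default phantom: noise-free at 1 mm voxels LVM −4.2%, WT −0.58 mm; at 5 mm
FWHM with default noise the median LVM error is ≈ −12% and WT ≈ −1.6 mm,
stable across seeds. The sign flips when surroundings are hotter or blur is
larger relative to the wall — the same threshold–resolution interaction that
motivates the 80% alternative for low-resolution scanners. Rest/stress repeat
runs show a small systematic offset (~7 g on ~130 g) because PSF-mixed
wall/background kinetics are not exactly representable by a single-flow
model and the approximation error grows with flow disparity; two-seed ICC on
a 20-phantom batch is nonetheless 0.98. Degenerate inputs are handled
explicitly: spherical PTF blobs refuse auto-orientation, slices without rings
are excluded, fewer than 3 usable septal profiles is an error, all-identical
ICC input returns 1 with a warning.

## Study sizes

Desk-scale defaults keep every study on one core: phantoms are 64³ at 2 mm
(the clean identity run uses 1 mm), recovery studies use 20 noise seeds, and
the repeatability batch 20 phantoms × 2 runs.
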