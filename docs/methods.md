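# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is validated on, in enough detail to judge what the tests
do and do not demonstrate.

## Coordinate and unit conventions

Pixel coordinates are 0-based `(column, row)` sub-pixel floats. All 3D
quantities are millimeters in the left camera's frame (x right, y down, z
along the optical axis). The right camera is `X_R = R_ext X_L + t_ext`.
Distortion uses the standard 5-coefficient radial–tangential model; the
synthetic renderer is distortion-free by default.

## Stereo stage

**Rectification** follows the calibrated construction: a shared rotation
aligns the baseline with the x axis, both views are resampled through the
resulting homographies, and depth follows from disparity as `Z = f·b/d`.
Triangulation is the closed-form rectified solve (rows averaged between the
two views); the result is rotated back into the left-camera frame.

**Detector.** The elliptical salient regions come from an affine-adapted
determinant-of-Hessian detector: scale-normalized DoH maxima over a small
scale stack (`σ ∈ {1.6, 2.4, 3.6, 5.4}` px by default), sub-pixel refined
by separable quadratic fits, each assigned a shape matrix proportional to
the inverse unit-determinant structure tensor at its scale (eccentricity
capped at 4:1 to keep patches well sampled). The saliency strength is the
normalized detector response; inputs are range-normalized so responses are
comparable across the two cameras. Any detector producing (location,
positive strength, SPD ellipse, patch) can be substituted.

**Patches and similarity.** Elliptical regions are sampled through the
*symmetric* square root of the shape matrix onto a fixed 21×21 grid
restricted to the unit circle — the symmetric root is unique and
rotation-free, so corresponding left/right patches are sampled consistently
without estimating a relative orientation. Appearance similarity is NCC
after histogram equalization (256 bins on each patch's own range), which
cancels monotone intensity differences between the cameras.

**Matching.** The combined similarity is region IoU plus the saliency
ratio. The overlap term is computed after translating the right ellipse
onto the left's center: with any nonzero disparity a positional overlap
would vanish, so the term compares region *shapes*, which is the quantity
that is actually preserved under the small-baseline assumption. Ellipse IoU
uses 256-gon polygonal approximation (shapely); accuracy is ~1e-4 relative.
Candidates must lie within ±1.5 px of the epipolar row. Argmax ties break
on higher appearance score, then smaller absolute disparity, then image
position, making the output independent of input ordering; a right region
is kept by at most one left region (strongest claim wins). An exhaustive
brute-force scorer reproduces the matcher exactly in the tests.

**Local densification** re-detects at a 4× more permissive threshold inside
the (inflated) bounding boxes of the matched ellipses and matches the new
regions under the same constraints.

**Surface normals for propagation.** Under a point light co-located with
the camera, a Lambertian surface's image irradiance falls with tilt as
`cos θ`. The estimator smooths the image (σ = 12 px) to suppress albedo
texture, divides out the known geometric `cos³α` off-axis falloff, and
attributes the remaining *log*-brightness deficit (relative to the 98th
percentile) to tilt: `cos θ = exp(−deficit)`, oriented along descending
brightness. Deficits below a deadband (0.15 log units) are within the
residual-texture noise floor and read as flat. Consequences, verified in
tests: a fronto-parallel plane reads flat to <1° almost everywhere; the
strong shading of a deep indentation flank is detected; tilts much
shallower than ~30° are invisible. This is a smooth *gating field* for
match propagation — it is not a shape-from-shading reconstruction, and the
recovered tilt magnitudes should not be used quantitatively.

**Propagation** transfers an unmatched left region through the affine map
of the strongest seed whose ellipse contains it and whose normal agrees
within 1°: `f_R = M_R⁻¹ R M_L (f_L − f_L^seed) + f_R^seed`, where `M_L`,
`M_R` normalize the seed ellipses to unit circles. The relative orientation
`R` between the normalized regions is taken as identity — with symmetric
square roots and a small rectified baseline the residual rotation is
negligible, and the appearance check (equalized NCC ≥ 0.80 at the predicted
location, else the transfer is rejected as an outlier) catches the cases
where it is not. Propagation is a single pass over candidates, seeds
strongest-first.

**Subpixel disparity and outlier rejection.** At the target geometry
(f ≈ 1200 px, b ≈ 6 mm, Z ≈ 100 mm) one pixel of disparity is ~1.4 mm of
depth, so integer-pixel matching cannot be submillimeter. Matched
disparities are therefore refined by 1-D NCC correlation along the
rectified row with parabola interpolation (0.25 px sampling). Triangulated
clouds then pass a smoothness gate: a point whose depth deviates from the
median of its 8 nearest image-space neighbors by more than 2.5 mm is a
residual mismatch and is dropped. On the noiseless default fixture the
surviving cloud has ~0.04 mm mean depth error.

## Deformation stage

**Tracking.** Stable features (global/local matches; propagated matches are
unstable by construction) are tracked on the left image with
translation-only pyramidal Lucas–Kanade (3 levels, 15×15 patches).
Confidence is the NCC of the matched patch against the template from the
last confidently tracked frame; a frame is lost below 0.7, outside the
image, or when the update exceeds a per-frame displacement bound (20 px).
The template *slides* (refreshes at each confident frame) rather than
staying fixed at frame 0: a 10 mm indentation tilts the flank by ~45°,
foreshortening its texture by ~30%, which a fixed frame-0 template
mis-scores as lost even though localization is still sub-pixel — and losing
the flank starves the TPS of control points exactly where deformation is
largest. The cost of a sliding template is slow drift; over the
sequence lengths targeted here (tens of frames) drift is well below the
stereo noise floor.

**Per-frame 3D.** Each tracked feature is re-matched along its epipolar row
by 1-D NCC (coarse 0.5 px pass, fine 0.125 px pass, parabola; 17×17
patches) starting from its previous disparity, and triangulated. The
reference positions of stable features are measured with this same
correlation operator at the reference frame, so per-feature
texture-induced disparity bias largely cancels in `D = ‖S_t − S_O‖`.
Stable measurements whose D deviates from the median of their 8 nearest
stable neighbors by more than 2 mm are demoted to the unstable set
(deformation is locally smooth at the quasi-dense sampling density; such
points are almost always wrong re-matches).

**TPS mapping of unstable points.** The 3D thin-plate spline uses the 3D
biharmonic kernel `U(r) = r` with the standard bordered system; with
`λ = 0` it interpolates control points exactly (asserted to 1e-8 mm) and
kernel weights are orthogonal to the affine monomials by construction. The
pipeline thins control points to ≤ 400 with ≥ 1 mm separation over a
deterministically shuffled order — near-duplicate controls make the system
ill-conditioned, and an order-biased subset (e.g. top rows first) lets the
warp extrapolate wildly elsewhere — and uses λ = 1e-6 for conditioning
(`fit_tps`'s own default remains 0, pure interpolation). Warped unstable
points are projected to the left image; if the current reconstruction has a
point within 3 px (configurable; association beyond a few px mixes
neighboring surface points) and within a 25 mm deformation sanity bound, that
position is used at full confidence, otherwise the warped position itself
is reported at confidence 0.5.

**Reference frame** defaults to the first frame of the sequence and is
selectable (`--reference-frame`).

## Force stage

The material model is a degree-2 least-squares polynomial `F(d)`; the
intercept is free by default (flag to force through the origin), the
residual RMS is reported, and evaluation is refused beyond 1.2× the
calibrated displacement range (flagged as extrapolation beyond 1.0×). A
non-monotone fit triggers a warning since the displacement→force readout is
then ambiguous. The package ships a demo model `F = 0.01d² + 0.02d` (N, mm)
for closed-loop tests; it is scale-plausible for sub-0.3 N forces at
few-millimeter displacements but is **not** a measured tissue property.

The indentation is modeled as an isotropic 2D Gaussian (with a free
baseline, default-fitted) over tangent-plane surface coordinates — here the
(x, y) of the reference structure, adequate for the near-fronto-parallel
surfaces targeted. The fit is Levenberg–Marquardt (trust-region with
bounds: amplitude ≥ 0, σ ∈ [0.5, 50] mm) from moment-based initial values;
samples inside the occluded tool region are excluded, and the force
pipeline additionally uses only samples with confidence ≥ 0.9 (stable
points and snapped unstable points), so TPS-fallback values never bias the
peak. The peak displacement is `A + baseline` at the fitted center.

## Synthetic scenes

The generator emulates the validation setup the method targets: a brain-
phantom-like surface ~100 mm below a narrow-baseline (4–8 mm) stereo rig
with 800–1500 px focal length. The surface is a smooth seeded heightfield
(±1.5 mm bumps, 14 mm correlation length) carrying band-limited noise
albedo; deformation is a Gaussian indentation (σ = 6 mm) whose amplitude
ramps linearly from 0 to 10 mm over the schedule ("deformations up to
10 mm"), displacing material points along +z; a dark rod of 4 mm tip radius
occludes the center while pressing, and the ground-truth force is the demo
polynomial at the scheduled amplitude. Rendering is per-pixel
ray/heightfield intersection (fixed-point, exact to solver tolerance) with
Lambertian shading under a light at the left camera center, so per-pixel
depth and displacement ground truth are exact and the projection equations
of the geometry module hold identically.

What the fixtures do **not** exercise: specular wet-tissue reflection,
smoke/blood artifacts, fluid motion, photometric differences between real
camera pairs, rolling shutter, calibration error, and sensor noise (a noise
parameter exists but the validation fixtures are noiseless). Passing the
suite therefore demonstrates correctness of the algorithms in the intended
geometric/photometric regime, not robustness to clinical image degradation.

## Problem sizes and validation choices

The stereo accuracy fixture is 640×480 (one pair, ~3000 points, ~0.04 mm
mean depth error). The deformation fixture is 480×360 with 6 frames
(0→10 mm in 2 mm steps), a size chosen so the whole tracked sequence runs
in a couple of minutes while preserving the geometry of the full-size
setup; the reported deformation error (~0.2 mm mean over ~15k point
reports) is dominated by TPS interpolation across the tool-occluded stripe,
where no visual measurement exists and ~1 mm mean error against the hidden
truth is intrinsic to bridging an 8 mm gap in a σ = 6 mm bump. Stable
tracked points themselves are accurate to ~0.1 mm. Matcher/oracle
equivalence is checked at 200 features per image; Gaussian-peak recovery
over 100 seeded trials.

## Known limitations

- The matcher assumes similar region shapes between views (small baseline);
  wide-baseline rigs would need disparity-dependent shape compensation.
- The normal gate is effectively a strong-shading detector; on surfaces
  where shading is dominated by albedo at large scales it may gate loosely.
- Translation-only LK fails under fast in-plane rotation or large scale
  change per frame; the sliding template trades robustness for slow drift.
- Occluded-region deformation is a TPS inference, reported at reduced
  confidence; it cannot see genuinely non-smooth deformation under the tool.
- The Gaussian indentation model is isotropic; oblique tool contact with a
  strongly anisotropic footprint would bias the inferred peak.
- Only the indentation-axis force is estimated; lateral and torque
  components are out of scope.
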