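# Methods

## Coordinate conventions and calibration

All quantities are defined in a right-handed physical frame (μm) with
+z pointing toward the observer of the end-on view. Image rows grow
downward, so the conversion from annotations is x = col · p,
y = −row · p, z = plane · Δz · c, with pixel size p = 0.083 μm, plane
spacing Δz = 0.5 μm and axial correction c = 0.81 by default. The axial
correction compensates the refractive-index mismatch between immersion
oil and the aqueous sample, which compresses apparent axial distances;
it is applied to *every* z conversion in the package — both the tracing
and the optical-flow branch — because both express rotation per physical
micrometre of axial distance.

With y = −row the frame stays right-handed, and "bundles rotate
clockwise when moving toward the observer" (the definition of a
left-handed spindle) corresponds to dθ/dz < 0, so left-handed twist is
negative throughout.

Untilting applies the *minimal* rotation taking the pole-to-pole axis
onto +z (rotation about the common perpendicular). The canonical frame
is therefore defined up to the azimuth, which no reported quantity
depends on. Spindles tilted more than `max_tilt_deg` (default 20°) are
flagged: strongly tilted "end-on" stacks violate the assumption that
imaging planes are perpendicular to the spindle axis.

## Oblique-circle bundle tracing

A traced bundle (≥ 3 ordered points, calibrated and untilted) is
summarized by two nested fits:

1. **Plane**: total least squares via SVD of the centered points; the
   normal is the singular vector of smallest scatter, oriented with
   n_z ≥ 0. Points whose two smallest scatter eigenvalues are both
   below 1e-12 of the largest are collinear: the bundle is straight,
   hence achiral — twist 0, curvature 0, flagged `degenerate`.
2. **Circle in the plane**: points are projected orthogonally into the
   plane; a Kåsa algebraic fit initializes a Levenberg–Marquardt
   refinement of the orthogonal-distance residuals. In-plane collinear
   projections (second in-plane singular value below 1e-5 of the first,
   or a refined radius above 1e6 μm) give the straight limit R = ∞,
   curvature 0.

Derived per bundle: curvature 1/R; β, the angle between the fitted
plane and the z-axis (β = arcsin |n_z|, 0 when the plane contains the
axis); ρ̄, the mean distance of the (raw untilted, not plane-projected)
points from the z-axis; |twist| = β/ρ̄ in °/μm. The magnitude is exact
for points lying on a circle in an oblique plane, which the synthetic
tilted-circle oracle verifies to 1e-6 over β ∈ {2…20}°, ρ̄ ∈ {1,2,4} μm.
Using raw rather than plane-projected points for ρ̄ makes no difference
at that tolerance for exact circles and is the more direct reading of
"distance of these points from the axis"; both agree to well within
measurement noise on real traces.

The sign of the twist is the sign of the least-squares slope of the
unwrapped azimuth θ against z along the ordered trace. This choice is
exactly antisymmetric under mirroring (θ → −θ), robust to non-uniform
point spacing, and agrees with β/ρ̄ in magnitude for helical arcs.

Bundles with ρ̄ < `rho_min_um` (default 0.25 μm) are flagged
`unreliable_twist` (β/ρ̄ diverges on-axis) and, like degenerate bundles,
are excluded from the per-spindle mean; they remain in the per-bundle
table. The per-spindle summary is the unweighted mean of bundle twists
with SEM = sd/√n; if no valid bundle remains, the analysis errors out
rather than reporting a silent zero.

Contour length = length of the fitted arc between the projections of
the first and last trace points (of the two candidate arcs, the one
containing the projected interior points) plus the distance of each
trace end to its nearer pole. For straight bundles the polyline length
substitutes for the arc.

## Optical-flow helicity

Pipeline on an end-on stack with tracked poles:

1. keep planes between the pole planes (inclusive);
2. per plane, negated Laplacian-of-Gaussian ("Mexican hat") filtering
   at `log_sigma_px` = 3 px (≈ the 0.25 μm bundle cross-section radius
   at 83 nm pixels), negative responses clipped — bundles appear as
   bright blobs, smooth background vanishes;
3. per plane, zero all pixels below the `threshold_percentile` = 90th
   intensity percentile, then drop connected components smaller than
   `min_blob_px` = 25 px. The size filter matters: isolated noise
   spikes that survive the threshold flicker between planes, and the
   flow estimator turns them into large spurious angular steps,
   amplified near the axis by the 1/ρ geometry;
4. dense two-frame optical flow between consecutive preprocessed
   planes. The backend is scikit-image's iterative Lucas–Kanade
   (`ilk`, window radius 7, 10 warps) by default, with TV-L1
   selectable; both are standard dense two-frame estimators for smooth
   sub-pixel motion fields. Input pairs are jointly normalized to unit
   peak, so the flow — and hence the helicity — is exactly invariant to
   a global intensity rescaling;
5. per pixel at offset **u** (μm) from the axis (the pole-to-pole line
   interpolated to the mid-plane of the pair) with displacement **d**
   (μm): Δθ = atan2(u×(u+d), u·(u+d)), the signed angle from **u** to
   **u**+**d** — exact for rigid rotation, → tangential/|u| for small
   angles. Helicity = Δθ (deg)/Δz_corrected. Pixels with |u| <
   `r_min_um` = 0.5 μm are masked (the azimuth is undefined on-axis);
6. pooled weighted mean over all pixels of all plane pairs. The weight
   of a pixel is the *smaller* of its preprocessed intensities in the
   two planes of the pair: a pixel informs on rotation only if the
   bundle is present in both frames, so appearing/vanishing blob ends
   get no weight. Per-pair means are also reported;
7. tilt correction: one plane step spans Δz/cos α of spindle-axis
   length at tilt α, so the reported helicity is the raw value times
   cos α (`inv_cos` selectable for comparison; at the ≤ 20° tilts
   accepted for analysis the two differ by < 7%).

## Synthetic spindles

The generator emulates what the estimators consume, not the microscope:

* **Helix model**: bundle b follows θ_b(z) = θ_0b + ω z with radial
  barrel profile ρ(z) = ρ_max (4 z (L − z)/L²)^e. Defaults: 12 bundles,
  L = 11.5 μm and ρ_max = 4.5 μm (a typical HeLa metaphase spindle of
  length 11.5 μm and width 9 μm), e = 0.5 (rounded barrel outline),
  bundles spanning the central 60% of L (bundles are ~5 μm long, not
  pole-to-pole), azimuths evenly spaced with 5° seeded jitter. L is
  snapped to a whole number of corrected plane steps so the poles sit
  on integer planes. Trace points are exact (annotation error is not
  modelled); ground truth twist is ω for every bundle.
* **Tilted-circle model**: points exactly on a circle of radius R
  (default 5 μm) in a plane inclined β to the z-axis; the circle center
  is positioned by 1D root finding so that ρ̄ equals the requested value
  to ~1e-12, making the true twist exactly β/ρ̄ and the true curvature
  1/R. This is the analytic oracle for the tracing method.
* **Rendering**: each trace point becomes an isotropic 2D Gaussian spot
  (σ = 0.25 μm) of amplitude 400 on background 100, with seeded Poisson
  shot noise plus Gaussian read noise (σ = 30), giving per-bundle peak
  SNR ≈ 10; output is 16-bit. `static_texture_amplitude` adds a smooth
  random texture identical in every plane, emulating out-of-focus
  cytoplasmic signal. A pure-rotation stack generator (base plane
  rotated k·dθ per plane, bilinear interpolation) provides the sharpest
  flow oracle, with true raw helicity dθ/Δz_corrected.

What the synthetic validation does *not* show: performance under real
confocal point-spread functions (axial elongation, depth-dependent
aberrations), photobleaching, spindle movement during acquisition,
annotation error in manual traces, or bundles that merge/cross in
projection. Recovery numbers on synthetic data are therefore evidence
of correctness of the estimators, not of accuracy on any particular
microscope's data.

## Validation results computed by the test suite and acceptance script

* Tilted-circle oracle: twist and curvature recovered to ~1e-14
  relative error (tolerance 1e-6) across the β × ρ̄ grid.
* Helix model: the oblique-circle mean twist is within 10% of ω (the
  documented bias of approximating a helical arc by a circle; −1.87
  recovered for ω = −2).
* Flow recovery: over ω ∈ {−3,…,3} °/μm on noisy 12-bundle spindles,
  the recovered helicity is within max(0.3 °/μm, 15% |ω|) of ω and
  strictly monotone in ω (the whole grid runs in ~25 s on one CPU;
  stacks are ~147 × 147 × 33).
* Antisymmetry: mirroring traces negates bundle twists exactly (to
  1e-12 relative); mirroring stacks negates the pooled helicity within
  5%.
* Flow vs tracing on shared synthetic data: without background the two
  agree within 0.5 °/μm; with static background at 75% of the bundle
  amplitude the flow estimate keeps the correct sign but is biased
  toward zero relative to tracing — the known direction of the flow
  method's sensitivity to non-moving signal (tracing ignores the image
  entirely). The 75% level is used because the effect scales with the
  background fraction and is unambiguous there while the handedness is
  still detected.

## Numerical choices and edge cases

* Collinearity thresholds: 1e-12 (eigenvalue ratio, 3D) and 1e-5
  (singular-value ratio, in-plane); refined radii above 1e6 μm collapse
  to the straight limit.
* Classification boundaries belong to the stronger category (|ω| = 1 →
  weak, |ω| = 2 → strong); classification is odd-symmetric by
  construction.
* The two-proportion z test uses the pooled variance without continuity
  correction, and proportion errors are binomial (Wald) SEs — the
  conventions that reproduce the published compression statistics
  (p = 0.0064 for 9/80 vs 21/73; ±3.5% and ±5.3%).
* One-sample t from summary statistics (t = mean/SEM, df = n − 1)
  reproduces published p values only to ~2 significant figures because
  the published means and SEMs are themselves rounded.
* All randomness flows from a single integer seed per generator call;
  traces are exactly reproducible, stacks bit-identical on the same
  platform.

## Known limitations

* The flow pipeline assumes one spindle, roughly centered, with the
  pole axis near the optical axis; it has no multi-spindle detection.
* Helicity mixes all moving signal between the poles; individual
  aberrant bundles are invisible in the average (use tracing for
  per-bundle work).
* The ILK flow backend underestimates displacements on very dense
  texture by a few percent (visible in the pure-rotation oracle at
  ~5%), which partially cancels against the arc-approximation bias in
  method comparisons.
* Sub-pixel pole annotations are accepted but planes are assumed
  equidistant; variable plane spacing is not supported.
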