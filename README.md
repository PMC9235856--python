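# spindletwist

Quantification of mitotic-spindle chirality from end-on 3D fluorescence
z-stacks.

The metaphase spindle is not mirror-symmetric: its microtubule bundles
wind around the pole-to-pole axis, typically in a left-handed sense, at
rates of a few degrees per micrometre. This *twist* reflects the torques
generated by motor proteins inside the bundles, responds to mechanical
load, and changes when motors or nucleators are perturbed — so measuring
it precisely, with a well-defined sign convention, is the core
quantitative task. `spindletwist` is for cell biophysicists who have
end-on (pole-to-pole axis along the optical axis) confocal stacks of
spindles and want per-bundle or spindle-average twist values they can
compare across conditions.

## Methods implemented

Conventions: right-handed frame with +z toward the observer of the
end-on view; θ is the azimuth about the pole-to-pole axis; twist ω =
dθ/dz in °/μm; **negative ω = clockwise rotation toward the observer =
left-handed**. Plane indices convert to physical z by
z = plane · Δz · 0.81, the 0.81 correcting the refractive-index mismatch
of the axial distances; lateral calibration is 83 nm/pixel by default.

**Oblique-circle bundle tracing** (semi-automatic, per bundle). After
rigidly untilting the spindle so the pole axis lies on +z, each manually
traced bundle gets a total-least-squares plane fit, then a circle fitted
in that plane (Kåsa initialisation, geometric refinement). Then

- curvature = 1/R,
- |twist| = β/ρ̄, where β is the angle between the fitted plane and the
  z-axis and ρ̄ the mean distance of the trace points from the axis,
- sign(twist) = sign of the mean azimuthal advance per unit z along the
  ordered trace,
- contour length = fitted arc length + distance of each bundle end to
  its nearer pole.

The identity |twist| = β/ρ̄ is exact for points on a circle in an
oblique plane; the package's synthetic tilted-circle generator verifies
the implementation against it to 1e-6.

**Optical-flow helicity** (automatic, spindle average). Planes between
the poles are blob-enhanced with a Mexican-hat (negated
Laplacian-of-Gaussian) filter, thresholded, and cleaned of small
components; dense two-frame optical flow (scikit-image iterative
Lucas–Kanade, or TV-L1) is estimated between consecutive planes; each
pixel's displacement **d** at offset **u** from the axis becomes an
angular step Δθ = ∠(**u**, **u**+**d**), and the spindle's helicity is
the mean of Δθ/Δz over all pixels of all plane pairs, weighted by
normalized intensity, finally multiplied by cos(tilt) to correct for
residual spindle tilt.

**Statistics**: five-level twist classification (|ω| < 1 none, 1–2 weak,
≥ 2 strong), strong-twist fractions with the mean − 1 SD cutoff rule
(−2.8 °/μm default), two-proportion z test (pooled, no continuity
correction), one-sample t from summary statistics, Welch and paired t,
one-way ANOVA + Tukey HSD, OLS twist-vs-aspect-ratio fits, background-
corrected intensity quantification.

**Synthetic spindles**: a seeded generator produces helix-model bundle
traces with known ω and a barrel-shaped radial profile, renders them
into 16-bit stacks (Gaussian spots, Poisson + Gaussian noise, optional
static out-of-focus background), and provides exact tilted-circle traces
and pure-rotation stacks as analytic oracles.

## Worked example

```sh
$ spindletwist simulate --twist -2 --seed 1 --out-dir demo
wrote synthetic spindle (omega=-2.0 deg/um) to demo
$ spindletwist trace demo/traces.csv demo/poles.csv --out-dir demo
synthetic: mean twist -1.87 +- 0.00 deg/um (n=12, weak_left)
$ spindletwist flow demo/stack.tif demo/poles.csv --out-dir demo
synthetic: helicity -1.93 deg/um (raw -1.93, tilt 0.0 deg)
```

`simulate` builds a 12-bundle spindle with ground-truth twist
−2 °/μm and writes the stack (`stack.tif`), the exact bundle traces and
pole annotations (CSV), and the ground truth (JSON). `trace` runs the
oblique-circle method on the traces: every bundle reports −1.87 °/μm
(SEM 0.00 — the bundles are noiseless copies up to azimuth), slightly
below the true rate because a helical arc is approximated by a circle;
the spindle is classified `weak_left`. `flow` runs the optical-flow
pipeline on the rendered noisy stack and reports −1.93 °/μm with zero
tilt correction — both methods agree on a left-handed spindle of about
2 °/μm. Library use mirrors the CLI: `generate_traces` /
`render_stack`, `analyze_spindle`, `flow_twist_pipeline`.

The per-bundle table (`demo/bundles.csv`) carries twist, curvature,
radius, β, ρ̄, contour length and quality flags per bundle; per-spindle
means, SEM and class land in `demo/spindles.csv`.

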