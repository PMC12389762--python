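# Methods

This note records the model, the numerical choices and the assumptions
behind `nwirecal`, in the order the pipeline runs.

## Coordinate model and estimation problem

Four frames: image `U`, probe-mounted sensor `R`, tracker world `W`,
phantom `P`. A pixel `(u, v)` lifts to the metric image plane as
`(sx*u, sy*v, 0)` and maps to the phantom through
`T_WP · T_RW · T_UR`. The sensor pose `T_RW` is measured per frame;
`T_UR` (the calibration), `T_WP` (where the phantom sits in the world)
and the pixel scales are estimated by minimizing the summed squared
distances to the known phantom positions of the diagonal-wire
crossings. Rigid transforms are parameterized by intrinsic Z-Y-X Euler
angles (radians) plus translation (mm) — 14 free scalars in total. The
pixel scales enter through their logarithms, which keeps them positive
without constrained optimization. Euler parameterization is adequate
here because all rotations stay far from gimbal lock; the convention is
used consistently everywhere (a fixed convention is all the objective
requires).

Each N-wire layer is a parallelogram `a, b, c, d` (`d = b + c − a`)
with two side wires `a→c`, `b→d` and the diagonal `a→d`. From an image
triplet A, B, C the ratio `alpha = |BA|/|CA|` places the diagonal
crossing at `a + alpha·(d − a)` by similar triangles, with the layer's
height known by construction. Triplets whose ratio falls outside
`[−0.05, 1.05]` are discarded as mislabeled; values inside the band are
clipped to `[0, 1]` before mapping. The default phantom has 3 layers,
10 mm apart, with 25 mm wire spacing and (a choice — only the spacings
are dictated by the open-source layout) 25 mm wire length.

## Feature detection

1. **Directional top-hat.** The background is the pixel-wise maximum of
   grey openings with 1-px-wide line elements (length 21 px) at 0°,
   45°, 90° and 135°; subtracting it removes any structure elongated
   along at least one tested direction (echo artifacts, phantom walls)
   while compact blobs survive. 21 px exceeds twice the largest
   expected blob diameter yet is shorter than typical artifacts.
2. **Multi-scale Hessian determinant.** Second derivatives come from
   separable Gaussian-derivative kernels (half-width `ceil(3σ)`,
   reflective borders; the second-derivative taps are re-centred to sum
   to zero so constants and ramps are annihilated exactly), and the
   determinant is normalized by `σ⁴` so responses are comparable across
   scales. The default scale set {1.5, 2, 2.5, 3, 4, 5, 6} px spans the
   apparent blob sizes of 5–12 cm imaging depths; the per-pixel maximum
   over scales is kept, with the arg-max scale recorded.
3. **Threshold and NMS.** The threshold is relative,
   `δ = 0.04 · max(Λ)`, making the candidate set invariant to global
   intensity scaling; sub-threshold responses are zeroed but
   supra-threshold values are preserved (the response value, not a
   binary mask, feeds later stages). 8-connected non-maximum
   suppression keeps strict local maxima; on exact plateaus the first
   pixel in row-major order represents the plateau. At most 60
   candidates (by response) continue, which bounds the triplet
   enumeration.

## Structural filtering

Collinearity keeps u-ordered triplets whose middle-to-neighbour slopes
are both within 0.05 of the reference slope (0 by default — the probe
is assumed to hold the wires roughly along image rows; a configurable
offset supports rotated mounts). The sorted slopes are scanned with a
window of size equal to the layer count; the tightest window's mean is
the frame's main slope, and triplets deviating by ≥ 0.05 from it are
dropped. Distance consistency requires the two intra-triplet gaps to
agree within 10 px and, across vertically adjacent rows, the B-to-B
gaps to agree within 10 px (B is chosen as the anchor because it is the
calibration point; the comparison of corresponding points is otherwise
ambiguous). When an inter-row violation implicates three rows, the row
whose removal minimizes the remaining violations is dropped, with lower
summed response breaking ties — this reliably removes a spurious row
wedged into an otherwise regular stack. Candidate-sharing conflicts are
resolved greedily by descending summed response.

Centre refinement selects, inside a ±30 px window, the pixel whose
8-neighbour mean intensity is highest (row-major tie-break). The
procedure intentionally returns whole pixels — selecting an integer
arg-max of a local statistic — and the ~0.3 px quantization this
implies is visible in the noiseless image-path error floor (~0.03 mm at
0.1 mm/px). An intensity-weighted centroid refinement exists behind
`FilterParams` for experimentation but is off by default.

Rows are assigned to phantom layers top-to-bottom and labeled A/B/C
left-to-right (flippable for mirrored mounts). If fewer rows survive
than the phantom has layers, the frame is excluded from calibration:
row order alone cannot tell *which* layers remain, and a wrong guess
injects a layer-spacing-sized (10 mm) gross error. Such frames still
count in detection metrics; they are only barred from correspondences.

## Robust estimation

Initialization draws 50 seeded guesses for `T_UR` (identity first, then
random rotations up to 20° with translations within ±50 mm), polishes
each by three sweeps of alternating closed-form rigid fits (with `T_UR`
fixed, the optimal `T_WP` is a Kabsch fit of world-frame image points
onto phantom points, and vice versa) and keeps the lowest mean
residual. On clean data this lands essentially at the optimum; the
restarts only matter when correspondences are heavily contaminated.

The Levenberg–Marquardt solve uses the three residual components per
correspondence (3N equations, 14 unknowns; at least 5 correspondences
required), tolerances 1e-10 and an iteration cap of 200; it never
returns a state with a larger residual sum than its start. RANSAC draws
minimal subsets of 10 correspondences (pooled across frames — the
correspondences, not the frames, are the exchangeable units), fits each
with a capped loose L-M solve (tolerance 1e-6, 50 iterations)
warm-started from the initialization, and counts inliers with residual
< 0.5 mm over the full set. The loop runs up to 3000 iterations but
stops early when the inlier ratio reaches 0.9 or when the best inlier
set has not improved for 150 consecutive draws — the "inlier-set
convergence" criterion; on clean data the very first draw typically
ends the loop. The final tight L-M refinement on the winning inlier set
yields the reported state; residuals are re-evaluated on all
correspondences and the mean/max are summarized over the inliers.

A diagnostic warns when the pose set spans less than 5° of rotation
about any axis: with little rotational diversity the split between
`T_UR` and `T_WP` becomes poorly conditioned (reconstruction residuals
remain meaningful, but individual parameters drift along sloppy
directions). The default simulated protocol deliberately uses small
rotations (below) and therefore triggers this warning; it is
informational.

## The simulator and what it does (not) show

The generator emulates a water-tank acquisition over the default
phantom at 0.1 mm/px on 512×512 frames, with the sensor mounted ~3–4 cm
from the image origin at a few degrees of misalignment. Design choices:

* **Scanning protocol.** Poses vary uniformly within (pitch, yaw, roll)
  = (0.8, 0.5, 1.0)° and (lateral, axial, elevational) translations
  (5, 5, 0.1) mm around the nominal pose, with rotations pivoting about
  the probe face (operators tilt the probe on its contact surface; a
  pivot at the sensor would translate the image by the lever arm). The
  ranges follow from the distance-consistency budget: the intra-row gap
  difference is `|2·alpha − 1| · ||AC||_px` plus localization noise,
  and with `||AC||` = 250 px and a 10 px tolerance the cut must stay
  within `|alpha − 0.5| ≲ 0.02` — i.e. the near-perpendicular,
  mid-wire protocol that the filtering thresholds themselves
  presuppose. Consequently the simulated poses are rotationally narrow;
  the conditioning warning above is expected.
* **Rendering.** Wire crossings are isotropic Gaussian blobs (default
  σ 2.5 px ≈ a 0.3 mm wire under a clinical PSF; configurable per frame
  to emulate depth), peak ≈ 230 over a background of 20. Echo artifacts
  are bright bars (length 60–140 px, ~2.4 px wide, random orientation);
  distractors are isolated wire-like blobs. Clutter keeps ≥ 38 px of
  vertical clearance from the wire rows (just beyond the 30 px
  refinement radius, so a refinement window never contains off-structure
  signal) and ≥ 30 px from other clutter, which also keeps any
  cross-structure pair steeper than the collinearity band. An optional
  *structured row* — three regularly spaced bright blobs forming a
  plausible but misplaced wire layer — exercises the
  distance-consistency stage in ablation experiments.
* **Noise.** Speckle is multiplicative `1 + s·(G − 1)` with `G` a
  mean-one gamma variate of shape 4 (a standard fully-developed-speckle
  approximation; `s` = 0.3 by default). Feature localization jitter is
  Gaussian (σ 1 px) truncated at 2σ — a bounded localization-error
  model — applied to the rendered blobs only; truth features stay
  exact. Recorded poses are the true poses perturbed by 0.2 mm / 0.1°
  zero-mean noise, below the nominal 1 mm tracker specification.

What the simulator does **not** reproduce: curvilinear scan-conversion
geometry (frames are rectilinear), depth-dependent attenuation and
focal-zone effects, beam-thickness (elevational) blur, correlated
speckle textures, reverberation trails under the wires, and temporal
misalignment between video and tracking. Passing tests therefore
demonstrate correctness of the algorithms under a controlled,
physically plausible noise model — not performance on any particular
clinical device.

## Problem sizes used in the checks

The bundled verification runs use 30-frame datasets (ten seeds) for the
calibration accuracy and RANSAC-benefit measurements, 200 frames with
per-frame blob scales drawn from {2, 2.5, 3, 4, 5} px for the detection
rates, and 50-frame sets for the two ablation contrasts. These sizes
match the acquisition protocol the generator emulates (30 frames per
dataset) while keeping the whole suite comfortably reproducible on a
single CPU.

## Known limitations

* The near-horizontal collinearity prior ties the method to roughly
  upright probe orientations; the reference-slope offset relaxes this
  only for known, fixed rotations.
* Layer identity requires the full layer stack in view (see above);
  heavily occluded acquisitions lose whole frames rather than
  contributing partial information.
* With the deliberately narrow rotational protocol, `T_UR`/`T_WP` are
  estimated jointly but are individually sloppy; reconstruction errors
  (the quantity that matters for navigation overlay accuracy) remain
  well-determined, and the reproducibility metric (CRE) quantifies the
  session-to-session dispersion that the sloppiness induces.
* Under gross contamination the expected *absolute* gap between plain
  L-M and RANSAC+L-M shrinks as the underlying noise floor shrinks
  (both errors are means of residual norms, so a bias `b` on top of a
  floor `f` raises the mean by roughly `sqrt(b² + f²) − f`); comparisons
  of the two fits should be read with the floor in mind.
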