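# Methods

## The estimation model

`mrtilt` measures the rigid head pose of a whole-head brain MR volume from
image content alone, in a fixed anatomical frame (X right, Y anterior,
Z superior; positive angles counter-clockwise looking down each axis):

* **Pitch (ω, about X).** On the mid-sagittal slice (sagittal extent
  floor-divided by two), Otsu thresholding yields the head contour and its
  centroid C. A search band is anchored on C — from half-way between the
  contour top and C down to half-way between C and the contour bottom —
  which excludes the philtrum and labial commissure, two anterior points
  that rival the Nasion in centroid distance. Within the band, the Nasion
  is the per-row anterior-most boundary pixel with minimal Euclidean
  distance to C, and the Inion the posterior-most pixel with maximal
  distance. ω is the angle of the Nasion–Inion line with the horizontal,
  computed in millimetres so anisotropic voxels do not bias it. The
  Nasion–Inion line is the classical surrogate for the AC–PC line: parallel
  to the anterior axis in an aligned head, tilted by exactly ω under a
  rotation about X.
* **Yaw (θ, about Z).** Every axial slice is skull-stripped (Otsu →
  3×3 erosion → largest 8-connected component → dilation → flood fill),
  opened morphologically, reduced to a solid brain contour (bounding-box
  frame removal, largest component, flood fill), and gated by three ellipse
  properties: moment-derived semi-axis ratio a/b > 1.2, a ≠ b, and
  |πab − pixel count| ≤ 200 pixel-area units. Accepted slices get a coarse
  angle from the dominant eigenvector of the contour's second central
  moments, then a fine offset from a reflected-image correlation: the
  coarse-corrected intensity slice is rotated by each δ ∈ {−5,…,+5}° in
  half-degree steps, mirrored about its vertical midline, and scored by the
  Pearson correlation over the union of the two foregrounds. θ is the plain
  mean of (coarse + fine) over accepted slices.
* **Roll (φ, about Y).** Each gated slice contributes three 3D points:
  the intersections of its first principal component with the first and
  last non-zero contour rows, and their midpoint. All of them lie on the
  head's mid-sagittal plane, so an orthogonal-regression
  (total-least-squares) plane through the pooled points — scaled to mm —
  recovers that plane. With the unit normal rescaled so its component
  along +X is −1, the Z-coefficient c satisfies φ = arctan c exactly for a
  pure rotation about Y (and arctan(tan φ / cos θ) under combined tilt).
* **Correction.** All three angles are estimated on the *original* volume
  (never sequentially on partially corrected data), composed as
  R = R_Z(θ)·R_Y(φ)·R_X(ω), and removed by resampling with the inverse
  rotation about the grid centre (inverse-mapped trilinear interpolation,
  constant-zero fill). With `reshape` the output grid grows to the rotated
  bounding box so no head voxels are clipped.

### Conventions fixed where the method family leaves them open

* The classical printed form of the yaw-roll-pitch matrix has an
  inconsistent middle element (a duplicated sin θ); the implementation
  uses cos ω cos θ + sin θ sin φ sin ω, the only reading that keeps the
  matrix orthonormal and consistent with its other eight entries.
* Normal scaling in the roll formula: the arctangent needs the normal on a
  definite scale. Rescaling so the X-component is −1 reproduces the
  applied roll exactly on analytic plane fixtures; scaling by the
  Y-component (the rotation axis itself) degenerates for pure roll, where
  the normal has no Y-component at all.
* Otsu ties break toward the smaller threshold; the returned threshold is
  placed midway between the two classes' nearest sample values so that
  `intensity > threshold` reproduces the variance-maximising split exactly.
* Connectivity is 8-neighbour in-plane for components and flood fill.
* The "±200 units" area gate is interpreted as 200 pixel-area units
  (mm² when spacing is known).
* The fine search breaks exact correlation ties toward the offset of
  smallest magnitude. A light 0.7 px Gaussian blur is applied before the
  candidate rotations: without it, candidates near 0° receive less
  interpolation smoothing than distant ones, which measurably biases the
  argmax away from zero by one grid step.
* Slice indices are 0-based everywhere, including CLI output.

## The synthetic head phantom

The generator builds a whole-head volume analytically: the untilted
implicit geometry is evaluated at R^T w for every voxel's world coordinate
w, so the applied tilt is exact up to voxel sampling and shares *no code
path* with the trilinear corrector (no resampling is involved at all; the
tilt matrix itself comes from `scipy.spatial.transform.Rotation`, not from
the package's own composition). Ground-truth landmarks, masks and angles
are recorded per phantom.

Anatomy, with defaults in mm on a 128³ grid at 1 mm spacing:

* an ellipsoidal outer head (semi-axes 40 × 55 × 66) whose in-plane aspect
  blends to circular toward crown and base, wearing a thin bright skin
  shell (outer 4% of the radius) over a dark skull/CSF gap — the bimodal
  background/tissue histogram the Otsu step assumes, and a shell the
  erosion-based skull strip removes cleanly;
* facial anatomy on the mid-sagittal anterior surface: a nasal notch
  (6 mm deep) whose floor is the Nasion, a protruding nose below it, and
  optional philtrum/labial-commissure distractor bumps that the pitch
  search band must exclude; an 8 mm occipital crest (Inion) posteriorly at
  the same height, so the untilted Nasion–Inion line is horizontal;
* an inner **brain column** (cross-section 33.5 × 49) that runs through
  the entire axial extent — the brainstem/neck continuation inferiorly —
  with an interhemispheric-fissure waist that deepens away from the
  mid-band and blunts the section's anterior/posterior tips until the
  moment axis ratio falls below the 1.2 gate;
* zero-mean Gaussian noise with σ = noise_pct/100 × brain intensity (the
  simulated-repository "% noise" convention), clipped at zero as for
  magnitude images, and slab-averaged slice-thickness degradation with a
  floor policy on the slice count.

### Why the brain is a column and not an ellipsoid

The roll estimator reads the lateral drift of axial cut centres. For a
smooth ellipsoid this signal is almost absent: the cut centres of a rolled
ellipsoid drift with slope cs(α−γ)/(αc² + γs²) (α, γ the squared inverse
lateral and vertical semi-axes), which vanishes as the shape approaches
rotational symmetry about Y — a 10° roll of an ellipsoidal brain reads as
~2.5°. The recipe is only consistent when cross-sections are identical and
centred through the gated band, so the cuts of the tilted shape are centred
exactly on the rolled mid-sagittal plane x = z·tan φ. The phantom therefore
uses a prismatic mid-band. Real heads approximate this regime through the
vertical extent of the head-and-neck column; shapes truly symmetric about
the anterior axis are a blind spot of this estimator family, phantom or
patient.

Two further geometric constraints follow from the gate and are built in
deliberately:

* every compartment end inside an acquisition's *oblique reach*
  (gate cut-off + in-plane extent × sin 30°) would be cut into elongated,
  gate-passing "almond" sections with off-plane centres; the column's
  taper (ending at 92 mm by default) therefore sits beyond the reach of
  the default field of view, and sections beyond 76 mm carry deep sulcal
  grooves whose concavity fails the ±200 px² area gate even when a section
  is truncated by an acquisition boundary;
* the waist depth (0.35, σ = 12 mm) is chosen inside the ratio gate's
  *dead zone*: it blunts a 1.46-aspect section below the 1.2 ratio without
  flipping it into lateral elongation, so off-band sections are rejected at
  every size and under any tilt up to the ±30° validity range.

### What the phantom does not emulate

Tissue textures, bias fields, Rician noise statistics, gyral/sulcal
surface detail, and genuinely asymmetric or pathological anatomy. Passing
recovery tests on the phantom therefore demonstrates the pipeline's
correctness under the method's own model assumptions — bilateral symmetry,
elliptical mid-band sections, a visible facial surface — not robustness to
anatomy that violates them. Two consequences are measured and accepted
rather than hidden:

* **Noise robustness is better than on real data.** The phantom's
  background/tissue contrast-to-noise ratio stays far above one even at 9%
  noise, and averaging ~80 gated slices suppresses per-slice jitter, so
  the median yaw error stays in the few-hundredths-of-a-degree range at
  every noise level (noise even *reduces* the deterministic half-degree
  quantisation bias by dithering it). On real anatomy this method family
  is reported to fail beyond 6% noise; that boundary does not reproduce at
  phantom scale.
* **The thick-slice failure mode reproduces only partially.** Rotating a
  slab-averaged (≥ 7 mm) acquisition degrades band-edge slices until the
  gate rejects them, but slabs from the prismatic mid-band blend into
  exact elliptical sections under trilinear resampling and keep passing.
  This is the flip side of the roll requirement above: a mid-band varied
  enough to break 9 mm slabs also breaks the ±30° oblique cuts the roll
  fit depends on. The harness reports the per-thickness accepted-slice
  counts rather than forcing a binary failure.

## Study designs used by the tests and the acceptance script

* Angle sweeps: ±10°, ±20°, ±30° for yaw and roll, ±5°, ±15° for pitch
  (the pitch landmarks are specified for moderate tilts; beyond ~20° the
  search band may clip a landmark), on noiseless 128³ phantoms.
* Idempotence: a (0, 20°, −10°) tilt on a taller acquisition
  (128×128×208) so the tilted head column is never clipped by the field
  of view; `correct_tilt(..., reshape=False)` then re-estimated. Clip
  planes from a too-short acquisition would reappear after correction as
  oblique truncations whose revived sections pollute the plane fit.
* Noise: 0–9% at 30° yaw, ≥ 10 seeds per level, medians reported.
* Thickness: slab-average to 1/3/5/9 mm, then rotate 30° about both Y and
  Z (the acquisition-then-software-rotation order), and count gate-accepted
  slices.
* The harness (`run_sweep`) applies single-axis tilts analytically at
  native thickness and switches to the thick-then-rotate protocol for
  degraded thickness; failures are recorded per-row, never raised.

## Numerical choices

* Trilinear (order-1) interpolation for all volume resampling; bilinear
  for in-plane candidate rotations; constant-zero fill.
* Rotation centre is the geometric grid centre; reshaped extents are the
  ceiling of the rotated bounding box, padded symmetrically.
* Orientation eigen-gap: principal axes are declared undefined when the
  relative eigenvalue gap is below 10⁻³ (a rasterised circle sits well
  below, a 1.05-aspect ellipse well above).
* Orthogonal regression uses the SVD of the centred point cloud; the
  normal is oriented with non-negative Z-component.
* `resample_thickness` accepts only integer multiples of the current
  axial spacing and truncates a trailing remainder of slices.
* Volumes are reoriented to the canonical frame at load time from the
  NIfTI affine; estimators never carry orientation metadata.

## Known limitations

* Pitch is estimated from the single mid-sagittal slice; under large yaw
  or roll that slice is off the anatomical mid-plane and the pitch reading
  degrades without compensation (the result carries a warning only when
  the nasal notch is not salient). Volumes without facial anatomy get a
  warning-tagged pitch and are corrected in yaw/roll only.
* The ±45° angle bound is a hard validity limit; the study designs stay
  within ±30°.
* No translation, shear, or non-rigid component is estimated.
* The fine yaw search saturates at its ±5° window edge when the coarse
  PCA residual exceeds the window; such slices are flagged.
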