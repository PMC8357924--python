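# Methods

## The problem and the approach

Compound joints — the temporomandibular joint (TMJ) is the motivating case —
are hard to segment directly: the socket bone has intricate, poorly
annotatable morphology, and the clinically relevant quantity is not either
bone but the *space between them*. `negvol` therefore segments the joint
space indirectly ("negative volume" extraction):

1. **Preprocess** — min–max intensity normalization of the CT volume.
2. **Localize** — coarse segmentation of the joint region at reduced
   resolution, histogram thresholding by the minimum method, morphological
   cleanup, and extraction of one bounding box per body side.
3. **Segment** — a small volumetric network labels each VOI voxel as
   background, condyle ("ball", MC), or socket bone ("fossa" slab, TB).
4. **Enhance** — a deterministic classical chain (median denoise, intensity
   threshold, morphological closing/opening, per-slice Canny edge detection
   with cross-slice linking, size-limited hole filling, small-component
   removal) re-segments the bone and is fused with the network's socket-bone
   heatmap.
5. **Reconstruct** — slice-stack median smoothing and marching-cubes
   isosurfacing turn both masks into watertight triangle meshes in mm.
6. **Inflate** — the condyle mesh is displaced along its vertex normals in
   small steps under Laplacian regularization until it is everywhere in
   contact with the socket bound; subtracting the original condyle and
   clipping below the equatorial neck plane yields the negative-volume mesh.
7. **Compare** — left and right negative volumes are mirrored into a common
   frame and compared with the Hausdorff distance H_LR and the surface-area
   ratio S_LR = max{S_L,S_R}/min{S_L,S_R}.

## Models and key algorithms

**Architectures.** Three encoder–decoder families are implemented on a
small tape-based numpy autodiff backend (`negvol/_autodiff.py`): a V-Net
(residual blocks, per-level conv counts 1/2/3/3/3, strided down-convolutions,
transposed-convolution upsampling; 5³ kernels by default), a 3D U-Net
(two convolutions per level with channel doubling inside each encoder block,
max pooling; 3³ kernels), and the attention-gated 3D U-Net (additive
attention gates on the skip connections). All three are fully convolutional.
Checkpoints are `.npz` files.

**FLOPs accounting.** `count_flops` walks the same layer layout the builder
instantiates and counts one multiply–accumulate as two FLOPs (the only
convention under which printed GFLOPs figures are comparable), plus bias,
ReLU, residual-add, pooling-comparison, gate and softmax elementwise work
(< 1 % of the total). Published cost estimates for these architectures
usually omit the channel configuration behind them; `search_flops_config`
therefore evaluates the counter over a documented grid of standard variants
(channel width 4–48, depth 3–5, kernel 3/5, decoder up-convolution halving)
and reports the configuration closest to a given printed figure, together
with the counter's own value for it.

**Losses and metrics.** Training minimizes a linear combination of
cross-entropy and soft Dice (smoothing ε = 1e−5; default weights (1, 1) —
the combination is standard but unweighted variants are equivalent up to
scale). Evaluation reports Dice (%), cross-entropy, and the symmetric
Hausdorff distance between mask surfaces in mm (surface voxels = mask minus
its erosion). For hard masks `dice_loss + DICE/100 = 1` by construction.
Cross-validation partitions *patients* (both joints of a head share a
fold), never patches.

**Augmentation.** Random 3D rotation (±15°), left–right flip, gamma
contrast (0.7–1.5), integer translation (±10 voxels), and elastic
deformation (displacements ≤ 4 voxels, Gaussian-smoothed fields), composed
on the fly; geometric transforms are shared between image and mask, and the
mask is resampled nearest-neighbor.

**Minimum-method threshold.** 256-bin histogram, smoothed with a 3-tap
moving average until exactly two local maxima remain; the threshold is the
deepest valley between them, with the *middle* bin of a flat minimum
plateau as tie-break (the natural choice for a threshold; a one-sided
argmin would bias the cut toward one mode). A unimodal histogram falls back
to 0.5 with a warning.

**Voxelization and isosurfacing.** Mesh→mask rasterization is an exact
voxel-center parity test: each z-column counts surface crossings above the
voxel center; odd parity = inside. Edge subdivision (the classical
refinement for rasterizing coarse annotation meshes) is applied first but
leaves the surface, and hence the parity test, unchanged. Small distinct
per-axis epsilon offsets prevent columns from passing exactly through
shared triangle edges. Mask→mesh uses marching cubes on the padded mask;
masks whose voxels touch only across edges/corners yield non-manifold
surfaces and are retried on a lightly Gaussian-smoothed occupancy field
(σ = 0.7 voxel, symmetric, so the surface position is unbiased).

**Inflation.** Per iteration every free vertex moves `step` along its
area-weighted normal and is smoothed toward its neighbor mean with weight
λ (`v ← (1−λ)v + λ·mean(neighbors)`); collision queries interpolate a
signed-distance grid sampled from the bound mesh (positive inside the bone,
grid spacing `max(step, 2·tolerance)` by default). A vertex whose proposed
position reaches within `collision_tolerance` of the bound surface is
bisected back to the tolerance shell and frozen. Defaults: step 0.1 mm,
λ = 0.2, tolerance 0.05 mm, max 500 iterations — chosen so the sphere-in-
shell calibration converges with all vertex radii within step+tolerance of
the shell. λ = 1 is rejected (it collapses each vertex onto its neighbor
mean). Initial penetration deeper than a configurable bound (defaulting to
two SDF voxels, and to one mask voxel in the pipeline) is a geometry error;
shallower contact freezes those vertices where they are — adjacent
predicted masks routinely produce sub-voxel surface crossings that are
contact noise, not overlap. No remeshing is performed during inflation;
the trace (per-iteration enclosed volume and frozen fraction) is exposed
for audit.

**Clipping and boolean subtraction.** Plane clipping cuts triangles
exactly and caps each boundary loop with a centroid fan (exact for the
convex cross-sections cut here); the plane is nudged by ~1e−6 of the mesh
scale when vertices lie exactly on it. Solid subtraction is voxel-based:
both solids are parity-rasterized on a common fine grid (default 1/128 of
the smaller extent, capped at 8M voxels), subtracted, cleaned (opening +
small-component removal), and isosurfaced back. A mesh-engine boolean
would be sharper at corners, but the voxel route is robust for the noisy
marching-cubes meshes the pipeline produces and is accurate to ~1 % on
analytic solids at the default resolution.

**Clip-plane placement.** For a ball-and-socket joint in an axial stack the
natural neck plane is the condyle equator. The pipeline estimates it from
the predicted condyle *mask*: the per-slice area profile of a ball is a
parabola, and its vertex (quadratic fit around the maximum-area slice)
gives a sub-voxel equator height that is robust to the mesh being cut at
the VOI walls; the normal is ±z toward the socket. A mesh-based
least-squares sphere fit (`fit_condyle_sphere`) and a minimal-cross-section
neck estimator (`estimate_neck_clip_plane`) are provided as alternatives,
and the plane is fully overridable in config.

**Fusion rule.** `fused = (classical ∧ dilate(heatmap ≥ τ, r)) ∨
(heatmap ≥ τ_core)` with τ = τ_core = 0.5 and r = 3 voxels by default: the
classical detail is trusted only where the network roughly agrees, and the
network's confident core is always kept. "Fused" admits several readings;
this rule is monotone in τ and bounded between the core and
classical ∪ core, and is config-exposed. Two guards matter for thin
joints: the classical route's closing radius must stay below half the
joint-space width (closing would bridge the gap), and Canny edge voxels are
admitted only at bone-like intensity (≥ 0.9 × threshold) because the
gradient maximum of a thin gap lies mid-gap, in soft tissue. After fusion
the pipeline removes condyle-labeled voxels from the socket mask (a voxel
cannot belong to both bones) and keeps only the condyle's largest connected
component.

**Symmetry metrics.** H_LR is the exact symmetric Hausdorff distance (KD
tree nearest-neighbor queries; identical to the brute-force double loop)
between point clouds sampled from the two negative-volume meshes — mesh
vertices by default, optionally 10⁴ area-uniform surface samples. The ±
spread reported with H_LR is the standard deviation over 20 seeded 50 %
subsamples of both clouds, making the resampling scheme explicit. The right
mesh is first reflected across the mid-sagittal plane (an involution;
faces re-wound to preserve orientation), with optional centroid/principal-
axes refinement. S_LR uses the exact triangle-area sums. The reported
units of H_LR are mm. The asymmetry flag `S_LR > threshold` defaults to
1.15 for clinical-scale data (a screening heuristic, not clinical
guidance); the phantom studies use 1.042 (below).

## The phantom and what it does and does not show

The CT cohorts such pipelines are developed on are private, so every stage
is validated on a synthetic ball-and-socket phantom with closed-form truth:
a condyle ball (radius r, default 6 mm) with a cylindrical neck, a
hemispherical fossa of radius r+g (gap g, default 2 mm — an SJS-scale joint
space) carved into a laterally bounded slab, three intensity plateaus
(bone 1000, soft tissue 300, air 0, arbitrary units) plus additive Gaussian
noise (σ = 30, a high-contrast CT-like SNR). The negative volume of this
geometry is the upper hemispherical shell

    V_neg = (2/3)π[(r+g)³ − r³],   S_neg = 2π(r+g)² + 2πr² + π[(r+g)² − r²],

which pins the clip plane at the equator and makes end-to-end recovery
checkable to a few percent. Heads embed two joints mirrored about the
mid-sagittal grid plane; `asymmetry_factor` scales the right gap, so
symmetric pairs have S_LR = 1 exactly and a gap×1.2 pair has
S_LR ≈ 1.086 in closed form.

Passing on phantoms demonstrates the geometry engine, the learned-
segmentation plumbing, and the metric definitions — not clinical
performance: the phantom has no trabecular texture, no articular disc, no
beam hardening or HU calibration, no head tilt, and plateau contrasts far
cleaner than real bone interfaces.

## Scaled-down study sizes

The learned components are exercised at sizes a single CPU handles in
minutes, chosen once as the package's study conditions:

* phantom heads of 72×36×44 voxels at 0.75 mm (so one 32³ patch — 24 mm —
  contains ball, fossa dome and joint space);
* a toy V-Net (base width 4, depth 2, 3³ kernels, ~43k parameters) for
  segmentation (3 classes) and localization (2 classes, at 36×18×22);
* Adam with learning rate 1e−3 (the localization-stage setting; the tiny
  network and high-contrast phantoms do not need the slower segmentation
  schedule), no weight decay, 30 epochs on the ten-head cohort (60 for the
  three-head test fixture, whose six patches need a longer schedule);
* patient-wise 5-fold cross-validation on ten heads, three of them
  asymmetric (gap factor drawn from [1.2, 1.5]).

Under these conditions held-out condyle Dice is ≈ 97 %, end-to-end
negative volumes land within ~10 % of the closed forms, and the S_LR flag
separates asymmetric from symmetric heads. The phantom flag threshold
1.042 is the geometric mean of the closed-form S_LR of symmetric (1.0) and
gap×1.2 (≈ 1.086) pairs — fixed analytically, not fitted to pipeline
output.

## Numerical choices and degenerate inputs

* Min–max normalization maps constant volumes to zeros; it is idempotent.
* "Bicubic" 3D resizing is implemented per-axial-slice bicubic plus linear
  along z; pure trilinear is the default (isotropy-correct).
* Resampling preserves physical extent (spacing rescaled by the shape
  ratio); targets above 2³⁰ voxels raise a resource error.
* Empty/full masks cannot be isosurfaced; empty point clouds have no
  Hausdorff distance; both-empty masks have undefined evaluation metrics —
  all raise typed errors rather than returning sentinels.
* DICOM series with slice-pitch deviations > 1e−3 mm raise a format error
  naming the offending gap; NIfTI round-trips are bit-identical.
* All randomness (phantom noise, cohort draws, initialization, shuffling,
  subsampling) flows from explicit integer seeds; training and the full
  pipeline are reproducible run-to-run.

## Known limitations

* The voxel-based boolean and SDF collision queries resolve geometry to
  their grid spacing; sub-voxel features of the bound are smoothed over.
* The inflation front can leave slivers where the bound is open laterally
  (real fossae are not closed shells); the clip plane and the frozen
  below-plane band control, but do not eliminate, this.
* Self-intersection of the inflating mesh is not detected; the Laplacian
  term suppresses it in practice for convex-ish fronts.
* The classical enhancement chain is tuned for plateau-contrast phantoms;
  on real CT its thresholds would need recalibration, which is why every
  stage parameter is config-exposed.
* The numpy training backend is single-threaded and float32; it is meant
  for desk-scale studies, not for 686³ clinical volumes.
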