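# Methods

## Problem and overall design

The package classifies Alzheimer's disease (AD) versus cognitively normal
(CN) subjects from paired left/right hippocampus segmentation masks. Its
premise is that convolutional networks encode local visual texture well but
represent global object shape poorly, so a classifier should receive both:

1. **Deep visual features** — a two-stream lightweight 3D dense
   convolutional network (one stream per hippocampus) whose merged global
   average pooling (GAP) output summarizes local appearance;
2. **Global shape features** — the truncated, normalized spectrum of the
   Laplace–Beltrami (LB) operator on each hippocampal surface (the
   Shape-DNA descriptor), an isometry-invariant summary of intrinsic
   geometry.

The two feature families are z-scored, concatenated, and fed to a small
fully connected softmax head ("late fusion"). Three model variants are
always compared under an identical cross-validation protocol: shape-only
head, visual-only CNN, and the fused model.

## Global shape representation

For a function *f* on a closed surface *M*, the LB operator is
Δf = div(grad f). Its eigenvalues 0 = λ₀ < λ₁ ≤ λ₂ ≤ … form the LB
spectrum, which is invariant under isometries (rotations, translations,
reflections, bending without stretching) and determines intrinsic shape up
to well-known isospectral exceptions.

Pipeline per mask:

- **Surface extraction.** Marching cubes at iso-level 0.5 with voxel
  spacing applied, so vertices are in mm. The mask must be a single
  6-connected component with no boundary-touching voxels, which guarantees
  a watertight genus-0 surface. No smoothing is applied by default; the raw
  mesh carries voxelization ridges that inflate surface area by roughly
  10%, and an optional volume-preserving Taubin smoothing
  (`taubin_iterations`) is available when metric fidelity matters. The
  spectral features are intentionally computed on the raw mesh: the
  normalization below absorbs global scale, and the ridge texture is
  identical across classes.
- **FEM discretization.** Linear (P1) elements: the cotangent stiffness
  matrix (off-diagonal −(cot α + cot β)/2 per interior edge, zero row sums)
  and the consistent mass matrix (per triangle of area A: A/6 diagonal,
  A/12 off-diagonal). Lumped (row-sum diagonal) mass is available as a
  speed option but the consistent matrix is the default, matching the
  classical surface-FEM formulation. Degenerate triangles (area ≤ 1e−12)
  are rejected with the face index named.
- **Eigensolve.** The generalized symmetric problem K f = λ M f is solved
  with ARPACK in shift-invert mode around σ = −1e−8, which captures the
  zero mode stably; eigenvalues within 1e−9 of zero are clamped to 0.
- **Normalization.** The zero mode is dropped and the remaining top-k
  eigenvalues are mapped to ln(λₙ/λ₁), n = 1…k, where λ₁ is the first
  *nonzero* eigenvalue (using λ₀ = 0 as the normalizer would divide by
  zero). Since eigenvalues scale as 1/s² under uniform scaling by s, the
  ratio cancels scale exactly and the first feature is identically 0. The
  natural logarithm is used; any other base is a constant rescaling of the
  features. Default truncation is k = 30 per hippocampus, giving a
  60-dimensional per-subject shape vector (left then right).

A deliberate interpretation: the *surface* (2-manifold) spectrum is
computed, not the volumetric Dirichlet spectrum of the solid interior. The
surface formulation is the standard Shape-DNA construction and is what the
FEM matrices above discretize; the solid spectrum is not implemented.

## Deep visual model

Each stream: initial 3×3×3 convolution (8 filters) + batch norm + ReLU,
2× max pool, then two dense blocks of two convolutions each (8 and 16
filters respectively), each block followed by a transition layer, then GAP.
Dense connectivity follows the DenseNet convention: every convolution in a
block receives the concatenation of the block input and all previous
convolution outputs, and the block output concatenates all of them. The
transition layer is a channel-preserving 1×1×1 convolution + batch norm +
ReLU ending in 2× max pooling. The two GAP vectors (56 channels each for
the default configuration) are concatenated into the 112-dimensional deep
feature vector, followed by dropout (0.5) and a fully connected 2-way
softmax. The default model has ~75k parameters.

Training uses SGD with momentum 0.9, initial learning rate 1e−3,
cross-entropy loss, L2 weight decay 0.02 on convolution and dense kernels
(not biases or batch-norm parameters), and dropout 0.5. A stratified 10%
validation split is carved from the training data and the parameters from
the epoch with the lowest validation loss are kept. Epochs (default 60) and
batch size (default 8) are configuration values.

The engine is a compact, explicitly backpropagated NumPy implementation
(channels-last layout; convolution as im2col + GEMM for few input channels
and per-offset slab GEMMs otherwise; the first layer skips its input
gradient). Inference is deterministic; training is reproducible for a fixed
seed on a fixed platform. Binary masks are fed as single-channel volumes in
[0, 1]; the generator's optional smooth-intensity mode exercises the same
path with graded values.

## Fusion

Deep and shape features are concatenated (deep first) and z-scored
per-feature with statistics computed on training rows only, using the
population (divide-by-n) standard deviation with a 1e−8 floor so constant
features map to 0. The head is a fully connected softmax network (default:
one hidden layer of 32 units, dropout 0.5, L2 0.02) trained with the same
optimizer family. With no hidden layers it reduces to multinomial logistic
regression. The feature extractors are frozen during fusion training; the
CNN is not fine-tuned through the fused head.

## Evaluation protocol

Repeated stratified k-fold cross-validation (default k = 5, 10 repeats,
each repeat re-randomized from a derived seed). Per fold: the CNN trains on
the training split with selection on the stratified validation split (10%
of the training portion, never fewer than one subject per class); deep
features are then extracted in inference mode for all subjects; z-score
normalizers and both heads are fit on non-test rows only; all three
variants are scored on the untouched test fold. AD is the positive class.
Reported metrics: accuracy, sensitivity, specificity, and trapezoid-rule
AUC over the full ROC (ties grouped at one threshold), which equals the
pairwise-concordance estimator with ties counted ½. Hard labels use the 0.5
threshold.

## Class separability and embedding

Each class is summarized by its sample mean and (n−1)-denominator
covariance with a 1e−6 ridge (configurable; the desk-scale experiment uses
1e−3 because feature dimension exceeds per-class counts). Indices between
the two Gaussians:

- Bhattacharyya distance B = ⅛ dᵀS⁻¹d + ½ ln(det S / √(det Σ₁ det Σ₂)),
  S = (Σ₁+Σ₂)/2, d = μ₁−μ₂;
- Jeffries–Matusita JM = 2(1 − e^{−B}) ∈ [0, 2];
- symmetric divergence D = ½tr[(Σ₁−Σ₂)(Σ₂⁻¹−Σ₁⁻¹)] + ½tr[(Σ₁⁻¹+Σ₂⁻¹)ddᵀ];
- transformed divergence TD = 2(1 − e^{−D/8}) ∈ [0, 2].

Both raw D and TD are reported and labelled, because the remote-sensing
literature (and tables derived from it) often prints the unbounded raw
divergence under the name "divergence" while the text says "transformed
divergence". Comparisons between feature sets use raw D alongside B and JM.
2-D visualization delegates to UMAP (n_neighbors 15, min_dist 0.1, seeded),
which is orchestration, not a re-implementation.

## Synthetic cohort

Real hippocampus segmentations come from access-controlled clinical data,
so the package ships a generator whose output has the same *structure*:
paired left/right closed binary shapes on a shared voxel grid with an AD/CN
label. Each shape is an ellipsoid (default semi-axes 12×8×6 mm on a 32³
grid at 1 mm) whose boundary radius is modulated by a smooth field of
Gaussian bumps on the sphere of directions, voxelized at voxel centers.
Two independent class signals mirror the biology the method targets:

- **global (atrophy)**: AD semi-axes are multiplied by `atrophy_factor`
  (default 0.85), shrinking volume — visible to the CNN, largely invisible
  to the scale-invariant spectrum;
- **local (surface texture)**: AD shapes carry more surface bumps (default
  12 vs 4, amplitude 0.9 mm, angular width 0.35 rad) — visible to the
  spectrum and, partially, to the CNN.

Per-subject variation: semi-axes jittered by N(0, 0.3 mm) and bump
directions redrawn per side; the right side is an independent draw mirrored
along the first axis, mimicking bilateral anatomy. The generator verifies a
2-voxel margin to every grid face and single 6-connectedness, and the whole
dataset is a pure function of the seed.

What passing tests on this cohort do *not* show: robustness to real
segmentation errors, partial-volume effects, MRI intensity variation,
nonrigid anatomical variability, or class overlap at clinical effect sizes.
The synthetic signals are chosen to make the pipeline's behaviour
interpretable, not to reproduce clinical performance numbers.

## Problem sizes and numerical choices

The bundled end-to-end experiment (`hippofuse.experiments
.run_desk_experiment`, also driven by `scripts/acceptance.py`) uses 100
subjects per class at 32³, 2-fold cross-validation, one repeat, and 20 CNN
epochs — sized so the complete pipeline (generation, 400 eigensolves, CNN
training, three heads, separability analysis) runs on a single CPU in
minutes. The evaluation defaults (5 folds, 10 repeats, 60 epochs) remain
the protocol for full-scale runs.

Other numerical conventions: crop/pad centering sends the extra voxel of an
odd margin to the high-index side; voxel world coordinates are
origin + index × spacing with no affine resampling (axis-aligned input is
assumed); batch norm uses eps 1e−3 and running-stat momentum 0.9; softmax
probabilities are clipped at 1e−12 inside the loss only.

## Known limitations

- No orientation/affine handling in NIfTI I/O beyond spacing and origin.
- The LB features are genus-0-surface descriptors; masks with handles or
  cavities are rejected rather than handled.
- Marching-cubes triangulation is not symmetric under grid reflection, so
  voxel-level mirroring reproduces spectra only to discretization accuracy
  (~1e−2 on normalized features), while mesh-level isometries hold to
  solver precision.
- Training the CNN end-to-end through the fusion head is not implemented;
  extractors are frozen.
- Single-channel binary or [0,1] intensity input only; no multi-modal data.
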