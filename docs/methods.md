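# Methods

`limbseg` implements slice-wise multi-class segmentation of individual
lower-limb muscles from stacked greyscale volumes, together with the
synthetic phantoms, training protocol and per-muscle error metrics needed
to exercise the whole pipeline on a single CPU.

## Problem setting and data model

A subject is a 3D greyscale volume (T1-weighted-like contrast) with a
paired integer label map: 0 is background, 1–37 are individual muscles of
the hip, thigh and calf, with class ids assigned alphabetically by muscle
name. A subset of 23 muscles carries an *analysis-included* flag; the
remaining 14 cannot be delineated manually with acceptable repeatability,
so they participate in training (they keep predicted tissue realistically
distributed) but are excluded from accuracy summaries.

Volumes follow a fixed `(axial, row, column)` axis order with slice 0 the
most proximal (hip) slice and axis 2 the left–right direction. Physical
spacing is carried in mm. Preprocessing reproduces how multi-sequence
limb MRI is prepared for a 2D network:

* **Isotropic resampling** to 1 mm via trilinear interpolation for images
  and nearest-neighbour for label maps (interpolating class ids is
  meaningless). The output grid spans the same physical extent to within
  one voxel; output voxel *i* samples input coordinate `i·t/s`, anchored
  at the first voxel centre with clamped edges.
* **Stacking**: sequences are pasted into the union field of view using
  their mm offsets rounded to voxels, uncovered voxels set to 0. Overlap
  handling is not uniquely determined by the problem; we use a
  deterministic later-in-list-wins rule with sequences ordered proximal to
  distal.
* **Reflection** of left limbs along the column axis so both limbs share
  one anatomical orientation. Per-class voxel counts are invariant under
  reflection.

## The three architectures

All variants share a 2D encoder–decoder trunk operating on one axial
slice at a time:

* four encoder stages of two 3×3 same-padding convolutions (batch norm +
  ReLU) followed by 2×2 stride-2 max pooling, a bottleneck block, then
  four decoder stages, each up-sampling ×2 and concatenating the
  same-size encoder feature map (skip connection) before two further
  convolutions;
* a final 1×1 convolution onto `n_muscle_classes + 1` channels (an
  explicit background channel at index 0 — a label for every pixel
  requires it; it can be disabled for inference-only use);
* per-pixel class probabilities via softmax over channels; predictions
  are the per-pixel arg-max with ties broken toward the lowest class id
  (so an all-uniform map predicts background).

**Attention UNet** inserts a multiplicative gate on every skip
connection: 1×1 projections of the skip and the (already up-sampled)
decoder features are added, passed through ReLU, projected to a single
channel and squashed by a sigmoid into (0,1); the resulting attention map
multiplies the skip features. Because gating happens after up-sampling,
the general formulation's resampling step is the identity here. The
internal projection width is half the skip channels. A `bypass_gates`
switch forces all attention coefficients to 1, which provably reduces the
network to the weight-shared plain UNet (tested).

**SC-UNet** adds a parallel *spatial channel*: the slice's axial position
is encoded as a one-hot vector of 100 nodes, `p = ceil(100·(i+1)/n)` for
slice i of n, clamped to [1, 100] (the percentage description is
off-by-one against 100 input nodes; the ceil-and-clamp mapping resolves
it deterministically, is total and monotone). One bias-free fully
connected layer (100 → 37) followed by a sigmoid produces a gate per
muscle; each muscle channel of the per-pixel probabilities is multiplied
by its gate, background by 1. Gating in probability space (rather than on
logits) makes a zero gate exclude a muscle outright, which is the
mechanism's stated intent; with all gates at 1 the SC-UNet is
output-identical to its UNet branch. The bias-free choice makes the
parameter difference between SC-UNet and UNet exactly 100×37 = 3700 at
every width preset.

### Width presets

`encoder_widths` must double stage to stage. Three presets ship:
`full` = (64, …, 1024), the classic full-size configuration (~34.5M
parameters here); `small` = (16, …, 256) (~2.2M, the regime of a
~1.7M-parameter published implementation of this design); and the default
`tiny` = (8, …, 128) (~0.5M), which one CPU trains in minutes at the
phantom scale. All structural properties tested (shape preservation,
gate semantics, the +3700 spatial-channel delta, attention > plain
parameter ordering) hold at every preset.

### Numerics

The networks are implemented directly on numpy in float32: convolutions
as im2col + GEMM (the input gradient of a same-padding correlation is a
correlation with the flipped, channel-transposed kernel, so forward and
backward share one primitive), batch norm with running statistics for
evaluation, nearest-neighbour up-sampling (a learned 2×2 transposed
convolution is available by flag), He-style seeded initialisation for
convolutions and small uniform for the spatial layer. Every layer passes
a numeric-gradient check; the full network gradient is verified
numerically with batch norm disabled, because the float32 central
difference through batch statistics is ill-conditioned (the analytic BN
backward is verified at the layer level). Inputs whose sides are not
multiples of 16 are zero-padded internally and cropped back.

## Phantoms

The phantom generator emulates the features of stacked limb MRI that this
pipeline is sensitive to: a circular soft-tissue limb cross-section;
per-class elliptical muscle tubes with distinct mean intensities,
smoothly wandering centrelines and radii, and characteristic axial
extents (class 1 most proximal → last class most distal, staggered bands
of 45 % of the axis by default); per-subject shape jitter; additive
Gaussian noise. Intensities live on a [0, 1] scale (background tissue
0.15, muscles evenly spaced in [0.35, 0.9], noise SD 0.03, jitter 0.10)
so no normalisation layer is needed. Default desk-scale geometry is
48×48 in-plane × 96 axial slices at 1 mm. Everything is deterministic
given `(spec.seed, subject_seed)`.

What the phantom deliberately does **not** model: MR physics (bias
fields, partial volume, fat infiltration texture), inter-muscle contrast
ambiguity (phantom classes are separable by intensity plus position,
which real neighbouring muscles are not), or anatomically realistic
shapes. Passing phantom experiments therefore demonstrates that the
pipeline — architectures, gating, optimisation, split hygiene, metrics —
is implemented correctly and can learn position-dependent multi-class
structure; it does not certify accuracy on clinical MRI.

**Augmentation.** Real cohorts are augmented by deformably registering
subject pairs and warping the moving subject's labels along. Here the
registration is replaced by a random smooth displacement field
(Gaussian-smoothed white noise, default smoothness 8 mm, peak amplitude
3 mm) applied identically to image (linear interpolation) and labels
(nearest neighbour), preserving the statistical role — anatomy-like,
label-consistent variation — without a registration toolkit. Fields are
checked for folding via the Jacobian determinant of `id + u`; a
non-positive determinant triggers amplitude damping with a warning. Each
augmented subject records `(fixed_id, moving_id)` provenance. An
11-subject cohort with one copy per ordered pair yields 110 augmented
subjects. Expert anatomical vetting of augmented subjects is replaced by
the automatic fold-rejection check, so no fixed "surviving subject" count
is meaningful here.

## Training protocol

* **Splits are by subject, never by slice** (slice-level splits leak
  anatomy): one test subject, then an 80:20 shuffle of the remaining
  originals (8 train / 2 validation for an 11-subject cohort). Any
  augmented subject whose provenance names the test subject — as fixed
  *or* moving — is excluded outright. Remaining augmented subjects join
  the validation set only when both parents are validation subjects,
  otherwise training (any rule for mixed pairs crosses the partition
  somewhere; sending mixed pairs to training keeps validation clean).
* **Optimisation**: per-pixel multi-class cross entropy (unweighted;
  phantom background dominance is mild by construction), Adam with its
  canonical defaults, mini-batches of 8 slices, slices shuffled per epoch
  under the run seed, batches drawn across subjects.
* **Learning rate**: piecewise constant — 1e-3 for epochs 1–30, 5e-4 for
  31–60, 1e-4 for 61–90; 90 epochs by default.
* For the SC variant the gated probabilities are renormalised per pixel
  before the log-likelihood, keeping the objective a proper cross entropy
  while training signal reaches the spatial layer.
* **Convergence check**: the mean validation loss over the last `window`
  epochs is compared with the mean over the preceding window; relative
  change below `tol` (default 1 %) counts as converged.

## Evaluation

Per muscle, restricted to the schema's included classes (23 for the full
anatomical schema):

* **RVE** = 100·(V_A − V_R)/V_R (%), volumes as voxel count × voxel
  volume; undefined for an empty reference.
* **DSC** = 2|A∩R|/(|A|+|R|); symmetric; undefined when both masks are
  empty.
* **HD**: symmetric Hausdorff distance in mm between surface voxel sets
  (foreground voxels with a six-connected background or out-of-grid
  neighbour), voxel-centre coordinates scaled by spacing, computed with a
  KD-tree and verified exactly against an exhaustive O(n²) oracle on
  random masks. The worded definition of this metric is sometimes
  garbled in the literature; the standard max of the two directed max–min
  distances is implemented.

A muscle the prediction misses entirely is reported with RVE = −100 %,
DSC = 0 and an *undefined* HD (not a large sentinel, which would corrupt
means); undefined HDs are excluded from summaries and counted.

Model comparisons mirror standard practice for non-normal per-muscle
metric distributions: Kolmogorov–Smirnov normality screen per group,
Kruskal–Wallis omnibus rank test across independent groups, Wilcoxon
signed-rank for paired designs (identical paired groups short-circuit to
p = 1), significance at 0.05; groups below n = 3 are refused. The null
rejection rate of the omnibus test is calibration-checked by Monte Carlo
in the test suite.

## Desk-scale experiment sizes

The end-to-end experiments (`limbseg.experiments.run_desk_experiment`,
also behind `scripts/acceptance.py`) use an 11-subject phantom cohort at
48×48×96 voxels with 6 muscle classes, 20 training epochs of the `tiny`
preset, and every second axial slice in the training stream (position
encodings always reference the full slice count, so positions stay
calibrated). These sizes are the package's chosen desk-scale protocol:
they train a variant end to end in ~2–3 minutes of single-threaded CPU
while leaving the learning problem non-trivial (six classes distinguished
jointly by intensity and axial position, held-out subject evaluation).
The augmented variant adds one deformed copy per original (copies
involving the test subject are excluded by the split, exercising the
provenance rule in earnest).

## Known limitations

* Phantom realism, as above; no claim transfers to clinical MRI without
  retraining and re-evaluation on real data.
* The numpy networks are CPU-bound and single-device; the `full` width
  preset is constructed and checked structurally but is not practical to
  train here.
* Only 2D slice-wise segmentation; no 3D convolutional variants.
* The attention gate's exact internal projection widths follow the
  common half-channel convention; published variants differ in detail.
* DICOM ingestion, bias-field correction and intensity normalisation are
  out of scope; volumes are expected as NIfTI with correct spacing.
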