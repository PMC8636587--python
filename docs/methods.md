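# Methods

## Overview

`limbtorsion` measures femoral and tibial torsion from axial MRI of the
lower limbs in two stages that mirror clinical reading: (1) a 3D U-net
assigns every voxel of the hip, knee and ankle stacks to background, femur,
tibia or fibula; (2) deterministic geometry on the label masks identifies
anatomic landmarks, constructs one proximal and one distal reference line
per bone, and reports the projected axial-plane angle between them.  Because
no public dataset of torsional MRI exists, a parametric phantom generator
with analytically known torsion provides training and validation data; it is
first-class, tested code, not a fixture.

## Coordinate conventions

All grids live in one canonical frame: `x` increases from the patient's
right to the left, `y` from anterior to posterior, `z` from superior
(proximal) to inferior (distal).  Voxel centres sit at
`(index + 0.5) * spacing` mm.  NIfTI and DICOM inputs are reoriented into
this frame on ingest.  All reference lines are 2D directions in the axial
plane; torsion angles are reduced to (−90°, 90°] because the lines are
undirected, and clinical torsion magnitudes (tens of degrees) never approach
the wrap boundary.

Sign conventions: femoral torsion is positive for antetorsion (neck axis
anterior of the posterior condylar line); tibial torsion is positive for
external torsion.  For left limbs the x axis is mirrored before the angle is
taken, so both sides report on the same clinical scale.

## Preprocessing

Volumes are resampled to a target spacing (default 0.6 × 0.6 × 6.5 mm, the
median spacing of the axial acquisition this pipeline models) with trilinear
interpolation (nearest-neighbour for label masks), z-scored over the whole
grid (a constant grid maps to zeros rather than erroring, so degenerate
synthetic cases do not abort batch runs), and zero-padded symmetrically so
every axis is a multiple of the network's pooling requirement (default
32 × 32 × 1 in-plane, since the ~29-slice z axis is barely pooled).  An
inverse record maps predictions back to the native grid.

## Segmentation network

A depth-6 encoder–decoder with skip connections; two 3×3×3 convolutions +
instance normalization + ReLU per level; filter counts 16, 32, 64, 128, 256,
512; max-pooling for down-sampling; trilinear upsampling followed by a 1×1×1
convolution (instead of transposed convolutions) on the way up; a final
1×1×1 convolution and per-voxel softmax over the four classes.  Instance
normalization replaces batch statistics because the batch size is one.
The classification bias is prior-initialized (log of a background-dominant
class frequency, 0.94/0.02/0.02/0.02): starting the softmax near realistic
priors gives rare foreground classes — the fibula occupies well under 1% of
a stack — strong loss gradients from the first iteration, instead of first
spending hundreds of iterations suppressing their probability mass on the
background.

The pooling plan is anisotropic and derived from the input shape: in-plane
axes are always pooled (hence the divisibility requirement), while the z
axis is pooled at a level only while its extent is at least `min_z_pool`
(default 8) *and* even.  A 29-slice stack is therefore never pooled in z; a
16-slice training patch is pooled twice.

The loss is the sum of (1 − soft Dice) over the foreground classes present
in the target (ε = 1e-5 in the denominator) plus voxel-averaged categorical
cross-entropy over all four classes.  When the target contains no foreground
the loss reduces exactly to the cross-entropy.  Optimization is Adam at
batch size 1 with initial learning rate 1e-3.  The learning rate is halved —
always by exactly 2, never clamped to a fraction — when the moving average
(window 50) of the training loss has not improved by a relative 1e-3 over
the last 100 iterations, comparing against the lagged average itself (not a
running minimum, which single-sample loss noise at batch size one would
snag); drops are at least 100 iterations apart and the rate never falls
below 1e-6.  Training is bit-reproducible given the seed.

The network, loss, backward passes and optimizer are implemented on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`limbtorsion.autograd`), with convolutions routed through single BLAS GEMMs
via im2col buffers and the Adam update fused with numba.  Every primitive's
analytic gradient is checked against central finite differences in the test
suite; the trilinear-upsampling backward is additionally verified by the
adjoint identity ⟨Ux, y⟩ = ⟨x, Uᵀy⟩.

### Artifact augmentation

Each training iteration corrupts the sample with probability 0.5, drawing
uniformly among four artifact families (all deterministic given their seed):

* **motion** — weighted average of the volume with 2 rigid-transformed
  copies (in-plane rotation ≤ 5°, shifts ≤ 3 mm converted to voxels by the
  actual spacing); the resting position keeps the dominant weight
  (0.55–0.75), modelling mild motion.
* **ghosting** — every 4th k-space plane along one in-plane axis attenuated
  by up to 0.3 (the DC plane is preserved).
* **spiking** — up to 3 conjugate-symmetric k-space spikes at 0.2 of the
  peak k-space magnitude.
* **bias field** — multiplication by `exp(P(x,y,z))`, `P` a random
  polynomial of order 3 with coefficients in ±0.3, normalized to mean 1.

These ranges are package defaults, exposed in configuration; they are
modelling choices, not reported protocol values.

## Landmark geometry

All landmark operations run on the largest 26-connected component of each
bone class (smaller fragments are treated as segmentation noise).

* **Femoral head centre** — the centre of the largest sphere inscribed in
  the proximal femur: argmax of the anisotropic Euclidean distance transform
  of the full femur, restricted to the proximal third of its z-range, then
  refined by hill-climbing on the distance field (this makes an isolated
  sphere resolve to its exact centre even when the restriction clips it).
  Ties break to the most proximal, then most medial voxel.
* **Proximal femoral line (neck axis)** — scanning distally from the head
  centre's slice, the first axial slice whose femur cross-section (the 2D
  component containing the head projection) has an in-plane maximum diameter
  ≥ 1.6 × the head diameter, i.e. the slice showing head, neck and greater
  trochanter together.  The neck axis is the major principal axis of that
  cross-section's second moments, oriented from the lateral end towards the
  head.  A nearly isotropic cross-section (eigenvalue gap < 1e-3 relative)
  falls back to the x axis with a warning; if no slice passes the criterion
  the widest one is used, with a warning.  The 1.6 factor is a calibrated
  package default.
* **Condylar slice** — the axial slice maximizing the spacing-weighted area
  of the convex hull of the bone's cross-section (qhull; degenerate sets
  have area 0).  Areas within 1e-9 relative are ties; ties break distally
  for the femur, proximally for the tibia.
* **Posterior condylar line** — the cross-section is split into medial and
  lateral halves by the vertical line through its centroid; in each half the
  posterior-most voxel row is found and its mean x used as the condylar
  point (sub-voxel in x, exact in y; exact for spherical condyles).  The
  line is oriented medial → lateral.
* **Distal tibial line** — on the most distal slice where tibia and fibula
  both show ≥ 25 mm² of cross-section (a calibrated default), the line
  connecting the two centroids, oriented tibia → fibula.

## Phantom generator

One phantom is a single limb imaged as three stacks (hip, knee, ankle;
default 144 × 144 × 29 voxels at 0.6 × 0.6 × 6.5 mm) with bright bone (1.0)
on dark background (0.0).  Construction guarantees the torsion angles
analytically:

* the femoral neck (head ball r = 14 mm, neck capsule, trochanter ball, all
  centred on one axial line) is rotated anteriorly by the femoral torsion
  relative to the condylar axis;
* femoral and tibial condyles are equal-radius ball pairs, so the line
  through their posterior poles is exactly parallel to the line through
  their centres; a smaller connecting capsule sits strictly anterior so the
  poles remain the posterior extrema;
* the fibula cylinder is placed so the tibio-fibular centroid line realizes
  the tibial torsion against the condylar axis.

Pose parameters rotate the whole limb (`axis_rotation`) or only the ankle
stack (`ankle_rotation`, in the external-positive sense) for invariance
testing; left-sided phantoms are exact grid mirrors of the right-sided
construction.  Optional additive Gaussian noise, one acquisition artifact
per stack, and an epiphyseal-gap intensity drop complete the imaging model.

What the phantoms do *not* emulate: textured bone and soft tissue, partial
volume at 6.5 mm slices beyond binary discretization, anatomical shape
variation (curved shafts, asymmetric condyles), orthopedic hardware, and
inter-stack pose differences of a real patient.  Passing the recovery tests
therefore demonstrates the correctness of the geometry and learning
machinery under the stated imaging model, not clinical performance.

A rule-based reference segmenter (`segment_stack_by_threshold`: in-plane
Gaussian smoothing σ = 0.7 voxels, threshold 0.5, minimum component size,
per-class hole filling, region rules for class identity) lets the geometry
pipeline be validated on corrupted phantoms independently of the network.

## Agreement statistics

Sørensen-Dice per class (two empty masks define Dice 1, logged); Pearson r
with t-transform p-value; the single-score ICC interpreted as the two-way
random-effects absolute-agreement single-rater ICC(2,1) (the consistency
variant ICC(3,1) is available behind a flag), computed via pingouin with its
F-bound 95% CI and cross-checked in the tests against a from-scratch ANOVA
decomposition; mean absolute difference with a t-based 95% CI.  Degenerate
inputs (zero variance) yield NaN plus a flag instead of raising.

## Scaled-down validation sizes

Everything is validated at desk scale on one CPU:

* torsion recovery over the full grid (femoral −20…45°, tibial 0…45°, both
  sides) on native-resolution phantoms, noiseless and with noise SD 0.2 plus
  one random artifact per stack;
* network training on 20 phantoms (60 stacks) of 64 × 64 × 16 voxels at
  1.2 × 1.2 × 6.5 mm, 300 iterations, no augmentation, evaluated by mean
  foreground Dice on 5 held-out phantoms.  The 1.2 mm in-plane spacing keeps
  the thinnest structure (the 9 mm fibula) at ≥ 7 voxels diameter — still
  coarser relative to anatomy than the 0.6 mm acquisition this emulates.
  A known dynamic of the combined loss at these sizes: classes occupying
  few voxels (the fibula) see weak gradients until the background
  probability mass has shrunk, so per-class Dice is not monotone in training
  length; the prior-initialized classification bias (above) largely removes
  this lag.

## Known limitations

* The published algorithm's exact slice-selection rules are not public;
  the 1.6× head-diameter and 25 mm² thresholds are this package's own
  calibrated defaults (exposed in configuration).
* No inter-stack registration: each stack's canonical axes are trusted, as
  in the acquisition protocol this models (patellae anterior).
* One network serves all three regions; per-region networks were not
  explored.
* The CPU autograd engine is single-sample and float32; it is built for
  correctness and desk-scale training, not for GPU-scale throughput.
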