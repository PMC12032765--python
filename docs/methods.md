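# Methods

This note records the models, conventions and design decisions behind
`fusionbench`, in the order a run executes them: phantom simulation,
preprocessing, architecture family, cross-validation, training, and paired
evaluation.

## Phantom model

The generator emulates the *output state* of a registration pipeline for
paired abdominal MR, not the pipeline itself.  Each subject-session is a
3D scene rasterized in the reference modality's frame:

* **Target** — an axis-aligned ellipsoid with in-plane radius drawn from
  `target_radius_range` (default 6–10 voxels) and a z-radius scaled by the
  voxel anisotropy so the organ is roughly isotropic in millimetres.  The
  binary label is this rasterization; it is exact in the reference frame by
  construction.  Diabetic conditions (`t1d`, `mody`) draw radii from the
  lower half of the range, the other conditions from the upper half,
  mirroring the smaller pancreases of diabetic cohorts.
* **Confuser** — a smaller ellipsoid abutting the target along a random
  in-plane direction.  Its intensity equals the target's in the reference
  modality (their shared boundary is invisible there) and contrasts
  strongly in the secondary modality.  This is the complementary-contrast
  premise stated as a validated invariant: the contrast table must give at
  least one non-target structure high contrast against the target in
  exactly one modality (threshold 0.3 on unit-scaled means).
* **Distractor organs** (`organ_count − 1` of them) placed uniformly with
  moderate contrast in both modalities.

Intensities are per-structure Gaussian textures (`mean ± sd` from the
contrast table), softened by an in-plane Gaussian filter (σ = 0.6 voxels)
so boundaries are not razor-sharp, plus global noise (`noise_sd`, default
0.02 on a unit intensity scale).

**Residual misalignment.**  Rather than simulating deformation followed by
registration, one smooth random displacement field is drawn directly — it
*is* what imperfect registration leaves behind.  Independent N(0,1)
control-point vectors (spacing = `deform_smoothness`, default 15 mm) are
upsampled with cubic interpolation and scaled so the maximum displacement
magnitude equals `deform_amplitude` (in mm; components drawn isotropically
in mm so anisotropic voxels do not bias its direction).  The secondary
image is the scene sampled at `x + u(x)` (linear interpolation), and `u` is
stored as ground truth.  `alignment_dice` warps the label by `u` (nearest)
and reports its Dice against the unwarped label; amplitude 0 yields exactly
1.0 because the zero field short-circuits to an identity.  No study
quantifies its own residual misalignment, so the default amplitude (3 mm ≈
2 in-plane voxels) is a free parameter chosen to produce mean alignment
Dice ≈ 0.96 — visible but not catastrophic — and it is the explicitly
varied axis of the monotonicity checks.

**Interleave artifact.**  Two breath holds produce two coherent slice
families: even-index slices of the reference volume are shifted in-plane by
`+interleave_shift/2` mm and odd-index slices by the opposite half (linear
interpolation along the first in-plane axis).  The artifact touches only
the reference modality.

**Cohorts.**  Condition counts follow largest-remainder rounding of the
requested proportions (ties by insertion order); the default proportions
(0.39/0.40/0.13/0.08) reproduce a 63/66/22/12 four-condition cohort at
n = 163.  Sessions per subject are uniform on a configurable range, so
repeat sessions occur.  Volumes are written as NIfTI-1 (`.nii.gz`, RAS
affine encoding the voxel size; labels as uint8), with a CSV manifest.
Per-pair determinism comes from hashing `(seed, subject_id, session_id)`
into a SeedSequence, so a pair's content does not depend on generation
order.

What the phantom does **not** emulate: MR physics (bias fields, coil
profiles, sequence-dependent contrast), realistic multi-organ anatomy,
breathing-correlated deformation structure, or the behaviour of any actual
registration algorithm.  Passing tests therefore demonstrate that the
pipeline detects and quantifies fusion effects when a complementary signal
and controlled misalignment are present — not that any particular fusion
point wins on clinical data.

## Preprocessing

Each volume is prepared independently: values above the nearest-rank
(100 − 0.001)th percentile (1-based ceiling index) are clipped to that
percentile, then the volume is min-max scaled to [0, 1] by its own extrema.
Constant volumes become all zeros with a `degenerate` flag.  Clipping is
one-sided (upper tail only), and normalization is per-volume, never
per-cohort.  For externally supplied data, resampling onto the reference
grid goes through the composed affines (`inv(A_mov) @ A_ref`), linear for
images and nearest for labels, zeros outside the field of view; when both
grids coincide this is an exact identity.  Clipping/normalization is
applied after resampling, so statistics are computed on the grid the
network actually sees.

## Architecture family

All members are built from one block list of length `2·depth`:
`enc_1..enc_{d−1}`, `bottleneck`, `dec_1..dec_{d−1}`, `head`.  A non-head
block is two 3×3 convolutions, each followed by affine instance
normalization and LeakyReLU(0.1); encoder blocks after the first are
preceded by 2× max-pooling, decoder blocks by 2× nearest-neighbour
upsampling plus concatenation of the matching encoder skip; the head is a
1×1 convolution to two class-score channels.  Channel widths double per
level from `base_channels`.  Instance normalization is part of the block
definition for a concrete numerical reason as well as fidelity to standard
basic-UNet blocks: without it, small networks driven by a pure Dice
objective can saturate their softmax early and freeze in an all-background
state.

The family at a given depth: `baseline_ref`, `baseline_sec` (one input
channel each), `input_concat` (two input channels), `block_concat` at each
block, and `logit_average` (two complete single-modality networks, output =
arithmetic mean of their pre-activation class scores — which is why it is
always the largest model of the family).

**Block-level fusion semantics.**  Fusion at block *i* runs two complete
modality streams — each with its own pooling, skips and upsampling —
through blocks 1..i−1 *and through the first convolution of block i*; the
two feature maps are then concatenated and the block's second convolution
(doubled input channels, no extra projection) continues as a single
stream.  Placing the merge after the block's first convolution means even
the earliest block fusion operates on learned features, keeping it
distinct from naive image concatenation; concatenation without projection
keeps capacity symmetric across fusion points.  The head has a single
convolution, so head fusion concatenates the two decoder outputs into a
doubled-width head.  After fusion, decoder blocks take pre-fusion encoder
skips from the reference-modality stream (`skip_policy="ref"`, the
default, since labels live in the reference frame); `"both-concat"`
concatenates both streams' skips instead.

Masks come from channel-wise argmax with background first, so exactly tied
logits give background.  2D models applied to volumes segment each axial
slice independently and restack.

The networks run on a purpose-built numpy reverse-mode autodiff engine
(convolution via shifted-window contractions, max-pool with first-maximum
tie-breaking, nearest upsampling, channel softmax); every operation's
gradient is verified against central finite differences in the test suite.
He-normal initialization, zero biases, unit norm gains, all seeded.

## Cross-validation design

Splits are subject-level and condition-stratified.  Per condition, the
seeded generator shuffles subjects and deals them into k folds whose sizes
differ by at most one; a fold's subjects are its test set, so test sets
partition the cohort.  Within a fold, the non-test subjects split 90/10
into train/validation — 10% computed per condition (round-half-up, minimum
one subject per condition), a choice exposed as `stratify_val` since an
unstratified 90/10 split is equally defensible.  Validation and test keep
exactly one session per subject (seeded choice among that subject's
sessions); training keeps all sessions.  A condition with fewer than k
subjects is rejected by name.  Plans serialize to canonical JSON, so equal
seeds give byte-equal plans.

## Training protocol

Full-scale defaults: 16,000 batches of two volumes, soft-Dice loss, Adam,
one-cycle learning rate with max 1e-3 (linear warm-up over 30% of the
horizon, cosine anneal to max/1e4), validation every 20 batches, early
stopping once `batch − best_batch ≥ 500`, and restoration of the weights
from the validation step with the lowest validation loss (earliest on
ties; "improvement" means strict decrease of the best-so-far mean
validation Dice loss).

The **desk preset** scales this to one CPU: 2D slices sampled from the
volumes (all foreground-bearing slices plus an equal number of background
slices), 600 batches, patience 200, max learning rate 3e-3, and a warm-up
of 10% rather than 30% — with patience 200 inside a 600-batch horizon, a
30% warm-up (180 batches) would let early stopping fire while the learning
rate is still ramping, so nothing is ever learned.  Paper-scale 3D whole-
volume training remains available in configuration but is GPU-sized work.

The training objective is one minus the *mean over both class channels* of
the batch-pooled soft Dice (smoothing ε = 1e-5 in numerator and
denominator).  Including the background channel keeps gradients alive on
foreground-poor batches; a foreground-only objective has a zero-gradient
attractor at the all-background prediction.  The reported/monitored
quantity — `dice_loss` — is the conventional foreground-only soft-Dice
loss.  Non-finite losses abort with a diagnostic rather than silently
continuing.  Checkpoints are `.npz` archives with the configuration
embedded; reloading reproduces validation losses exactly.

## Evaluation and statistics

Per-pair Dice uses the strict binary definition, `2|X∩Y|/(|X|+|Y|)`,
defined as 1.0 when both masks are empty.  Fold test tables are
concatenated (duplicate pair/config rows are an error), then every
configuration is compared with the reference-modality baseline on exactly
matching pairs:

* **Wilcoxon signed-rank**, two-sided, zero differences dropped (classic
  convention; the report flags when more than 10% drop).  For n ≤ 25 the
  null distribution of W⁺ is computed exactly by dynamic programming over
  doubled midranks (valid under ties; the null remains symmetric), and the
  p-value is twice the smaller tail.  Above 25, the normal approximation
  with the standard tie correction (Σ(t³−t)/48) is used, without
  continuity correction.
* **Bonferroni**: corrected p = min(1, m·p) with m = 6 by default (the
  number of key comparisons per family; configurable), stars at corrected
  p < 0.05 / 0.01 / 0.001.
* **Nonparametric Bland-Altman**: bias = median difference; limits of
  agreement = nearest-rank 5th and 95th percentiles of the differences
  (not mean ± 1.96 sd); a warning below 20 pairs, where percentile limits
  are unstable.
* Conventions throughout: nearest-rank (1-based ceiling) percentiles,
  including the reported (25th, 75th) IQR; even-length medians average the
  two central order statistics.

## Problem sizes

Desk-scale experiments use 32×32×8 voxel grids at 1.5×1.5×5 mm, depth-4
2D networks with 8 base channels (~120k–240k parameters), and the desk
protocol above.  The packaged fusion-effect experiment trains the
reference-only, secondary-only and input-concatenation configurations on
24 training / 6 validation subjects and evaluates on 60 held-out pairs;
with a 2-voxel misalignment amplitude this reliably shows a positive
median Dice residual for input concatenation (corrected p well below 0.05)
and a deficit for the secondary-only baseline, the scaled-down analogue of
the clinical finding it emulates.  These sizes are deliberate: the aim is
a trustworthy, fully seeded pipeline whose properties are checkable on one
CPU, not competitive segmentation accuracy.

## Known limitations

* The phantom's simplicity means absolute Dice values are far higher than
  on clinical abdominal MR; only *relative* comparisons between fusion
  points are meaningful.
* 2D slice-wise training ignores through-plane context; the 3D code path
  exists but is untested at clinical scale.
* The one-cycle/early-stopping interaction is resolved for the desk preset
  by the shorter warm-up; other schedule/patience combinations may need
  the same care.
* `block_concat` semantics follow the "fuse after the block's first
  convolution" reading described above; wiring conventions differ between
  published dual-encoder implementations, and results can be sensitive to
  the skip policy after decoder-side fusion.
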