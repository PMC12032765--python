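# fusionbench

**Where should two imperfectly registered imaging modalities be fused inside
a UNet-style segmentation network?**

Abdominal anatomy is deformable and scans of it are acquired across breath
holds, so even state-of-the-art deformable registration leaves paired
modalities (e.g. T2w and T1w MR of the pancreas) *imperfectly* aligned: the
label, drawn in the reference modality's frame, does not quite match the
anatomy in the secondary modality.  Whether — and where — to fuse the
second modality is then a genuine design question: early fusion exposes the
network to the misalignment directly, late fusion wastes the chance to
combine features, and the answer may be model-specific.

`fusionbench` is a reusable pipeline for studying that question.  It
provides:

* **A fusion family** of dual-modality UNet variants, each with exactly one
  fusion point: single-modality baselines, naive image concatenation at the
  input, channel concatenation inside any encoder/bottleneck/decoder/head
  block (dual streams up to the fusion point), and logit averaging of two
  complete networks.  At depth *d* the family has `2 + 1 + 2d + 1` members.
  Networks run on a compact, gradient-checked numpy autodiff engine — no
  GPU or deep-learning framework required.
* **A seeded multimodal phantom generator** that emulates the
  post-registration state of such a study: complementary contrast (a
  structure iso-intense with the target in the reference modality but
  bright in the secondary one), a smooth residual misalignment field of
  controlled amplitude stored as ground truth, a two-breath-hold slice
  interleave artifact, anisotropic voxels, and a four-condition cohort
  (control / type-1-diabetes / autoantibody-positive / MODY) in which
  diabetic conditions have smaller targets.
* **Study plumbing**: intensity preprocessing (top-0.001% clip, per-volume
  min-max normalization), subject-level condition-stratified k-fold
  cross-validation with single-session validation/test sets, a Dice-loss /
  Adam / one-cycle training harness with early stopping and
  best-validation-weight selection.
* **Paired evaluation**: per-pair Dice `2|X∩Y|/(|X|+|Y|)`, Dice residuals
  against the reference-modality baseline, exact paired Wilcoxon
  signed-rank tests (brute-force-verified null enumeration for n ≤ 25),
  Bonferroni correction `p̃ = min(1, m·p)` with `*`/`**`/`***` stars, and
  nonparametric Bland-Altman agreement whose limits are the 5th/95th
  percentiles of the paired differences.

## Worked example

```python
import numpy as np
from fusionbench.phantom import PhantomParams, generate_pair, alignment_dice
from fusionbench.stats import wilcoxon_signed_rank, bonferroni, bland_altman

params = PhantomParams(deform_amplitude=3.0, seed=7)   # 2-voxel residual misalignment
pair = generate_pair(params, "sub001", "ses1", "t1d")
print(f"label voxels: {int(pair.label.sum())}")
print(f"alignment Dice (label vs secondary frame): {alignment_dice(pair):.3f}")

rng = np.random.default_rng(0)
baseline = rng.beta(8, 3, size=60)          # per-pair Dice of the baseline
fusion = np.clip(baseline + rng.normal(0.02, 0.03, size=60), 0, 1)
res = wilcoxon_signed_rank(fusion, baseline)
corrected, stars = bonferroni(res.p, m=6)
ba = bland_altman(fusion, baseline)
print(f"median residual: {np.median(fusion - baseline):+.4f}")
print(f"Wilcoxon p = {res.p:.2e} ({res.method}), Bonferroni x6 -> {corrected:.2e} {stars}")
print(f"Bland-Altman bias {ba.bias:+.4f}, LoA [{ba.loa_low:+.4f}, {ba.loa_high:+.4f}]")
```

prints

```
label voxels: 464
alignment Dice (label vs secondary frame): 0.959
median residual: +0.0123
Wilcoxon p = 1.46e-04 (normal), Bonferroni x6 -> 8.73e-04 ***
Bland-Altman bias +0.0123, LoA [-0.0225, +0.0728]
```

The alignment Dice of 0.959 says the 3 mm residual field displaces the
target's secondary-frame rendition enough to cost ~4% overlap — the
"imperfect registration" the fusion variants have to cope with.  The
synthetic residuals show a fusion configuration that is ~0.012 Dice better
than its baseline on the median pair, significant after correcting for six
comparisons, with small systematic bias and tight agreement limits.

Full experiments run from the command line:

```bash
fpb run --preset smoke --seed 0 --outdir runs/smoke     # minutes, 2 configs
fpb run --preset desk  --seed 0 --outdir runs/desk      # full family, 2D
fpb compare --preset smoke --depths 3,4 --outdir runs/cmp
```

Each run writes the cohort (NIfTI + manifest CSV), the split plan, one
checkpoint and train record per (configuration, fold), the per-pair
evaluation table, the statistical report (CSV + JSON) and a `summary.md`
ranking configurations by median Dice residual.

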