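"""Seeded multimodal phantom cohorts with residual misalignment.

The generator emulates the *post-registration* state of a paired abdominal
MR study: a reference modality (think T2w) in whose frame the target label
is drawn, and a secondary modality (think T1w) with complementary contrast
that remains smoothly misaligned after deformable registration.  Rather
than simulating an acquisition plus a registration algorithm, a single
smooth random displacement field of bounded magnitude is drawn and applied
to the secondary modality — that residual field is exactly what imperfect
registration leaves behind, and it is stored as ground truth.

Complementary contrast is built in through a "confuser" structure that is
iso-intense with the target in the reference modality (so their shared
boundary is invisible there) but strongly contrasted in the secondary
modality.  The reference modality additionally carries a two-breath-hold
interleave artifact: even-index slices are shifted in-plane by half the
interleave offset, odd-index slices by the opposite half.

Cohorts contain four clinical conditions (control, type 1 diabetes,
autoantibody-positive, MODY); the diabetic conditions draw target radii
from the lower part of the radius range, mimicking the smaller pancreases
of diabetic subjects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomParams",
    "ModalityPair",
    "CohortManifest",
    "generate_pair",
    "generate_cohort",
    "simulate_pairs",
    "alignment_dice",
    "largest_remainder",
    "DEFAULT_CONTRAST",
    "CONDITIONS",
]

CONDITIONS = ("control", "t1d", "aab", "mody")
DIABETIC_CONDITIONS = ("t1d", "mody")

# per-structure (mean, sd) intensity for each modality; the confuser is
# iso-intense with the target in the reference modality but bright in the
# secondary one — the complementary-information premise.
DEFAULT_CONTRAST: dict[str, dict[str, tuple[float, float]]] = {
    "background": {"ref": (0.20, 0.02), "sec": (0.20, 0.02)},
    "target":     {"ref": (0.70, 0.03), "sec": (0.35, 0.03)},
    "confuser":   {"ref": (0.70, 0.03), "sec": (0.90, 0.03)},
    "organ":      {"ref": (0.45, 0.03), "sec": (0.60, 0.03)},
}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, contrast and artifact model of one phantom cohort.

    Lengths are millimetres unless stated otherwise; ``target_radius_range``
    is the in-plane radius in voxels.  ``deform_amplitude`` bounds the
    physical magnitude of the residual misalignment field and
    ``deform_smoothness`` is its correlation length (control-point spacing).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 5.0)
    organ_count: int = 2
    target_radius_range: tuple[float, float] = (6.0, 10.0)
    contrast_table: dict = field(default_factory=lambda: {
        k: {m: tuple(v) for m, v in d.items()}
        for k, d in DEFAULT_CONTRAST.items()})
    deform_amplitude: float = 3.0
    deform_smoothness: float = 15.0
    interleave_shift: float = 1.5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        if self.deform_smoothness <= 0:
            raise ValueError("deform_smoothness must be > 0")
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 8")
        if self.organ_count < 1:
            raise ValueError("organ_count must be >= 1")
        lo, hi = self.target_radius_range
        if not (0 < lo <= hi):
            raise ValueError("bad target_radius_range")
        if not self.complementary_structures():
            raise ValueError(
                "contrast_table must give at least one non-target structure "
                "high contrast against the target in exactly one modality")

    def complementary_structures(self, threshold: float = 0.3) -> list[str]:
        """Non-target structures whose contrast against the target exceeds
        ``threshold`` in exactly one of the two modalities."""
        tgt = self.contrast_table["target"]
        out = []
        for name, spec in self.contrast_table.items():
            if name in ("target", "background"):
                continue
            hits = [abs(spec[m][0] - tgt[m][0]) >= threshold
                    for m in ("ref", "sec")]
            if sum(hits) == 1:
                out.append(name)
        return out


@dataclass
class ModalityPair:
    """One subject-session: both modality volumes plus the target label.

    ``truth`` holds the residual displacement field (in voxels, shaped
    ``(3, *grid)``) for synthetic pairs; real data has none.
    """

    subject_id: str
    session_id: str
    condition: str
    image_ref: np.ndarray
    image_sec: np.ndarray
    label: np.ndarray
    truth: Optional[np.ndarray] = None
    degenerate: bool = False

    def validate(self) -> None:
        if not (self.image_ref.shape == self.image_sec.shape
                == self.label.shape):
            raise ValueError("modality volumes and label must share one grid")
        vals = np.unique(self.label)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("label must be strictly binary")
        if not self.degenerate and not self.label.any():
            raise ValueError("label has no foreground and is not flagged "
                             "degenerate")


# ---------------------------------------------------------------------------
# deterministic per-pair RNG


def _pair_rng(seed: int, subject_id: str, session_id: str) -> np.random.Generator:
    h = hashlib.sha256(f"{seed}|{subject_id}|{session_id}".encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed % 2**31,
                                int.from_bytes(h[:4], "big")]))


# ---------------------------------------------------------------------------
# geometry


def _ellipsoid(grid: tuple[int, int, int], center, radii) -> np.ndarray:
    coords = np.indices(grid, dtype=float)
    d = sum(((coords[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d <= 1.0


def _smooth_field(rng, params: PhantomParams) -> np.ndarray:
    """Residual misalignment: low-resolution random vectors upsampled with
    cubic interpolation, scaled so the maximum displacement magnitude equals
    ``deform_amplitude`` (mm).  Returned in voxel units, shape (3, *grid)."""
    grid = params.grid_shape
    if params.deform_amplitude == 0:
        return np.zeros((3,) + grid)
    n_ctrl = tuple(
        max(2, int(np.ceil(g * params.voxel_size[i]
                           / params.deform_smoothness)) + 1)
        for i, g in enumerate(grid))
    # control vectors drawn isotropically in mm so anisotropic voxels do not
    # bias the direction of the simulated misalignment
    ctrl = rng.standard_normal((3,) + n_ctrl)
    d_mm = np.stack([
        ndimage.zoom(ctrl[i], [g / c for g, c in zip(grid, n_ctrl)],
                     order=3, mode="nearest", grid_mode=True)
        for i in range(3)])
    mag = np.sqrt((d_mm ** 2).sum(axis=0))
    peak = mag.max()
    if peak > 0:
        d_mm *= params.deform_amplitude / peak
    return d_mm / np.asarray(params.voxel_size).reshape(3, 1, 1, 1)


def _warp(volume: np.ndarray, field_vox: np.ndarray, order: int) -> np.ndarray:
    """Sample ``volume`` at x + u(x); nearest for masks (order=0)."""
    coords = np.indices(volume.shape, dtype=float) + field_vox
    return ndimage.map_coordinates(volume.astype(float), coords, order=order,
                                   mode="nearest")


def _interleave(volume: np.ndarray, shift_mm: float,
                voxel_size) -> np.ndarray:
    """Two-breath-hold artifact: even slices move by +shift/2 in-plane,
    odd slices by -shift/2 (along the first in-plane axis)."""
    if shift_mm == 0:
        return volume
    dx = 0.5 * shift_mm / voxel_size[0]
    plus = ndimage.shift(volume, (dx, 0, 0), order=1, mode="nearest")
    minus = ndimage.shift(volume, (-dx, 0, 0), order=1, mode="nearest")
    out = volume.copy()
    out[:, :, 0::2] = plus[:, :, 0::2]
    out[:, :, 1::2] = minus[:, :, 1::2]
    return out


def _draw_radius(rng, params: PhantomParams, condition: str) -> float:
    lo, hi = params.target_radius_range
    mid = 0.5 * (lo + hi)
    if condition in DIABETIC_CONDITIONS:
        return float(rng.uniform(lo, mid))
    return float(rng.uniform(mid, hi))


def generate_pair(params: PhantomParams, subject_id: str, session_id: str,
                  condition: str) -> ModalityPair:
    """One deterministic phantom pair (see module docstring for the model).

    Deterministic given ``(params.seed, subject_id, session_id)``; the label
    is the target rasterized in the reference frame and ``truth`` stores the
    residual field that misaligns the secondary modality.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    grid = params.grid_shape
    vx = params.voxel_size
    rng = _pair_rng(params.seed, subject_id, session_id)

    rp = _draw_radius(rng, params, condition)
    rz = max(1.2, rp * vx[0] / vx[2])
    margin = 2.0
    if 2 * (rp + margin) > min(grid[0], grid[1]) or 2 * rz > grid[2]:
        raise ValueError(
            f"target radius {rp:.1f} vox does not fit grid {grid}; "
            "enlarge grid_shape or shrink target_radius_range")
    center = np.array([
        rng.uniform(rp + margin, grid[0] - rp - margin),
        rng.uniform(rp + margin, grid[1] - rp - margin),
        rng.uniform(rz + 0.5, grid[2] - rz - 0.5),
    ])
    jitter = rng.uniform(0.85, 1.15, size=2)
    target = _ellipsoid(grid, center, (rp * jitter[0], rp * jitter[1], rz))

    # confuser abutting the target boundary along a random in-plane direction
    rc = 0.55 * rp
    theta = rng.uniform(0, 2 * np.pi)
    c_center = center + np.array([np.cos(theta), np.sin(theta), 0.0]) \
        * (rp + 0.5 * rc)
    confuser = _ellipsoid(grid, c_center, (rc, rc, max(1.0, 0.8 * rz)))

    organs = []
    for _ in range(params.organ_count - 1):
        ro = rng.uniform(0.4, 0.8) * rp
        o_center = np.array([rng.uniform(2, grid[0] - 2),
                             rng.uniform(2, grid[1] - 2),
                             rng.uniform(1, grid[2] - 1)])
        organs.append(_ellipsoid(grid, o_center, (ro, ro, max(1.0, 0.6 * rz))))

    def render(modality: str) -> np.ndarray:
        table = params.contrast_table
        mean, sd = table["background"][modality]
        img = mean + sd * rng.standard_normal(grid)
        for mask, name in [*((o, "organ") for o in organs),
                           (confuser, "confuser"), (target, "target")]:
            mean, sd = table[name][modality]
            img[mask] = mean + sd * rng.standard_normal(int(mask.sum()))
        # mild in-plane smoothing: soften razor-sharp structure boundaries
        return ndimage.gaussian_filter(img, sigma=(0.6, 0.6, 0.0))

    ref_clean = render("ref")
    sec_clean = render("sec")

    field = _smooth_field(rng, params)
    image_sec = _warp(sec_clean, field, order=1)
    image_ref = _interleave(ref_clean, params.interleave_shift, vx)

    image_ref = image_ref + params.noise_sd * rng.standard_normal(grid)
    image_sec = image_sec + params.noise_sd * rng.standard_normal(grid)

    pair = ModalityPair(
        subject_id=subject_id, session_id=session_id, condition=condition,
        image_ref=image_ref.astype(np.float32),
        image_sec=image_sec.astype(np.float32),
        label=target.astype(np.uint8), truth=field)
    pair.validate()
    return pair


def alignment_dice(pair: ModalityPair) -> float:
    """Dice between the label and the target as it sits in the secondary
    modality's frame (label warped by the residual field, nearest)."""
    from .stats import dice_score

    if pair.truth is None:
        raise ValueError("pair has no ground-truth displacement field")
    warped = _warp(pair.label, pair.truth, order=0) > 0.5
    return dice_score(warped.astype(np.uint8), pair.label)


# ---------------------------------------------------------------------------
# cohorts


def largest_remainder(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer seat allocation by largest remainder; ties broken by the
    insertion order of ``proportions``."""
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total}, not 1")
    keys = list(proportions)
    quotas = {k: n * proportions[k] for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    left = n - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]),
                                        keys.index(k)))
    for k in order[:left]:
        counts[k] += 1
    return counts


@dataclass
class CohortManifest:
    """Table of generated subject-sessions with file locations."""

    frame: pd.DataFrame   # subject_id, session_id, condition, image_ref, image_sec, label

    COLUMNS = ("subject_id", "session_id", "condition",
               "image_ref", "image_sec", "label")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        dup = self.frame.duplicated(["subject_id", "session_id"])
        if dup.any():
            raise ValueError("duplicate (subject_id, session_id) rows")

    @property
    def condition_counts(self) -> dict[str, int]:
        return (self.frame.drop_duplicates("subject_id")
                .groupby("condition", sort=False)["subject_id"]
                .count().to_dict())

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False, columns=list(self.COLUMNS))

    @classmethod
    def read(cls, path) -> "CohortManifest":
        return cls(pd.read_csv(path, dtype=str))

    def load_pair(self, row) -> ModalityPair:
        """Materialize one row's volumes from disk."""
        if isinstance(row, int):
            row = self.frame.iloc[row]
        ref = nib.load(row["image_ref"])
        sec = nib.load(row["image_sec"])
        lab = nib.load(row["label"])
        return ModalityPair(
            subject_id=row["subject_id"], session_id=row["session_id"],
            condition=row["condition"],
            image_ref=np.asarray(ref.dataobj, dtype=np.float32),
            image_sec=np.asarray(sec.dataobj, dtype=np.float32),
            label=np.asarray(lab.dataobj).astype(np.uint8))

    def load_pairs(self, keys: Sequence[tuple[str, str]] | None = None
                   ) -> list[ModalityPair]:
        df = self.frame
        if keys is not None:
            keyset = set(map(tuple, keys))
            df = df[[(s, e) in keyset for s, e in
                     zip(df["subject_id"], df["session_id"])]]
        return [self.load_pair(r) for _, r in df.iterrows()]


def simulate_pairs(params: PhantomParams, n_subjects: int,
                   condition_proportions: dict[str, float],
                   id_prefix: str = "sub") -> list[ModalityPair]:
    """In-memory cohort of one-session subjects (no files written).

    Condition counts follow largest-remainder rounding, as in
    :func:`generate_cohort`; useful when the volumes are consumed
    immediately and disk round-tripping is not under test.
    """
    counts = largest_remainder(n_subjects, condition_proportions)
    pairs = []
    i = 0
    for cond in condition_proportions:
        for _ in range(counts[cond]):
            pairs.append(generate_pair(params, f"{id_prefix}{i:03d}",
                                       "ses1", cond))
            i += 1
    return pairs


def generate_cohort(params: PhantomParams, n_subjects: int,
                    condition_proportions: dict[str, float],
                    sessions_per_subject_range: tuple[int, int],
                    out_dir) -> CohortManifest:
    """Write a full phantom cohort as NIfTI volumes plus a manifest CSV.

    Per-condition subject counts follow ``condition_proportions`` via
    largest-remainder rounding; each subject gets a uniform number of
    sessions in ``sessions_per_subject_range`` (inclusive), so repeat
    sessions occur whenever the range allows them.
    """
    conds = list(condition_proportions)
    if n_subjects < len(conds):
        raise ValueError(
            f"n_subjects={n_subjects} is fewer than the "
            f"{len(conds)} conditions")
    unknown = set(conds) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions {sorted(unknown)}")
    counts = largest_remainder(n_subjects, condition_proportions)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    affine = np.diag(list(params.voxel_size) + [1.0])

    rows = []
    sub_idx = 0
    lo, hi = sessions_per_subject_range
    for cond in conds:
        for _ in range(counts[cond]):
            subject_id = f"sub{sub_idx:03d}"
            sub_idx += 1
            n_ses = int(rng.integers(lo, hi + 1))
            for s in range(1, n_ses + 1):
                session_id = f"ses{s}"
                pair = generate_pair(params, subject_id, session_id, cond)
                paths = {}
                for tag, arr, dtype in [
                        ("ref", pair.image_ref, np.float32),
                        ("sec", pair.image_sec, np.float32),
                        ("label", pair.label, np.uint8)]:
                    p = out_dir / f"{subject_id}_{session_id}_{tag}.nii.gz"
                    nib.save(nib.Nifti1Image(arr.astype(dtype), affine), p)
                    paths[tag] = str(p)
                rows.append(dict(subject_id=subject_id, session_id=session_id,
                                 condition=cond, image_ref=paths["ref"],
                                 image_sec=paths["sec"],
                                 label=paths["label"]))
    manifest = CohortManifest(pd.DataFrame(rows))
    manifest.write(out_dir / "manifest.csv")
    return manifest
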