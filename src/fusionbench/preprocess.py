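"""Intensity preparation and the resampling contract.

Each volume is prepared independently: the top 0.001% of voxel intensities
are clipped to the nearest-rank 99.999th percentile, then the volume is
min-max normalized to [0, 1] using its own minimum and maximum.  Constant
volumes normalize to all zeros and carry a ``degenerate`` flag.

For externally supplied data, :func:`resample_to_reference` moves a volume
onto a reference grid through the two affines (linear for images, nearest
for labels, zeros outside the field of view).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "NormalizedVolume",
    "clip_and_normalize",
    "resample_to_reference",
    "preprocess_pair",
    "CLIP_TOP_FRACTION",
]

CLIP_TOP_FRACTION = 0.001e-2      # top 0.001% of voxel intensities


@dataclass
class NormalizedVolume:
    data: np.ndarray
    clip_threshold_used: float
    degenerate: bool = False


def clip_and_normalize(volume: np.ndarray) -> NormalizedVolume:
    """Upper-tail clip at the nearest-rank (100 - 0.001)th percentile, then
    min-max rescale to [0, 1]."""
    v = np.asarray(volume, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume")
    n = v.size
    q = 100.0 * (1.0 - CLIP_TOP_FRACTION)
    idx = max(1, math.ceil(q / 100.0 * n))          # 1-based nearest rank
    threshold = float(np.partition(v.ravel(), idx - 1)[idx - 1])
    clipped = np.minimum(v, threshold)
    lo = clipped.min()
    hi = clipped.max()
    if hi == lo:
        return NormalizedVolume(np.zeros_like(v), threshold, degenerate=True)
    return NormalizedVolume((clipped - lo) / (hi - lo), threshold)


def resample_to_reference(moving: np.ndarray, moving_affine: np.ndarray,
                          reference_shape, reference_affine: np.ndarray,
                          mode: str = "linear") -> np.ndarray:
    """Resample ``moving`` onto the reference grid.

    The voxel map is ``inv(moving_affine) @ reference_affine``; images use
    linear interpolation, labels nearest; voxels outside the moving field of
    view become 0.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    moving_affine = np.asarray(moving_affine, dtype=float)
    reference_affine = np.asarray(reference_affine, dtype=float)
    for name, aff in (("moving", moving_affine),
                      ("reference", reference_affine)):
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError(f"{name} affine is not invertible")
    vox_map = np.linalg.inv(moving_affine) @ reference_affine
    order = 1 if mode == "linear" else 0
    out = ndimage.affine_transform(
        np.asarray(moving, dtype=float), vox_map[:3, :3], vox_map[:3, 3],
        output_shape=tuple(reference_shape), order=order,
        mode="constant", cval=0.0)
    if mode == "nearest":
        return out.astype(np.asarray(moving).dtype)
    return out


def preprocess_pair(pair):
    """Clip/normalize both modality volumes of a pair (label untouched)."""
    return replace(
        pair,
        image_ref=clip_and_normalize(pair.image_ref).data.astype(np.float32),
        image_sec=clip_and_normalize(pair.image_sec).data.astype(np.float32),
    )
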