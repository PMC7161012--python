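"""Intensity normalization, resampling, and paired augmentation for CT-like volumes.

CT intensities arrive in Hounsfield units (HU); abdominal scans span roughly
-1000 HU (air) to >800 HU (bone, contrast media). Soft-tissue segmentation
only needs a narrow band of that range, so volumes are clipped to a fixed
window and min-max scaled to [0, 1] before any model or CRF sees them. The
clip bounds — not per-volume extrema — define the scaling, which keeps
intensities comparable across cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "DEFAULT_HU_MIN",
    "DEFAULT_HU_MAX",
    "clip_and_normalize",
    "resample_volume",
    "augment_pair",
]

DEFAULT_HU_MIN = -200.0
DEFAULT_HU_MAX = 500.0


@dataclass
class VolumeImage:
    """A 3D scalar image with voxel spacing and optional world origin.

    Parameters
    ----------
    data
        3D array of voxel intensities.
    spacing
        Per-axis voxel size (mm or unit voxels); strictly positive.
    origin
        Optional world-coordinate offset of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def clip_and_normalize(
    volume: VolumeImage,
    hu_min: float = DEFAULT_HU_MIN,
    hu_max: float = DEFAULT_HU_MAX,
) -> VolumeImage:
    """Clip intensities to [hu_min, hu_max] and min-max scale to [0, 1].

    The clip bounds play the role of X_min/X_max in the scaling
    (X - X_min) / (X_max - X_min), so -200 HU maps to 0.0 and 500 HU to 1.0
    under the defaults regardless of the values present in the volume.
    """
    if hu_min >= hu_max:
        raise ValueError(f"hu_min ({hu_min}) must be < hu_max ({hu_max})")
    clipped = np.clip(volume.data.astype(np.float64), hu_min, hu_max)
    scaled = (clipped - hu_min) / (hu_max - hu_min)
    return VolumeImage(scaled, spacing=volume.spacing, origin=volume.origin)


def resample_volume(
    volume: VolumeImage,
    target_shape: tuple[int, int, int],
    is_mask: bool = False,
) -> VolumeImage:
    """Resample to ``target_shape``: trilinear for images, nearest for masks.

    Spacing is rescaled so the physical extent of the volume is preserved.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 2 for t in target_shape):
        raise ValueError(f"target_shape must be 3 dims each >= 2, got {target_shape}")
    src_shape = volume.shape
    if target_shape == src_shape:
        return VolumeImage(volume.data.copy(), spacing=volume.spacing, origin=volume.origin)
    zoom = [t / s for t, s in zip(target_shape, src_shape)]
    order = 0 if is_mask else 1
    out = ndimage.zoom(volume.data.astype(np.float64), zoom, order=order, mode="nearest", grid_mode=True)
    # grid_mode zoom can land one voxel off on some ratios; enforce the contract
    out = out[tuple(slice(0, t) for t in target_shape)]
    if out.shape != target_shape:
        pad = [(0, t - s) for t, s in zip(target_shape, out.shape)]
        out = np.pad(out, pad, mode="edge")
    if is_mask:
        out = (out > 0.5).astype(np.uint8)
    spacing = tuple(sp * s / t for sp, s, t in zip(volume.spacing, src_shape, target_shape))
    return VolumeImage(out, spacing=spacing, origin=volume.origin)


def augment_pair(
    image: VolumeImage,
    mask: np.ndarray,
    seed: int,
    crop_shape: tuple[int, int, int],
    flip_prob: float = 0.5,
) -> tuple[VolumeImage, np.ndarray]:
    """Apply one random crop + random flips, identically to image and mask.

    The crop window is drawn uniformly among windows that retain at least one
    foreground voxel of ``mask`` (when the mask has any foreground); a crop
    with no tumor would make box-supervised training degenerate. Each axis is
    then flipped independently with probability ``flip_prob``. Deterministic
    under ``seed``.
    """
    crop_shape = tuple(int(c) for c in crop_shape)
    shape = image.shape
    if any(c > s for c, s in zip(crop_shape, shape)):
        raise ValueError(f"crop_shape {crop_shape} exceeds image shape {shape}")
    mask = np.asarray(mask)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {shape}")
    rng = np.random.default_rng(seed)

    fg = np.argwhere(mask > 0)
    starts = []
    for ax in range(3):
        lo, hi = 0, shape[ax] - crop_shape[ax]  # inclusive range of valid starts
        if fg.size:
            # window [s, s+c) must intersect [fg_min, fg_max]
            fg_min, fg_max = int(fg[:, ax].min()), int(fg[:, ax].max())
            lo = max(lo, fg_max - crop_shape[ax] + 1)
            hi = min(hi, fg_min)
            if lo > hi:  # tumor wider than the crop: any overlapping start
                lo, hi = max(0, fg_min - crop_shape[ax] + 1), min(shape[ax] - crop_shape[ax], fg_max)
        starts.append(int(rng.integers(lo, hi + 1)))
    window = tuple(slice(s, s + c) for s, c in zip(starts, crop_shape))
    img = image.data[window].copy()
    msk = mask[window].copy()

    flips = rng.random(3) < flip_prob
    axes = tuple(int(ax) for ax in np.nonzero(flips)[0])
    if axes:
        img = np.flip(img, axis=axes).copy()
        msk = np.flip(msk, axis=axes).copy()
    return VolumeImage(img, spacing=image.spacing, origin=image.origin), msk
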