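"""NIfTI read/write helpers (nibabel), preserving voxel spacing."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocessing import VolumeImage

__all__ = ["save_volume", "load_volume", "save_mask", "load_mask"]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(volume: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _affine(volume.spacing))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(np.asarray(img.dataobj, dtype=np.float64), spacing=spacing)


def save_mask(mask: np.ndarray, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(tuple(spacing)))
    nib.save(img, str(path))


def save_mask_int(values: np.ndarray, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Integer-valued volume (e.g. voxel-wise weight map) as NIfTI."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.int16), _affine(tuple(spacing)))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return (np.asarray(img.dataobj) > 0.5).astype(np.uint8)
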