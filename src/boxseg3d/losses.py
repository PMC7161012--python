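"""Cross-entropy training losses: plain, class-weighted, and voxel-wise weighted.

Tumor voxels are vastly outnumbered by background, so the class-weighted
cross-entropy (WCE) down-weights background terms (defaults 1.0 for tumor,
0.2 for background). The voxel-wise weighted cross-entropy (VWCE) further
multiplies each voxel's term by an integer confidence weight v in {1..K+1}
derived from how many of the K group-trained models (plus the pseudo-mask)
voted that voxel foreground; voxels no mask marked foreground are confident
background and get the maximum weight K+1.

All three losses sum the per-voxel, per-class terms of one sample and are
averaged over samples by the caller (training averages per-batch); a
convenience reduction over a leading batch axis is supported here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClassWeights", "ce_loss", "wce_loss", "vwce_loss", "validate_weight_map"]

_LOG_EPS = 1e-8


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights. Defaults follow the tumor/background imbalance."""

    w_tumor: float = 1.0
    w_background: float = 0.2

    def __post_init__(self) -> None:
        if self.w_tumor < 0 or self.w_background < 0:
            raise ValueError("class weights must be >= 0")
        if self.w_tumor == 0 and self.w_background == 0:
            raise ValueError("class weights must not both be 0")


def _check_shapes(pred_probs: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Accept (2, *vol3d) single samples or (M, 2, *vol3d) batches.

    The target's dimensionality decides: 3D arrays are single volumes, 4D
    arrays are batches of volumes.
    """
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    target = np.asarray(target)
    if target.ndim == 3 and pred_probs.shape == (2,) + target.shape:
        return pred_probs[None], target[None], False
    if target.ndim == 4 and pred_probs.shape == (target.shape[0], 2) + target.shape[1:]:
        return pred_probs, target, True
    raise ValueError(
        f"pred_probs shape {pred_probs.shape} incompatible with target shape {target.shape}"
    )


def _onehot(target: np.ndarray) -> np.ndarray:
    t = (np.asarray(target) > 0).astype(np.float64)
    return np.stack([1.0 - t, t], axis=1)  # (M, 2, *vol)


def ce_loss(pred_probs: np.ndarray, target: np.ndarray) -> float:
    """Cross-entropy: -(1/M) sum_m sum_voxels sum_c y_c log p_c."""
    p, t, _ = _check_shapes(pred_probs, target)
    y = _onehot(t)
    logp = np.log(np.clip(p, _LOG_EPS, None))
    return float(-(y * logp).sum() / p.shape[0])


def wce_loss(pred_probs: np.ndarray, target: np.ndarray, cw: ClassWeights = ClassWeights()) -> float:
    """Class-weighted cross-entropy: each class term scaled by w_c."""
    p, t, _ = _check_shapes(pred_probs, target)
    y = _onehot(t)
    logp = np.log(np.clip(p, _LOG_EPS, None))
    w = np.array([cw.w_background, cw.w_tumor]).reshape(1, 2, *([1] * (p.ndim - 2)))
    return float(-(w * y * logp).sum() / p.shape[0])


def validate_weight_map(vmap: np.ndarray, k: int | None = None) -> np.ndarray:
    """Check the {1..K+1} integer range of a voxel-wise weight map."""
    vmap = np.asarray(vmap)
    if not np.issubdtype(vmap.dtype, np.integer):
        if not np.all(vmap == np.round(vmap)):
            raise ValueError("weight map must be integer-valued")
        vmap = vmap.astype(np.int64)
    if vmap.min() < 1:
        raise ValueError(f"weight map contains values < 1 (min {vmap.min()})")
    if k is not None and vmap.max() > k + 1:
        raise ValueError(f"weight map contains values > K+1={k + 1} (max {vmap.max()})")
    return vmap


def vwce_loss(
    pred_probs: np.ndarray,
    target: np.ndarray,
    cw: ClassWeights = ClassWeights(),
    vmap: np.ndarray | None = None,
    k: int | None = None,
) -> float:
    """Voxel-wise weighted cross-entropy: WCE with per-voxel weights v.

    ``vmap`` aligns with ``target`` (single sample or batch); ``k`` enables
    the strict {1..K+1} range check when the group size is known.
    """
    p, t, batched = _check_shapes(pred_probs, target)
    if vmap is None:
        raise ValueError("vwce_loss requires a weight map")
    v = validate_weight_map(vmap, k=k)
    if not batched and v.shape == t.shape[1:]:
        v = v[None]
    if v.shape != t.shape:
        raise ValueError(f"weight map shape {np.asarray(vmap).shape} does not match target")
    y = _onehot(t)
    logp = np.log(np.clip(p, _LOG_EPS, None))
    w = np.array([cw.w_background, cw.w_tumor]).reshape(1, 2, *([1] * (p.ndim - 2)))
    return float(-(v[:, None] * w * y * logp).sum() / p.shape[0])
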