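"""Synthetic CT-like tumor phantoms.

Real contrast-enhanced renal tumors vary widely in size, location, mean
intensity and internal texture, which is exactly what makes box-supervised
segmentation hard. The generator emulates that variability at desk scale: a
tumor built as a union of randomly rotated, overlapping ellipsoid lobes
(shape irregularity), with a drawn mean intensity, a smooth low-frequency
intra-tumor texture field, and additive Gaussian noise, embedded in a darker
homogeneous organ-like background. Intensities are in Hounsfield-like units
so the standard CT clipping window (-200..500 HU) is exercised nontrivially.

Every sample is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocessing import VolumeImage
from . import io as bio

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_dataset"]

# fraction of the smallest lobe radius used to jitter secondary lobe centers;
# keeping it < 0.5 guarantees lobes pairwise overlap, hence a single
# 18-connected foreground component
_LOBE_JITTER_FRAC = 0.4


@dataclass
class PhantomSpec:
    """Parameters of the phantom family (ranges are sampled per phantom)."""

    shape: tuple[int, int, int] = (48, 48, 48)
    background_level: float = 50.0          # HU-like organ background
    tumor_level_range: tuple[float, float] = (150.0, 450.0)  # HU-like mean tumor intensity
    tumor_radius_range: tuple[float, float] = (6.0, 11.0)    # ellipsoid semi-axes, voxels
    texture_amplitude: float = 40.0         # SD of the smooth intra-tumor field, HU-like
    noise_sigma: float = 20.0               # additive Gaussian noise SD, HU-like
    n_lobes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"shape must be 3 dims each >= 8, got {self.shape}")
        for name in ("tumor_level_range", "tumor_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has lower > upper: ({lo}, {hi})")
        if self.tumor_radius_range[0] <= 0:
            raise ValueError("tumor radii must be positive")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if self.noise_sigma < 0 or self.texture_amplitude < 0:
            raise ValueError("noise_sigma and texture_amplitude must be >= 0")
        if self._center_bounds() is None:
            raise ValueError(
                f"tumor with max radius {self.tumor_radius_range[1]} cannot fit "
                f"strictly inside shape {self.shape}"
            )

    def _center_bounds(self) -> list[tuple[float, float]] | None:
        """Per-axis interval of admissible primary-lobe centers, or None."""
        rmin, rmax = self.tumor_radius_range
        pad = rmax + _LOBE_JITTER_FRAC * rmin + 1.0
        bounds = []
        for dim in self.shape:
            lo, hi = pad, dim - 1 - pad
            if lo > hi:
                return None
            bounds.append((lo, hi))
        return bounds


@dataclass
class PhantomSample:
    image: VolumeImage
    gt_mask: np.ndarray          # uint8 {0,1}, same shape as image
    meta: dict = field(default_factory=dict)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix via a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: np.ndarray,
    semi_axes: np.ndarray,
    rotation: np.ndarray,
) -> np.ndarray:
    """Inclusive voxel-center indicator of a rotated ellipsoid."""
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    coords = np.stack([g - c for g, c in zip(grids, center)], axis=-1)  # (x,y,z,3)
    local = coords @ rotation  # rotate into ellipsoid frame
    q = np.sum((local / semi_axes) ** 2, axis=-1)
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Draw one phantom from the spec's distribution, seeded by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    bounds = spec._center_bounds()
    assert bounds is not None  # spec validation guarantees fit

    rmin, rmax = spec.tumor_radius_range
    tumor_level = float(rng.uniform(*spec.tumor_level_range))
    primary = np.array([rng.uniform(lo, hi) for lo, hi in bounds])

    mask = np.zeros(spec.shape, dtype=bool)
    lobes = []
    for _ in range(spec.n_lobes):
        semi = rng.uniform(rmin, rmax, size=3)
        rot = _random_rotation(rng)
        offset = rng.uniform(-_LOBE_JITTER_FRAC * rmin, _LOBE_JITTER_FRAC * rmin, size=3)
        center = primary + offset
        mask |= _ellipsoid_mask(spec.shape, center, semi, rot)
        lobes.append({"center": center.tolist(), "semi_axes": semi.tolist()})

    image = np.full(spec.shape, spec.background_level, dtype=np.float64)
    image[mask] = tumor_level

    # smooth low-frequency texture inside the tumor only
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=3.0)
    tstd = texture.std()
    if tstd > 0:
        texture = texture / tstd * spec.texture_amplitude
    image[mask] += texture[mask]

    image += spec.noise_sigma * rng.standard_normal(spec.shape)

    # union-of-overlapping-lobes construction guarantees this; assert anyway
    n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 2))[1]
    if n_comp != 1:
        raise RuntimeError(f"phantom foreground has {n_comp} 18-connected components")

    meta = {
        "seed": int(spec.seed),
        "tumor_level": tumor_level,
        "background_level": spec.background_level,
        "lobes": lobes,
        "mask_voxels": int(mask.sum()),
    }
    return PhantomSample(
        image=VolumeImage(image),
        gt_mask=mask.astype(np.uint8),
        meta=meta,
    )


def generate_dataset(
    n: int,
    spec: PhantomSpec,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample seeds derived from ``seed``.

    When ``out_dir`` is given, each case is persisted as NIfTI image/mask
    pairs (``case_XXX_image.nii.gz`` / ``case_XXX_mask.nii.gz``) with a JSON
    meta sidecar.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    samples = []
    for i in range(n):
        sub = PhantomSpec(**{**asdict(spec), "seed": int(child_seeds[i])})
        samples.append(generate_phantom(sub))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(samples):
            cid = f"case_{i:03d}"
            bio.save_volume(s.image, out / f"{cid}_image.nii.gz")
            bio.save_mask(s.gt_mask, out / f"{cid}_mask.nii.gz", spacing=s.image.spacing)
            (out / f"{cid}_meta.json").write_text(json.dumps(s.meta, indent=2))
    return samples
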