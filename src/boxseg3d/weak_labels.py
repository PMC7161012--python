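"""Bounding-box weak annotations derived from ground-truth masks.

A 3D axis-aligned bounding box is the cheapest practical annotation a
radiologist can provide for a tumor. Boxes are generated from reference
masks as the tight foreground extent expanded by a margin ``d`` on every
face (d in {0, 5, 10} voxels emulates progressively sloppier annotation),
clipped to the image bounds. Coordinates are 0-based half-open [min, max).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["BoundingBox3D", "box_from_mask", "box_to_mask"]

_CONVENTION = "0-based half-open"


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned box in voxel indices: [min_corner, max_corner) per axis."""

    min_corner: tuple[int, int, int]
    max_corner: tuple[int, int, int]
    margin_d: int = 0

    def __post_init__(self) -> None:
        if len(self.min_corner) != 3 or len(self.max_corner) != 3:
            raise ValueError("corners must be 3D voxel index triples")
        if any(lo >= hi for lo, hi in zip(self.min_corner, self.max_corner)):
            raise ValueError(
                f"min_corner {self.min_corner} must be < max_corner {self.max_corner} componentwise"
            )
        if any(lo < 0 for lo in self.min_corner):
            raise ValueError(f"min_corner {self.min_corner} has negative indices")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.min_corner, self.max_corner))

    @property
    def volume(self) -> int:
        return int(np.prod([hi - lo for lo, hi in zip(self.min_corner, self.max_corner)]))

    def to_json(self, case_id: str = "") -> dict:
        return {
            "case_id": case_id,
            "min_corner": list(self.min_corner),
            "max_corner": list(self.max_corner),
            "margin_d": self.margin_d,
            "convention": _CONVENTION,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BoundingBox3D":
        conv = obj.get("convention", _CONVENTION)
        if conv != _CONVENTION:
            raise ValueError(f"unsupported box convention {conv!r}")
        return cls(
            min_corner=tuple(int(v) for v in obj["min_corner"]),
            max_corner=tuple(int(v) for v in obj["max_corner"]),
            margin_d=int(obj.get("margin_d", 0)),
        )

    def save(self, path: str | Path, case_id: str = "") -> None:
        Path(path).write_text(json.dumps(self.to_json(case_id), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BoundingBox3D":
        return cls.from_json(json.loads(Path(path).read_text()))


def box_from_mask(mask: np.ndarray, margin_d: int = 0) -> BoundingBox3D:
    """Tight foreground extent expanded by ``margin_d`` voxels per face.

    The expanded box is clipped to the image bounds, so large margins near an
    edge saturate at the volume extent. Raises on an empty mask: a box cannot
    be annotated for a tumor that is not there.
    """
    if margin_d < 0:
        raise ValueError(f"margin_d must be >= 0, got {margin_d}")
    mask = np.asarray(mask)
    fg = np.argwhere(mask > 0)
    if fg.size == 0:
        raise ValueError("cannot build a bounding box from an empty mask")
    mins = fg.min(axis=0)
    maxs = fg.max(axis=0) + 1  # half-open
    mins = np.maximum(mins - margin_d, 0)
    maxs = np.minimum(maxs + margin_d, mask.shape)
    return BoundingBox3D(tuple(int(v) for v in mins), tuple(int(v) for v in maxs), margin_d=margin_d)


def box_to_mask(box: BoundingBox3D, shape: tuple[int, int, int]) -> np.ndarray:
    """Binary mask that is 1 exactly inside the half-open box."""
    if any(hi > s for hi, s in zip(box.max_corner, shape)):
        raise ValueError(f"box {box.min_corner}..{box.max_corner} exceeds shape {shape}")
    out = np.zeros(shape, dtype=np.uint8)
    out[box.slices] = 1
    return out
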