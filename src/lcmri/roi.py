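"""ROI placement: the LC search box and the bilateral ventral-pons references.

An :class:`RoiSpec` records where the operator-style regions sit on the common
grid: a rectangular LC search region over the fourth-ventricle floor and two
square reference regions placed symmetrically in the ventral pons, all
propagated across a contiguous axial slice range (mirroring software that
drags a first-slice placement across slices). Sizes are given in millimetres
and converted to voxel counts with round-half-away-from-zero, so an 8.5 mm
square on a 0.5 mm grid is exactly 17x17 voxels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .grid import VolumeGrid

__all__ = ["BoxRoi", "RoiSpec", "mm_to_voxels"]


def mm_to_voxels(extent_mm: float, voxel_mm: float) -> int:
    """Millimetre extent to voxel count, rounding half away from zero."""
    x = extent_mm / voxel_mm
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _axis_slice(center: int, n_vox: int, axis_len: int, name: str) -> slice:
    # centered span; for even counts the extra voxel goes to the low side
    lo = center - n_vox // 2
    hi = lo + n_vox
    if n_vox % 2 == 0:
        lo, hi = center - n_vox // 2, center + n_vox // 2
    if lo < 0 or hi > axis_len:
        raise ValueError(
            f"{name}: span [{lo}, {hi}) exceeds axis of length {axis_len}; "
            "grid too small for the requested ROI size"
        )
    return slice(lo, hi)


@dataclass(frozen=True)
class BoxRoi:
    """A rectangular in-plane region, identical on every slice it spans.

    ``center_xy`` is the 0-based (x, y) voxel index of the box centre;
    ``extent_mm`` the (x, y) side lengths in millimetres.
    """

    center_xy: tuple[int, int]
    extent_mm: tuple[float, float]

    def plane_slices(self, shape: tuple[int, int, int], voxel_size_mm, name: str = "roi"):
        nx = mm_to_voxels(self.extent_mm[0], voxel_size_mm[0])
        ny = mm_to_voxels(self.extent_mm[1], voxel_size_mm[1])
        if nx < 1 or ny < 1:
            raise ValueError(f"{name}: extent {self.extent_mm} mm collapses to zero voxels")
        return (
            _axis_slice(self.center_xy[0], nx, shape[0], f"{name} x"),
            _axis_slice(self.center_xy[1], ny, shape[1], f"{name} y"),
        )


@dataclass(frozen=True)
class RoiSpec:
    """LC search ROI plus bilateral reference ROIs over a slice range.

    ``slice_range`` is an inclusive 0-based (first, last) pair of axial (z)
    indices. The reference squares must be mirror-symmetric about the grid
    midline to within one voxel and disjoint from the LC region on every
    slice; :meth:`validate` enforces both.
    """

    lc_roi: BoxRoi
    ref_left: BoxRoi
    ref_right: BoxRoi
    slice_range: tuple[int, int]

    def z_slice(self) -> slice:
        z0, z1 = self.slice_range
        if z1 < z0:
            raise ValueError(f"slice_range {self.slice_range} is reversed")
        return slice(z0, z1 + 1)

    def _box_mask(self, box: BoxRoi, grid: VolumeGrid, name: str) -> np.ndarray:
        sx, sy = box.plane_slices(grid.shape, grid.voxel_size_mm, name)
        zs = self.z_slice()
        if zs.stop > grid.shape[2]:
            raise ValueError(
                f"slice_range {self.slice_range} exceeds {grid.shape[2]} axial slices"
            )
        mask = np.zeros(grid.shape, dtype=bool)
        mask[sx, sy, zs] = True
        return mask

    def lc_mask(self, grid: VolumeGrid) -> np.ndarray:
        return self._box_mask(self.lc_roi, grid, "lc_roi")

    def ref_mask(self, grid: VolumeGrid, side: str | None = None) -> np.ndarray:
        """Boolean mask of the reference region(s); both sides when side is None."""
        if side == "left":
            return self._box_mask(self.ref_left, grid, "ref_left")
        if side == "right":
            return self._box_mask(self.ref_right, grid, "ref_right")
        if side is None:
            return self.ref_mask(grid, "left") | self.ref_mask(grid, "right")
        raise ValueError(f"side must be 'left', 'right' or None, got {side!r}")

    def validate(self, grid: VolumeGrid) -> None:
        lc = self.lc_mask(grid)
        refs = self.ref_mask(grid)
        if np.any(lc & refs):
            raise ValueError("LC ROI and reference ROIs overlap")
        mid = (grid.shape[0] - 1) / 2.0
        off_l = self.ref_left.center_xy[0] - mid
        off_r = mid - self.ref_right.center_xy[0]
        if abs(off_l - off_r) > 1.0 or self.ref_left.center_xy[1] != self.ref_right.center_xy[1]:
            raise ValueError(
                "reference ROIs are not mirror-symmetric about the midline within one voxel"
            )

    # -- JSON sidecar round-trip ------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(
            lc_roi=BoxRoi(tuple(d["lc_roi"]["center_xy"]), tuple(d["lc_roi"]["extent_mm"])),
            ref_left=BoxRoi(tuple(d["ref_left"]["center_xy"]), tuple(d["ref_left"]["extent_mm"])),
            ref_right=BoxRoi(tuple(d["ref_right"]["center_xy"]), tuple(d["ref_right"]["extent_mm"])),
            slice_range=tuple(d["slice_range"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RoiSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
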