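"""3D scalar volumes on a regular grid, with NIfTI-1 persistence.

The package fixes the axis convention once: array axis 0 is x (increasing
toward the subject's left), axis 1 is y (posterior to anterior), axis 2 is z
(inferior to superior, the axial slice direction). Voxel indices are 0-based.
All scans, templates and masks in a pipeline run live on one common grid; the
carrier below holds the array plus the spacing/origin metadata needed to talk
about millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "require_spacing",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing and origin.

    Parameters
    ----------
    data:
        3D array, axis order (x, y, z).
    voxel_size_mm:
        Spacing per axis in millimetres.
    origin_mm:
        World coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive values, got {self.voxel_size_mm}")
        self.voxel_size_mm = vs
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def same_grid(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new volume carrying ``data`` on this volume's grid."""
        if data.shape != self.shape:
            raise GridMismatchError(
                f"data shape {data.shape} does not match grid {self.shape}"
            )
        return VolumeGrid(data, self.voxel_size_mm, self.origin_mm)


def check_same_grid(volumes: list[VolumeGrid]) -> None:
    """Raise :class:`GridMismatchError` naming the first offending volume."""
    if not volumes:
        raise ValueError("no volumes given")
    ref = volumes[0]
    for i, vol in enumerate(volumes[1:], start=1):
        if not ref.same_grid(vol):
            raise GridMismatchError(
                f"volume {i} (shape {vol.shape}, spacing {vol.voxel_size_mm}) does not "
                f"match volume 0 (shape {ref.shape}, spacing {ref.voxel_size_mm})"
            )


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a volume to a NIfTI-1 file, spacing and origin preserved."""
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float64), grid.affine)
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI-1 file into a :class:`VolumeGrid`.

    Refuses files whose orientation metadata is missing or degenerate rather
    than guessing axes.
    """
    try:
        img = nib.load(str(path))
    except nib.filebasedimages.ImageFileError as exc:
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    aff = img.affine
    if aff is None or not np.all(np.isfinite(aff)) or np.isclose(np.linalg.det(aff[:3, :3]), 0.0):
        raise ValueError(
            f"{path}: orientation metadata missing or degenerate; refusing to guess axes"
        )
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(abs(v)) for v in np.asarray(img.header.get_zooms()[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    return VolumeGrid(data, spacing, origin)  # type: ignore[arg-type]


def require_spacing(grid: VolumeGrid, expected_mm: float, tol: float = 1e-6) -> None:
    """Assert isotropic spacing, e.g. the 0.5 mm template grid contract."""
    if any(abs(v - expected_mm) > tol for v in grid.voxel_size_mm):
        raise GridMismatchError(
            f"expected {expected_mm} mm isotropic spacing, got {grid.voxel_size_mm}"
        )
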