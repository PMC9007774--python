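"""Template-space LC quantification: group template, μ+4σ mask, extraction.

The template-space route averages pre-aligned brainstem volumes into a group
template, thresholds the template at μ_ROI + 4·σ_ROI (mean and population SD
pooled over both ventral-pons reference squares across the slice span) to
obtain the candidate LC voxels, intersects them with an anatomical
plausibility mask, and splits the result by the midline plane into left and
right LC. Per subject, on the template grid:

    LC_CR-TS(side) = [max(LC, side) - max(Ref, side)] / max(Ref, side)

with maxima of the subject's intensities over that side's mask voxels and
reference square, and LC_VOX-TS(side) the number of side-mask voxels whose
subject intensity strictly exceeds the subject's own μ+4σ reference
threshold. The combined value pools maxima (and sums counts) over both
sides. A group probabilistic map — the per-voxel fraction of subjects whose
supra-threshold map covers the voxel — summarizes spatial consistency.

Nonlinear registration, MNI warping and bias-field estimation are upstream
concerns: every input here is assumed to already sit on the common grid (an
external registration tool can be slotted in before this module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VolumeGrid, check_same_grid
from .roi import RoiSpec

__all__ = [
    "RoiStats",
    "LcMask",
    "TsResult",
    "build_template",
    "roi_stats",
    "create_lc_mask",
    "extract_subject",
    "probabilistic_map",
]

SIDES = ("left", "right", "combined")


@dataclass(frozen=True)
class RoiStats:
    """Reference-ROI statistics and the derived threshold μ + 4σ."""

    mu: float
    sigma: float
    multiplier: float = 4.0

    @property
    def threshold(self) -> float:
        return self.mu + self.multiplier * self.sigma


@dataclass
class LcMask:
    """Binary LC labeling of the template grid, split left/right by midline."""

    left: np.ndarray                     # bool arrays on the template grid
    right: np.ndarray
    threshold: float
    per_slice_counts: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.left & self.right).any():
            raise ValueError("left and right mask components overlap")
        if self.per_slice_counts is None:
            zs = np.arange(self.left.shape[2])
            self.per_slice_counts = pd.DataFrame({
                "slice": zs,
                "left": self.left.sum(axis=(0, 1)).astype(int),
                "right": self.right.sum(axis=(0, 1)).astype(int),
            })

    @property
    def mask(self) -> np.ndarray:
        return self.left | self.right

    def side_mask(self, side: str) -> np.ndarray:
        if side == "left":
            return self.left
        if side == "right":
            return self.right
        if side == "combined":
            return self.mask
        raise ValueError(f"unknown side {side!r}")

    def count(self, side: str = "combined") -> int:
        return int(self.side_mask(side).sum())


@dataclass
class TsResult:
    """Template-space biomarkers for one subject, per side and combined."""

    lc_cr: dict                         # side -> float | None
    lc_vox: dict                        # side -> int
    subject_threshold: float
    ref_max: dict = field(default_factory=dict)
    ref_mean: dict = field(default_factory=dict)


def build_template(aligned_volumes: list[VolumeGrid]) -> VolumeGrid:
    """Voxelwise arithmetic mean of pre-aligned volumes (≥2, identical grids)."""
    if len(aligned_volumes) < 2:
        raise ValueError("template construction needs at least 2 aligned volumes")
    check_same_grid(aligned_volumes)
    stack = np.stack([v.data for v in aligned_volumes], axis=0)
    return aligned_volumes[0].like(stack.mean(axis=0))


def roi_stats(template: VolumeGrid, roispec: RoiSpec, multiplier: float = 4.0) -> RoiStats:
    """μ and σ over the pooled voxels of both reference squares.

    σ is the population standard deviation (divisor N), fixed so the
    threshold is exactly reproducible.
    """
    ref = roispec.ref_mask(template)
    vals = template.data[ref]
    if vals.size == 0:
        raise ValueError("reference ROIs select no voxels")
    return RoiStats(mu=float(vals.mean()), sigma=float(vals.std(ddof=0)), multiplier=multiplier)


def _midline_split(mask: np.ndarray, midline_x: float | None) -> tuple[np.ndarray, np.ndarray]:
    nx = mask.shape[0]
    mid = (nx - 1) / 2.0 if midline_x is None else midline_x
    x = np.arange(nx)[:, None, None]
    left = mask & (x > mid)
    right = mask & (x < mid)
    on_plane = mask & (x == mid)
    if on_plane.any():
        warnings.warn("mask voxels on the midline plane assigned to neither side; "
                      "they are dropped from the side split", stacklevel=2)
    return left, right


def create_lc_mask(
    template: VolumeGrid,
    roispec: RoiSpec,
    plausibility: np.ndarray,
    multiplier: float = 4.0,
    midline_x: float | None = None,
) -> LcMask:
    """Threshold the template at μ+4σ, veto implausible voxels, split by side."""
    plausibility = np.asarray(plausibility, dtype=bool)
    if plausibility.shape != template.shape:
        raise ValueError("plausibility mask grid does not match the template")
    stats = roi_stats(template, roispec, multiplier=multiplier)
    raw = (template.data > stats.threshold) & plausibility
    if not raw.any():
        warnings.warn("LC mask is empty: no template voxel exceeds "
                      f"threshold {stats.threshold:.3f}", stacklevel=2)
    left, right = _midline_split(raw, midline_x)
    return LcMask(left=left, right=right, threshold=stats.threshold)


def extract_subject(
    subject_volume: VolumeGrid,
    mask: LcMask,
    roispec: RoiSpec,
    multiplier: float = 4.0,
) -> TsResult:
    """Per-subject LC_CR-TS and LC_VOX-TS, per side and combined."""
    data = subject_volume.data
    subj_stats = roi_stats(subject_volume, roispec, multiplier=multiplier)
    lc_cr: dict = {}
    lc_vox: dict = {}
    ref_max: dict = {}
    ref_mean: dict = {}
    for side in ("left", "right"):
        ref_vals = data[roispec.ref_mask(subject_volume, side)]
        ref_max[side] = float(ref_vals.max())
        ref_mean[side] = float(ref_vals.mean())
        if ref_max[side] <= 0:
            raise ValueError(f"max(Ref, {side}) = {ref_max[side]} is not positive")
        m = mask.side_mask(side)
        if m.any():
            lc_max = float(data[m].max())
            lc_cr[side] = (lc_max - ref_max[side]) / ref_max[side]
            lc_vox[side] = int((data[m] > subj_stats.threshold).sum())
        else:
            lc_cr[side] = None
            lc_vox[side] = 0
    ref_max["combined"] = max(ref_max["left"], ref_max["right"])
    ref_mean["combined"] = float(data[roispec.ref_mask(subject_volume)].mean())
    if mask.mask.any():
        lc_max_all = float(data[mask.mask].max())
        lc_cr["combined"] = (lc_max_all - ref_max["combined"]) / ref_max["combined"]
    else:
        lc_cr["combined"] = None
    lc_vox["combined"] = lc_vox["left"] + lc_vox["right"]
    return TsResult(
        lc_cr=lc_cr,
        lc_vox=lc_vox,
        subject_threshold=subj_stats.threshold,
        ref_max=ref_max,
        ref_mean=ref_mean,
    )


def probabilistic_map(
    subject_binary_maps: list[VolumeGrid],
    min_probability: float = 0.10,
):
    """Voxelwise fraction of subjects positive, with a probability cutoff.

    Returns ``(fraction_volume, thresholded_mask, peaks)`` where the mask
    keeps voxels whose fraction strictly exceeds ``min_probability`` and
    ``peaks`` tabulates, per axial slice and side, the coordinate of the
    voxel with the maximal fraction.
    """
    if not subject_binary_maps:
        raise ValueError("probabilistic map needs at least one subject map")
    check_same_grid(subject_binary_maps)
    stack = np.stack([np.asarray(v.data, dtype=bool) for v in subject_binary_maps], axis=0)
    frac = stack.mean(axis=0)
    grid = subject_binary_maps[0].like(frac)
    thresholded = frac > min_probability
    mid = (frac.shape[0] - 1) / 2.0
    rows = []
    for z in range(frac.shape[2]):
        plane = frac[:, :, z]
        for side, sel in (("left", np.arange(plane.shape[0]) > mid),
                          ("right", np.arange(plane.shape[0]) < mid)):
            sub = plane[sel, :]
            if sub.max() <= 0:
                continue
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            x = int(np.flatnonzero(sel)[i])
            rows.append((z, side, x, int(j), float(sub[i, j])))
    peaks = pd.DataFrame(rows, columns=["slice", "side", "x", "y", "fraction"])
    return grid, thresholded, peaks
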