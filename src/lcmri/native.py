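"""Native-space LC quantification: iterative connected-maximum thresholding.

The semi-automatic native-space protocol places an LC search ROI at the
fourth-ventricle floor and two reference squares in the ventral pons, drags
them across contiguous slices, and then thresholds the search ROI: the
threshold is the lowest intensity within the 10 spatially interconnected
voxels of maximum intensity. Voxels at or above the threshold become LC
candidates; anatomically incongruent candidates are vetoed (here by a
deterministic plausibility mask standing in for the operator) and the
threshold is recomputed over the remaining eligible voxels, until no new
candidate appears. The accepted voxels yield

    LC_CR-NS = LC(intensity) / Ref(intensity)

with LC(intensity) the mean over accepted voxels and Ref(intensity) the mean
over both reference squares, and LC_VOX-NS the accepted voxel count. Both
sides of the LC are quantified together (the search ROI spans the midline).

The k-voxel "spatially interconnected" set is built greedily: seed at the
global maximum, repeatedly absorb the brightest voxel 26-connected (or
6-connected, see ``connectivity``) to the current set; ties break toward the
lowest C-order linear index. Candidate selection is inclusive at the
threshold, which is itself the intensity of a member of that set.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid
from .roi import RoiSpec

__all__ = ["NsResult", "ns_threshold", "ns_select", "ns_parameters", "run_native"]

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass
class NsResult:
    """Native-space outcome for one subject (both LC sides combined)."""

    lc_cr_ns: float | None
    lc_vox_ns: int
    selected_voxels: np.ndarray          # bool mask on the grid
    threshold_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0


def _greedy_connected_set(values: np.ndarray, eligible: np.ndarray, k: int, offsets) -> np.ndarray:
    """Linear indices of the greedy k-voxel connected maximum-intensity set."""
    shape = values.shape
    flat = values.ravel()
    elig = eligible.ravel()
    n_elig = int(elig.sum())
    if n_elig < k:
        raise ValueError(
            f"ROI holds {n_elig} eligible voxels but the threshold needs k={k}"
        )
    # seed: global max among eligible, lowest linear index on ties
    cand = np.flatnonzero(elig)
    seed = cand[np.argmax(flat[cand])]          # argmax returns first (lowest index) tie
    in_set = np.zeros(flat.shape, dtype=bool)
    members = [seed]
    in_set[seed] = True
    heap: list[tuple[float, int]] = []

    def push_neighbors(lin: int) -> None:
        x, y, z = np.unravel_index(lin, shape)
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                nl = int(np.ravel_multi_index((nx, ny, nz), shape))
                if elig[nl] and not in_set[nl]:
                    heapq.heappush(heap, (-float(flat[nl]), nl))

    push_neighbors(seed)
    while len(members) < k:
        if not heap:
            raise ValueError(
                f"eligible region is disconnected: only {len(members)} voxels reachable, "
                f"k={k} required"
            )
        _, lin = heapq.heappop(heap)
        if in_set[lin]:
            continue
        in_set[lin] = True
        members.append(lin)
        push_neighbors(lin)
    return np.asarray(members)


def ns_threshold(
    values: np.ndarray,
    k: int = 10,
    eligible: np.ndarray | None = None,
    connectivity: int = 26,
) -> float:
    """Native-space intensity threshold over an ROI.

    Returns the minimum intensity within the k-voxel spatially connected set
    grown greedily from the global maximum.

    Parameters
    ----------
    values:
        3D intensity array (the ROI, or a full volume with ``eligible``).
    k:
        Size of the connected maximum-intensity set (default 10).
    eligible:
        Optional boolean mask restricting which voxels may enter the set.
    connectivity:
        26 (default) or 6; voxel adjacency used for "spatially interconnected".
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("values must be a 3D array")
    if eligible is None:
        eligible = np.ones(values.shape, dtype=bool)
    offsets = {26: _OFFSETS_26, 6: _OFFSETS_6}.get(connectivity)
    if offsets is None:
        raise ValueError("connectivity must be 6 or 26")
    members = _greedy_connected_set(values, eligible, k, offsets)
    return float(values.ravel()[members].min())


def ns_select(
    volume: VolumeGrid,
    roispec: RoiSpec,
    plausibility: np.ndarray,
    k: int = 10,
    max_iter: int = 50,
    connectivity: int = 26,
) -> NsResult:
    """Iterative threshold-and-veto voxel selection in the LC search ROI.

    Each round computes the connected-maximum threshold over the currently
    eligible ROI voxels, flags voxels at or above it as candidates, vetoes
    candidates outside the plausibility mask (making them permanently
    ineligible), and repeats until a round neither vetoes nor adds anything.
    The returned result carries no contrast ratio yet (see
    :func:`ns_parameters`).
    """
    plausibility = np.asarray(plausibility, dtype=bool)
    if plausibility.shape != volume.shape:
        raise ValueError(
            f"plausibility mask shape {plausibility.shape} != volume {volume.shape}"
        )
    roi = roispec.lc_mask(volume)
    data = volume.data
    eligible = roi.copy()
    accepted = np.zeros(volume.shape, dtype=bool)
    trace: list[float] = []
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        n_elig = int(eligible.sum())
        if n_elig < k:
            # nothing left to threshold; whatever was accepted stands
            converged = True
            break
        thr = ns_threshold(data, k=k, eligible=eligible, connectivity=connectivity)
        trace.append(thr)
        candidates = eligible & (data >= thr)
        vetoed = candidates & ~plausibility
        accepted = candidates & plausibility
        if not vetoed.any():
            # eligibility unchanged: the next round would reproduce this one
            converged = True
            break
        eligible &= ~vetoed
    return NsResult(
        lc_cr_ns=None,
        lc_vox_ns=int(accepted.sum()),
        selected_voxels=accepted,
        threshold_trace=trace,
        converged=converged,
        n_iterations=it,
    )


def ns_parameters(volume: VolumeGrid, selected_voxels: np.ndarray, roispec: RoiSpec) -> NsResult:
    """Compute LC_CR-NS and LC_VOX-NS from an accepted voxel set.

    LC(intensity) is the mean over the selected voxels and Ref(intensity)
    the mean over the union of both reference squares across the slice
    range. An empty selection leaves the contrast ratio missing (None)
    rather than zero.
    """
    selected_voxels = np.asarray(selected_voxels, dtype=bool)
    ref = roispec.ref_mask(volume)
    ref_mean = float(volume.data[ref].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean {ref_mean} is not positive; cannot normalize")
    n = int(selected_voxels.sum())
    lc_cr = float(volume.data[selected_voxels].mean()) / ref_mean if n else None
    return NsResult(lc_cr_ns=lc_cr, lc_vox_ns=n, selected_voxels=selected_voxels)


def run_native(
    volume: VolumeGrid,
    roispec: RoiSpec,
    plausibility: np.ndarray,
    k: int = 10,
    max_iter: int = 50,
    connectivity: int = 26,
) -> NsResult:
    """Full native-space pass: selection followed by parameter extraction."""
    sel = ns_select(volume, roispec, plausibility, k=k, max_iter=max_iter, connectivity=connectivity)
    params = ns_parameters(volume, sel.selected_voxels, roispec)
    params.threshold_trace = sel.threshold_trace
    params.converged = sel.converged
    params.n_iterations = sel.n_iterations
    return params
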