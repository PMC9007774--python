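"""Compatibility metrics between two binary LC masks on a shared grid.

The overlap convention follows the LC-atlas literature rather than the usual
classifier one: with A the study mask and B the reference ("meta") mask,

    sensitivity = |A ∩ B| / |B|
    specificity = |A ∩ B| / |A|
    accuracy    = (sensitivity + specificity) / 2

Warping between grids (e.g. to MNI) is upstream and must use
nearest-neighbor interpolation so the masks stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd

from .grid import VolumeGrid, GridMismatchError

__all__ = ["OverlapReport", "overlap", "mask_summary", "format_percent"]


def format_percent(fraction: float | None, decimals: int = 1) -> str | None:
    """Fraction as a percentage string, round-half-even to ``decimals``."""
    if fraction is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(str(fraction)) * 100).quantize(q, rounding=ROUND_HALF_EVEN)
    return f"{pct}%"


@dataclass(frozen=True)
class OverlapReport:
    """Voxel-sharing summary between study mask A and reference mask B."""

    n_maskA: int
    n_maskB: int
    n_shared: int
    sensitivity: float | None           # shared / |B|; None when B is empty
    specificity: float | None           # shared / |A|; None when A is empty
    accuracy: float | None              # mean of the two, None if either missing

    def as_dict(self) -> dict:
        d = {
            "n_maskA": self.n_maskA,
            "n_maskB": self.n_maskB,
            "n_shared": self.n_shared,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }
        d.update({
            "sensitivity_pct": format_percent(self.sensitivity),
            "specificity_pct": format_percent(self.specificity),
            "accuracy_pct": format_percent(self.accuracy),
        })
        return d


def _as_bool(vol) -> np.ndarray:
    data = vol.data if isinstance(vol, VolumeGrid) else vol
    return np.asarray(data) > 0


def overlap(maskA: VolumeGrid, maskB: VolumeGrid) -> OverlapReport:
    """Overlap metrics between two binary masks on an identical grid.

    An empty mask leaves its ratio (and the accuracy) missing rather than
    forcing a 0/0.
    """
    if isinstance(maskA, VolumeGrid) and isinstance(maskB, VolumeGrid):
        if not maskA.same_grid(maskB):
            raise GridMismatchError(
                f"mask grids differ: {maskA.shape}/{maskA.voxel_size_mm} vs "
                f"{maskB.shape}/{maskB.voxel_size_mm}"
            )
    a = _as_bool(maskA)
    b = _as_bool(maskB)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    n_a = int(a.sum())
    n_b = int(b.sum())
    n_shared = int((a & b).sum())
    sens = n_shared / n_b if n_b else None
    spec = n_shared / n_a if n_a else None
    acc = (sens + spec) / 2 if (sens is not None and spec is not None) else None
    return OverlapReport(n_a, n_b, n_shared, sens, spec, acc)


def mask_summary(mask: VolumeGrid) -> dict:
    """Per-axial-slice voxel counts, total, non-empty slice count and extent.

    The rostro-caudal extent is the span in mm from the first to the last
    non-empty axial slice (inclusive); an empty mask reports zeros.
    """
    m = _as_bool(mask)
    vz = mask.voxel_size_mm[2] if isinstance(mask, VolumeGrid) else 1.0
    counts = m.sum(axis=(0, 1)).astype(int)
    nonempty = np.flatnonzero(counts)
    per_slice = pd.DataFrame({"slice": np.arange(m.shape[2]), "n_voxels": counts})
    return {
        "per_slice": per_slice,
        "total": int(counts.sum()),
        "n_nonempty_slices": int(nonempty.size),
        "extent_mm": float((nonempty[-1] - nonempty[0] + 1) * vz) if nonempty.size else 0.0,
    }
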