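"""Independent reference implementations used only to cross-check the package.

Everything here is written in plain loops/sets against the written
definitions, deliberately sharing no code with ``lcmri``.
"""

from __future__ import annotations

import numpy as np


def greedy_threshold_oracle(values: np.ndarray, k: int = 10, connectivity: int = 26) -> float:
    """Min intensity of the greedy k-voxel connected maximum set.

    Seed at the global maximum (lowest C-order linear index on ties); each
    step scans every voxel adjacent to the current set and absorbs the
    brightest (again lowest linear index on ties).
    """
    values = np.asarray(values, dtype=float)
    shape = values.shape
    if connectivity == 26:
        offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    coords = [tuple(c) for c in np.argwhere(np.ones(shape, dtype=bool))]
    best = max(coords, key=lambda c: (values[c], -int(np.ravel_multi_index(c, shape))))
    chosen = {best}
    while len(chosen) < k:
        frontier = set()
        for (x, y, z) in chosen:
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[i] < shape[i] for i in range(3)) and n not in chosen:
                    frontier.add(n)
        nxt = max(frontier, key=lambda c: (values[c], -int(np.ravel_multi_index(c, shape))))
        chosen.add(nxt)
    return min(values[c] for c in chosen)


def bh_oracle(pvalues) -> np.ndarray:
    """Brute-force Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        value = p[i] * n / (rank_from_top + 1)
        running_min = min(running_min, value)
        adj[i] = min(running_min, 1.0)
    return adj


def overlap_counts_oracle(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(n_a, n_b, n_shared) by explicit voxel-by-voxel counting."""
    n_a = n_b = n_shared = 0
    for av, bv in zip(np.asarray(a).ravel(), np.asarray(b).ravel()):
        av, bv = bool(av), bool(bv)
        n_a += av
        n_b += bv
        n_shared += av and bv
    return n_a, n_b, n_shared


def per_slice_counts_oracle(mask: np.ndarray) -> list[int]:
    """Voxel count per axial (z) slice by explicit iteration."""
    m = np.asarray(mask) > 0
    return [int(sum(bool(m[x, y, z]) for x in range(m.shape[0]) for y in range(m.shape[1])))
            for z in range(m.shape[2])]


def tube_signal_oracle(cfg) -> dict[str, np.ndarray]:
    """Noise-free voxel intensities of each LC tube, rebuilt from geometry.

    Recomputes, by explicit per-voxel distance arithmetic, the intensity a
    noise-free subject should show at every true tube voxel. Returns flat
    intensity arrays per side.
    """
    nx, ny, nz = cfg.grid_shape
    mid = (nx - 1) / 2.0
    off = cfg.lc_lateral_offset_mm / cfg.voxel_size_mm
    centers = {"left": round(mid + off), "right": round(mid - off)}
    r_vox = cfg.lc_radius_mm / cfg.voxel_size_mm
    z0 = (nz - cfg.lc_length_slices) // 2
    b = cfg.background_mean
    out = {}
    for side, xc in centers.items():
        c = cfg.lc_contrast_true[0] if side == "left" else cfg.lc_contrast_true[1]
        vals = []
        for k in range(cfg.lc_length_slices):
            w = cfg.rostrocaudal_profile[k]
            for x in range(nx):
                for y in range(ny):
                    r2 = (x - xc) ** 2 + (y - cfg.lc_center_y) ** 2
                    if r2 <= r_vox ** 2 + 1e-9:
                        if cfg.radial_profile == "tophat":
                            radial = 1.0
                        else:
                            radial = np.exp(-r2 / (2 * (r_vox / 2) ** 2))
                        vals.append(b * (1 + (c - 1) * w * radial))
        out[side] = np.asarray(vals)
    return out
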