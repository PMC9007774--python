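"""Synthetic pre-aligned brainstem cohorts with known LC ground truth.

The generator emulates the post-registration state of an LC-sensitive
brainstem study: every subject's scan already sits on a common 0.5 mm
isotropic grid whose axial extent matches a 12-slice, 2.2 mm acquisition
(53 resampled slices). The scene is a homogeneous ventral-pons background
carrying two bilateral para-midline hyperintense tubes — the locus coeruleus
— that span 17 axial slices with a middle-heavy rostro-caudal profile,
reflecting the denser packing of noradrenergic cells in the middle of the
nucleus. Left/right asymmetry of the true contrast is configurable and
defaults to left > right.

Each tube is a per-slice disc of configurable radius around a fixed
para-midline centerline, with a Gaussian radial taper truncated at the
radius (a top-hat option exists for constructions that need a flat plateau).
Intensities are ``background * (1 + (contrast - 1) * slice_weight * radial)``
so the peak voxel of a noise-free subject is exactly ``contrast *
background_mean``. Subject-level contrast jitter, additive Gaussian noise
and an optional smooth multiplicative bias field complete the model; the
acquisition physics (pulse sequence, coil profile, k-space) and inter-subject
anatomy requiring nonlinear registration are deliberately not simulated.

Ground truth — the exact voxel sets of each tube, the per-subject true
contrasts, and a deterministic anatomical-plausibility mask that stands in
for operator vetoes (it excludes a midline "fourth ventricle" stripe) — is
returned alongside the volumes so every downstream stage can be verified.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grid import VolumeGrid, write_volume
from .roi import BoxRoi, RoiSpec

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_rostrocaudal_profile",
    "generate_cohort",
    "write_fixture",
    "simulate_paired_measurements",
    "simulate_agreement_table",
]


def default_rostrocaudal_profile(n_slices: int) -> np.ndarray:
    """Middle-heavy slice weights in (0, 1] peaking at the interior centre."""
    i = np.arange(n_slices)
    return 0.4 + 0.6 * np.sin(np.pi * (i + 0.5) / n_slices)


@dataclass
class SimulationConfig:
    """Cohort-level parameters of the synthetic brainstem scene.

    Intensities are in arbitrary scanner units; the defaults put the
    background at 100 so percentages read directly (noise_sd=2.0 is 2 % of
    background). ``lc_contrast_true`` is the ratio of the LC peak intensity
    to the background mean, per side.
    """

    n_subjects: int = 30
    grid_shape: tuple[int, int, int] = (64, 64, 53)
    voxel_size_mm: float = 0.5
    background_mean: float = 100.0
    background_sd: float = 0.0          # static anatomical texture, shared across subjects
    lc_contrast_true: tuple[float, float] = (1.30, 1.25)   # (left, right)
    lc_length_slices: int = 17
    lc_radius_mm: float = 0.75
    rostrocaudal_profile: np.ndarray | None = None
    radial_profile: str = "gaussian"    # "gaussian" (truncated at radius) or "tophat"
    subject_jitter_sd: float = 0.05     # per-subject, per-side contrast jitter
    noise_sd: float = 2.0               # additive Gaussian, per voxel
    bias_field_amplitude: float = 0.0   # fractional amplitude of smooth multiplicative field
    seed: int = 0
    # geometry of the scene, in voxels (midline is at (nx-1)/2)
    lc_lateral_offset_mm: float = 3.25  # tube centreline distance from midline
    lc_center_y: int = 40
    ref_center_y: int = 18
    ref_lateral_offset_mm: float = 6.75
    ref_size_mm: float = 8.5

    def __post_init__(self) -> None:
        if self.rostrocaudal_profile is None:
            self.rostrocaudal_profile = default_rostrocaudal_profile(self.lc_length_slices)
        self.rostrocaudal_profile = np.asarray(self.rostrocaudal_profile, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if min(self.lc_contrast_true) <= 1.0:
            raise ValueError("lc_contrast_true must exceed 1 on both sides")
        for name in ("background_sd", "subject_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        w = self.rostrocaudal_profile
        if len(w) != self.lc_length_slices:
            raise ValueError(
                f"rostrocaudal_profile has {len(w)} entries, expected {self.lc_length_slices}"
            )
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("rostrocaudal_profile entries must lie in (0, 1]")
        peak = np.flatnonzero(w == w.max())
        if not np.any((peak > 0) & (peak < len(w) - 1)):
            raise ValueError("rostrocaudal_profile must peak at an interior slice")
        if self.radial_profile not in ("gaussian", "tophat"):
            raise ValueError(f"unknown radial_profile {self.radial_profile!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rostrocaudal_profile"] = list(np.asarray(self.rostrocaudal_profile, dtype=float))
        d["grid_shape"] = list(self.grid_shape)
        d["lc_contrast_true"] = list(self.lc_contrast_true)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("rostrocaudal_profile") is not None:
            d["rostrocaudal_profile"] = np.asarray(d["rostrocaudal_profile"], dtype=float)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "lc_contrast_true" in d:
            d["lc_contrast_true"] = tuple(d["lc_contrast_true"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True LC geometry and contrasts behind a generated cohort."""

    left_mask: np.ndarray               # bool, true LC voxels, left tube
    right_mask: np.ndarray
    plausibility: np.ndarray            # bool, anatomically plausible region
    contrasts: pd.DataFrame             # subject_id, side, true_contrast, true_n_voxels
    signal: dict = field(default_factory=dict)  # noise-free per-voxel signal weight per side

    @property
    def mask(self) -> np.ndarray:
        return self.left_mask | self.right_mask

    def n_voxels(self, side: str) -> int:
        if side == "left":
            return int(self.left_mask.sum())
        if side == "right":
            return int(self.right_mask.sum())
        if side == "combined":
            return int(self.mask.sum())
        raise ValueError(f"unknown side {side!r}")


def _tube_geometry(cfg: SimulationConfig):
    """Tube voxel masks and the per-voxel signal weight w_z * radial per side."""
    nx, ny, nz = cfg.grid_shape
    vox = cfg.voxel_size_mm
    mid = (nx - 1) / 2.0
    off_vox = cfg.lc_lateral_offset_mm / vox
    # snap centrelines onto voxel centres, symmetric about the midline
    xc_left = int(round(mid + off_vox))
    xc_right = int(round(mid - off_vox))
    yc = cfg.lc_center_y
    z0 = (nz - cfg.lc_length_slices) // 2
    z1 = z0 + cfg.lc_length_slices - 1
    if z0 < 0 or z1 >= nz:
        raise ValueError(
            f"grid has {nz} axial slices but the LC tube needs {cfg.lc_length_slices}; "
            "enlarge grid_shape or shorten lc_length_slices"
        )
    r_vox = cfg.lc_radius_mm / vox
    xs = np.arange(nx)[:, None]
    ys = np.arange(ny)[None, :]
    weights = {}
    masks = {}
    for side, xc in (("left", xc_left), ("right", xc_right)):
        r2 = (xs - xc) ** 2 + (ys - yc) ** 2          # in voxels^2, in-plane
        inside = r2 <= r_vox ** 2 + 1e-9
        if not inside.any():
            raise ValueError("lc_radius_mm too small to cover any voxel at this spacing")
        if cfg.radial_profile == "tophat":
            radial = inside.astype(float)
        else:                                          # Gaussian taper, sigma = radius/2
            radial = np.exp(-r2 / (2.0 * (r_vox / 2.0) ** 2)) * inside
        w = np.zeros(cfg.grid_shape, dtype=float)
        m = np.zeros(cfg.grid_shape, dtype=bool)
        for k, z in enumerate(range(z0, z1 + 1)):
            w[:, :, z] = radial * cfg.rostrocaudal_profile[k]
            m[:, :, z] = inside
        weights[side] = w
        masks[side] = m
    if (masks["left"] & masks["right"]).any():
        raise ValueError("LC tubes overlap; increase lc_lateral_offset_mm or shrink radius")
    return masks, weights, (z0, z1), (xc_left, xc_right, yc)


def _plausibility_mask(cfg: SimulationConfig, masks: dict, zspan: tuple[int, int]) -> np.ndarray:
    """Dilated box around both tubes minus a midline 'fourth ventricle' stripe."""
    nx, ny, nz = cfg.grid_shape
    union = masks["left"] | masks["right"]
    xs, ys, zs = np.nonzero(union)
    margin = 3
    plaus = np.zeros(cfg.grid_shape, dtype=bool)
    plaus[
        max(xs.min() - margin, 0): min(xs.max() + margin + 1, nx),
        max(ys.min() - margin, 0): min(ys.max() + margin + 1, ny),
        max(zspan[0] - 1, 0): min(zspan[1] + 2, nz),
    ] = True
    mid = (nx - 1) / 2.0
    stripe_half_mm = 1.0
    half = stripe_half_mm / cfg.voxel_size_mm
    ventricle = np.abs(np.arange(nx) - mid) <= half
    plaus[ventricle, :, :] = False
    if not (union <= plaus).all():
        raise ValueError("ventricle exclusion stripe intersects the true LC tubes")
    return plaus


def _default_roispec(cfg: SimulationConfig, zspan: tuple[int, int]) -> RoiSpec:
    nx = cfg.grid_shape[0]
    mid = (nx - 1) / 2.0
    off = cfg.ref_lateral_offset_mm / cfg.voxel_size_mm
    lc_extent_x = 2 * (cfg.lc_lateral_offset_mm + cfg.lc_radius_mm) + 2.0
    lc_extent_y = 2 * cfg.lc_radius_mm + 2.0
    spec = RoiSpec(
        lc_roi=BoxRoi((int(round(mid)), cfg.lc_center_y), (lc_extent_x, lc_extent_y)),
        ref_left=BoxRoi((int(round(mid + off)), cfg.ref_center_y), (cfg.ref_size_mm, cfg.ref_size_mm)),
        ref_right=BoxRoi((int(round(mid - off)), cfg.ref_center_y), (cfg.ref_size_mm, cfg.ref_size_mm)),
        slice_range=zspan,
    )
    return spec


def _bias_field(cfg: SimulationConfig) -> np.ndarray:
    """Smooth low-order multiplicative field, 1 +- amplitude."""
    if cfg.bias_field_amplitude == 0:
        return np.ones(cfg.grid_shape)
    axes = [np.linspace(-1.0, 1.0, n) for n in cfg.grid_shape]
    ramp = (axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]) / 3.0
    return 1.0 + cfg.bias_field_amplitude * ramp


def generate_cohort(cfg: SimulationConfig):
    """Generate a pre-aligned cohort.

    Returns ``(volumes, truth, roispec)``: one :class:`VolumeGrid` per
    subject on the common grid, the :class:`GroundTruth`, and the
    :class:`RoiSpec` placing the LC search region over the tubes and the
    reference squares in pure-background ventral pons. Deterministic for a
    fixed ``cfg.seed``.
    """
    masks, weights, zspan, _ = _tube_geometry(cfg)
    plaus = _plausibility_mask(cfg, masks, zspan)
    roispec = _default_roispec(cfg, zspan)
    vox3 = (cfg.voxel_size_mm,) * 3
    proto = VolumeGrid(np.zeros(cfg.grid_shape), vox3)
    roispec.validate(proto)
    # reference squares must sit in pure background
    for side in ("left", "right"):
        if (roispec.ref_mask(proto, side) & (masks["left"] | masks["right"])).any():
            raise ValueError("reference ROI intersects the LC tubes; grid too small")
    if not ((masks["left"] | masks["right"]) <= roispec.lc_mask(proto)).all():
        raise ValueError("LC search ROI does not cover the tubes; grid too small")

    rng = np.random.default_rng(cfg.seed)
    texture = (
        rng.normal(0.0, cfg.background_sd, cfg.grid_shape) if cfg.background_sd > 0 else 0.0
    )
    bias = _bias_field(cfg)
    b = cfg.background_mean
    volumes = []
    rows = []
    for s in range(cfg.n_subjects):
        jitter = rng.normal(0.0, cfg.subject_jitter_sd, size=2) if cfg.subject_jitter_sd > 0 else np.zeros(2)
        c = {"left": cfg.lc_contrast_true[0] + jitter[0], "right": cfg.lc_contrast_true[1] + jitter[1]}
        signal = np.full(cfg.grid_shape, b, dtype=float) + texture
        for side in ("left", "right"):
            signal += b * (c[side] - 1.0) * weights[side]
        signal *= bias
        if cfg.noise_sd > 0:
            signal = signal + rng.normal(0.0, cfg.noise_sd, cfg.grid_shape)
        volumes.append(VolumeGrid(signal, vox3))
        sid = f"sub-{s + 1:03d}"
        for side in ("left", "right"):
            rows.append((sid, side, c[side], int(masks[side].sum())))
        rows.append((sid, "combined", max(c.values()), int((masks["left"] | masks["right"]).sum())))
    contrasts = pd.DataFrame(rows, columns=["subject_id", "side", "true_contrast", "true_n_voxels"])
    truth = GroundTruth(masks["left"], masks["right"], plaus, contrasts, signal=weights)
    return volumes, truth, roispec


def write_fixture(volumes, truth: GroundTruth, roispec: RoiSpec, directory, config: SimulationConfig | None = None) -> dict:
    """Write a cohort to disk: NIfTI scans and masks plus CSV/JSON sidecars.

    Returns a manifest dict listing every path written; the manifest itself
    is also stored as ``manifest.json``.
    """
    directory = str(directory)
    try:
        os.makedirs(directory, exist_ok=True)
        probe = os.path.join(directory, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {directory!r} is not writable: {exc}") from exc

    vox3 = volumes[0].voxel_size_mm
    manifest: dict = {"scans": [], "n_subjects": len(volumes)}
    for i, vol in enumerate(volumes):
        path = os.path.join(directory, f"sub-{i + 1:03d}_scan.nii.gz")
        write_volume(vol, path)
        manifest["scans"].append(path)
    for name, arr in (
        ("plausibility_mask", truth.plausibility),
        ("truth_mask_left", truth.left_mask),
        ("truth_mask_right", truth.right_mask),
        ("truth_mask", truth.mask),
    ):
        path = os.path.join(directory, f"{name}.nii.gz")
        write_volume(VolumeGrid(arr.astype(np.uint8), vox3), path)
        manifest[name] = path
    truth_csv = os.path.join(directory, "truth.csv")
    truth.contrasts.to_csv(truth_csv, index=False)
    manifest["truth_csv"] = truth_csv
    roi_json = os.path.join(directory, "roi_spec.json")
    roispec.to_json(roi_json)
    manifest["roi_spec"] = roi_json
    if config is not None:
        cfg_json = os.path.join(directory, "sim_config.json")
        with open(cfg_json, "w") as fh:
            json.dump(config.to_dict(), fh, indent=2)
        manifest["config"] = cfg_json
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# -- measurement-level cohort simulators (for the statistics stage) ---------

def simulate_paired_measurements(
    n_subjects: int = 53,
    gap: float = 0.06,
    noise_sd: float = 0.02,
    between_sd: float = 0.05,
    base_mean: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject left/right biomarker values with an injected side gap.

    ``left = base + gap + e``, ``right = base + e'`` with shared between-
    subject variation ``base ~ N(base_mean, between_sd)`` and independent
    measurement noise per side. With ``gap = 0`` this is the symmetric null.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(base_mean, between_sd, n_subjects)
    left = base + gap + rng.normal(0.0, noise_sd, n_subjects)
    right = base + rng.normal(0.0, noise_sd, n_subjects)
    return pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)],
        "left": left,
        "right": right,
    })


def simulate_agreement_table(
    n_subjects: int = 53,
    noise_frac: float = 0.5,
    between_sd: float = 0.05,
    asymmetry: float = 0.04,
    seed: int = 0,
) -> pd.DataFrame:
    """Wide cohort table with NS and TS columns sharing a common ground truth.

    Each subject carries one true contrast excess; the native-space and
    template-space measurements observe it through independent noise whose SD
    is ``noise_frac`` times the between-subject spread. Voxel counts follow
    the same construction on a count scale. The result matches the schema
    consumed by :func:`lcmri.agreement.agreement_pipeline`.
    """
    rng = np.random.default_rng(seed)
    t_comb = rng.normal(0.30, between_sd, n_subjects)
    t = {"left": t_comb + asymmetry / 2.0, "right": t_comb - asymmetry / 2.0, "combined": t_comb}
    v_comb = rng.normal(230.0, 25.0, n_subjects)
    v = {"left": v_comb / 2 + 10, "right": v_comb / 2 - 10, "combined": v_comb}
    sd_cr = noise_frac * between_sd
    sd_vox = noise_frac * 25.0
    table = pd.DataFrame({"subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)]})
    table["lc_cr_ns"] = t_comb + rng.normal(0, sd_cr, n_subjects)
    table["lc_vox_ns"] = v_comb + rng.normal(0, sd_vox, n_subjects)
    for side in ("combined", "left", "right"):
        table[f"lc_cr_ts_{side}"] = t[side] + rng.normal(0, sd_cr, n_subjects)
        table[f"lc_vox_ts_{side}"] = v[side] + rng.normal(0, sd_vox, n_subjects)
    table["ref_left"] = rng.normal(100.0, 1.0, n_subjects)
    table["ref_right"] = rng.normal(100.0, 1.0, n_subjects)
    return table
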