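import numpy as np
import pytest

from lcmri import (
    VolumeGrid,
    BoxRoi,
    RoiSpec,
    SimulationConfig,
    generate_cohort,
    build_template,
    roi_stats,
    create_lc_mask,
    extract_subject,
    probabilistic_map,
    GridMismatchError,
)


def _vol(data, vox=0.5):
    return VolumeGrid(np.asarray(data, dtype=float), (vox, vox, vox))


def _simple_spec():
    return RoiSpec(
        lc_roi=BoxRoi((10, 14), (4.0, 4.0)),
        ref_left=BoxRoi((16, 4), (2.0, 2.0)),
        ref_right=BoxRoi((3, 4), (2.0, 2.0)),
        slice_range=(0, 3),
    )


class TestBuildTemplate:
    def test_mean_of_identical_volumes_is_identity(self):
        v = _vol(np.random.default_rng(0).normal(100, 5, (8, 8, 4)))
        np.testing.assert_array_equal(build_template([v, v]).data, v.data)

    def test_mean_of_constants(self):
        t = build_template([_vol(np.full((4, 4, 2), 10.0)), _vol(np.full((4, 4, 2), 20.0))])
        np.testing.assert_array_equal(t.data, 15.0)

    def test_grid_mismatch_names_offender(self):
        with pytest.raises(GridMismatchError, match="volume 1"):
            build_template([_vol(np.zeros((4, 4, 2))), _vol(np.zeros((5, 4, 2)))])

    def test_single_volume_rejected(self):
        with pytest.raises(ValueError):
            build_template([_vol(np.zeros((4, 4, 2)))])

    def test_template_noise_shrinks_like_sqrt_n(self):
        """Averaging 30 noisy subjects leaves background noise ~ sigma/sqrt(30)."""
        cfg = SimulationConfig(n_subjects=30, noise_sd=2.0, subject_jitter_sd=0.0, seed=99)
        volumes, _, roispec = generate_cohort(cfg)
        template = build_template(volumes)
        ref = roispec.ref_mask(template)
        sd = template.data[ref].std()
        assert sd == pytest.approx(2.0 / np.sqrt(30), rel=0.2)


class TestRoiStats:
    def test_constant_roi_threshold_is_the_constant(self):
        stats = roi_stats(_vol(np.full((20, 20, 4), 42.0)), _simple_spec())
        assert stats.sigma == 0.0
        assert stats.threshold == pytest.approx(42.0, abs=1e-12)

    def test_half_zero_half_one_closed_form(self):
        data = np.zeros((20, 20, 4))
        spec = _simple_spec()
        vol = _vol(data)
        ref = spec.ref_mask(vol)
        idx = np.argwhere(ref)
        data[tuple(idx[: len(idx) // 2].T)] = 1.0   # exactly half the ROI voxels
        stats = roi_stats(_vol(data), spec)
        assert stats.mu == pytest.approx(0.5, abs=1e-12)
        assert stats.sigma == pytest.approx(0.5, abs=1e-12)   # population SD
        assert stats.threshold == pytest.approx(2.5, abs=1e-12)

    def test_random_roi_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        data = rng.normal(100, 7, (20, 20, 4))
        spec = _simple_spec()
        vol = _vol(data)
        stats = roi_stats(vol, spec)
        vals = data[spec.ref_mask(vol)]
        assert stats.mu == pytest.approx(vals.sum() / vals.size, abs=1e-12)
        assert stats.sigma == pytest.approx(
            np.sqrt(((vals - vals.mean()) ** 2).sum() / vals.size), abs=1e-12)

    def test_reference_square_is_17x17_at_half_mm(self):
        cfg = SimulationConfig(n_subjects=2, noise_sd=0.0, subject_jitter_sd=0.0)
        volumes, _, roispec = generate_cohort(cfg)
        per_side = roispec.ref_mask(volumes[0], "left").sum()
        n_slices = roispec.slice_range[1] - roispec.slice_range[0] + 1
        assert per_side == 17 * 17 * n_slices


class TestCreateLcMask:
    def test_noise_free_template_mask_equals_truth(self, noise_free_cohort):
        _, volumes, truth, roispec = noise_free_cohort
        template = build_template(volumes)
        mask = create_lc_mask(template, roispec, truth.plausibility)
        np.testing.assert_array_equal(mask.mask, truth.mask)
        np.testing.assert_array_equal(mask.left, truth.left_mask)
        np.testing.assert_array_equal(mask.right, truth.right_mask)

    def test_bright_midline_artifact_is_excluded(self, noise_free_cohort):
        _, volumes, truth, roispec = noise_free_cohort
        template = build_template(volumes)
        data = template.data.copy()
        mid = data.shape[0] // 2
        data[mid, 40, 20:25] = 500.0                     # ventricle artifact
        mask = create_lc_mask(template.like(data), roispec, truth.plausibility)
        assert not mask.mask[mid, 40, 20:25].any()

    def test_threshold_above_global_max_gives_empty_mask(self):
        cfg = SimulationConfig(n_subjects=2, noise_sd=2.0, seed=4)
        volumes, truth, roispec = generate_cohort(cfg)
        template = build_template(volumes)
        with pytest.warns(UserWarning, match="empty"):
            mask = create_lc_mask(template, roispec, truth.plausibility, multiplier=1e9)
        assert mask.count() == 0

    def test_side_split_conserves_counts(self, noise_free_cohort):
        _, volumes, truth, roispec = noise_free_cohort
        mask = create_lc_mask(build_template(volumes), roispec, truth.plausibility)
        assert mask.count("left") + mask.count("right") == mask.count("combined")
        assert mask.per_slice_counts["left"].sum() == mask.count("left")


class TestExtractSubject:
    def test_contrast_ratio_arithmetic(self, noise_free_cohort):
        _, volumes, truth, roispec = noise_free_cohort
        template = build_template(volumes)
        mask = create_lc_mask(template, roispec, truth.plausibility)
        data = np.full(template.shape, 100.0)
        data[truth.left_mask] = 120.0                    # max(LC)=120, max(Ref)=100
        data[truth.right_mask] = 120.0
        res = extract_subject(template.like(data), mask, roispec)
        assert res.lc_cr["left"] == pytest.approx(0.2)
        assert res.lc_cr["combined"] == pytest.approx(0.2)

    def test_constant_subject_has_zero_contrast_and_zero_voxels(self, noise_free_cohort):
        _, volumes, truth, roispec = noise_free_cohort
        template = build_template(volumes)
        mask = create_lc_mask(template, roispec, truth.plausibility)
        res = extract_subject(template.like(np.full(template.shape, 100.0)), mask, roispec)
        for side in ("left", "right", "combined"):
            assert res.lc_cr[side] == 0.0
            assert res.lc_vox[side] == 0                 # strict >, sigma=0

    def test_noise_free_recovery_per_side(self, noise_free_cohort):
        """True contrasts 1.30/1.25 recovered as LC_CR 0.30/0.25 and exact counts."""
        _, volumes, truth, roispec = noise_free_cohort
        template = build_template(volumes)
        mask = create_lc_mask(template, roispec, truth.plausibility)
        for vol in volumes:
            res = extract_subject(vol, mask, roispec)
            assert res.lc_cr["left"] == pytest.approx(0.30, abs=1e-12)
            assert res.lc_cr["right"] == pytest.approx(0.25, abs=1e-12)
            assert res.lc_vox["left"] == truth.n_voxels("left")
            assert res.lc_vox["right"] == truth.n_voxels("right")
            assert res.lc_vox["combined"] == truth.n_voxels("combined")

    def test_scale_invariance(self, noise_free_cohort):
        _, volumes, truth, roispec = noise_free_cohort
        template = build_template(volumes)
        mask = create_lc_mask(template, roispec, truth.plausibility)
        base = extract_subject(volumes[0], mask, roispec)
        scaled = extract_subject(volumes[0].like(volumes[0].data * 3.7), mask, roispec)
        for side in ("left", "right", "combined"):
            assert scaled.lc_cr[side] == pytest.approx(base.lc_cr[side], abs=1e-12)
            assert scaled.lc_vox[side] == base.lc_vox[side]

    def test_voxel_count_monotone_in_threshold_multiplier(self):
        cfg = SimulationConfig(n_subjects=4, noise_sd=2.0, seed=21)
        volumes, truth, roispec = generate_cohort(cfg)
        template = build_template(volumes)
        mask = create_lc_mask(template, roispec, truth.plausibility)
        counts = [
            extract_subject(volumes[0], mask, roispec, multiplier=m).lc_vox["combined"]
            for m in (2.0, 4.0, 6.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_asymmetry_direction_preserved(self):
        cfg = SimulationConfig(n_subjects=12, noise_sd=2.0, seed=31)
        volumes, truth, roispec = generate_cohort(cfg)
        template = build_template(volumes)
        mask = create_lc_mask(template, roispec, truth.plausibility)
        results = [extract_subject(v, mask, roispec) for v in volumes]
        left = np.mean([r.lc_cr["left"] for r in results])
        right = np.mean([r.lc_cr["right"] for r in results])
        assert left > right


class TestProbabilisticMap:
    def test_unanimity_gives_binary_fractions(self):
        m = np.zeros((6, 6, 3), dtype=bool)
        m[2:4, 2:4, 1] = True
        maps = [_vol(m)] * 5
        frac, thresh, _ = probabilistic_map(maps)
        assert set(np.unique(frac.data)) <= {0.0, 1.0}
        np.testing.assert_array_equal(thresh, m)

    def test_rare_voxel_excluded_at_ten_percent(self):
        maps = []
        for i in range(53):
            m = np.zeros((4, 4, 2), dtype=bool)
            m[0, 0, 0] = i < 5                           # positive in 5 of 53
            m[1, 1, 0] = i < 10                          # positive in 10 of 53
            maps.append(_vol(m))
        frac, thresh, _ = probabilistic_map(maps, min_probability=0.10)
        assert frac.data[0, 0, 0] == pytest.approx(5 / 53)
        assert not thresh[0, 0, 0]                       # 9.4% < 10%
        assert thresh[1, 1, 0]                           # 18.9% > 10%

    def test_fractions_match_indicator_mean_oracle(self):
        rng = np.random.default_rng(11)
        stack = rng.random((7, 5, 5, 3)) < 0.3
        maps = [_vol(s) for s in stack]
        frac, _, _ = probabilistic_map(maps)
        np.testing.assert_allclose(frac.data, stack.mean(axis=0), atol=1e-15)

    def test_empty_subject_list_is_an_error(self):
        with pytest.raises(ValueError):
            probabilistic_map([])

    def test_peak_coordinates_reported_per_slice_and_side(self, noise_free_cohort):
        _, volumes, truth, roispec = noise_free_cohort
        maps = [_vol(truth.left_mask | truth.right_mask)]
        _, _, peaks = probabilistic_map(maps)
        assert set(peaks["side"]) == {"left", "right"}
        assert peaks["slice"].nunique() == 17
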