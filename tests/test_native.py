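import numpy as np
import pytest

from lcmri import VolumeGrid, ns_threshold, ns_select, ns_parameters, run_native
from oracles import greedy_threshold_oracle


def _volume(data):
    return VolumeGrid(np.asarray(data, dtype=float), (0.5, 0.5, 0.5))


class TestNsThreshold:
    def test_constant_roi_returns_the_constant(self):
        assert ns_threshold(np.full((4, 4, 3), 7.5)) == 7.5

    def test_unique_bright_blob_defines_the_threshold(self):
        vals = np.full((5, 5, 3), 50.0)
        vals[1:3, 1:3, 0] = 100.0   # 4 voxels
        vals[1:3, 1:3, 1] = 100.0   # +4
        vals[1:3, 1:2, 2] = 100.0   # +2 -> exactly 10 connected at 100
        assert ns_threshold(vals) == 100.0

    def test_roi_smaller_than_k_is_an_error(self):
        with pytest.raises(ValueError, match="k=10"):
            ns_threshold(np.zeros((2, 2, 2)))

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_greedy_oracle_on_random_rois(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        vals = rng.normal(100, 10, (6, 6, 3))
        assert ns_threshold(vals, k=10, connectivity=connectivity) == pytest.approx(
            greedy_threshold_oracle(vals, k=10, connectivity=connectivity)
        )

    def test_connectivity_matters_for_diagonal_chains(self):
        # a diagonal run of bright voxels is one set under 26- but not 6-connectivity
        vals = np.full((12, 12, 1), 10.0)
        for i in range(10):
            vals[i, i, 0] = 100.0 - i          # descending diagonal chain
        t26 = ns_threshold(vals, k=10, connectivity=26)
        t6 = ns_threshold(vals, k=10, connectivity=6)
        assert t26 == 91.0
        assert t6 < t26                        # 6-connectivity must leave the chain


class TestNsSelect:
    def _scene(self):
        """60-voxel flat blob inside an LC ROI, uniform background."""
        from lcmri import BoxRoi, RoiSpec
        data = np.full((24, 24, 8), 100.0)
        data[10:14, 10:15, 2:5] = 130.0
        vol = _volume(data)
        spec = RoiSpec(
            lc_roi=BoxRoi((12, 12), (8.0, 8.0)),
            ref_left=BoxRoi((19, 4), (2.0, 2.0)),
            ref_right=BoxRoi((4, 4), (2.0, 2.0)),
            slice_range=(0, 7),
        )
        return vol, spec

    def test_clean_blob_selected_in_single_iteration(self):
        vol, spec = self._scene()
        res = ns_select(vol, spec, np.ones(vol.shape, dtype=bool))
        assert res.n_iterations == 1
        assert res.converged
        np.testing.assert_array_equal(res.selected_voxels, vol.data == 130.0)

    def test_implausible_brighter_blob_is_vetoed_then_rescreened(self):
        vol, spec = self._scene()
        data = vol.data.copy()
        data[8:10, 8:10, 2:5] = 150.0          # brighter blob B, 12 voxels
        vol = _volume(data)
        plaus = np.ones(vol.shape, dtype=bool)
        plaus[8:10, 8:10, :] = False           # B is anatomically implausible
        res = ns_select(vol, spec, plaus)
        # hand trace: round 1 threshold 150 (B's plateau), B vetoed;
        # round 2 threshold 130 (A's plateau), A accepted
        assert res.threshold_trace == [150.0, 130.0]
        assert res.n_iterations == 2
        np.testing.assert_array_equal(res.selected_voxels, data == 130.0)

    def test_empty_plausibility_selects_nothing(self):
        vol, spec = self._scene()
        res = ns_select(vol, spec, np.zeros(vol.shape, dtype=bool))
        assert res.lc_vox_ns == 0
        assert not res.selected_voxels.any()
        assert res.converged

    def test_rerun_is_idempotent(self):
        vol, spec = self._scene()
        plaus = np.ones(vol.shape, dtype=bool)
        plaus[10:12, 10:12, :] = False
        first = ns_select(vol, spec, plaus)
        second = ns_select(vol, spec, plaus)
        np.testing.assert_array_equal(first.selected_voxels, second.selected_voxels)
        assert first.threshold_trace == second.threshold_trace

    def test_mismatched_plausibility_grid_rejected(self):
        vol, spec = self._scene()
        with pytest.raises(ValueError, match="plausibility"):
            ns_select(vol, spec, np.ones((2, 2, 2), dtype=bool))


class TestNsParameters:
    def test_contrast_ratio_arithmetic(self):
        from lcmri import BoxRoi, RoiSpec
        data = np.full((20, 20, 4), 100.0)
        sel = np.zeros(data.shape, dtype=bool)
        sel[9:11, 9:11, 1] = True
        data[sel] = 130.0
        spec = RoiSpec(
            lc_roi=BoxRoi((10, 10), (4.0, 4.0)),
            ref_left=BoxRoi((16, 3), (2.0, 2.0)),
            ref_right=BoxRoi((3, 3), (2.0, 2.0)),
            slice_range=(0, 3),
        )
        res = ns_parameters(_volume(data), sel, spec)
        assert res.lc_cr_ns == pytest.approx(1.30)
        assert res.lc_vox_ns == 4

    def test_selection_at_reference_intensity_gives_unity(self):
        from lcmri import BoxRoi, RoiSpec
        data = np.full((20, 20, 4), 100.0)
        sel = np.zeros(data.shape, dtype=bool)
        sel[9, 9, 1] = True
        spec = RoiSpec(
            lc_roi=BoxRoi((10, 10), (4.0, 4.0)),
            ref_left=BoxRoi((16, 3), (2.0, 2.0)),
            ref_right=BoxRoi((3, 3), (2.0, 2.0)),
            slice_range=(0, 3),
        )
        assert ns_parameters(_volume(data), sel, spec).lc_cr_ns == pytest.approx(1.0)

    def test_empty_selection_reports_missing_not_zero(self):
        from lcmri import BoxRoi, RoiSpec
        data = np.full((20, 20, 4), 100.0)
        spec = RoiSpec(
            lc_roi=BoxRoi((10, 10), (4.0, 4.0)),
            ref_left=BoxRoi((16, 3), (2.0, 2.0)),
            ref_right=BoxRoi((3, 3), (2.0, 2.0)),
            slice_range=(0, 3),
        )
        res = ns_parameters(_volume(data), np.zeros(data.shape, dtype=bool), spec)
        assert res.lc_cr_ns is None
        assert res.lc_vox_ns == 0

    def test_nonpositive_reference_mean_is_an_error(self):
        from lcmri import BoxRoi, RoiSpec
        data = np.zeros((20, 20, 4))
        spec = RoiSpec(
            lc_roi=BoxRoi((10, 10), (4.0, 4.0)),
            ref_left=BoxRoi((16, 3), (2.0, 2.0)),
            ref_right=BoxRoi((3, 3), (2.0, 2.0)),
            slice_range=(0, 3),
        )
        with pytest.raises(ValueError, match="reference mean"):
            ns_parameters(_volume(data), np.zeros(data.shape, dtype=bool), spec)


def test_flat_tube_cohort_recovered_exactly(flat_tube_cohort):
    """Noise-free flat tubes: the full native pass recovers every tube voxel
    and LC_CR-NS equals the true contrast exactly."""
    cfg, volumes, truth, roispec = flat_tube_cohort
    for vol in volumes:
        res = run_native(vol, roispec, truth.plausibility)
        assert res.converged
        assert res.lc_vox_ns == truth.n_voxels("combined")
        assert res.lc_cr_ns == pytest.approx(1.25, abs=1e-12)


def test_threshold_trace_bounds_selected_intensities(noise_free_cohort):
    _, volumes, truth, roispec = noise_free_cohort
    res = run_native(volumes[0], roispec, truth.plausibility)
    assert np.all(np.isfinite(res.threshold_trace))
    assert volumes[0].data[res.selected_voxels].min() >= res.threshold_trace[-1]
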