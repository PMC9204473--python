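import numpy as np
import pytest

import metalsim as ms


class TestRoiNoise:
    def test_constant_volume_zero_sd(self):
        vol = ms.VoxelVolume(np.full((5, 32, 32), 40.0), (1, 1, 1))
        res = ms.roi_noise(vol, ms.RoiSpec("circle", (16, 16), radius=8))
        assert res.sd_hu == 0.0
        assert res.mean_hu == 40.0

    def test_gaussian_noise_sd_recovered(self, rng):
        """Per-slice SD averaged over slices estimates the true sigma."""
        vol = ms.VoxelVolume(rng.normal(0.0, 10.0, (20, 40, 40)), (1, 1, 1))
        res = ms.roi_noise(vol, ms.RoiSpec("circle", (20, 20), radius=18))
        assert res.sd_hu == pytest.approx(10.0, abs=0.5)
        assert len(res.per_slice_sd) == 20
        assert res.sd_across_slices < 1.0

    def test_single_voxel_roi_flagged_degenerate(self):
        vol = ms.VoxelVolume(np.zeros((3, 16, 16)), (1, 1, 1))
        res = ms.roi_noise(vol, ms.RoiSpec("circle", (8, 8), radius=0))
        assert res.degenerate
        assert res.sd_hu == 0.0

    def test_roi_outside_volume_rejected(self):
        vol = ms.VoxelVolume(np.zeros((1, 16, 16)), (1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            ms.roi_noise(vol, ms.RoiSpec("circle", (8, 8), radius=10))

    def test_rectangle_roi(self, rng):
        vol = ms.VoxelVolume(rng.normal(0, 5.0, (4, 32, 32)), (1, 1, 1))
        res = ms.roi_noise(vol, ms.RoiSpec("rectangle", (16, 16), extents=(6, 6)))
        assert res.sd_hu == pytest.approx(5.0, abs=0.7)


class TestArtifactHistogram:
    def test_uniform_water_counts_nothing(self):
        vol = ms.VoxelVolume(np.zeros((2, 32, 32)), (1, 1, 1))
        hist = ms.artifact_histogram(vol)
        assert hist.low_count == 0 and hist.high_count == 0
        assert hist.total_considered == 2 * 32 * 32

    def test_known_dark_voxels_counted(self):
        data = np.zeros((1, 10, 10))
        data[0, :3, 0] = -100.0
        hist = ms.artifact_histogram(ms.VoxelVolume(data, (1, 1, 1)))
        assert hist.low_count == 3
        assert hist.high_count == 0

    def test_metal_cap_excludes_probe_voxels(self):
        data = np.zeros((1, 4, 4))
        data[0, 0, 0] = 600.0  # above the 500-HU cap: neither band
        data[0, 1, 1] = 300.0  # bright-band member
        hist = ms.artifact_histogram(ms.VoxelVolume(data, (1, 1, 1)))
        assert hist.high_count == 1

    def test_exclusion_mask_removes_voxels(self):
        data = np.full((1, 4, 4), -100.0)
        mask = np.zeros_like(data, bool)
        mask[0, :2] = True
        hist = ms.artifact_histogram(ms.VoxelVolume(data, (1, 1, 1)),
                                     exclusion_mask=mask)
        assert hist.low_count == 8
        assert hist.total_considered == 8

    def test_histogram_bins_partition(self):
        data = np.zeros((1, 8, 8))
        data[0, 0] = np.linspace(80, 480, 8)
        hist = ms.artifact_histogram(ms.VoxelVolume(data, (1, 1, 1)))
        assert hist.high_hist[0].sum() == hist.high_count

    def test_unordered_thresholds_rejected(self):
        vol = ms.VoxelVolume(np.zeros((1, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError, match="ordered"):
            ms.artifact_histogram(vol, thresholds=(75.0, -75.0, 500.0))


class TestSinogramDifference:
    def test_identical_inputs_zero_map(self, rng):
        a = rng.random((10, 8, 2))
        diff, _ = ms.sinogram_difference(a, a.copy())
        assert not diff.any()

    def test_constant_offset(self, rng):
        a = rng.random((10, 8, 2))
        diff, _ = ms.sinogram_difference(a, a + 3.0)
        assert np.allclose(diff, -3.0)

    def test_detector_row_selection(self, rng):
        a = rng.random((10, 8, 3))
        b = np.zeros_like(a)
        diff, _ = ms.sinogram_difference(a, b, detector_row=1)
        assert diff.shape == (10, 8)
        assert np.allclose(diff, a[:, :, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ms.sinogram_difference(np.zeros((2, 2, 1)), np.zeros((3, 2, 1)))

    def test_roi_stats(self):
        a = np.zeros((20, 20, 1))
        a[5:10, 5:10, 0] = 2.0
        diff, stats = ms.sinogram_difference(
            a, np.zeros_like(a),
            roi=ms.RoiSpec("rectangle", (7, 7), extents=(2, 2)),
        )
        assert stats["mean"] == pytest.approx(2.0)
        assert stats["sd"] == 0.0

    def test_difference_confined_to_metal_mask(self, spectrum120):
        """Insertion with vs without noise differs only on metal rays."""
        phantom = ms.make_disc_phantom(60.0, voxel_mm=1.0, n_slices=1,
                                       grid_shape=(80, 80))
        geo = ms.AcquisitionGeometry.parallel(fov_mm=80.0, n_views=60,
                                              det_pitch_mm=1.0, n_rows=1)
        original = ms.scan_phantom(phantom, geo, spectrum120)
        rod = ms.make_rod_object(6.0, 20.0, "titanium", voxel_mm=0.5,
                                 orientation=(0.0, 90.0))
        placement = ms.Placement(tip_mm=(0.0, 0.0, 10.0))
        runs = {}
        for noise_on in (False, True):
            run = ms.InsertionRun(probes=[(rod, placement)], spectrum=spectrum120,
                                  noise_on=noise_on,
                                  noise=ms.NoiseParams(n0=1e5, ne=20.0), seed=2)
            runs[noise_on], diag = ms.insert_projection_domain(
                original, run, phantom, return_diagnostics=True)
        diff, _ = ms.sinogram_difference(runs[True], runs[False])
        off_mask = diag["p_metal"] <= 0
        assert not diff[off_mask].any()
        assert diff[~off_mask].any()


class TestDice:
    def test_identical_masks(self):
        a = ms.VoxelVolume(np.full((1, 4, 4), 1000.0), (1, 1, 1))
        assert ms.dice_overlap(a, a.copy(), 500.0) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((1, 4, 4)); a[0, 0, 0] = 1000.0
        b = np.zeros((1, 4, 4)); b[0, 3, 3] = 1000.0
        assert ms.dice_overlap(a, b, 500.0) == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 1, 100)); a[0, 0, :100] = 1000.0
        b = np.zeros((1, 1, 100)); b[0, 0, 50:] = 1000.0
        assert ms.dice_overlap(a, b, 500.0) == pytest.approx(2 * 50 / 150)

    def test_both_empty_is_one(self):
        z = np.zeros((1, 2, 2))
        assert ms.dice_overlap(z, z, 500.0) == 1.0

    def test_grid_mismatch_rejected(self):
        a = ms.VoxelVolume(np.zeros((1, 4, 4)), (1, 1, 1))
        b = ms.VoxelVolume(np.zeros((1, 4, 4)), (2, 2, 2))
        with pytest.raises(ValueError, match="grid"):
            ms.dice_overlap(a, b, 500.0)
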