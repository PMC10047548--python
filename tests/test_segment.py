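"""Nuclei spots, cell bodies, microcarrier spheres, thresholds, stripes."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from carrierscope import segment as sg, synthscene as sy
from carrierscope.segment import SegmentSettings
from carrierscope.synthscene import DEFAULT_GEOMETRY, OpticsParams, SceneParams
from carrierscope.volio import MultiChannelVolume, VoxelGeometry

NUC = SegmentSettings(intensity_threshold=450.0)
CARR = SegmentSettings(carrier_lowpass_threshold=220.0,
                       carrier_highpass_threshold=580.0)


def _vol(data, roles, geometry=VoxelGeometry(1, 1, 1)):
    return MultiChannelVolume(np.asarray(data, dtype=np.float32)[None], geometry,
                              roles)


class TestDetectNuclei:
    def test_empty_volume_no_spots(self):
        vol = _vol(np.zeros((20, 20, 20)), ("nuclear",))
        assert len(sg.detect_nuclei(vol, NUC)) == 0

    def test_threshold_above_maximum_warns(self):
        vol = _vol(np.full((10, 10, 10), 5.0), ("nuclear",))
        spots = sg.detect_nuclei(
            vol, SegmentSettings(intensity_threshold=1e6))
        assert len(spots) == 0
        assert any("above channel maximum" in f for f in spots.findings)

    def test_five_nuclei_found_within_2um(self, geometry):
        params = SceneParams(domain_um=(200, 260, 260), n_carriers=1,
                             explicit_counts=[5], n_debris=0, seed=11)
        scene = sy.sample_scene(params)
        vol = sy.render(scene, OpticsParams(), geometry, channels=("nuclear",))
        spots = sg.detect_nuclei(vol, NUC)
        assert len(spots) == 5
        truth = scene.cells[["nucleus_z_um", "nucleus_y_um",
                             "nucleus_x_um"]].to_numpy()
        d, _ = cKDTree(spots.centroids()).query(truth)
        assert d.max() <= 2.0

    def test_debris_rejected_by_size_and_intensity(self, geometry):
        # 2 μm debris at 0.6x nuclear intensity must not add spots
        params = SceneParams(domain_um=(200, 260, 260), n_carriers=1,
                             explicit_counts=[5], n_debris=20,
                             debris_diameter_um=(2.0, 2.0), seed=11)
        scene = sy.sample_scene(params)
        vol = sy.render(scene, OpticsParams(), geometry, channels=("nuclear",))
        assert len(sg.detect_nuclei(vol, NUC)) == 5

    def test_minimum_separation_invariant(self, small_volume):
        spots = sg.detect_nuclei(small_volume, NUC)
        if len(spots) > 1:
            pts = spots.centroids()
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 0.7 * NUC.nucleus_diameter_um

    def test_missing_channel(self, geometry):
        vol = _vol(np.zeros((5, 5, 5)), ("scatter",))
        with pytest.raises(KeyError):
            sg.detect_nuclei(vol, NUC)


class TestSegmentCells:
    def test_painted_region_measured_exactly(self):
        # 1000 voxels at 1 μm³ each -> exactly 1000 μm³
        grid = np.zeros((20, 20, 20))
        grid[2:12, 3:13, 4:14] = 100.0  # 10x10x10 = 1000 voxels
        vol = _vol(grid, ("cytoplasm",))
        seg = sg.segment_cells(
            vol, SegmentSettings(intensity_threshold=50.0,
                                 min_cell_volume_um3=10.0))
        assert seg.n_objects == 1
        assert seg.objects.volume_um3.iloc[0] == 1000.0

    def test_labels_contiguous_and_volume_exact(self, small_volume):
        seg = sg.segment_cells(
            small_volume, SegmentSettings(intensity_threshold=400.0))
        labs = np.unique(seg.labels)
        assert list(labs[labs > 0]) == list(range(1, seg.n_objects + 1))
        voxvol = small_volume.geometry.voxel_volume
        for row in seg.objects.itertuples():
            assert row.volume_um3 == (seg.labels == row.label).sum() * voxvol

    def test_debris_removed_total_volume_recovered(self, small_volume,
                                                   small_scene):
        seg = sg.segment_cells(
            small_volume, SegmentSettings(intensity_threshold=400.0))
        truth = sy.ground_truth(small_scene)
        assert seg.n_objects == len(small_scene.cells)
        assert seg.total_volume_um3 == pytest.approx(
            truth.total_cell_volume_um3, rel=0.10)

    def test_threshold_above_max_empty_not_error(self):
        vol = _vol(np.random.default_rng(0).uniform(0, 10, (10, 10, 10)),
                   ("cytoplasm",))
        seg = sg.segment_cells(vol, SegmentSettings(intensity_threshold=100.0))
        assert seg.n_objects == 0
        assert seg.labels.max() == 0

    def test_cavity_filling_on_scatter(self, small_volume_clean, small_scene):
        filled = sg.segment_cells(
            small_volume_clean, SegmentSettings(intensity_threshold=580.0),
            role="scatter")
        open_ = sg.segment_cells(
            small_volume_clean,
            SegmentSettings(intensity_threshold=580.0, fill_cavities=False),
            role="scatter")
        assert filled.total_volume_um3 >= open_.total_volume_um3


class TestDetectMicrocarriers:
    def test_pure_medium_no_detection(self):
        vol = _vol(np.full((40, 40, 40), 300.0), ("scatter",),
                   VoxelGeometry(2, 2, 2))
        assert len(sg.detect_microcarriers(vol, CARR)) == 0

    def test_single_carrier_center_and_radius(self, small_volume, small_scene):
        det = sg.detect_microcarriers(small_volume, CARR)
        assert len(det) == 1
        truth = small_scene.carriers.iloc[0]
        center_err = np.linalg.norm(
            det.centers()[0] - np.array([truth.z_um, truth.y_um, truth.x_um]))
        assert center_err <= 3.0
        assert det.radii()[0] == pytest.approx(truth.radius_um, rel=0.05)

    def test_small_bodies_rejected_by_size_filter(self):
        # a 30 μm low-scatter inclusion is below the 90 μm size filter
        grid = np.full((60, 60, 60), 300.0)
        zz, yy, xx = np.ogrid[:60, :60, :60]
        d2 = (zz - 30) ** 2 + (yy - 30) ** 2 + (xx - 30) ** 2
        grid[d2 <= (15 / 2) ** 2] = 150.0
        vol = _vol(grid, ("scatter",), VoxelGeometry(2, 2, 2))
        assert len(sg.detect_microcarriers(vol, CARR)) == 0


class TestAutoThreshold:
    def test_bimodal_separated(self):
        rng = np.random.default_rng(0)
        chan = np.concatenate(
            [rng.normal(100, 10, 5000), rng.normal(1000, 50, 5000)])
        thr = sg.auto_threshold(chan.reshape(10, 10, 100), "otsu")
        assert 100 < thr < 1000

    def test_percentile_exact_quantile(self):
        rng = np.random.default_rng(1)
        chan = rng.uniform(0, 1, (10, 10, 10))
        thr = sg.auto_threshold(chan, "percentile", q=0.99)
        assert thr == pytest.approx(np.quantile(chan, 0.99))

    def test_constant_channel_errors(self):
        with pytest.raises(ValueError):
            sg.auto_threshold(np.full((5, 5, 5), 7.0))


class TestRemoveStripes:
    def test_constant_volume_unchanged(self):
        grid = np.full((10, 20, 30), 42.0)
        np.testing.assert_array_equal(sg.remove_stripes(grid, 3), grid)

    def test_narrow_stripe_recovered(self):
        grid = np.full((6, 40, 40), 100.0)
        grid[:, 17, :] *= 0.5  # one attenuated line along x
        out = sg.remove_stripes(grid, half_width=3)
        assert abs(out[:, 17, :].mean() - 100.0) / 100.0 < 0.05

    def test_wide_stripe_only_partially_removed(self):
        grid = np.full((4, 40, 40), 100.0)
        grid[:, 10:25, :] *= 0.5  # wider than 2x half-width
        out = sg.remove_stripes(grid, half_width=3)
        assert out[:, 17, :].mean() < 60.0  # documented limitation

    def test_half_width_validated(self):
        with pytest.raises(ValueError):
            sg.remove_stripes(np.zeros((4, 4, 4)), 0)
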