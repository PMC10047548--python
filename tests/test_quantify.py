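"""Cell assignment, CPM distribution rules, summaries, morphology."""

import numpy as np
import pandas as pd
import pytest

from carrierscope import quantify as q, segment as sg, stats as st, synthscene as sy
from carrierscope.segment import (
    LabeledSegmentation,
    MicrocarrierSet,
    SegmentSettings,
    SpotSet,
)
from carrierscope.synthscene import DEFAULT_GEOMETRY, OpticsParams, SceneParams
from carrierscope.volio import VoxelGeometry

G1 = VoxelGeometry(1, 1, 1)


def _spots(coords):
    df = pd.DataFrame(coords, columns=["z_um", "y_um", "x_um"])
    df.insert(0, "id", range(len(df)))
    df["diameter_um"] = 10.0
    df["peak_intensity"] = 1.0
    return SpotSet(df, G1)


def _carriers(rows):
    df = pd.DataFrame(rows, columns=["z_um", "y_um", "x_um", "radius_um"])
    df.insert(0, "id", range(len(df)))
    return MicrocarrierSet(df, G1)


class TestAssignCells:
    def test_nucleus_above_surface_assigned(self):
        carriers = _carriers([[100, 100, 100, 60.0]])
        spots = _spots([[100, 100, 165.0]])  # 5 μm above the surface
        a = q.assign_cells(spots, carriers, max_distance=15.0)
        assert a.table.carrier_id.iloc[0] == 0
        assert a.table.surface_distance_um.iloc[0] == pytest.approx(5.0)

    def test_too_far_unassigned(self):
        carriers = _carriers([[100, 100, 100, 60.0]])
        spots = _spots([[100, 100, 180.0]])  # 20 μm above
        a = q.assign_cells(spots, carriers, max_distance=15.0)
        assert a.table.carrier_id.iloc[0] == q.UNASSIGNED

    def test_exact_tie_goes_to_lower_id(self):
        carriers = _carriers([[100, 100, 40, 30.0], [100, 100, 160, 30.0]])
        spots = _spots([[100, 100, 100.0]])  # equidistant from both surfaces
        a = q.assign_cells(spots, carriers, max_distance=50.0)
        assert a.table.carrier_id.iloc[0] == 0

    def test_synthetic_scene_assignment_accuracy(self, geometry):
        params = SceneParams(domain_um=(330, 660, 660), n_carriers=7,
                             cpm_lambda=2.0, n_debris=0, seed=17)
        scene = sy.sample_scene(params)
        truth_spots = _spots(
            scene.cells[["nucleus_z_um", "nucleus_y_um", "nucleus_x_um"]]
            .to_numpy())
        carriers = MicrocarrierSet(
            scene.carriers[["id", "z_um", "y_um", "x_um", "radius_um"]].copy(),
            geometry)
        a = q.assign_cells(truth_spots, carriers)
        correct = (
            a.table.carrier_id.to_numpy()
            == scene.cells.carrier_id.to_numpy()).mean()
        assert correct >= 0.98

    def test_max_distance_validated(self):
        with pytest.raises(ValueError):
            q.assign_cells(_spots([[0, 0, 0]]), _carriers([[0, 0, 0, 10]]), 0.0)


def _assignment(counts, carriers):
    rows = []
    sid = 0
    for cid, k in enumerate(counts):
        for _ in range(k):
            rows.append({"spot_id": sid, "carrier_id": cid,
                         "surface_distance_um": 5.0})
            sid += 1
    table = pd.DataFrame(rows, columns=["spot_id", "carrier_id",
                                        "surface_distance_um"])
    return q.CellAssignment(table, 15.0)


class TestCPMDistribution:
    def test_zero_truncation(self):
        carriers = _carriers([[0, 0, 0, 60], [0, 0, 300, 60], [0, 0, 600, 60]])
        a = _assignment([2, 0, 4], carriers)
        cpm = q.cpm_distribution(a, carriers)
        assert cpm.histogram == {2: 1, 4: 1}
        assert cpm.n == 2
        assert 0 not in cpm.histogram

    def test_aggregate_exclusion(self):
        # carriers 0-2 form a touching chain; 3 and 4 are isolated
        carriers = _carriers([
            [100, 100, 100, 60], [100, 100, 220, 60], [100, 100, 340, 60],
            [100, 500, 100, 60], [100, 500, 400, 60],
        ])
        a = _assignment([1, 2, 3, 4, 5], carriers)
        cpm = q.cpm_distribution(a, carriers, exclude_aggregates=True)
        assert cpm.histogram == {4: 1, 5: 1}
        assert cpm.cluster_sizes == {1: 2, 3: 1}
        incl = q.cpm_distribution(a, carriers, exclude_aggregates=False)
        assert incl.n == 5

    def test_exclusion_never_increases_n(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(100, 900, size=(15, 3))
        carriers = _carriers([[z, y, x, 60] for z, y, x in pts])
        a = _assignment(rng.integers(0, 4, size=15).tolist(), carriers)
        n_off = q.cpm_distribution(a, carriers, exclude_aggregates=False).n
        n_on = q.cpm_distribution(a, carriers, exclude_aggregates=True).n
        assert n_on <= n_off

    def test_mass_conservation(self):
        carriers = _carriers([[0, 0, 0, 60], [0, 0, 300, 60], [0, 0, 600, 60]])
        a = _assignment([3, 1, 0], carriers)
        cpm = q.cpm_distribution(a, carriers)
        assert sum(k * n for k, n in cpm.histogram.items()) == 4

    def test_ztp_fit_recovers_rate_from_scene(self):
        params = SceneParams(domain_um=(1400, 1400, 1400), n_carriers=300,
                             cpm_lambda=2.0, n_debris=0, seed=8)
        scene = sy.sample_scene(params)
        carriers = MicrocarrierSet(
            scene.carriers[["id", "z_um", "y_um", "x_um", "radius_um"]].copy(),
            DEFAULT_GEOMETRY)
        spots = _spots(
            scene.cells[["nucleus_z_um", "nucleus_y_um", "nucleus_x_um"]]
            .to_numpy())
        a = q.assign_cells(spots, carriers)
        cpm = q.cpm_distribution(a, carriers)
        fit = st.ztp_fit(cpm.counts())
        assert abs(fit.lam - 2.0) <= 3 * fit.se


class TestSummarize:
    def test_average_cpm(self):
        carriers = _carriers([[0, 0, 0, 60], [0, 0, 300, 60], [0, 0, 600, 60]])
        a = _assignment([1, 2, 3], carriers)
        s = q.summarize(a, carriers, None)
        assert s.average_cpm == pytest.approx(2.0)
        assert s.total_cell_count == 6

    def test_mean_volume_per_object(self):
        labels = np.zeros((10, 10, 30), dtype=np.int32)
        for i in range(3):
            labels[:10, :10, i * 10:i * 10 + 10] = i + 1
        objects = pd.DataFrame({
            "label": [1, 2, 3], "volume_um3": [1000.0] * 3,
            "surface_area_um2": [600.0] * 3, "z_um": [5] * 3, "y_um": [5] * 3,
            "x_um": [5, 15, 25], "mean_intensity": [1.0] * 3})
        seg = LabeledSegmentation(labels, G1, objects)
        s = q.summarize(None, None, seg)
        assert s.total_cell_volume_um3 == 3000.0
        assert s.mean_cell_volume_um3 == 1000.0
        assert s.volume_estimator == "per_object"

    def test_confluent_fallback_per_nucleus(self):
        labels = np.ones((5, 5, 5), dtype=np.int32)
        objects = pd.DataFrame({
            "label": [1], "volume_um3": [6000.0], "surface_area_um2": [600.0],
            "z_um": [2], "y_um": [2], "x_um": [2], "mean_intensity": [1.0]})
        seg = LabeledSegmentation(labels, G1, objects)
        carriers = _carriers([[2, 2, 2, 60]])
        a = _assignment([3], carriers)
        s = q.summarize(a, carriers, seg)
        assert s.volume_estimator == "volume_per_nucleus"
        assert s.mean_cell_volume_um3 == pytest.approx(2000.0)

    def test_zero_populated_is_defined(self):
        carriers = _carriers([[0, 0, 0, 60]])
        a = _assignment([0], carriers)
        s = q.summarize(a, carriers, None)
        assert s.populated_microcarrier_count == 0
        assert np.isnan(s.average_cpm)


def _seg_from_mask(mask, geometry=G1):
    labels = mask.astype(np.int32)
    vox = int(mask.sum())
    area = sg._surface_area(mask, geometry)
    com = np.array(np.nonzero(mask)).mean(axis=1)
    objects = pd.DataFrame({
        "label": [1], "volume_um3": [vox * geometry.voxel_volume],
        "surface_area_um2": [area],
        "z_um": [(com[0] + 0.5) * geometry.dz],
        "y_um": [(com[1] + 0.5) * geometry.dy],
        "x_um": [(com[2] + 0.5) * geometry.dx],
        "mean_intensity": [1.0]})
    return LabeledSegmentation(labels, geometry, objects)


class TestMorphology:
    def test_sphere_sphericity_unity(self):
        n = 50
        zz, yy, xx = np.ogrid[:n, :n, :n]
        mask = (zz - 25) ** 2 + (yy - 25) ** 2 + (xx - 25) ** 2 <= 20 ** 2
        m = q.morphology(_seg_from_mask(mask))
        assert m.sphericity.iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_cube_sphericity_closed_form(self):
        # V = a^3, A = 6 a^2 -> sphericity = (pi/6)^(1/3) ~ 0.806
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[5:25, 5:25, 5:25] = True
        m = q.morphology(_seg_from_mask(mask))
        assert m.sphericity.iloc[0] == pytest.approx((np.pi / 6) ** (1 / 3),
                                                     abs=0.05)

    def test_nc_ratio_on_synthetic_cell(self, small_volume_clean, small_scene):
        cells = sg.segment_cells(
            small_volume_clean, SegmentSettings(intensity_threshold=580.0),
            role="scatter")
        nuclei = sg.segment_cells(
            small_volume_clean,
            SegmentSettings(intensity_threshold=450.0,
                            min_cell_volume_um3=100.0),
            role="nuclear")
        m = q.morphology(cells, nuclei)
        truth = small_scene.cells
        true_ratio = (truth.nucleus_volume_um3
                      / (truth.volume_um3 - truth.nucleus_volume_um3))
        got = m.nc_ratio.dropna().sort_values().to_numpy()
        want = true_ratio.sort_values().to_numpy()
        assert len(got) == len(want)
        np.testing.assert_allclose(got, want, rtol=0.10)

    def test_unmatched_nucleus_leaves_nan(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[2:10, 2:10, 2:10] = True
        cells = _seg_from_mask(mask)
        far = np.zeros((20, 20, 20), dtype=bool)
        far[15:18, 15:18, 15:18] = True
        nuclei = _seg_from_mask(far)
        m = q.morphology(cells, nuclei)
        assert np.isnan(m.nc_ratio.iloc[0])
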