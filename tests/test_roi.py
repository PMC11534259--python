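"""Isodose shells, CSF subtraction, healthy-cylinder placement, ROI stats."""

import numpy as np
import pytest

from natsc.core import GridMeta, LabelVolume, ScalarVolume
from natsc.dose import DoseGrid, PrescriptionSpec, compute_dose
from natsc.phantom import LABELS
from natsc.register import segment_tissues
from natsc.roi import (
    build_isodose_shells,
    cylinder_mask,
    place_healthy_rois,
    roi_statistics,
    subtract_csf,
)


def _radial_dose(n=64, spacing=1.0, rx=22.0, r50=10.0, half=4.0):
    """Analytic spherically symmetric dose: 2·rx·min(1, 0.5·2^(−(r−r50)/half))."""
    meta = GridMeta(shape=(n,) * 3, spacing=(spacing,) * 3)
    x, y, z = meta.coordinate_arrays()
    c = np.array(meta.fov_mm) / 2
    r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
    d = 2.0 * rx * np.minimum(1.0, 0.5 * np.exp2(-(r - r50) / half))
    gtv = (r <= r50 * 0.6).astype(np.int16)
    grid = DoseGrid(
        dose=ScalarVolume(d, meta, "Gy"),
        prescriptions=(PrescriptionSpec(rx, margin_mm=0.0),),
    )
    return grid, LabelVolume(gtv, meta), r, meta


def _radius_at(dose_gy, rx=22.0, r50=10.0, half=4.0):
    """Invert the analytic dose profile: radius where dose equals dose_gy."""
    return r50 + half * np.log2(rx / dose_gy)


class TestIsodoseShells:
    def test_shells_partition_dose_band(self):
        grid, gtv, r, meta = _radial_dose()
        shells = build_isodose_shells(grid, gtv)
        d = grid.dose.data
        excluded = (gtv.data != 0) | shells.upper_bound_mask
        total = np.zeros(meta.shape, np.int32)
        for lev in shells.levels:
            total += (shells.shell_masks[lev].data != 0).astype(np.int32)
        assert total.max() <= 1  # pairwise disjoint
        target = (d >= 2.0) & ~shells.upper_bound_mask
        assert np.array_equal(total > 0, target & ~(gtv.data != 0))

    def test_shell_volumes_match_analytic_spherical_shells(self):
        grid, gtv, r, meta = _radial_dose(n=96, spacing=1.0)
        shells = build_isodose_shells(grid, gtv)
        levels = shells.levels
        for lev, nxt in zip(levels[:-1], levels[1:]):
            r_out, r_in = _radius_at(lev), _radius_at(nxt)
            analytic = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
            shell_vol = shells.shell_masks[lev].data.sum() * meta.voxel_volume_mm3
            surface = 4.0 * np.pi * (r_out**2 + r_in**2) * 1.0  # one voxel shell
            assert abs(shell_vol - analytic) <= surface, f"shell {lev} Gy"

    def test_mean_dose_ordered_across_shells(self):
        grid, gtv, _, _ = _radial_dose()
        shells = build_isodose_shells(grid, gtv)
        means = [
            grid.dose.data[shells.shell_masks[lev].data != 0].mean()
            for lev in shells.levels
            if (shells.shell_masks[lev].data != 0).any()
        ]
        assert np.all(np.diff(means) > 0)

    def test_subthreshold_dose_yields_all_empty_flagged_shells(self):
        grid, gtv, _, meta = _radial_dose()
        grid.dose.data[:] = 1.0  # everywhere below the lowest level
        with pytest.warns(UserWarning, match="empty"):
            shells = build_isodose_shells(grid, gtv)
        assert set(shells.empty_levels) == set(shells.levels)

    def test_prescription_below_top_level_flags_top_shell_empty(self):
        grid, gtv, _, _ = _radial_dose(rx=16.0)
        with pytest.warns(UserWarning, match="empty"):
            shells = build_isodose_shells(grid, gtv)
        assert 18.0 in shells.empty_levels


class TestSubtractCSF:
    @pytest.fixture(scope="class")
    def segmented(self, small_phantom):
        return segment_tissues(
            small_phantom.reference_anatomy,
            brain_mask=small_phantom.brain_mask,
            seed=0,
        )

    def test_pure_wm_roi_unchanged(self, small_phantom, segmented):
        meta = small_phantom.labels.meta
        from scipy import ndimage

        wm_core = ndimage.binary_erosion(
            small_phantom.labels.data == LABELS["wm"], iterations=3
        )
        roi = LabelVolume(wm_core.astype(np.int16), meta)
        out, removed = subtract_csf(roi, segmented)
        assert removed == 0
        assert np.array_equal(out.data, roi.data)

    def test_ventricle_overlap_removed_matches_ground_truth(
        self, small_phantom, segmented
    ):
        meta = small_phantom.labels.meta
        csf_true = small_phantom.labels.data == LABELS["csf"]
        from scipy import ndimage

        roi_arr = ndimage.binary_dilation(csf_true, iterations=2) & (
            small_phantom.brain_mask
        )
        roi = LabelVolume(roi_arr.astype(np.int16), meta)
        out, removed = subtract_csf(roi, segmented)
        true_in_roi = int((roi_arr & csf_true).sum())
        assert abs(removed - true_in_roi) / true_in_roi <= 0.05

    def test_threshold_one_removes_nothing(self, small_phantom, segmented):
        meta = small_phantom.labels.meta
        roi = LabelVolume(small_phantom.brain_mask.astype(np.int16), meta)
        _, removed = subtract_csf(roi, segmented, threshold=1.0)
        assert removed == 0


class TestHealthyROIs:
    @pytest.fixture(scope="class")
    def placed(self, small_phantom):
        tissue = segment_tissues(
            small_phantom.reference_anatomy,
            brain_mask=small_phantom.brain_mask,
            seed=0,
        )
        gtv = small_phantom.gtv_mask()
        rois = place_healthy_rois(tissue, None, gtv, seed=3)
        return tissue, gtv, rois

    def test_cylinders_mostly_in_white_matter(self, placed):
        tissue, _, rois = placed
        for roi in rois:
            m = roi.mask.data != 0
            assert (tissue.p_wm.data[m] > 0.5).mean() >= 0.95

    def test_volume_matches_analytic_cylinder(self, placed):
        _, _, rois = placed
        for roi in rois:
            vol = roi.mask.data.sum() * roi.mask.meta.voxel_volume_mm3
            assert abs(vol - roi.analytic_volume_mm3) / roi.analytic_volume_mm3 < 0.10

    def test_distance_from_gtv_respected(self, placed):
        _, gtv, rois = placed
        from scipy import ndimage

        meta = rois[0].mask.meta
        dist = ndimage.distance_transform_edt(~gtv, sampling=meta.spacing)
        for roi in rois:
            assert dist[roi.mask.data != 0].min() >= 20.0 - max(meta.spacing)

    def test_same_seed_reproduces_centers(self, small_phantom):
        tissue = segment_tissues(
            small_phantom.reference_anatomy,
            brain_mask=small_phantom.brain_mask,
            seed=0,
        )
        gtv = small_phantom.gtv_mask()
        a = place_healthy_rois(tissue, None, gtv, seed=3)
        b = place_healthy_rois(tissue, None, gtv, seed=3)
        assert all(r1.center == r2.center for r1, r2 in zip(a, b))


class TestROIStatistics:
    def test_constant_map(self):
        meta = GridMeta(shape=(8, 8, 8), spacing=(2.0,) * 3)
        tsc = ScalarVolume(np.full(meta.shape, 45.0), meta)
        roi = np.zeros(meta.shape, bool)
        roi[2:5, 2:5, 2:5] = True
        st = roi_statistics(tsc, roi)
        assert st.mean_tsc == 45.0
        assert st.sd_tsc == 0.0

    def test_two_voxel_hand_calculation(self):
        meta = GridMeta(shape=(4, 4, 4), spacing=(2.0,) * 3)
        data = np.zeros(meta.shape)
        data[0, 0, 0], data[1, 0, 0] = 40.0, 50.0
        roi = np.zeros(meta.shape, bool)
        roi[0, 0, 0] = roi[1, 0, 0] = True
        st = roi_statistics(ScalarVolume(data, meta), roi)
        assert st.mean_tsc == pytest.approx(45.0)
        assert st.sd_tsc == pytest.approx(np.sqrt(50.0))  # ≈ 7.071

    def test_empty_roi_flagged_missing(self):
        meta = GridMeta(shape=(4, 4, 4), spacing=(2.0,) * 3)
        st = roi_statistics(
            ScalarVolume(np.ones(meta.shape), meta), np.zeros(meta.shape, bool)
        )
        assert st.missing
        assert np.isnan(st.mean_tsc)

    def test_cylinder_mask_geometry(self):
        meta = GridMeta(shape=(32, 32, 32), spacing=(1.0,) * 3)
        c = tuple(np.array(meta.fov_mm) / 2)
        m = cylinder_mask(meta, c, radius_mm=5.0, height_mm=10.0)
        vol = m.sum() * meta.voxel_volume_mm3
        analytic = np.pi * 25.0 * 10.0
        assert abs(vol - analytic) / analytic < 0.10
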