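"""Marker detection, Procrustes referencing and distortion reports."""

import numpy as np
import pytest

from dwiqa.distortion import (
    DistortionReport,
    RegistrationError,
    detect_markers,
    grid_manufacturing_qc,
    make_cross_template,
    marker_distortion,
    rigid_procrustes,
    scenario_summary,
)
from dwiqa.markers import MarkerSet
from dwiqa.synthetic import beam_union_image, centered_affine, make_grid_phantom


def _rot_z(deg):
    th = np.deg2rad(deg)
    return np.array([
        [np.cos(th), -np.sin(th), 0.0],
        [np.sin(th), np.cos(th), 0.0],
        [0.0, 0.0, 1.0],
    ])


@pytest.fixture(scope="module")
def grid():
    return make_grid_phantom(voxel_size=(1.5, 1.5, 1.5))


@pytest.fixture(scope="module")
def template(grid):
    return make_cross_template(grid.beam_thickness_mm, (1.5, 1.5, 1.5))


@pytest.fixture(scope="module")
def detected_clean(grid, template):
    return detect_markers(grid.image, grid.affine, template,
                          approx=grid.markers, search_radius_mm=12.5)


class TestCrossTemplate:
    def test_symmetric_under_axis_permutation_for_isotropic_voxels(self):
        t = make_cross_template(6.0, (1.5, 1.5, 1.5))
        np.testing.assert_allclose(t, np.transpose(t, (1, 2, 0)))
        np.testing.assert_allclose(t, np.transpose(t, (2, 0, 1)))

    def test_center_voxel_is_foreground(self):
        t = make_cross_template(6.0, (1.5, 1.5, 1.5))
        c = tuple(s // 2 for s in t.shape)
        assert t[c] == pytest.approx(1.0)

    def test_template_volume_matches_inclusion_exclusion(self):
        # union of three orthogonal boxes: 3*L*t^2 - 2*t^3
        thickness, arm = 6.0, 15.0
        voxel = (0.5, 0.5, 0.5)
        t = make_cross_template(thickness, voxel, arm_length_mm=arm)
        volume = t.sum() * np.prod(voxel)
        analytic = 3 * arm * thickness**2 - 2 * thickness**3
        assert volume == pytest.approx(analytic, rel=0.02)

    def test_arm_shorter_than_beam_raises(self):
        with pytest.raises(ValueError):
            make_cross_template(6.0, (1.0, 1.0, 1.0), arm_length_mm=5.0)


class TestDetectMarkers:
    def test_clean_grid_all_markers_found_subvoxel(self, grid, detected_clean):
        assert detected_clean.found.all()
        err = np.linalg.norm(detected_clean.pos_mm - grid.markers.pos_mm, axis=1)
        assert err.max() < 0.5 * 1.5  # half a voxel

    def test_integer_voxel_shift_equivariance(self, grid, template):
        shift_vox = 2
        shifted = np.zeros_like(grid.image)
        shifted[:, shift_vox:, :] = grid.image[:, :-shift_vox, :]
        approx = MarkerSet(
            ids=grid.markers.ids,
            grid_index=grid.markers.grid_index,
            pos_mm=grid.markers.pos_mm + np.array([0.0, shift_vox * 1.5, 0.0]),
        )
        det = detect_markers(shifted, grid.affine, template, approx=approx,
                             search_radius_mm=12.5)
        base = detect_markers(grid.image, grid.affine, template,
                              approx=grid.markers, search_radius_mm=12.5)
        # markers whose shifted search window leaves the volume are excluded
        ok = det.found & base.found & (grid.markers.grid_index[:, 1] <= 3)
        np.testing.assert_allclose(
            det.pos_mm[ok] - base.pos_mm[ok],
            np.broadcast_to([0.0, 3.0, 0.0], (ok.sum(), 3)), atol=1e-9)

    def test_pure_noise_reports_all_markers_missing(self, grid, template):
        rng = np.random.default_rng(8)
        noise = rng.normal(size=grid.image.shape)
        det = detect_markers(noise, grid.affine, template, approx=grid.markers,
                             search_radius_mm=12.5, min_score=0.5)
        assert not det.found.any()

    def test_zero_variance_neighborhood_reported_missing(self, grid, template):
        flat = np.zeros_like(grid.image)
        det = detect_markers(flat, grid.affine, template, approx=grid.markers)
        assert not det.found.any()


class TestRigidProcrustes:
    def test_identity_on_equal_sets(self, rng):
        pts = rng.normal(size=(27, 3)) * 20
        xf = rigid_procrustes(pts, pts)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(xf.translation, 0.0, atol=1e-12)

    def test_pure_translation_recovered(self, rng):
        pts = rng.normal(size=(10, 3)) * 10
        xf = rigid_procrustes(pts + np.array([5.0, 0.0, 0.0]), pts)
        np.testing.assert_allclose(xf.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(xf.translation, [-5.0, 0.0, 0.0], atol=1e-10)

    def test_known_rotation_inverted(self, rng):
        pts = rng.normal(size=(27, 3)) * 20
        rz = _rot_z(10.0)
        xf = rigid_procrustes(pts @ rz.T, pts)
        np.testing.assert_allclose(xf.rotation, _rot_z(-10.0), atol=1e-6)
        np.testing.assert_allclose(xf.apply(pts @ rz.T), pts, atol=1e-9)

    def test_collinear_points_raise(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(RegistrationError):
            rigid_procrustes(pts, pts + 1.0)

    def test_fewer_than_three_pairs_raise(self):
        with pytest.raises(RegistrationError):
            rigid_procrustes(np.zeros((2, 3)), np.zeros((2, 3)))


class TestMarkerDistortion:
    def test_identity_detection_gives_zero_distortion(self, grid):
        report = marker_distortion(grid.markers, grid.markers)
        assert report.mean_mm == pytest.approx(0.0, abs=1e-12)
        assert report.max_mm == pytest.approx(0.0, abs=1e-12)

    def test_single_peripheral_displacement(self, grid):
        moved = grid.markers.select(np.ones(len(grid.markers), dtype=bool))
        corner = np.argwhere((moved.grid_index == [0, 0, 0]).all(axis=1))[0, 0]
        moved.pos_mm = moved.pos_mm.copy()
        moved.pos_mm[corner, 0] += 2.0
        report = marker_distortion(moved, grid.markers)
        assert report.max_mm == pytest.approx(2.0, abs=1e-9)
        assert report.mean_mm == pytest.approx(2.0 / len(grid.markers), abs=1e-9)

    def test_global_rigid_motion_removed(self, grid, rng):
        rz = _rot_z(4.0)
        moved = MarkerSet(
            ids=grid.markers.ids,
            grid_index=grid.markers.grid_index,
            pos_mm=grid.markers.pos_mm @ rz.T + np.array([3.0, -2.0, 1.0]),
        )
        report = marker_distortion(moved, grid.markers)
        assert report.max_mm < 1e-6

    def test_report_invariant_under_rigid_motion_of_detections(self, grid,
                                                               detected_clean):
        base = marker_distortion(detected_clean, grid.markers)
        rz = _rot_z(7.0)
        moved = MarkerSet(
            ids=detected_clean.ids,
            grid_index=detected_clean.grid_index,
            pos_mm=detected_clean.pos_mm @ rz.T + np.array([10.0, 5.0, -4.0]),
            score=detected_clean.score,
        )
        again = marker_distortion(moved, grid.markers)
        assert again.mean_mm == pytest.approx(base.mean_mm, abs=1e-6)
        assert again.max_mm == pytest.approx(base.max_mm, abs=1e-6)

    def test_mean_never_exceeds_max(self, grid, detected_clean):
        report = marker_distortion(detected_clean, grid.markers)
        assert report.mean_mm <= report.max_mm

    def test_too_few_central_markers_raise(self, grid):
        missing = grid.markers.select(np.ones(len(grid.markers), dtype=bool))
        missing.pos_mm = missing.pos_mm.copy()
        central = grid.markers.central_block(3)
        missing.pos_mm[central] = np.nan
        with pytest.raises(RegistrationError):
            marker_distortion(missing, grid.markers)


class TestScenarioSummary:
    def test_single_report_is_identity(self):
        r = DistortionReport.from_distances([0.5, 1.5], 2, 2)
        assert scenario_summary([r]) == (pytest.approx(1.0), pytest.approx(1.5))

    def test_means_of_means_and_maxima(self):
        rs = [DistortionReport.from_distances([m], 1, 1) for m in (1.0, 2.0, 3.0)]
        mean_mm, max_mm = scenario_summary(rs)
        assert mean_mm == pytest.approx(2.0)
        assert max_mm == pytest.approx(2.0)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            scenario_summary([])


class TestManufacturingQC:
    def test_undeformed_ct_resolution_grid_below_tenth_mm(self):
        ph = make_grid_phantom(fov_mm=(50.0, 50.0, 50.0),
                               voxel_size=(0.78, 0.78, 0.6))
        report = grid_manufacturing_qc(ph.image, ph.affine, ph.markers)
        assert report.n_detected == len(ph.markers)
        assert report.mean_mm < 0.1

    def test_known_beam_jitter_recovered(self):
        # jitter every lattice plane: marker m moves by (jx_i, jy_j, jz_k)
        rng = np.random.default_rng(21)
        spacing, thickness, fov = 25.0, 6.0, 50.0
        voxel = np.array([0.78, 0.78, 0.6])
        n_lines = 3
        base = (np.arange(n_lines) - 1.0) * spacing
        jitter = rng.normal(0.0, 0.3 / 1.5958, size=(3, n_lines))
        lines = [base + jitter[ax] for ax in range(3)]
        shape = tuple(int(np.ceil((fov + 20.0) / v)) for v in voxel)
        affine = centered_affine(shape, voxel)
        xs = [affine[a, a] * np.arange(shape[a]) + affine[a, 3] for a in range(3)]
        image = beam_union_image(xs, voxel, lines, thickness,
                                 np.full(3, fov + 15.0))
        idx = np.stack(np.meshgrid(*[np.arange(n_lines)] * 3,
                                   indexing="ij"), -1).reshape(-1, 3)
        ref = MarkerSet(ids=np.arange(len(idx)), grid_index=idx,
                        pos_mm=base[idx])
        true_pos = np.stack([lines[a][idx[:, a]] for a in range(3)], axis=1)
        true_mean = np.linalg.norm(true_pos - ref.pos_mm, axis=1).mean()
        report = grid_manufacturing_qc(image, affine, ref)
        assert report.mean_mm == pytest.approx(true_mean, rel=0.3)
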