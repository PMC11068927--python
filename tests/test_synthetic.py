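"""Generators: phantoms, signal model, Rician noise, EPI warp."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dwiqa.protocol import AcquisitionProtocol, mr_linac_protocol
from dwiqa.synthetic import (
    GeometryError,
    Scene,
    TissueParams,
    WarpError,
    add_rician_noise,
    apply_epi_warp,
    centered_affine,
    make_brain_scene,
    make_grid_phantom,
    make_susceptibility_field,
    make_vial_phantom,
    simulate_signal,
    vial_voi_masks,
)


class TestVialPhantom:
    def test_default_vials_carry_calibrated_diffusivities(self):
        scene = make_vial_phantom()
        assert sorted(set(np.unique(scene.label_map)) - {0}) == [1, 2, 3, 4]
        assert [scene.tissue_params[i].d for i in (1, 2, 3, 4)] == [
            400.0, 1000.0, 1600.0, 2020.0]

    def test_zero_diffusivity_vial_has_constant_signal(self):
        scene = make_vial_phantom(vial_adcs=[0.0])
        mask = scene.label_map == 1
        s0 = simulate_signal(scene, 0.0)
        s800 = simulate_signal(scene, 800.0)
        np.testing.assert_allclose(s800[mask], s0[mask])

    def test_cylinder_voxel_count_matches_analytic_volume(self):
        # fine rasterization: count within 5% of pi r^2 h / voxel volume
        scene = make_vial_phantom(
            grid_shape=(40, 40, 64), voxel_size=(1.0, 1.0, 1.0),
            vial_adcs=[1000.0], vial_radius_mm=9.0, vial_height_mm=54.0,
        )
        count = int((scene.label_map == 1).sum())
        analytic = np.pi * 9.0**2 * 54.0
        assert abs(count - analytic) / analytic < 0.05

    def test_overlapping_or_outsized_vials_raise(self):
        with pytest.raises(GeometryError):
            make_vial_phantom(grid_shape=(10, 10, 12), vial_radius_mm=20.0)

    def test_default_voi_is_inside_its_vial(self):
        scene = make_vial_phantom()
        for lab, voi in vial_voi_masks(scene).items():
            assert voi.sum() > 0
            assert np.all(scene.label_map[voi] == lab)


class TestGridPhantom:
    def test_ct_resolution_defaults_give_five_lines_and_exact_lattice(self):
        ph = make_grid_phantom(voxel_size=(0.78, 0.78, 0.6))
        assert len(ph.markers) == 5**3
        for ax in range(3):
            assert len(np.unique(ph.markers.grid_index[:, ax])) == 5
        # world coordinates are exact multiples of the 25 mm spacing
        np.testing.assert_allclose(ph.markers.pos_mm % 25.0, 0.0, atol=1e-12)

    def test_nearest_neighbor_marker_distance_equals_spacing(self):
        ph = make_grid_phantom(voxel_size=(1.5, 1.5, 1.5))
        p = ph.markers.pos_mm
        d = np.linalg.norm(p[None] - p[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(25.0)

    def test_central_block_selects_27_of_125(self):
        ph = make_grid_phantom(voxel_size=(1.5, 1.5, 1.5))
        sel = ph.markers.central_block(3)
        assert sel.sum() == 27
        central = ph.markers.select(sel)
        assert np.abs(central.pos_mm).max() <= 25.0

    def test_markers_sorted_lexicographically_by_grid_index(self):
        ph = make_grid_phantom(voxel_size=(1.5, 1.5, 1.5))
        gi = ph.markers.grid_index
        keys = [tuple(row) for row in gi]
        assert keys == sorted(keys)

    def test_voxel_coarser_than_beam_raises(self):
        with pytest.raises(GeometryError):
            make_grid_phantom(beam_thickness_mm=6.0, voxel_size=(7.0, 7.0, 7.0))

    def test_spacing_must_exceed_thickness(self):
        with pytest.raises(GeometryError):
            make_grid_phantom(spacing_mm=5.0, beam_thickness_mm=6.0)


class TestBrainScene:
    def test_three_mutually_exclusive_tissue_labels(self):
        scene = make_brain_scene()
        labels = set(np.unique(scene.label_map)) - {0}
        assert labels == {1, 2, 3}

    def test_true_diffusivity_map_matches_inputs_per_label(self):
        scene = make_brain_scene()
        dmap = scene.param_map("d")
        for name, lab in scene.meta["labels"].items():
            expected = scene.tissue_params[lab].d
            assert dmap[scene.label_map == lab].mean() == pytest.approx(expected)

    def test_biexponential_csf_exceeds_monoexp_extrapolation(self):
        params = {"csf": TissueParams(s0=1000.0, d=3000.0, f=0.3, d_star=10000.0)}
        scene = make_brain_scene(tissue_params=params)
        mask = scene.label_map == scene.meta["labels"]["csf"]
        bs = np.array([200.0, 400.0, 600.0, 800.0])
        logs = [np.log(simulate_signal(scene, b)[mask].mean()) for b in bs]
        slope, intercept = np.polyfit(bs, logs, 1)
        s0_extrapolated = np.exp(intercept)
        s0_true = simulate_signal(scene, 0.0)[mask].mean()
        assert s0_true > s0_extrapolated

    def test_too_small_grid_raises(self):
        with pytest.raises(GeometryError):
            make_brain_scene(grid_shape=(4, 4, 2))


class TestSignalModel:
    def test_monoexponential_closed_form(self):
        scene = make_vial_phantom(vial_adcs=[1000.0])
        s = simulate_signal(scene, 800.0)
        assert s[scene.label_map == 1].max() == pytest.approx(
            1000.0 * np.exp(-0.8), rel=1e-12)
        assert float(s[scene.label_map == 1][0]) == pytest.approx(449.33, abs=0.005)

    def test_b_zero_returns_s0(self):
        scene = make_brain_scene()
        np.testing.assert_allclose(simulate_signal(scene, 0.0),
                                   scene.param_map("s0"))

    def test_biexponential_closed_form(self):
        lm = np.ones((2, 2, 2), dtype=int)
        scene = Scene(
            label_map=lm,
            tissue_params={1: TissueParams(s0=1000.0, d=1000.0, f=0.2,
                                           d_star=10000.0)},
            affine=centered_affine((2, 2, 2), (1, 1, 1)),
        )
        expected = 1000.0 * (0.2 * np.exp(-8.0) + 0.8 * np.exp(-0.8))
        assert simulate_signal(scene, 800.0)[0, 0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(359.53, abs=0.005)

    @settings(derandomize=True, max_examples=30)
    @given(
        d=st.floats(0.0, 4000.0),
        f=st.floats(0.0, 0.9),
        extra=st.floats(0.0, 20000.0),
    )
    def test_signal_monotone_nonincreasing_in_b(self, d, f, extra):
        lm = np.ones((1, 1, 1), dtype=int)
        scene = Scene(
            label_map=lm,
            tissue_params={1: TissueParams(s0=500.0, d=d, f=f, d_star=d + extra)},
            affine=np.eye(4),
        )
        bs = np.linspace(0, 1000, 11)
        sig = np.array([simulate_signal(scene, b)[0, 0, 0] for b in bs])
        assert np.all(np.diff(sig) <= 1e-12)

    def test_invalid_tissue_params_rejected(self):
        with pytest.raises(ValueError):
            TissueParams(s0=1.0, d=-5.0)
        with pytest.raises(ValueError):
            TissueParams(s0=1.0, d=1000.0, f=1.0)
        with pytest.raises(ValueError):
            TissueParams(s0=1.0, d=1000.0, f=0.2, d_star=500.0)


class TestRicianNoise:
    def test_zero_sigma_is_identity(self, rng):
        v = rng.random((5, 5, 5))
        np.testing.assert_array_equal(add_rician_noise(v, 0.0, rng), v)

    def test_background_matches_rayleigh_moments(self):
        out = add_rician_noise(np.zeros(10**6), 10.0, 99)
        assert out.mean() == pytest.approx(10.0 * np.sqrt(np.pi / 2), rel=0.01)
        assert (out**2).mean() == pytest.approx(200.0, rel=0.01)

    def test_negative_sigma_raises(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.zeros(3), -1.0, 0)

    def test_fixed_seed_reproducible(self):
        v = np.full((4, 4, 4), 7.0)
        np.testing.assert_array_equal(
            add_rician_noise(v, 3.0, 42), add_rician_noise(v, 3.0, 42))


class TestEPIWarp:
    def test_zero_field_is_identity(self, box_object, small_protocol):
        field = np.zeros_like(box_object)
        out = apply_epi_warp(box_object, field, small_protocol)
        np.testing.assert_allclose(out, box_object, atol=1e-12)

    def test_uniform_field_is_rigid_one_pixel_shift(self, box_object, small_protocol):
        field = np.full_like(box_object, small_protocol.bw_pe_px)  # 1 px
        out = apply_epi_warp(box_object, field, small_protocol, pe_sign=1)
        expected = np.zeros_like(box_object)
        expected[:, 1:, :] = box_object[:, :-1, :]
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_smooth_field_conserves_pe_line_integrals(self, box_object,
                                                      small_protocol):
        fm = make_susceptibility_field(
            box_object.shape, small_protocol.voxel_size,
            amplitude_hz=1.5 * small_protocol.bw_pe_px,
            smooth_scale_mm=14.0, seed=5)
        out = apply_epi_warp(box_object, fm.values, small_protocol)
        sums_in = box_object.sum(axis=1)
        sums_out = out.sum(axis=1)
        assert np.abs(sums_out - sums_in).max() <= 0.005 * sums_in.max()

    def test_opposite_pe_equals_negated_field(self, box_object, small_protocol):
        fm = make_susceptibility_field(
            box_object.shape, small_protocol.voxel_size, amplitude_hz=150.0,
            smooth_scale_mm=10.0, seed=11)
        a = apply_epi_warp(box_object, -fm.values, small_protocol, pe_sign=1)
        b = apply_epi_warp(box_object, fm.values, small_protocol, pe_sign=-1)
        assert np.abs(a - b).max() <= 1e-6 * box_object.max()

    def test_displacement_beyond_extent_raises(self, box_object, small_protocol):
        field = np.full_like(box_object, 100 * small_protocol.bw_pe_px)
        with pytest.raises(WarpError):
            apply_epi_warp(box_object, field, small_protocol)


class TestSusceptibilityField:
    def test_zero_amplitude_gives_zero_field(self):
        fm = make_susceptibility_field((8, 8, 8), (2, 2, 2), amplitude_hz=0.0,
                                       seed=0)
        np.testing.assert_array_equal(fm.values, 0.0)

    def test_magnitude_bounded_by_amplitudes(self):
        blob = {"center_mm": (0, 0, 0), "sigma_mm": 5.0, "amplitude_hz": 40.0}
        fm = make_susceptibility_field((16, 16, 16), (2, 2, 2),
                                       amplitude_hz=30.0, blob=blob, seed=2)
        assert np.abs(fm.values).max() <= 70.0 + 1e-9

    def test_fixed_seed_bit_identical(self):
        a = make_susceptibility_field((12, 12, 12), (2, 2, 2), 25.0, seed=7)
        b = make_susceptibility_field((12, 12, 12), (2, 2, 2), 25.0, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
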