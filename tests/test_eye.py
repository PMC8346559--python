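"""Eye assembly: lens/retina estimation formulas, focusing rules, serialization."""

import numpy as np
import pytest

import ocusim as oc
from ocusim.eye import (
    AQUEOUS,
    CORNEA,
    LENS,
    VITREOUS,
    EyeModel,
    LensModel,
    SingularConfigurationError,
    SpectacleStateError,
    gaussian_thick_lens_power,
    mean_biometry,
)
from ocusim.raytrace import on_axis_rms_spot, paraxial_solve


class TestBennettLensPower:
    def test_vanishing_first_term(self):
        # S + P_C = 0 leaves only the vitreous term: 1337 / 19.02266
        assert oc.bennett_lens_power(-43.0, 43.0, 3.39, 3.79, 17.59) == pytest.approx(
            70.285, abs=1e-3)

    def test_hand_computed_value(self):
        assert oc.bennett_lens_power(-4.56, 42.44, 3.39, 3.79, 17.59) == pytest.approx(
            25.33, abs=0.01)

    def test_record_and_scalar_forms_agree(self):
        rec = mean_biometry("pre")
        assert oc.bennett_lens_power(rec) == pytest.approx(
            oc.bennett_lens_power(rec.S, rec.P_C, rec.T_AC, rec.T_L, rec.T_V))

    def test_monotone_in_vitreous_length(self):
        p1 = oc.bennett_lens_power(-43.0, 43.0, 3.39, 3.79, 17.59)
        p2 = oc.bennett_lens_power(-43.0, 43.0, 3.39, 3.79, 20.0)
        assert p2 < p1

    def test_singular_configuration(self):
        with pytest.raises(SingularConfigurationError):
            oc.bennett_lens_power(0.0, 0.0, 3.39, 3.79, -1.43262)


class TestRozemaAtchison:
    def test_rozema_intercepts(self):
        assert oc.rozema_radii(1e-12, 0.0) == pytest.approx((26.02, -16.675), abs=1e-6)

    def test_rozema_table_row(self):
        # mean lens thickness and the power implied by the printed anterior radius
        r_la, r_lp = oc.rozema_radii(3.79, 24.785)
        assert r_la == pytest.approx(10.83, abs=0.005)
        assert r_lp == pytest.approx(-7.12, abs=0.01)

    def test_rozema_hand_value(self):
        assert oc.rozema_radii(4.0, 20.0) == pytest.approx((11.22, -7.371), abs=1e-3)

    def test_atchison_intercepts(self):
        assert oc.atchison_retina(0.0) == (-12.815, 0.26)

    def test_atchison_table_row(self):
        r, q = oc.atchison_retina(-4.556)
        assert r == pytest.approx(-12.61, abs=0.005)
        assert q == pytest.approx(0.16, abs=0.005)

    def test_atchison_high_myopia(self):
        assert oc.atchison_retina(-10.0) == pytest.approx((-12.365, 0.04))


class TestRozemaGaussianConsistency:
    def test_homogeneous_lens_power_underestimates_equivalent_power(self):
        """The regression radii describe real (gradient-index) lenses; with a
        homogeneous n=1.42 lens their Gaussian power sits a few diopters
        below the Bennett equivalent power, systematically and monotonically."""
        for t_l in (3.4, 3.79, 4.2):
            prev = -np.inf
            for p_l in (20.0, 24.0, 28.0):
                r_la, r_lp = oc.rozema_radii(t_l, p_l)
                pg = gaussian_thick_lens_power(AQUEOUS.n_d, LENS.n_d, VITREOUS.n_d,
                                               r_la, r_lp, t_l)
                assert 0.0 < p_l - pg < 11.0
                assert pg > prev  # monotone in the target power
                prev = pg
        # at the cohort-mean lens the shortfall is around five diopters
        r_la, r_lp = oc.rozema_radii(3.79, 25.33)
        pg = gaussian_thick_lens_power(AQUEOUS.n_d, LENS.n_d, VITREOUS.n_d,
                                       r_la, r_lp, 3.79)
        assert 25.33 - pg == pytest.approx(5.9, abs=1.0)


class TestBuildEye:
    def test_surface_stack_positions(self):
        rec = mean_biometry("pre")
        eye = oc.build_eye(rec, stop_diameter=4.0, focus=False)
        names = [s.name for s in eye.refracting_surfaces()]
        assert names == ["cornea_anterior", "cornea_posterior", "lens_anterior",
                         "lens_posterior"]
        z = [s.surface.vertex_z for s in eye.refracting_surfaces()]
        assert z == pytest.approx([0.0, 0.54, 3.93, 7.72])
        assert eye.stop.z == pytest.approx(3.93)
        assert eye.retina.surface.vertex_z == pytest.approx(25.31)
        assert z == sorted(z)  # strictly ordered along the axis
        assert eye.retina_shift == 0.0

    def test_pre_epoch_attaches_spectacle_post_does_not(self):
        pre = oc.build_eye(mean_biometry("pre"), stop_diameter=2.0, focus=True)
        post = oc.build_eye(mean_biometry("post"), stop_diameter=2.0, focus=True)
        assert pre.spectacle is not None and pre.spectacle.z == -12.0
        assert pre.retina_shift == 0.0
        assert post.spectacle is None
        assert post.retina_shift != 0.0

    def test_lens_radii_sign_invariant(self):
        lens = LensModel.from_biometry(mean_biometry("pre"))
        assert lens.R_anterior > 0 > lens.R_posterior
        assert lens.Q_anterior == -3.13 and lens.Q_posterior == -1.0

    def test_build_is_deterministic_bit_for_bit(self):
        a = oc.build_eye(mean_biometry("post"), stop_diameter=4.0, focus=True)
        b = oc.build_eye(mean_biometry("post"), stop_diameter=4.0, focus=True)
        assert a.to_json() == b.to_json()

    def test_json_round_trip(self, mean_pre_eye_2mm):
        text = mean_pre_eye_2mm.to_json()
        eye2 = EyeModel.from_json(text)
        assert eye2.to_json() == text

    def test_paraxial_power_in_physiological_band(self):
        eye = oc.build_eye(mean_biometry("pre"), stop_diameter=2.0, focus=False)
        sol = paraxial_solve(eye)
        assert 58.6 * 0.95 < sol.power < 64.0 * 1.05

    def test_stop_diameter_change(self, mean_pre_eye_2mm):
        eye6 = oc.with_stop_diameter(mean_pre_eye_2mm, 6.0)
        assert eye6.stop.diameter == 6.0
        assert mean_pre_eye_2mm.stop.diameter == 2.0


class TestSpectacle:
    def test_double_spectacle_raises(self, mean_pre_eye_2mm):
        with pytest.raises(SpectacleStateError):
            oc.correct_with_spectacle(mean_pre_eye_2mm, -4.556)

    def test_explicit_power_is_attached_verbatim(self):
        eye = oc.build_eye(mean_biometry("pre"), stop_diameter=2.0, focus=False)
        corrected = oc.correct_with_spectacle(eye, -5.0, optimize=False)
        assert corrected.spectacle.power == 5.0

    def test_optimized_power_beats_prescription_and_nothing(self):
        """The optimized ideal spectacle reaches a sharper on-axis focus than
        either the bare eye or the plain -S prescription lens."""
        rec = mean_biometry("pre")
        bare = oc.build_eye(rec, stop_diameter=2.0, focus=False)
        rx = oc.correct_with_spectacle(bare, rec.S, optimize=False)
        opt = oc.correct_with_spectacle(bare, rec.S)
        rms_opt = on_axis_rms_spot(opt)
        assert rms_opt < on_axis_rms_spot(bare)
        assert rms_opt < on_axis_rms_spot(rx)
        assert rms_opt < 2e-3  # mm: sub-2-um green spot at a 2-mm pupil

    def test_zero_power_spectacle_is_inert(self):
        rec = mean_biometry("pre")
        bare = oc.build_eye(rec, stop_diameter=2.0, focus=False)
        with_flat = oc.correct_with_spectacle(bare, 0.0, power=0.0)
        assert on_axis_rms_spot(with_flat) == pytest.approx(
            on_axis_rms_spot(bare), abs=1e-12)


class TestRetinaShiftFocus:
    def test_idempotence(self, mean_post_eye_2mm):
        from dataclasses import replace

        again = oc.focus_by_retina_shift(
            replace(mean_post_eye_2mm, retina_shift=mean_post_eye_2mm.retina_shift))
        assert abs(again.retina_shift - mean_post_eye_2mm.retina_shift) < 1e-3

    def test_translation_with_retina_position(self):
        """Displacing the unshifted retina vertex by +0.1 mm changes the
        solved shift by -0.1 mm (the optics in front are unchanged)."""
        from dataclasses import replace

        base = oc.build_eye(mean_biometry("post"), stop_diameter=2.0, focus=True)
        retina = base.retina
        moved_surface = replace(retina.surface, vertex_z=retina.surface.vertex_z + 0.1)
        moved = replace(base, elements=base.elements[:-1]
                        + [replace(retina, surface=moved_surface)], retina_shift=0.0)
        refocused = oc.focus_by_retina_shift(moved)
        assert refocused.retina_shift == pytest.approx(base.retina_shift - 0.1,
                                                       abs=1e-3)

    def test_deterministic_solver(self):
        a = oc.build_eye(mean_biometry("post"), stop_diameter=4.0, focus=True)
        b = oc.build_eye(mean_biometry("post"), stop_diameter=4.0, focus=True)
        assert a.retina_shift == b.retina_shift


class TestMaterials:
    def test_printed_indices(self):
        assert (CORNEA.n_d, CORNEA.abbe) == (1.377, 56.28)
        assert (AQUEOUS.n_d, AQUEOUS.abbe) == (1.337, 52.659)
        assert (LENS.n_d, LENS.abbe) == (1.42, 51.226)
        assert (VITREOUS.n_d, VITREOUS.abbe) == (1.336, 53.342)

    def test_biometry_validation(self):
        rec = mean_biometry("pre")
        assert rec.violations() == []
        rec.CCT = -0.1
        msgs = " ".join(rec.violations())
        assert "CCT" in msgs

    def test_corneal_power_matches_printed_means(self):
        assert oc.gaussian_corneal_power(8.56, 6.38, 0.45) == pytest.approx(
            37.84, abs=0.1)
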