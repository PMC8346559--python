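"""Optical metrics: spot RMS, chromatic aberrations, FFT PSF/Strehl, MTF."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ocusim as oc
from ocusim.eye import AIR, EyeModel, ImageSurface, Material, RefractingSurface, Stop
from ocusim.metrics import (
    GeometryError,
    NoRaysError,
    OpdMap,
    geometric_mtf_from_maps,
    longitudinal_chromatic_shift,
    mtf_curve,
    opd_from_trace,
    opd_maps,
    psf_strehl,
    spot_rms,
    transverse_chromatic,
    evaluate_eye,
)
from ocusim.raytrace import FieldSpec, TraceBundle, WavelengthTrace
from ocusim.surfaces import _BASIS, ConicZernikeSurface


def _bundle_from_points(points_by_wl):
    traces = {}
    for wl, pts in points_by_wl.items():
        pts = np.asarray(pts, dtype=float)
        traces[wl] = WavelengthTrace(
            wavelength=wl, points=pts, status=np.zeros(len(pts), dtype=int),
            opl=np.zeros(len(pts)), chief_point=pts[0].copy(),
            pupil_xy=np.zeros_like(pts))
    return TraceBundle(field=FieldSpec(0.0), traces=traces)


def _synthetic_map(opd, mask, wavelength=587.562, na=0.1):
    opd = np.where(mask, opd - opd[mask].mean(), 0.0)
    return OpdMap(opd=opd, mask=mask, wavelength=wavelength, na=na,
                  ref_sphere_radius=20.0, chief_point=np.zeros(2))


def _disk(n):
    c = (np.arange(n) + 0.5) / n * 2 - 1
    xx, yy = np.meshgrid(c, c)
    return xx, yy, xx**2 + yy**2 <= 1.0


class TestSpotRms:
    def test_coincident_points_give_zero(self):
        b = _bundle_from_points({587.562: [[0.1, -0.2]] * 5})
        assert spot_rms(b) == 0.0

    def test_four_point_cross(self):
        a = 0.05  # mm
        b = _bundle_from_points({587.562: [[a, 0], [-a, 0], [0, a], [0, -a]]})
        assert spot_rms(b) == pytest.approx(a * 1e3)

    def test_pooling_equals_concatenation(self):
        p1 = [[0.01, 0.0], [-0.01, 0.0]]
        p2 = [[0.0, 0.02], [0.0, -0.02]]
        pooled = _bundle_from_points({500.0: p1, 600.0: p2})
        merged = _bundle_from_points({550.0: p1 + p2})
        assert spot_rms(pooled) == pytest.approx(spot_rms(merged))

    @given(dx=st.floats(-0.5, 0.5), dy=st.floats(-0.5, 0.5))
    def test_translation_invariance(self, dx, dy):
        pts = np.array([[0.01, 0.0], [-0.02, 0.01], [0.0, -0.015]])
        a = spot_rms(_bundle_from_points({587.562: pts}))
        b = spot_rms(_bundle_from_points({587.562: pts + [dx, dy]}))
        assert b == pytest.approx(a, abs=1e-9)

    def test_empty_bundle_raises(self):
        b = _bundle_from_points({587.562: [[0, 0]]})
        b.traces[587.562].status[:] = 1
        with pytest.raises(NoRaysError):
            spot_rms(b)


class TestOpdMaps:
    def test_corrected_eye_is_nearly_stigmatic_on_axis(self, mean_pre_eye_2mm):
        m = opd_from_trace(mean_pre_eye_2mm, 0.0, 587.562, grid_n=48)
        assert m.rms < 0.05  # waves: all live-ray OPLs agree to ~lambda/20

    def test_known_retina_shift_is_pure_defocus(self, mean_pre_eye_2mm):
        """A small axial image shift produces an OPD fitted by the defocus
        term with residual below lambda/50."""
        from dataclasses import replace

        eye = replace(mean_pre_eye_2mm, retina_shift=0.05)
        m = opd_from_trace(eye, 0.0, 587.562, grid_n=48)
        xx, yy, _ = _disk(48)
        rho = np.hypot(xx, yy)[m.mask]
        phi = np.arctan2(yy, xx)[m.mask]
        A = _BASIS.evaluate(rho, phi).T[:, [0, 4, 12]]  # piston, Z20, Z40
        resid = m.opd[m.mask] - A @ np.linalg.lstsq(A, m.opd[m.mask], rcond=None)[0]
        spherical_only = np.sqrt(np.mean(resid**2))
        A2 = A[:, :2]
        resid2 = m.opd[m.mask] - A2 @ np.linalg.lstsq(A2, m.opd[m.mask], rcond=None)[0]
        defocus_resid = np.sqrt(np.mean(resid2**2))
        assert defocus_resid < 1 / 50  # defocus dominates
        assert spherical_only < 1 / 200  # remainder is the eye's own SA

    def test_grid_doubling_leaves_strehl(self, mean_pre_eye_2mm):
        s = []
        for g in (32, 64):
            maps = opd_maps(mean_pre_eye_2mm, 0.0, oc.RGB_WAVELENGTHS, grid_n=g)
            s.append(psf_strehl(maps).strehl)
        assert abs(s[1] - s[0]) / s[0] < 0.005

    def test_wavelength_seeded_maps_match_independent_maps(self, mean_pre_eye_2mm):
        bulk = opd_maps(mean_pre_eye_2mm, 10.0, oc.RGB_WAVELENGTHS, grid_n=32)
        single = [opd_from_trace(mean_pre_eye_2mm, 10.0, wl, grid_n=32)
                  for wl in oc.RGB_WAVELENGTHS]
        for a, b in zip(bulk, single):
            # aiming stops within 0.1 um of the targets, so independently
            # seeded solutions agree to well below a thousandth of a wave
            assert np.abs(a.opd - b.opd).max() < 1e-3
            assert np.array_equal(a.mask, b.mask)


class TestPsfStrehl:
    def test_zero_opd_strehl_is_one(self):
        _, _, mask = _disk(64)
        res = psf_strehl([_synthetic_map(np.zeros((64, 64)), mask)])
        assert res.strehl == pytest.approx(1.0, abs=1e-6)

    def test_quarter_wave_defocus(self):
        """Quarter-wave peak defocus sits in the Marechal regime: the classic
        ~0.80 Strehl, cross-checked against a direct diffraction sum."""
        xx, yy, mask = _disk(96)
        w = 0.25 * (xx**2 + yy**2)
        res = psf_strehl([_synthetic_map(w, mask)])
        assert res.strehl == pytest.approx(0.80, abs=0.02)
        # independent oracle: on-axis diffraction integral
        direct = abs(np.exp(2j * np.pi * w[mask]).mean()) ** 2
        assert res.strehl == pytest.approx(direct, abs=0.01)

    def test_marechal_small_aberration_limit(self, rng):
        xx, yy, mask = _disk(64)
        shape = np.cos(3 * xx) * yy + 0.5 * xx**2 - yy**3
        shape -= shape[mask].mean()
        for sigma in (0.02, 0.05):
            w = shape / np.sqrt(np.mean(shape[mask] ** 2)) * sigma
            res = psf_strehl([_synthetic_map(w, mask)])
            expected = 1.0 - (2 * np.pi * sigma) ** 2
            assert res.strehl == pytest.approx(expected, rel=0.05)

    def test_polychromatic_weights_validated(self):
        _, _, mask = _disk(32)
        m = _synthetic_map(np.zeros((32, 32)), mask)
        with pytest.raises(ValueError):
            psf_strehl([m, m], weights=[0.9, 0.2])

    def test_mismatched_grids_raise(self):
        _, _, m32 = _disk(32)
        _, _, m64 = _disk(64)
        with pytest.raises(GeometryError):
            psf_strehl([_synthetic_map(np.zeros((32, 32)), m32),
                        _synthetic_map(np.zeros((64, 64)), m64)])

    def test_strehl_bounded(self, mean_post_eye_2mm):
        maps = opd_maps(mean_post_eye_2mm, 10.0, oc.RGB_WAVELENGTHS, grid_n=40)
        res = psf_strehl(maps)
        assert 0.0 < res.strehl <= 1.05


class TestMtf:
    def test_zero_frequency_is_one(self, rng):
        psf = rng.random((64, 64))
        c = mtf_curve(psf, pixel_mm=1e-3)
        assert c.mean[0] == pytest.approx(1.0)
        assert np.all(c.mean <= 1.0 + 1e-9) and np.all(c.mean >= 0.0)

    def test_diffraction_limited_circular_pupil_closed_form(self):
        """|FFT| of the unaberrated PSF matches the analytic incoherent MTF."""
        _, _, mask = _disk(128)
        m = _synthetic_map(np.zeros((128, 128)), mask, na=0.1)
        res = psf_strehl([m], pad=4)
        nu_c = 2 * m.na / (m.wavelength * 1e-6)  # cyc/mm
        c = mtf_curve(res, max_freq=0.9 * nu_c, n_freq=80)
        x = c.freq / nu_c
        closed = 2 / np.pi * (np.arccos(x) - x * np.sqrt(1 - x**2))
        assert np.abs(c.mean - closed).max() < 1e-2

    def test_rotationally_symmetric_psf_tan_equals_sag(self):
        _, _, mask = _disk(64)
        res = psf_strehl([_synthetic_map(np.zeros((64, 64)), mask)])
        c = mtf_curve(res)
        np.testing.assert_allclose(c.tangential, c.sagittal, atol=1e-6)

    def test_geometric_mtf_of_point_spot_is_unity(self):
        _, _, mask = _disk(32)
        m = _synthetic_map(np.zeros((32, 32)), mask)
        m.spot_points = np.zeros((500, 2))
        c = geometric_mtf_from_maps([m])
        np.testing.assert_allclose(c.mean, 1.0, atol=1e-12)


def _single_surface_eye(R=5.55, material=None, image_z=None, pupil=1.2):
    material = material or Material(1.337, 52.659, "medium")
    # paraxial image of an object at infinity: z = n R / (n - 1)
    z_img = image_z if image_z is not None else material.n_d * R / (material.n_d - 1.0)
    surf = ConicZernikeSurface(R=R, Q=0.0, semi_diameter=6.0, vertex_z=0.0)
    img = ConicZernikeSurface(R=1e9, Q=0.0, semi_diameter=20.0, vertex_z=z_img)
    return EyeModel(elements=[
        RefractingSurface(surf, AIR, material, "front"),
        Stop(z=0.4, diameter=pupil),
        ImageSurface(img),
    ], stop_diameter=pupil)


class TestChromatic:
    def test_dispersionless_model_has_zero_shifts(self):
        eye = _single_surface_eye(material=Material(1.337, None, "flat"))
        lca = longitudinal_chromatic_shift(eye)
        assert max(abs(v) for v in lca.values()) < 2e-3  # mm, solver tolerance

    def test_single_surface_matches_paraxial_prediction(self):
        """Best-focus chromatic shifts of one Cauchy surface agree with the
        closed-form paraxial image position n(l) R / (n(l) - 1) within 1%."""
        mat = Material(1.337, 52.659, "medium")
        eye = _single_surface_eye(material=mat)
        lca = longitudinal_chromatic_shift(eye)
        z_green = mat.n_d * 5.55 / (mat.n_d - 1.0)
        span_traced = lca[oc.RGB_WAVELENGTHS[0]] - lca[oc.RGB_WAVELENGTHS[2]]
        n_r = mat.index(oc.RGB_WAVELENGTHS[0])
        n_b = mat.index(oc.RGB_WAVELENGTHS[2])
        span_parax = n_r * 5.55 / (n_r - 1.0) - n_b * 5.55 / (n_b - 1.0)
        assert span_traced == pytest.approx(span_parax, rel=0.01)

    def test_red_and_blue_shifts_straddle_green(self, mean_pre_eye_2mm,
                                                mean_post_eye_2mm):
        for eye in (mean_pre_eye_2mm, mean_post_eye_2mm):
            lca = longitudinal_chromatic_shift(eye)
            assert lca[oc.RGB_WAVELENGTHS[0]] > 0 > lca[oc.RGB_WAVELENGTHS[2]]
            assert lca[oc.RGB_WAVELENGTHS[1]] == 0.0

    def test_tca_vanishes_on_axis(self, mean_pre_eye_2mm):
        assert transverse_chromatic(mean_pre_eye_2mm, 0.0) < 1e-6

    def test_tca_grows_with_field(self, mean_pre_eye_2mm):
        vals = [transverse_chromatic(mean_pre_eye_2mm, f) for f in (0.0, 10.0, 20.0, 30.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestEvaluateEye:
    def test_report_grid_is_complete(self, mean_post_eye_2mm):
        fields, pupils = (0.0, 15.0), (2.0, 3.0)
        rep = evaluate_eye(mean_post_eye_2mm, fields=fields, pupils=pupils,
                           psf_grid=24, spot_rings=3, with_lca=False)
        for metric in ("rms_spot_um", "strehl", "strehl_green", "mtf_mean_30cpm"):
            sub = rep.df[rep.df.metric == metric]
            assert len(sub) == len(fields) * len(pupils)
            assert sub.value.notna().all()

    def test_green_strehl_near_diffraction_limit_on_design_point(self,
                                                                 mean_pre_eye_2mm):
        """The spectacle-corrected mean pre-operative eye is near
        diffraction-limited on axis at a 2-mm pupil."""
        m = opd_from_trace(mean_pre_eye_2mm, 0.0, 587.562, grid_n=64)
        assert psf_strehl([m]).strehl > 0.8

    def test_csv_round_trip(self, mean_post_eye_2mm, tmp_path):
        rep = evaluate_eye(mean_post_eye_2mm, fields=(0.0,), pupils=(2.0,),
                           psf_grid=24, spot_rings=3, with_lca=False)
        p = tmp_path / "report.csv"
        rep.to_csv(p)
        back = oc.QualityReport.from_csv(p)
        assert back.value(0.0, 2.0, "strehl") == pytest.approx(
            rep.value(0.0, 2.0, "strehl"))
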