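"""Image formation, white balance, virtual ColorChecker, gamma transfer."""

import numpy as np
import pytest

from chromodecomp import data as cdata
from chromodecomp.errors import (
    DegenerateProfileError,
    DomainError,
    FitDegenerateError,
    SpaceError,
)
from chromodecomp.imaging import (
    AcquisitionProfile,
    ColorTransform,
    LinearImage,
    apply_color_transform,
    build_virtual_colorchecker_transform,
    camera_response,
    default_profile,
    form_image,
    gamma_decode,
    gamma_encode,
    normalize_profile,
    white_balance,
)
from chromodecomp.maps import ChromophoreMaps
from chromodecomp.optics import default_optics
from chromodecomp.spectral import SpectralCurve, default_grid


class TestNormalizeProfile:
    def test_idempotent(self, profile):
        again = normalize_profile(profile)
        assert np.allclose(again.spd.values, profile.spd.values)

    def test_scale_invariant(self, profile):
        scaled = AcquisitionProfile(
            spd=profile.spd * 10.0,
            sensitivity_r=profile.sensitivity_r,
            sensitivity_g=profile.sensitivity_g,
            sensitivity_b=profile.sensitivity_b,
        )
        assert np.allclose(
            normalize_profile(scaled).spd.values, profile.spd.values
        )

    def test_max_channel_white_response_is_one(self, profile):
        assert np.isclose(profile.white_response.max(), 1.0)

    def test_zero_spd_degenerate(self, profile):
        dead = AcquisitionProfile(
            spd=SpectralCurve.constant(default_grid(), 0.0),
            sensitivity_r=profile.sensitivity_r,
            sensitivity_g=profile.sensitivity_g,
            sensitivity_b=profile.sensitivity_b,
        )
        with pytest.raises(DegenerateProfileError):
            normalize_profile(dead)


class TestCameraResponse:
    def test_black_surface(self, profile):
        r = SpectralCurve.constant(default_grid(), 0.0)
        assert np.allclose(camera_response(r, profile), 0.0)

    def test_perfect_reflector_is_white_point(self, profile):
        r = SpectralCurve.constant(default_grid(), 1.0)
        assert np.allclose(camera_response(r, profile), profile.white_response)

    def test_box_sensitivity_analytic_integral(self):
        grid = np.arange(400.0, 701.0)  # exact 1 nm grid
        box = np.where((grid >= 500) & (grid <= 600), 1.0, 0.0)
        prof = AcquisitionProfile(
            spd=SpectralCurve.constant(grid, 1.0),
            sensitivity_r=SpectralCurve(grid, box),
            sensitivity_g=SpectralCurve(grid, box),
            sensitivity_b=SpectralCurve(grid, box),
            lambda_min_nm=400.0, lambda_max_nm=700.0, step_nm=1.0,
        )
        resp = camera_response(SpectralCurve.constant(grid, 1.0), prof)
        oracle = np.trapezoid(box, grid)  # analytic 100 +- edge trapezoids
        assert np.allclose(resp, oracle, rtol=1e-12)
        assert abs(resp[0] - 100.0) <= 1.0

    def test_linear_in_reflectance(self, profile, rng):
        grid = default_grid()
        r1 = SpectralCurve(grid, rng.uniform(0, 1, grid.size))
        r2 = SpectralCurve(grid, rng.uniform(0, 1, grid.size))
        a, b = 0.3, 1.7
        combo = SpectralCurve(grid, a * r1.values + b * r2.values)
        lhs = camera_response(combo, profile)
        rhs = a * camera_response(r1, profile) + b * camera_response(r2, profile)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_quadrature_refinement_below_half_percent(self, profile, optics):
        from chromodecomp.optics import ChromophoreState, skin_reflectance

        fine_profile = AcquisitionProfile(
            spd=cdata.load_d65(),
            sensitivity_r=cdata.load_curve("profile_default/sensitivity_r.csv"),
            sensitivity_g=cdata.load_curve("profile_default/sensitivity_g.csv"),
            sensitivity_b=cdata.load_curve("profile_default/sensitivity_b.csv"),
            step_nm=2.5,
        )
        state = ChromophoreState(0.15, 0.05)
        r5 = skin_reflectance(state, optics.layers, optics.scattering, default_grid())
        r25 = skin_reflectance(
            state, optics.layers, optics.scattering, default_grid(step=2.5)
        )
        coarse_profile = AcquisitionProfile(
            spd=cdata.load_d65(),
            sensitivity_r=cdata.load_curve("profile_default/sensitivity_r.csv"),
            sensitivity_g=cdata.load_curve("profile_default/sensitivity_g.csv"),
            sensitivity_b=cdata.load_curve("profile_default/sensitivity_b.csv"),
            step_nm=5.0,
        )
        coarse = camera_response(r5, coarse_profile)
        fine = camera_response(r25, fine_profile)
        assert np.all(np.abs(coarse - fine) / fine < 0.005)


class TestWhiteBalance:
    def test_light_source_maps_to_ones(self, profile):
        img = LinearImage(np.tile(profile.white_response, (2, 2, 1)), space="camera")
        out = white_balance(img, profile)
        assert np.allclose(out.pixels, 1.0)
        assert out.space == "camera_wb"

    def test_zero_image_stays_zero(self, profile):
        out = white_balance(LinearImage(np.zeros((2, 2, 3)), space="camera"), profile)
        assert np.all(out.pixels == 0)

    def test_elementwise_scaling(self, profile, rng):
        px = rng.uniform(0, 1, (2, 2, 3))
        out = white_balance(LinearImage(px, space="camera"), profile)
        assert np.allclose(out.pixels, px / profile.white_response)

    def test_wrong_space_rejected(self, profile):
        with pytest.raises(SpaceError):
            white_balance(LinearImage(np.zeros((2, 2, 3)), space="srgb"), profile)


class TestVirtualColorChecker:
    def test_cmf_sensitivities_give_near_zero_residual(self):
        xbar, ybar, zbar = cdata.load_cie_observer()
        prof = normalize_profile(AcquisitionProfile(
            spd=cdata.load_d65(), sensitivity_r=xbar, sensitivity_g=ybar,
            sensitivity_b=zbar,
        ))
        t = build_virtual_colorchecker_transform(prof)
        assert t.residual_rms < 1e-10
        # transform must be diagonal up to white scaling
        off = t.matrix - np.diag(np.diag(t.matrix))
        assert np.abs(off).max() < 1e-8

    def test_neutral_patches_map_grays_to_grays(self, profile):
        grid = default_grid()
        neutrals = [SpectralCurve.constant(grid, v) for v in
                    (0.05, 0.1, 0.2, 0.4, 0.6, 0.9)]
        t = build_virtual_colorchecker_transform(profile, neutrals, degree=1)
        for v in (0.1, 0.5, 0.9):
            rgb = t.camera_to_xyz(np.array([v, v, v])) @ t.xyz_to_rgb.T
            assert np.allclose(rgb, rgb[0], atol=1e-6)

    def test_duplicating_patches_leaves_fit_unchanged(self, profile):
        patches = cdata.load_colorchecker()
        t1 = build_virtual_colorchecker_transform(profile, patches)
        t2 = build_virtual_colorchecker_transform(profile, patches + patches)
        assert np.allclose(t1.matrix, t2.matrix)

    def test_chart_without_signal_rejected(self, profile):
        black = SpectralCurve.constant(default_grid(), 0.0)
        with pytest.raises(FitDegenerateError):
            build_virtual_colorchecker_transform(profile, [black] * 24)

    def test_white_point_lands_on_working_white(self, profile):
        t = build_virtual_colorchecker_transform(profile)
        white = t.camera_to_xyz(np.ones(3)) @ t.xyz_to_rgb.T
        assert np.allclose(white, 1.0, atol=1e-3)


class TestColorTransform:
    def test_identity_matrix_is_noop(self, rng):
        t = ColorTransform(matrix=np.linalg.inv(
            np.array([[3.2406, -1.5372, -0.4986],
                      [-0.9689, 1.8758, 0.0415],
                      [0.0557, -0.2040, 1.0570]])))
        px = rng.uniform(0, 1, (3, 3, 3))
        out = apply_color_transform(LinearImage(px, space="camera_wb"), t)
        assert out.space == "rgb_linear"
        assert np.allclose(out.pixels, px, atol=1e-10)

    def test_round_trip_through_inverse(self, profile, rng):
        t = build_virtual_colorchecker_transform(profile)
        px = rng.uniform(0.1, 0.9, (1, 1, 3))
        out = apply_color_transform(LinearImage(px, space="camera_wb"), t)
        m = t.xyz_to_rgb @ t.matrix
        back = out.pixels @ np.linalg.inv(m).T
        assert np.allclose(back, px, atol=1e-6)

    def test_wrong_space_tag_rejected(self, profile):
        t = build_virtual_colorchecker_transform(profile)
        with pytest.raises(SpaceError):
            apply_color_transform(LinearImage(np.zeros((1, 1, 3)), space="camera"), t)


class TestGamma:
    def test_one_is_fixed_point(self):
        assert gamma_encode(np.array([[[1.0, 1.0, 1.0]]]))[0, 0, 0] == pytest.approx(1.0, abs=1e-15)
        assert gamma_decode(np.array([[[1.0, 1.0, 1.0]]]))[0, 0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("x", [0.1, 0.5, 0.9])
    def test_decode_encode_identity(self, x):
        enc = 1.055 * x ** (1 / 2.4) - 0.055  # pre-clip algebraic form
        dec = ((enc + 0.055) / 1.055) ** 2.4
        assert dec == pytest.approx(x, abs=1e-12)
        arr = np.full((1, 1, 3), x)
        assert np.allclose(gamma_decode(gamma_encode(arr)), x, atol=1e-12)

    def test_decode_zero_scalar_oracle(self):
        expected = (0.055 / 1.055) ** 2.4
        assert gamma_decode(np.zeros((1, 1, 3)))[0, 0, 0] == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            gamma_encode(np.full((1, 1, 3), -0.1))
        with pytest.raises(DomainError):
            gamma_decode(np.full((1, 1, 3), -0.1))

    def test_encode_clips_into_unit_interval(self):
        out = gamma_encode(np.array([[[0.0, 2.0, 0.5]]]))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestFormImage:
    def small_maps(self):
        mel = np.full((4, 4), 0.1)
        mel[2:, :] = 0.3
        hb = np.full((4, 4), 0.03)
        hb[:, 2:] = 0.06
        return ChromophoreMaps(mel, hb, np.full((4, 4), 0.8), np.zeros((4, 4)))

    def test_pure_diffuse_equals_per_pixel_camera_response(self, profile, optics):
        from chromodecomp.optics import ChromophoreState, skin_reflectance

        maps = self.small_maps()
        img = form_image(maps, profile, optics)
        assert img.space == "camera"
        for i, j in [(0, 0), (3, 3), (0, 3)]:
            r = skin_reflectance(
                ChromophoreState(maps.mel_map[i, j], maps.hb_map[i, j]),
                optics.layers, optics.scattering, profile.grid,
            )
            expected = 0.8 * camera_response(r, profile)
            assert np.allclose(img.pixels[i, j], expected, atol=1e-12)

    def test_zero_shading_leaves_pure_specular(self, profile, optics):
        maps = self.small_maps()
        maps.shading_map[:] = 0.0
        maps.specular_map[:] = 0.25
        img = form_image(maps, profile, optics)
        assert np.allclose(img.pixels, 0.25 * profile.white_response)

    def test_full_chain_lands_in_unit_interval(self, profile, optics, rng):
        t = build_virtual_colorchecker_transform(profile)
        maps = ChromophoreMaps(
            rng.uniform(0.013, 0.43, (4, 4)),
            rng.uniform(0.02, 0.07, (4, 4)),
            rng.uniform(0.0, 1.0, (4, 4)),
            rng.uniform(0.0, 0.2, (4, 4)),
        )
        cam = form_image(maps, profile, optics)
        srgb = gamma_encode(
            LinearImage(np.clip(
                apply_color_transform(white_balance(cam, profile), t).pixels, 0, None
            ))
        )
        assert srgb.pixels.min() >= 0.0 and srgb.pixels.max() <= 1.0
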