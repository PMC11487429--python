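import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panelpet import constants as const
from panelpet.imagevol import ImageGrid, ImageVolume
from panelpet.metrics import (
    BACKGROUND_ROI_XY_MM,
    contrast_at_variability,
    fit_gaussian_3d,
    necr,
    necr_tof,
    nema_iq_analysis,
    normalize_by_homogeneous,
    ssim,
    ssim_curve,
)


def _gaussian_image(sigma=(1.0, 1.2, 0.8), amp=10.0, offset=0.0, n=32, voxel=0.4,
                    center=(0.0, 0.0, 0.0), noise=0.0, rng=None):
    grid = ImageGrid.centered(n, voxel)
    xs, ys, zs = grid.voxel_center_mesh()
    data = amp * np.exp(
        -((xs - center[0]) ** 2) / (2 * sigma[0] ** 2)
        - ((ys - center[1]) ** 2) / (2 * sigma[1] ** 2)
        - ((zs - center[2]) ** 2) / (2 * sigma[2] ** 2)
    ) + offset
    if noise:
        data = data + noise * amp * rng.standard_normal(data.shape)
    return ImageVolume(data=data, grid=grid)


class TestGaussianFit:
    def test_exact_recovery_noiseless(self):
        img = _gaussian_image()
        fit = fit_gaussian_3d(img)
        assert fit.converged
        assert fit.sigma_mm == pytest.approx((1.0, 1.2, 0.8), rel=1e-6)
        assert fit.fwhm_mm[0] == pytest.approx(2.0 * np.sqrt(2 * np.log(2)), rel=1e-6)
        assert fit.center_mm == pytest.approx((0.0, 0.0, 0.0), abs=1e-6)

    def test_offset_identifiable(self):
        img = _gaussian_image(offset=5.0)
        fit = fit_gaussian_3d(img)
        assert fit.offset == pytest.approx(5.0, abs=1e-6)
        assert fit.sigma_mm == pytest.approx((1.0, 1.2, 0.8), rel=1e-6)

    def test_noise_recovery_within_3pct(self, rng):
        img = _gaussian_image(n=64, noise=0.05, rng=rng)
        fit = fit_gaussian_3d(img)
        assert fit.converged
        for got, true in zip(fit.sigma_mm, (1.0, 1.2, 0.8)):
            assert abs(got - true) / true < 0.03

    def test_off_center_peak(self):
        img = _gaussian_image(center=(1.3, -0.9, 0.5))
        fit = fit_gaussian_3d(img)
        assert fit.center_mm == pytest.approx((1.3, -0.9, 0.5), abs=1e-6)

    def test_window_restricts_fit(self):
        img = _gaussian_image(n=48)
        fit = fit_gaussian_3d(img, window=((8, 40), (8, 40), (8, 40)))
        assert fit.sigma_mm == pytest.approx((1.0, 1.2, 0.8), rel=1e-5)

    def test_multiple_peaks_warn(self):
        grid = ImageGrid.centered(24, 1.0)
        data = np.zeros(grid.shape)
        data[6, 12, 12] = 10.0
        data[18, 12, 12] = 9.0
        img = ImageVolume(data=data, grid=grid)
        with pytest.warns(UserWarning, match="multiple peaks"):
            fit = fit_gaussian_3d(img)
        assert fit.n_peaks >= 2


class TestNormalization:
    def _grids(self, n=20):
        grid = ImageGrid.centered(n, 2.0)
        return grid

    def test_constant_homog_identity(self):
        grid = self._grids()
        img = ImageVolume(data=np.random.default_rng(0).uniform(1, 2, grid.shape), grid=grid)
        homog = ImageVolume(data=np.full(grid.shape, 3.0), grid=grid)
        out = normalize_by_homogeneous(img, homog)
        np.testing.assert_allclose(out.data, img.data, rtol=1e-10)

    def test_scaled_homog_identity(self):
        grid = self._grids()
        img = ImageVolume(data=np.ones(grid.shape), grid=grid)
        h1 = ImageVolume(data=np.full(grid.shape, 1.0), grid=grid)
        h2 = ImageVolume(data=np.full(grid.shape, 2.0), grid=grid)
        np.testing.assert_allclose(
            normalize_by_homogeneous(img, h1).data,
            normalize_by_homogeneous(img, h2).data,
            rtol=1e-10,
        )

    def test_ramp_flattened(self):
        grid = self._grids()
        xs, _, _ = grid.voxel_center_mesh()
        ramp = 1.0 + 0.01 * (xs - xs.min())
        img = ImageVolume(data=ramp.copy(), grid=grid)
        homog = ImageVolume(data=ramp.copy(), grid=grid)
        out = normalize_by_homogeneous(img, homog, filter_fwhm_mm=0.0)
        np.testing.assert_allclose(out.data, out.data.flat[0], rtol=1e-10)

    def test_grid_mismatch_rejected(self):
        a = ImageVolume(data=np.ones((4, 4, 4)), grid=ImageGrid.centered(4, 1.0))
        b = ImageVolume(data=np.ones((4, 4, 4)), grid=ImageGrid.centered(4, 2.0))
        with pytest.raises(ValueError):
            normalize_by_homogeneous(a, b)


def _synthetic_iq_image(hot=4.0, bg=1.0, voxel=3.0, shape=(120, 120, 120)):
    """Noiseless ground-truth voxelization of the IQ phantom."""
    from panelpet.phantoms import nema_iq_phantom, voxelize

    ph = nema_iq_phantom(background_kBq_mL=bg, sphere_kBq_mL=hot)
    grid = ImageGrid.centered(shape, voxel)
    return voxelize(ph, grid, supersample=3)


class TestNemaIQ:
    def test_ground_truth_large_sphere_contrast(self):
        # fine voxels keep the ROI-edge partial-volume residual small
        img = _synthetic_iq_image(voxel=1.5, shape=(214, 214, 32))
        res = nema_iq_analysis(img, upsample=5)
        by_diam = {r.sphere_diameter_mm: r for r in res}
        assert 95.0 <= by_diam[37.0].percent_contrast <= 100.5
        assert by_diam[37.0].background_variability < 1.0

    def test_equal_concentrations_zero_contrast(self):
        img = _synthetic_iq_image(hot=1.0, bg=1.0)
        res = nema_iq_analysis(img, upsample=2)
        for r in res:
            assert r.percent_contrast == pytest.approx(0.0, abs=1.5)

    def test_toy_two_level_formula(self):
        # C_H = 4, C_B = 1, ratio 4 -> Q = 100 * (4-1)/(4-1) = 100%
        assert 100.0 * (4.0 / 1.0 - 1.0) / (4.0 - 1.0) == 100.0

    def test_roi_template_inside_body(self):
        for x, y in BACKGROUND_ROI_XY_MM:
            # inside the torso (two half-circles + rectangle) with margin
            ax = max(abs(x) - 35.0, 0.0)
            assert ax**2 + y**2 <= (115.0 - 18.5) ** 2 + 1e-9

    def test_roi_outside_image_rejected(self):
        img = ImageVolume(data=np.ones((10, 10, 5)), grid=ImageGrid.centered((10, 10, 5), 3.0))
        with pytest.raises(ValueError):
            nema_iq_analysis(img, upsample=2)


class TestContrastInterpolation:
    def test_exact_bracket_point(self):
        curve = [(0, 80.0, 7.0), (2, 75.0, 5.0), (4, 70.0, 3.0)]
        assert contrast_at_variability(curve, 5.0) == 75.0

    def test_linear_interpolation(self):
        curve = [(0, 80.0, 4.0), (2, 70.0, 6.0)]
        assert contrast_at_variability(curve, 5.0) == pytest.approx(75.0)

    def test_extrapolation_refused(self):
        curve = [(0, 80.0, 4.0), (2, 70.0, 6.0)]
        with pytest.raises(ValueError):
            contrast_at_variability(curve, 10.0)


class TestNECR:
    def test_simple_values(self):
        assert necr(100.0, 0.0, 0.0) == 100.0
        assert necr(80.0, 15.0, 5.0) == pytest.approx(64.0)
        assert necr(0.0, 0.0, 0.0) == 0.0

    @given(
        t=st.floats(0, 1e6),
        s=st.floats(0, 1e6),
        r=st.floats(0, 1e6),
    )
    def test_necr_at_most_t(self, t, s, r):
        assert necr(t, s, r) <= t + 1e-9

    def test_tof_gain_closed_form(self):
        # 2 * 0.2 m / (2.998e8 m/s * 75 ps) ~ 17.79
        gain = necr_tof(1.0, d_mm=200.0, ctr_ps=75.0)
        assert gain == pytest.approx(17.79, abs=0.01)

    def test_gain_inverse_in_ctr(self):
        assert necr_tof(10.0, ctr_ps=75.0) == pytest.approx(2 * necr_tof(10.0, ctr_ps=150.0))

    def test_zero_ctr_rejected(self):
        with pytest.raises(ValueError):
            necr_tof(10.0, ctr_ps=0.0)

    @given(n=st.floats(0, 1e5), d=st.floats(10, 1000), ctr=st.floats(10, 500))
    def test_gain_identity(self, n, d, ctr):
        gain = 2.0 * (d * 1e-3) / (const.C_M_PER_S * ctr * 1e-12)
        assert necr_tof(n, d_mm=d, ctr_ps=ctr) == pytest.approx(gain * n, rel=1e-12)


class TestSSIM:
    def test_identical_images(self, rng):
        a = rng.uniform(0, 1, (64, 64))
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        a = rng.uniform(0, 1, (48, 48))
        b = rng.uniform(0, 1, (48, 48))
        assert ssim(a, b, data_range=1.0) == pytest.approx(ssim(b, a, data_range=1.0), abs=1e-12)

    def test_matches_skimage_reference(self, rng):
        skimage_metrics = pytest.importorskip("skimage.metrics")
        for _ in range(5):
            a = rng.uniform(0, 1, (72, 80))
            b = np.clip(a + 0.1 * rng.standard_normal(a.shape), 0, 1)
            ours = ssim(a, b, data_range=1.0)
            ref = skimage_metrics.structural_similarity(
                a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False,
            )
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.ones((10, 10)), np.ones((12, 10)))

    def test_curve_converges_under_heavy_filtering(self, rng):
        grid = ImageGrid.centered((64, 64, 8), 1.0)
        ref = np.zeros(grid.shape)
        ref[16:48, 16:48, :] = 1.0
        ref[24:40, 24:40, :] = 3.0
        noisy = ref + 0.4 * rng.standard_normal(grid.shape)
        recon = ImageVolume(data=np.clip(noisy, 0, None), grid=grid)
        reference = ImageVolume(data=ref, grid=grid)
        df = ssim_curve(recon, reference, [0.0, 2.0, 4.0], slice_index=4)
        assert set(df.columns) == {"filter_fwhm_mm", "ssim"}
        assert df["ssim"].iloc[1] > df["ssim"].iloc[0]  # light filtering helps noise


class TestSensitivityScan:
    def test_profile_symmetric_and_zero_outside(self, cs3_geometry, cs3_policy):
        from panelpet.metrics import sensitivity_scan

        prof = sensitivity_scan(
            cs3_geometry, cs3_policy,
            axial_positions_mm=[-100.0, 0.0, 100.0, 400.0],
            duration_s=2.0, activity_Bq=100_000.0, seed=17,
        )
        v = prof.sensitivity_kcps_per_MBq
        # symmetry about Z=0 within MC error
        assert abs(v[0] - v[2]) / max(v[0], v[2]) < 0.06
        assert v[1] == prof.total_system_sensitivity
        assert v[1] > v[0]  # centre is maximal
        assert v[3] == 0.0  # source far outside the axial extent
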