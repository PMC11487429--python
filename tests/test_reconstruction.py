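import numpy as np
import pytest
import scipy.sparse as sp

from panelpet import constants as const
from panelpet.coincidence import COINCIDENCE_DTYPE, flat_panel_policy
from panelpet.geometry import CrystalSpec, build_flat_panel
from panelpet.imagevol import ImageGrid, ImageVolume
from panelpet.phantoms import AnalyticPhantom, point_source
from panelpet.reconstruction import (
    TOFKernel,
    build_system_matrix,
    compute_sensitivity,
    gaussian_post_filter,
    mlem,
    ray_trace,
    reconstruct,
    tof_weights,
)
from panelpet.simulation import simulate_coincidences


class TestSiddon:
    def test_axis_aligned_unit_lengths(self):
        grid = ImageGrid.centered(10, 1.0)
        idx, lengths = ray_trace([-20.0, 0.5 - 5 + 5, 0.5], [20.0, 0.5, 0.5], grid)
        # crosses all 10 voxels along x at y=z=0.5 (voxel row 5)
        assert len(lengths) == 10
        np.testing.assert_allclose(lengths, 1.0, atol=1e-9)
        assert set(idx[:, 0]) == set(range(10))

    def test_diagonal_sqrt2(self):
        grid = ImageGrid.centered(8, 1.0)
        idx, lengths = ray_trace([-10.0, -10.0, 0.5], [10.0, 10.0, 0.5], grid)
        np.testing.assert_allclose(lengths, np.sqrt(2.0), atol=1e-9)

    def test_lengths_sum_to_chord(self, rng):
        grid = ImageGrid.centered((12, 9, 7), (1.0, 1.3, 2.1))
        for _ in range(200):
            p1 = rng.uniform(-40, 40, 3)
            p1 += 30 * np.sign(p1)  # push outside the grid
            p2 = rng.uniform(-6, 6, 3)
            d = p2 - p1
            p2 = p1 + d * 4.0
            _, lengths = ray_trace(p1, p2, grid)
            # chord by clipping the segment against the grid box
            lo = np.asarray(grid.origin_mm)
            hi = lo + grid.extent_mm
            t0, t1 = 0.0, 1.0
            for a in range(3):
                if abs(d[a] * 4) < 1e-12:
                    if not (lo[a] <= p1[a] <= hi[a]):
                        t0, t1 = 1.0, 0.0
                    continue
                ta = (lo[a] - p1[a]) / (d[a] * 4)
                tb = (hi[a] - p1[a]) / (d[a] * 4)
                ta, tb = min(ta, tb), max(ta, tb)
                t0, t1 = max(t0, ta), min(t1, tb)
            chord = max(t1 - t0, 0.0) * np.linalg.norm(d * 4)
            assert lengths.sum() == pytest.approx(chord, abs=1e-9)

    def test_missing_lor_empty(self):
        grid = ImageGrid.centered(8, 1.0)
        idx, lengths = ray_trace([-20, 50, 0], [20, 50, 0], grid)
        assert len(lengths) == 0


class TestTOF:
    def test_kernel_sigma(self):
        k = TOFKernel(ctr_ps=75.0)
        expected = const.C_MM_PER_NS * (0.075 / const.FWHM_PER_SIGMA) / 2.0
        assert k.sigma_mm == pytest.approx(expected)

    def test_localisation_at_214ps(self):
        # c * dt / 2 for dt = 214 ps is 3.2 cm
        assert const.C_MM_PER_NS * 0.214 / 2.0 == pytest.approx(32.0, abs=0.1)

    def test_zero_dt_peaks_at_midpoint(self):
        k = TOFKernel(ctr_ps=100.0)
        s = np.linspace(0, 100, 101)
        w = tof_weights(s, 50.0, k)
        assert s[np.argmax(w)] == 50.0

    def test_disabled_kernel_unit_weights(self):
        w = tof_weights(np.linspace(0, 10, 5), 3.0, None)
        np.testing.assert_array_equal(w, 1.0)

    def test_weight_shifts_with_dt(self):
        grid = ImageGrid.centered(40, 1.0)
        p1 = np.array([[-100.0, 0.5, 0.5]])
        p2 = np.array([[100.0, 0.5, 0.5]])
        kernel = TOFKernel(ctr_ps=200.0)
        dt = np.array([0.1])  # dt = t1 - t2 > 0: peak displaced toward p2
        a = build_system_matrix(p1, p2, dt, grid, kernel)
        dense = np.asarray(a.todense()).reshape(grid.shape)
        peak_x = grid.voxel_centers_1d(0)[np.argmax(dense.max(axis=(1, 2)))]
        assert peak_x == pytest.approx(const.C_MM_PER_NS * 0.1 / 2.0, abs=1.0)


class TestAdjointness:
    def test_forward_back_consistency(self, rng):
        grid = ImageGrid.centered(16, 2.0)
        p1 = rng.uniform(-60, -40, (50, 3))
        p2 = rng.uniform(40, 60, (50, 3))
        a = build_system_matrix(p1, p2, None, grid, None)
        x = rng.uniform(0, 1, a.shape[1])
        y = rng.uniform(0, 1, a.shape[0])
        lhs = float((a @ x) @ y)
        rhs = float(x @ (a.T @ y))
        assert lhs == pytest.approx(rhs, rel=1e-8)


def _complete_axis_lors(n):
    """All axis-aligned LORs of an n^3 grid (outside endpoints)."""
    p1s, p2s = [], []
    c = np.arange(n) + 0.5 - n / 2
    for a, b in [(1, 2), (0, 2), (0, 1)]:
        axis = 3 - a - b
        for u in c:
            for v in c:
                p1 = np.zeros(3)
                p2 = np.zeros(3)
                p1[axis], p2[axis] = -2 * n, 2 * n
                p1[a] = p2[a] = u
                p1[b] = p2[b] = v
                p1s.append(p1)
                p2s.append(p2)
    return np.array(p1s), np.array(p2s)


@pytest.fixture(scope="module")
def small_instance():
    n = 5
    grid = ImageGrid.centered(n, 1.0)
    p1s, p2s = _complete_axis_lors(n)
    a_all = build_system_matrix(p1s, p2s, None, grid, None)
    sens = ImageVolume(
        data=np.asarray(a_all.sum(axis=0)).ravel().reshape(grid.shape), grid=grid
    )
    # noiseless single hot voxel at the centre: only the 3 LORs through
    # (2,2,2) record counts; repeat each 50 times as list-mode events
    hot = [i for i in range(len(p1s)) if a_all[i, (2 * 5 + 2) * 5 + 2] > 0]
    assert len(hot) == 3
    rows = np.repeat(hot, 50)
    system = a_all[rows]
    return grid, system, sens, a_all


class TestMLEM:

    def test_recovers_single_hot_voxel(self, small_instance):
        grid, system, sens, _ = small_instance
        img = mlem(system, grid, sens, n_iter=100)
        flat = img.data.ravel()
        assert np.argmax(flat) == (2 * 5 + 2) * 5 + 2
        assert flat[np.argmax(flat)] / flat.sum() > 0.99

    def test_non_negativity(self, small_instance):
        grid, system, sens, _ = small_instance
        img = mlem(system, grid, sens, n_iter=7)
        assert img.data.min() >= 0.0

    def test_one_iteration_closed_form(self, small_instance):
        grid, system, sens, _ = small_instance
        img = mlem(system, grid, sens, n_iter=1)
        s = sens.data.ravel()
        support = s > 0.01 * s.max()
        x0 = support.astype(float)
        proj = system @ x0
        ratio = np.where(proj > 0, 1.0 / proj, 0.0)
        expected = x0 / np.where(support, s, 1.0) * (system.T @ ratio)
        expected[~support] = 0.0
        np.testing.assert_allclose(img.data.ravel(), expected, rtol=1e-12)

    def test_likelihood_monotone(self, small_instance):
        grid, system, sens, a_all = small_instance
        s = sens.data.ravel()

        def loglik(x):
            proj = system @ x
            good = proj > 0
            return float(np.log(proj[good]).sum() - s @ x)

        vals = [loglik(mlem(system, grid, sens, n_iter=k).data.ravel()) for k in range(1, 8)]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_empty_listmode_rejected(self, small_instance):
        grid, _, sens, _ = small_instance
        with pytest.raises(ValueError):
            mlem(sp.csr_matrix((0, 125)), grid, sens, n_iter=1)

    def test_zero_sensitivity_rejected(self, small_instance):
        grid, system, _, _ = small_instance
        zero = ImageVolume(data=np.zeros(grid.shape), grid=grid)
        with pytest.raises(ValueError):
            mlem(system, grid, zero, n_iter=1)


class TestSensitivityImage:
    def test_center_maximal_and_outside_zero(self, cs3_geometry):
        # grid extending axially beyond the panels: top voxels see no LORs
        grid = ImageGrid.centered((9, 9, 15), (20.0, 20.0, 40.0))
        sens = compute_sensitivity(cs3_geometry, grid, n_samples=400_000, seed=1)
        d = sens.data
        center = d[4, 4, 7]
        assert center == d.max()
        assert d[4, 4, 0] == 0.0 and d[4, 4, -1] == 0.0  # |z| > 280 mm

    def test_zero_samples_rejected(self, cs3_geometry):
        grid = ImageGrid.centered(4, 10.0)
        with pytest.raises(ValueError):
            compute_sensitivity(cs3_geometry, grid, n_samples=0)

    def test_mc_variance_shrinks_with_samples(self, cs3_geometry):
        grid = ImageGrid.centered(8, 10.0)
        ref = compute_sensitivity(cs3_geometry, grid, n_samples=1_600_000, seed=99).data
        err = []
        for n in (50_000, 200_000):
            d = compute_sensitivity(cs3_geometry, grid, n_samples=n, seed=5).data
            err.append(np.linalg.norm(d / d.mean() - ref / ref.mean()))
        assert err[1] < err[0]


class TestPostFilter:
    def _delta(self):
        grid = ImageGrid.centered(41, 1.0)
        data = np.zeros(grid.shape)
        data[20, 20, 20] = 1.0
        return ImageVolume(data=data, grid=grid)

    def test_zero_fwhm_identity(self):
        img = self._delta()
        out = gaussian_post_filter(img, 0.0)
        np.testing.assert_array_equal(out.data, img.data)

    def test_total_preserved(self):
        out = gaussian_post_filter(self._delta(), 4.0)
        assert out.total == pytest.approx(1.0, abs=1e-6)

    def test_delta_gets_requested_fwhm(self):
        out = gaussian_post_filter(self._delta(), 5.0)
        prof = out.data[:, 20, 20]
        xs = np.arange(41)
        half = prof.max() / 2
        above = xs[prof >= half]
        width = above.max() - above.min() + 1 - 1  # coarse, +-1 voxel
        assert width == pytest.approx(5.0, abs=1.0)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_post_filter(self._delta(), -1.0)


class TestLimitedAngleTOF:
    def test_tof_shrinks_missing_axis_fwhm(self):
        """Two opposing panels only: without TOF the off-centre point is
        elongated along the panel axis; TOF localisation shrinks it."""
        from panelpet.metrics import fit_gaussian_3d

        geom = build_flat_panel(
            CrystalSpec(3.0, 10.0, 3.0), n_panels=2, panel_extent_mm=60.0
        )
        policy = flat_panel_policy(ctr_ps=75.0)
        ph = AnalyticPhantom(
            primitives=[point_source((30.0, 0.0, 0.0), activity_Bq=3_000_000.0)]
        )
        coinc = simulate_coincidences(ph, geom, policy, 1.0, seed=42)
        assert (coinc["klass"] == 0).sum() > 1500
        grid = ImageGrid.centered(32, 1.5, center_mm=(30.0, 0.0, 0.0))
        widths = {}
        for tof in (True, False):
            img = reconstruct(
                coinc, geom, grid, n_iter=10, tof=tof, ctr_ps=policy.ctr_ps,
                n_sens_samples=300_000, seed=3, psf_fwhm_mm=3.0,
            )
            fit = fit_gaussian_3d(img)
            widths[tof] = fit.fwhm_mm[0]
        assert widths[True] < 0.8 * widths[False]
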