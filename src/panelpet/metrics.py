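"""Quantitative endpoints: 3D Gaussian spatial resolution, NEMA-style
image quality (percent contrast / background variability with
homogeneous-cube normalization), axial sensitivity profiles, NECR and
TOF-effective NECR, and SSIM curves."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.optimize import curve_fit

from . import constants as const
from .imagevol import ImageGrid, ImageVolume
from .reconstruction import gaussian_post_filter

# ---------------------------------------------------------------------------
# 3D Gaussian fit (spatial resolution)
# ---------------------------------------------------------------------------


@dataclass
class GaussianFit3D:
    """A * exp(-sum (u-u0)^2 / 2 sigma_u^2) + C and per-axis FWHM."""

    amplitude: float
    center_mm: tuple
    sigma_mm: tuple
    offset: float
    converged: bool
    residual_rms: float
    n_peaks: int = 1

    @property
    def fwhm_mm(self) -> tuple:
        return tuple(const.FWHM_PER_SIGMA * s for s in self.sigma_mm)


def _gauss3d(coords, a, x0, y0, z0, sx, sy, sz, c):
    x, y, z = coords
    return (
        a
        * np.exp(
            -((x - x0) ** 2) / (2 * sx**2)
            - ((y - y0) ** 2) / (2 * sy**2)
            - ((z - z0) ** 2) / (2 * sz**2)
        )
        + c
    )


def fit_gaussian_3d(image: ImageVolume, window: Optional[tuple] = None) -> GaussianFit3D:
    """Nonlinear least-squares 3D Gaussian fit of a single dominant peak.

    ``window`` is an optional ((i0,i1),(j0,j1),(k0,k1)) voxel sub-box.
    Initialization: A = max - min, centre = centroid of the top-decile
    voxels, sigmas from second moments, C = border median.
    """
    data = image.data
    grid = image.grid
    if window is not None:
        (i0, i1), (j0, j1), (k0, k1) = window
        data = data[i0:i1, j0:j1, k0:k1]
        sub_origin = [
            grid.origin_mm[0] + i0 * grid.voxel_mm[0],
            grid.origin_mm[1] + j0 * grid.voxel_mm[1],
            grid.origin_mm[2] + k0 * grid.voxel_mm[2],
        ]
        grid = ImageGrid(shape=data.shape, voxel_mm=grid.voxel_mm, origin_mm=tuple(sub_origin))
    xs, ys, zs = np.meshgrid(
        *[grid.voxel_centers_1d(a) for a in range(3)], indexing="ij"
    )
    vmax, vmin = float(data.max()), float(data.min())
    # centre init: centroid of the top-decile values among voxels near the
    # peak (the global maximum), which keeps a uniform background from
    # dragging the initial guess off the source
    peak = np.unravel_index(int(np.argmax(data)), data.shape)
    half = vmin + 0.5 * (vmax - vmin)
    above = data >= max(np.quantile(data, 0.9), half)
    w = np.where(above, data - vmin, 0.0)
    dist2 = (
        (xs - xs[peak]) ** 2 + (ys - ys[peak]) ** 2 + (zs - zs[peak]) ** 2
    )
    w[dist2 > (10.0 * max(grid.voxel_mm)) ** 2] = 0.0
    wsum = w.sum()
    if wsum <= 0:
        w = np.zeros_like(data)
        w[peak] = 1.0
        wsum = 1.0
    cx = float((xs * w).sum() / wsum)
    cy = float((ys * w).sum() / wsum)
    cz = float((zs * w).sum() / wsum)
    sx = np.sqrt(max(((xs - cx) ** 2 * w).sum() / wsum, grid.voxel_mm[0] ** 2 / 12))
    sy = np.sqrt(max(((ys - cy) ** 2 * w).sum() / wsum, grid.voxel_mm[1] ** 2 / 12))
    sz = np.sqrt(max(((zs - cz) ** 2 * w).sum() / wsum, grid.voxel_mm[2] ** 2 / 12))
    border = np.concatenate(
        [data[0].ravel(), data[-1].ravel(), data[:, 0].ravel(), data[:, -1].ravel(),
         data[:, :, 0].ravel(), data[:, :, -1].ravel()]
    )
    c0 = float(np.median(border))
    p0 = [vmax - vmin, cx, cy, cz, sx, sy, sz, c0]
    coords = (xs.ravel(), ys.ravel(), zs.ravel())
    try:
        popt, _ = curve_fit(_gauss3d, coords, data.ravel(), p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
    a, x0, y0, z0, gsx, gsy, gsz, c = popt
    resid = data.ravel() - _gauss3d(coords, *popt)
    # secondary-peak diagnostic: local maxima above half amplitude
    thresh = c + abs(a) / 2.0
    local_max = (data == ndi.maximum_filter(data, size=3)) & (data > thresh)
    n_peaks = int(ndi.label(local_max)[1])
    if n_peaks > 1:
        warnings.warn(f"multiple peaks ({n_peaks}) detected in fit window", stacklevel=2)
    return GaussianFit3D(
        amplitude=float(a),
        center_mm=(float(x0), float(y0), float(z0)),
        sigma_mm=(abs(float(gsx)), abs(float(gsy)), abs(float(gsz))),
        offset=float(c),
        converged=converged,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_peaks=n_peaks,
    )


def resolution_study(
    geometry,
    policy,
    source_phantoms: Sequence,
    source_centers: Sequence,
    duration_s: float,
    seed: int = 0,
    n_iter: int = 30,
    voxel_mm: float = 0.8,
    grid_n: int = 64,
    ctr_ps: Optional[float] = None,
    n_sens_samples: int = 500_000,
    fit_window_mm: float = 12.0,
    psf_fwhm_mm: Optional[float] = None,
) -> pd.DataFrame:
    """Simulate -> reconstruct (local sub-grid) -> fit, per source.

    Reconstruction parameters are fixed across sources so comparisons are
    fair; fit failures are flagged in the table, not dropped.
    """
    from .reconstruction import compute_sensitivity, reconstruct
    from .simulation import simulate_coincidences

    ctr = ctr_ps if ctr_ps is not None else policy.ctr_ps
    if psf_fwhm_mm is None:
        # image-space resolution model at the LOR quantization scale (one
        # crystal pitch): counterpart of the paper's distance-driven
        # projector choice -- a thin-line projector lets MLEM super-resolve
        # point sources far below the detector resolution
        psf_fwhm_mm = geometry.crystal.pitch
    rows = []
    for idx, (phantom, center) in enumerate(zip(source_phantoms, source_centers)):
        grid = ImageGrid.centered(grid_n, voxel_mm, center_mm=center)
        sens = compute_sensitivity(
            geometry, grid, level=policy.readout_level,
            min_sector_difference=policy.min_sector_difference,
            n_samples=n_sens_samples, seed=seed + 7919 * idx,
        )
        coinc = simulate_coincidences(
            phantom, geometry, policy, duration_s, seed=seed + 104729 * idx
        )
        img = reconstruct(
            coinc, geometry, grid, n_iter=n_iter, tof=True, ctr_ps=ctr,
            level=policy.readout_level, sensitivity=sens,
            psf_fwhm_mm=psf_fwhm_mm, seed=seed + idx,
        )
        half_vox = max(int(round(fit_window_mm / voxel_mm)), 4)
        mid = grid_n // 2
        lo = max(mid - half_vox, 0)
        hi = min(mid + half_vox, grid_n)
        fit = fit_gaussian_3d(img, window=((lo, hi),) * 3)
        fx, fy, fz = fit.fwhm_mm
        rows.append(
            {
                "source_x": center[0], "source_y": center[1], "source_z": center[2],
                "fwhm_x": fx, "fwhm_y": fy, "fwhm_z": fz,
                "fit_x": fit.center_mm[0], "fit_y": fit.center_mm[1], "fit_z": fit.center_mm[2],
                "converged": fit.converged, "n_peaks": fit.n_peaks,
                "n_trues": int((coinc["klass"] == 0).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NEMA image quality
# ---------------------------------------------------------------------------

#: background ROI template: 12 positions per slice (mm), placed in the
#: torso background clear of the spheres and the lung insert
BACKGROUND_ROI_XY_MM = tuple(
    (92.0 * np.cos(np.deg2rad(15 + 30 * k)), 92.0 * np.sin(np.deg2rad(15 + 30 * k)))
    for k in range(12)
)

#: background slice offsets (mm): central, +/-1 cm, +/-2 cm
BACKGROUND_SLICE_OFFSETS_MM = (-20.0, -10.0, 0.0, 10.0, 20.0)


@dataclass
class IQResult:
    sphere_diameter_mm: float
    percent_contrast: float
    background_variability: float
    filter_fwhm_mm: float = 0.0
    repetition: int = 0


def normalize_by_homogeneous(
    image: ImageVolume, homog_image: ImageVolume, filter_fwhm_mm: float = 15.0
) -> ImageVolume:
    """Divide by a wide-filtered homogeneous-cube image and restore the
    scale by its mean; guarded where the homogeneous image is < 1% of its
    mean (set to 0)."""
    if image.grid != homog_image.grid:
        raise ValueError("image and homogeneous image must share a grid")
    if filter_fwhm_mm > 0:
        # nearest-edge handling: a constant homogeneous image must stay
        # constant under the wide filter (identity normalization)
        sigma_vox = [
            filter_fwhm_mm / const.FWHM_PER_SIGMA / v for v in image.grid.voxel_mm
        ]
        smooth = ndi.gaussian_filter(homog_image.data, sigma=sigma_vox, mode="nearest")
    else:
        smooth = homog_image.data.copy()
    mean = smooth.mean()
    good = smooth > 0.01 * mean
    out = np.zeros_like(image.data)
    np.divide(image.data, smooth, out=out, where=good)
    out *= mean
    out[~good] = 0.0
    return image.copy_with(out)


def _circle_mask(xs, ys, cx, cy, radius):
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2


def nema_iq_analysis(
    image: ImageVolume,
    sphere_diameters_mm=(10.0, 13.0, 17.0, 22.0, 28.0, 37.0),
    sphere_ring_radius_mm: float = 57.2,
    activity_ratio: float = 4.0,
    upsample: int = 10,
    filter_fwhm_mm: float = 0.0,
    repetition: int = 0,
):
    """Percent contrast and background variability per hot sphere.

    ROIs are drawn on a grid upsampled ``upsample``-fold in X and Y
    (voxel replication) to correct the partial-volume effect of coarse
    voxels; ROI diameter = sphere inner diameter.  Background: 12 ROI
    positions x 5 slices (central, +/-1 cm, +/-2 cm).
    """
    grid = image.grid
    up = int(upsample)
    data = np.repeat(np.repeat(image.data, up, axis=0), up, axis=1)
    xs = grid.origin_mm[0] + (np.arange(grid.shape[0] * up) + 0.5) * grid.voxel_mm[0] / up
    ys = grid.origin_mm[1] + (np.arange(grid.shape[1] * up) + 0.5) * grid.voxel_mm[1] / up
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    zc = grid.voxel_centers_1d(2)
    k_central = int(np.argmin(np.abs(zc)))
    results = []
    for j, diam in enumerate(sphere_diameters_mm):
        radius = diam / 2.0
        ang = np.pi / 3.0 * j
        cx = sphere_ring_radius_mm * np.cos(ang)
        cy = sphere_ring_radius_mm * np.sin(ang)
        hot_mask = _circle_mask(X, Y, cx, cy, radius)
        if not hot_mask.any():
            raise ValueError("hot ROI outside image")
        c_hot = float(data[:, :, k_central][hot_mask].mean())
        bg_means = []
        for dz in BACKGROUND_SLICE_OFFSETS_MM:
            k = int(np.argmin(np.abs(zc - dz)))
            sl = data[:, :, k]
            for bx, by in BACKGROUND_ROI_XY_MM:
                m = _circle_mask(X, Y, bx, by, radius)
                if not m.any():
                    raise ValueError("background ROI outside image")
                bg_means.append(float(sl[m].mean()))
        bg_means = np.asarray(bg_means)
        c_bg = float(bg_means.mean())
        q = 100.0 * (c_hot / c_bg - 1.0) / (activity_ratio - 1.0)
        n = 100.0 * float(bg_means.std(ddof=1)) / c_bg
        results.append(
            IQResult(
                sphere_diameter_mm=diam,
                percent_contrast=q,
                background_variability=n,
                filter_fwhm_mm=filter_fwhm_mm,
                repetition=repetition,
            )
        )
    return results


def contrast_at_variability(curve, target_variability: float = 5.0) -> float:
    """Linear interpolation of percent contrast at the target background
    variability over a filter-width sweep for one sphere.

    ``curve``: sequence of (filter_fwhm, contrast, variability), one entry
    per filter width.  Extrapolation outside the swept range is refused.
    """
    pts = sorted(curve, key=lambda r: r[2])  # by variability
    variab = np.array([p[2] for p in pts])
    contr = np.array([p[1] for p in pts])
    if not (variab[0] <= target_variability <= variab[-1]):
        raise ValueError(
            f"target variability {target_variability}% outside swept range "
            f"[{variab[0]:.2f}, {variab[-1]:.2f}]%"
        )
    return float(np.interp(target_variability, variab, contr))


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------


@dataclass
class SensitivityProfile:
    axial_positions_mm: np.ndarray
    sensitivity_kcps_per_MBq: np.ndarray
    total_system_sensitivity: float = field(init=False)

    def __post_init__(self):
        k = int(np.argmin(np.abs(self.axial_positions_mm)))
        self.total_system_sensitivity = float(self.sensitivity_kcps_per_MBq[k])


def sensitivity_scan(
    geometry,
    policy,
    axial_positions_mm: np.ndarray,
    duration_s: float = 10.0,
    activity_Bq: float = 10_000.0,
    seed: int = 0,
) -> SensitivityProfile:
    """Point source in air stepped along the axis; accepted coincidences
    per unit time and activity (kcps/MBq)."""
    from .phantoms import AnalyticPhantom, point_source
    from .simulation import simulate_coincidences

    vals = []
    for i, z in enumerate(np.atleast_1d(axial_positions_mm)):
        ph = AnalyticPhantom(
            primitives=[point_source((0.0, 0.0, float(z)), activity_Bq=activity_Bq)]
        )
        coinc = simulate_coincidences(ph, geometry, policy, duration_s, seed=seed + 31 * i)
        rate_cps = len(coinc) / duration_s
        vals.append(rate_cps / activity_Bq * 1e3)  # kcps/MBq
    return SensitivityProfile(
        axial_positions_mm=np.atleast_1d(np.asarray(axial_positions_mm, float)),
        sensitivity_kcps_per_MBq=np.asarray(vals),
    )


# ---------------------------------------------------------------------------
# NECR
# ---------------------------------------------------------------------------


def necr(t_cps: float, s_cps: float, r_cps: float) -> float:
    """T^2 / (T + S + R); 0 when the denominator vanishes."""
    denom = t_cps + s_cps + r_cps
    if denom <= 0:
        return 0.0
    return t_cps**2 / denom


def necr_tof(necr_cps: float, d_mm: float = 200.0, ctr_ps: float = 75.0) -> float:
    """TOF-effective NECR: gain 2D/(c*dt) times NECR; D is the diameter of
    the imaged object."""
    if ctr_ps <= 0:
        raise ValueError("CTR must be positive for the TOF gain")
    gain = 2.0 * (d_mm * 1e-3) / (const.C_M_PER_S * ctr_ps * 1e-12)
    return gain * necr_cps


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


def ssim(
    img1: np.ndarray,
    img2: np.ndarray,
    data_range: Optional[float] = None,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
    win_size: int = 11,
) -> float:
    """Structural similarity of two 2D images with a Gaussian window
    (population statistics), matching the standard reference formulation."""
    a = np.asarray(img1, dtype=np.float64)
    b = np.asarray(img2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    if data_range is None:
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    radius = (win_size - 1) // 2
    truncate = radius / sigma

    def f(x):
        return ndi.gaussian_filter(x, sigma=sigma, truncate=truncate, mode="reflect")

    mu1 = f(a)
    mu2 = f(b)
    var1 = f(a * a) - mu1**2
    var2 = f(b * b) - mu2**2
    cov = f(a * b) - mu1 * mu2
    s = ((2 * mu1 * mu2 + c1) * (2 * cov + c2)) / (
        (mu1**2 + mu2**2 + c1) * (var1 + var2 + c2)
    )
    crop = s[radius:-radius, radius:-radius]
    return float(crop.mean())


def _crop_to_support(reference: np.ndarray, *others, pad: int = 2):
    mask = reference > 0
    if not mask.any():
        raise ValueError("empty reference image")
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    r0 = max(r0 - pad, 0)
    c0 = max(c0 - pad, 0)
    r1 = min(r1 + pad, reference.shape[0] - 1)
    c1 = min(c1 + pad, reference.shape[1] - 1)
    sl = (slice(r0, r1 + 1), slice(c0, c1 + 1))
    return (reference[sl],) + tuple(o[sl] for o in others)


def ssim_curve(
    recon: ImageVolume,
    reference: ImageVolume,
    filter_fwhms_mm: Sequence[float],
    slice_index: Optional[int] = None,
) -> pd.DataFrame:
    """SSIM of a reconstructed slice vs. the activity-phantom slice as a
    function of the Gaussian filter applied to the reconstruction.

    Both slices are cropped to the bounding box of the reference support;
    SSIM dynamic range is set by the reference maximum.
    """
    k = slice_index if slice_index is not None else recon.grid.shape[2] // 2
    ref_slice = reference.data[:, :, k]
    rows = []
    for fwhm in filter_fwhms_mm:
        filt = gaussian_post_filter(recon, fwhm)
        rec_slice = filt.data[:, :, k]
        ref_c, rec_c = _crop_to_support(ref_slice, rec_slice)
        # match overall scale (reconstructions are unnormalized counts)
        if rec_c.sum() > 0:
            rec_c = rec_c * (ref_c.sum() / rec_c.sum())
        val = ssim(rec_c, ref_c, data_range=float(ref_c.max()))
        rows.append({"filter_fwhm_mm": fwhm, "ssim": val})
    return pd.DataFrame(rows)
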