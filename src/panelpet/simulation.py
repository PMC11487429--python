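"""Monte Carlo acquisition driver: Poisson decay timing, back-to-back
pair emission with non-colinearity, and chunked photon transport through
phantom and detector.

Each decay emits exactly two 511 keV photons (branching ratio 1, no
positron range).  The output of an acquisition is a time-stamped stream
of crystal energy deposits ("interactions") carrying event IDs and
phantom-scatter counts as ground truth for coincidence classification.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import _mc
from . import constants as const
from .geometry import FlatPanelGeometry, RingGeometry, ScannerGeometry
from .phantoms import AnalyticPhantom, export_arrays

INTERACTION_DTYPE = np.dtype(
    [
        ("event", "i8"),
        ("crystal", "i8"),
        ("energy", "f8"),
        ("time_ns", "f8"),
        ("nscat", "i2"),
    ]
)

_LOG_E_TAB = np.log(const.ATTEN_ENERGIES_KEV)
_LOG_MU = np.log(const.MU_TOTAL_PER_CM)
_PE_FRAC = const.PE_FRACTION


def geometry_arrays(geometry: ScannerGeometry):
    """Kernel-side geometry descriptor (type code, float params, int params)."""
    if isinstance(geometry, FlatPanelGeometry):
        gp = np.array(
            [
                geometry.face_distance_mm,
                geometry.crystal.pitch,
                geometry.crystal.cross_section,
                geometry.crystal.length,
                geometry.panel_extent_mm / 2.0,
            ]
        )
        gi = np.array([geometry.n_panels, geometry.n_side], dtype=np.int64)
        return 0, gp, gi
    if isinstance(geometry, RingGeometry):
        gp = np.array(
            [
                geometry.bore_diameter_mm / 2.0,
                geometry.crystal.length,
                geometry.axial_pitch_mm,
                geometry.crystal.cross_section,
                geometry.axial_fov_mm / 2.0,
            ]
        )
        gi = np.array([geometry.n_transaxial, geometry.n_axial], dtype=np.int64)
        return 1, gp, gi
    raise TypeError(f"unsupported geometry {type(geometry)}")


def emit_pair(rng: np.random.Generator, n: int = 1, noncolinearity_deg_fwhm: float = 0.5):
    """Directions of n annihilation pairs: first photon isotropic, second
    anti-parallel deflected by a Gaussian angle (FWHM as given) with
    uniform azimuth.  Returns (d1, d2), each (n, 3)."""
    cost = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sint = np.sqrt(1.0 - cost**2)
    d1 = np.stack([sint * np.cos(phi), sint * np.sin(phi), cost], axis=1)
    d2 = -d1
    if noncolinearity_deg_fwhm > 0:
        sigma = np.deg2rad(noncolinearity_deg_fwhm) / const.FWHM_PER_SIGMA
        delta = sigma * rng.standard_normal(n)
        az = rng.uniform(0.0, 2.0 * np.pi, n)
        d2 = _rotate_many(d2, np.cos(delta), az)
    return d1, d2


def _rotate_many(d, cost, phi):
    sint = np.sqrt(np.clip(1.0 - cost**2, 0.0, None))
    # basis perpendicular to d
    u = np.stack([-d[:, 1], d[:, 0], np.zeros(len(d))], axis=1)
    degen = np.abs(d[:, 2]) >= 0.999999
    u[degen] = [1.0, 0.0, 0.0]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (
        sint[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
        + cost[:, None] * d
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def generate_decay_times(total_activity_Bq: float, duration_s: float, rng) -> np.ndarray:
    """Homogeneous Poisson process arrival times in seconds, sorted."""
    if total_activity_Bq < 0:
        raise ValueError("activity must be non-negative")
    n = rng.poisson(total_activity_Bq * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, n))


def _phantom_kernel_args(phantom: AnalyticPhantom):
    shapes, centers, params, concs, mats, bg = export_arrays(phantom)
    lo, hi = phantom.bounding_box()
    matset = np.unique(np.concatenate([mats, [bg]])).astype(np.int64)
    return shapes, centers, params, mats.astype(np.int64), int(bg), lo, hi, matset


def _acquisition_chunks(
    phantom: AnalyticPhantom,
    geometry: ScannerGeometry,
    duration_s: float,
    seed: int,
    noncolinearity_deg_fwhm: float = 0.5,
    chunk_decays: int = 1_000_000,
    activity_scale: float = 1.0,
):
    """Yield (interaction record array, emission points) per decay block."""
    activity = phantom.total_activity_Bq() * activity_scale
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(1 << 16)
    shapes, centers, params, mats, bg, lo, hi, matset = _phantom_kernel_args(phantom)
    geom_type, gp, gi = geometry_arrays(geometry)
    sigma_nc = (
        np.deg2rad(noncolinearity_deg_fwhm) / const.FWHM_PER_SIGMA
        if noncolinearity_deg_fwhm > 0
        else 0.0
    )
    from .phantoms import sample_emission

    n_total = rng.poisson(activity * duration_s)
    t_clock = 0.0  # running acquisition clock, ns
    mean_gap_ns = 1e9 / activity if activity > 0 else 0.0
    for c0 in range(0, n_total, chunk_decays):
        m = min(chunk_decays, n_total - c0)
        pts, _ = sample_emission(phantom, rng, m)
        # exponential inter-arrivals continue the Poisson process across chunks
        gaps = rng.exponential(mean_gap_ns, m)
        times_ns = t_clock + np.cumsum(gaps)
        t_clock = times_ns[-1]
        cap = max(4 * m, 1024)
        out_ev = np.empty(cap, dtype=np.int64)
        out_cr = np.empty(cap, dtype=np.int64)
        out_e = np.empty(cap)
        out_t = np.empty(cap)
        out_ns = np.empty(cap, dtype=np.int16)
        nout = _mc.run_chunk(
            int(seeds[(c0 // chunk_decays) % len(seeds)]),
            pts,
            times_ns,
            c0,
            shapes, centers, params, mats, bg, lo, hi, matset,
            geom_type, gp, gi,
            _LOG_E_TAB, _LOG_MU, _PE_FRAC,
            const.MAT_LYSO,
            sigma_nc,
            const.ENERGY_CUTOFF_KEV,
            const.MAX_SCATTERS,
            out_ev, out_cr, out_e, out_t, out_ns,
        )
        if nout >= cap - 2 * _mc._MAX_CHAIN:
            raise RuntimeError("interaction scratch buffer overflow")
        rec = np.empty(nout, dtype=INTERACTION_DTYPE)
        rec["event"] = out_ev[:nout]
        rec["crystal"] = out_cr[:nout]
        rec["energy"] = out_e[:nout]
        rec["time_ns"] = out_t[:nout]
        rec["nscat"] = out_ns[:nout]
        yield rec, pts


def run_acquisition(
    phantom: AnalyticPhantom,
    geometry: ScannerGeometry,
    duration_s: float,
    seed: int,
    noncolinearity_deg_fwhm: float = 0.5,
    chunk_decays: int = 1_000_000,
    return_truth: bool = False,
    activity_scale: float = 1.0,
):
    """Simulate an acquisition; returns an interaction record array sorted
    by timestamp (and optionally the per-event emission-point truth).

    ``activity_scale`` uniformly rescales the phantom activity (desk-scale
    event-count reduction knob); it scales rates, not physics.
    """
    out = []
    truth_pts = [] if return_truth else None
    for rec, pts in _acquisition_chunks(
        phantom, geometry, duration_s, seed,
        noncolinearity_deg_fwhm, chunk_decays, activity_scale,
    ):
        out.append(rec)
        if return_truth:
            truth_pts.append(pts.astype(np.float32))
    interactions = (
        np.concatenate(out) if out else np.empty(0, dtype=INTERACTION_DTYPE)
    )
    interactions = interactions[np.argsort(interactions["time_ns"], kind="stable")]
    if return_truth:
        truth = np.concatenate(truth_pts) if truth_pts else np.empty((0, 3), np.float32)
        return interactions, truth
    return interactions


def simulate_coincidences(
    phantom: AnalyticPhantom,
    geometry: ScannerGeometry,
    policy,
    duration_s: float,
    seed: int,
    noncolinearity_deg_fwhm: float = 0.5,
    chunk_decays: int = 1_000_000,
    activity_scale: float = 1.0,
) -> np.ndarray:
    """Memory-lean acquisition + digitizer chain: interactions are grouped,
    blurred and energy-windowed chunk by chunk (raw deposits are never
    held for the whole run), then the surviving singles are pooled and
    paired.  Chunk boundaries are ~ms apart versus ns windows, so cross-
    chunk cluster/window splitting is negligible."""
    from .coincidence import (
        apply_energy_window,
        blur_energy,
        blur_time,
        group_to_singles,
        sort_coincidences,
    )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD161]).generate_state(1)[0])
    all_singles = []
    for rec, _ in _acquisition_chunks(
        phantom, geometry, duration_s, seed,
        noncolinearity_deg_fwhm, chunk_decays, activity_scale,
    ):
        singles = group_to_singles(
            rec, geometry,
            level=policy.readout_level,
            energy_policy=policy.energy_policy,
            integration_window_ns=policy.integration_ns,
        )
        singles["energy"] = blur_energy(
            singles["energy"], rng, policy.energy_resolution_fwhm_511
        )
        singles["time_ns"] = blur_time(singles["time_ns"], rng, policy.ctr_ps)
        all_singles.append(apply_energy_window(singles, *policy.energy_window_kev))
    if not all_singles:
        from .coincidence import COINCIDENCE_DTYPE

        return np.empty(0, dtype=COINCIDENCE_DTYPE)
    singles = np.concatenate(all_singles)
    singles = singles[np.argsort(singles["time_ns"], kind="stable")]
    return sort_coincidences(singles, geometry, policy)


# ---------------------------------------------------------------------------
# Thin single-photon wrappers used by closed-form physics checks
# ---------------------------------------------------------------------------


@njit(cache=True)
def _transport_many(
    seed, origins, dirs, shapes, centers, params, mats, bg, lo, hi, matset,
    log_e_tab, log_mu, pe_frac, e_cutoff, max_scatters,
):
    n = origins.shape[0]
    status = np.empty(n, dtype=np.int64)
    nscat = np.empty(n, dtype=np.int64)
    energy = np.empty(n)
    np.random.seed(seed)
    for i in range(n):
        st, _, _, _, _, _, _, e, ns, _ = _mc._transport_phantom(
            origins[i, 0], origins[i, 1], origins[i, 2],
            dirs[i, 0], dirs[i, 1], dirs[i, 2],
            511.0, shapes, centers, params, mats, bg, lo, hi, matset,
            log_e_tab, log_mu, pe_frac, e_cutoff, max_scatters,
        )
        status[i] = st
        nscat[i] = ns
        energy[i] = e
    return status, nscat, energy


def transport_phantom_batch(phantom: AnalyticPhantom, origins, dirs, seed: int):
    """Transport photons through the phantom only.  Returns
    (escaped flag, phantom-scatter count, final energy)."""
    shapes, centers, params, mats, bg, lo, hi, matset = _phantom_kernel_args(phantom)
    return _transport_many(
        seed,
        np.ascontiguousarray(origins, dtype=np.float64),
        np.ascontiguousarray(dirs, dtype=np.float64),
        shapes, centers, params, mats, bg, lo, hi, matset,
        _LOG_E_TAB, _LOG_MU, _PE_FRAC,
        const.ENERGY_CUTOFF_KEV, const.MAX_SCATTERS,
    )


@njit(cache=True)
def _detect_many(
    seed, origins, dirs, energies, geom_type, gp, gi,
    log_e_tab, log_mu_lyso, pe_lyso, e_cutoff,
):
    n = origins.shape[0]
    ndep = np.empty(n, dtype=np.int64)
    e_tot = np.zeros(n)
    first_crystal = np.full(n, -1, dtype=np.int64)
    sc = np.empty(_mc._MAX_CHAIN + 1, dtype=np.int64)
    se = np.empty(_mc._MAX_CHAIN + 1)
    sp = np.empty(_mc._MAX_CHAIN + 1)
    np.random.seed(seed)
    for i in range(n):
        k = _mc._transport_detector(
            origins[i, 0], origins[i, 1], origins[i, 2],
            dirs[i, 0], dirs[i, 1], dirs[i, 2],
            energies[i], 0.0, geom_type, gp, gi,
            log_e_tab, log_mu_lyso, pe_lyso, e_cutoff,
            sc, se, sp, 0,
        )
        ndep[i] = k
        for j in range(k):
            e_tot[i] += se[j]
        if k > 0:
            first_crystal[i] = sc[0]
    return ndep, e_tot, first_crystal


def transport_detector_batch(geometry: ScannerGeometry, origins, dirs, seed: int, energy_kev: float = 511.0):
    """Transport photons through the detector only.  Returns
    (deposit count, total deposited energy, first crystal id)."""
    geom_type, gp, gi = geometry_arrays(geometry)
    n = len(origins)
    return _detect_many(
        seed,
        np.ascontiguousarray(origins, dtype=np.float64),
        np.ascontiguousarray(dirs, dtype=np.float64),
        np.full(n, energy_kev),
        geom_type, gp, gi,
        _LOG_E_TAB, _LOG_MU[const.MAT_LYSO], _PE_FRAC[const.MAT_LYSO],
        const.ENERGY_CUTOFF_KEV,
    )
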