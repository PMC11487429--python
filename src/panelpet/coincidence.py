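"""Digitizer chain: readout grouping, energy/time blurring, energy
windowing and coincidence sorting with truth classification.

Order of operations follows the usual digitizer convention: deposits are
grouped into singles per readout group (integration window), energies
and timestamps are blurred, the energy window is applied, and the
surviving singles are paired by a sliding coincidence window.  Windows
containing more than two qualifying singles are discarded entirely
(killAll); pairs failing the geometric acceptance (same panel, or sector
difference below the minimum on the ring) are consumed but not emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from . import constants as const
from .geometry import (
    FlatPanelGeometry,
    ReadoutLevel,
    RingGeometry,
    ScannerGeometry,
)

SINGLE_DTYPE = np.dtype(
    [
        ("group", "i8"),
        ("crystal", "i8"),
        ("event", "i8"),
        ("energy", "f8"),
        ("time_ns", "f8"),
        ("nscat", "i2"),
    ]
)

COINCIDENCE_DTYPE = np.dtype(
    [
        ("crystal1", "i8"),
        ("crystal2", "i8"),
        ("group1", "i8"),
        ("group2", "i8"),
        ("event1", "i8"),
        ("event2", "i8"),
        ("dt_ns", "f8"),
        ("time_ns", "f8"),
        ("klass", "i1"),
    ]
)

CLASS_TRUE = 0
CLASS_SCATTERED = 1
CLASS_RANDOM = 2


@dataclass(frozen=True)
class CoincidencePolicy:
    """Digitizer + sorter settings for one scanner."""

    window_ns: float = 2.0
    readout_level: ReadoutLevel = ReadoutLevel.CRYSTAL
    energy_policy: str = "winner_take_all"  # or "energy_centroid"
    energy_window_kev: tuple = (435.0, 585.0)
    min_sector_difference: Optional[int] = None
    integration_window_ns: Optional[float] = None  # defaults to window_ns
    energy_resolution_fwhm_511: float = 0.10
    ctr_ps: float = 75.0

    def __post_init__(self):
        if self.window_ns <= 0:
            raise ValueError("coincidence window must be positive")

    @property
    def integration_ns(self) -> float:
        return self.integration_window_ns if self.integration_window_ns else self.window_ns


def flat_panel_policy(ctr_ps: float = 75.0, level: ReadoutLevel = ReadoutLevel.CRYSTAL) -> CoincidencePolicy:
    """2 ns window, winner-take-all, any panel pair."""
    return CoincidencePolicy(
        window_ns=2.0,
        readout_level=level,
        energy_policy="winner_take_all",
        ctr_ps=ctr_ps,
    )


def reference_policy(ctr_ps: float = 214.0) -> CoincidencePolicy:
    """4.7 ns window, submodule readout, energy centroid, min sector diff 4."""
    return CoincidencePolicy(
        window_ns=4.7,
        readout_level=ReadoutLevel.SUBMODULE,
        energy_policy="energy_centroid",
        min_sector_difference=4,
        ctr_ps=ctr_ps,
    )


@njit(cache=True)
def _aggregate_clusters(groups, times, energies, events, nscat, crystals, win):
    n = groups.shape[0]
    o_group = np.empty(n, dtype=np.int64)
    o_crystal = np.empty(n, dtype=np.int64)
    o_event = np.empty(n, dtype=np.int64)
    o_energy = np.empty(n)
    o_time = np.empty(n)
    o_nscat = np.empty(n, dtype=np.int16)
    o_start = np.empty(n, dtype=np.int64)
    o_len = np.empty(n, dtype=np.int64)
    m = 0
    i = 0
    while i < n:
        g = groups[i]
        t0 = times[i]
        e_sum = 0.0
        e_max = -1.0
        c_max = -1
        ev_max = -1
        ns_max = np.int16(0)
        t_min = t0
        j = i
        while j < n and groups[j] == g and times[j] - t0 <= win:
            e_sum += energies[j]
            if energies[j] > e_max:
                e_max = energies[j]
                c_max = crystals[j]
                ev_max = events[j]
            if nscat[j] > ns_max:
                ns_max = nscat[j]
            if times[j] < t_min:
                t_min = times[j]
            j += 1
        o_group[m] = g
        o_crystal[m] = c_max
        o_event[m] = ev_max
        o_energy[m] = e_sum
        o_time[m] = t_min
        o_nscat[m] = ns_max
        o_start[m] = i
        o_len[m] = j - i
        m += 1
        i = j
    return (
        o_group[:m],
        o_crystal[:m],
        o_event[:m],
        o_energy[:m],
        o_time[:m],
        o_nscat[:m],
        o_start[:m],
        o_len[:m],
    )


def group_to_singles(
    interactions: np.ndarray,
    geometry: ScannerGeometry,
    level: ReadoutLevel = ReadoutLevel.CRYSTAL,
    energy_policy: str = "winner_take_all",
    integration_window_ns: float = 2.0,
) -> np.ndarray:
    """Sum deposits per readout group within the integration window.

    Position carrier: winner-take-all assigns the cluster to the crystal
    with the largest deposit; energy-centroid takes the energy-weighted
    mean of the member crystal centres snapped to the nearest crystal.
    Timestamp = earliest deposit.
    """
    if len(interactions) == 0:
        return np.empty(0, dtype=SINGLE_DTYPE)
    groups = np.asarray(geometry.readout_group(interactions["crystal"], level))
    order = np.lexsort((interactions["time_ns"], groups))
    ints = interactions[order]
    groups = groups[order]
    g, c, ev, e, t, ns, starts, lens = _aggregate_clusters(
        groups.astype(np.int64),
        ints["time_ns"].astype(np.float64),
        ints["energy"].astype(np.float64),
        ints["event"].astype(np.int64),
        ints["nscat"].astype(np.int16),
        ints["crystal"].astype(np.int64),
        float(integration_window_ns),
    )
    if energy_policy == "energy_centroid":
        centers = geometry.crystal_centers(ints["crystal"])
        weighted = centers * ints["energy"][:, None]
        cum = np.vstack([np.zeros(3), np.cumsum(weighted, axis=0)])
        cum_e = np.concatenate([[0.0], np.cumsum(ints["energy"])])
        num = cum[starts + lens] - cum[starts]
        den = (cum_e[starts + lens] - cum_e[starts])[:, None]
        centroids = num / den
        c = _snap_to_crystal(geometry, centroids)
    elif energy_policy != "winner_take_all":
        raise ValueError(f"unknown energy policy {energy_policy!r}")
    singles = np.empty(len(g), dtype=SINGLE_DTYPE)
    singles["group"] = g
    singles["crystal"] = c
    singles["event"] = ev
    singles["energy"] = e
    singles["time_ns"] = t
    singles["nscat"] = ns
    return singles[np.argsort(singles["time_ns"], kind="stable")]


def _snap_to_crystal(geometry: ScannerGeometry, points: np.ndarray) -> np.ndarray:
    """Vectorized nearest-crystal lookup (indices clipped to valid range)."""
    pts = np.asarray(points, dtype=float)
    if isinstance(geometry, FlatPanelGeometry):
        theta = np.arctan2(pts[:, 1], pts[:, 0])
        step = 2.0 * np.pi / geometry.n_panels
        panel = np.round(theta / step).astype(np.int64) % geometry.n_panels
        th = panel * step
        u = -np.sin(th) * pts[:, 0] + np.cos(th) * pts[:, 1]
        half = (geometry.n_side - 1) / 2.0
        col = np.clip(
            np.round(u / geometry.crystal.pitch + half).astype(np.int64),
            0,
            geometry.n_side - 1,
        )
        row = np.clip(
            np.round(pts[:, 2] / geometry.crystal.pitch + half).astype(np.int64),
            0,
            geometry.n_side - 1,
        )
        return geometry.flat_id(panel, row, col)
    if isinstance(geometry, RingGeometry):
        theta = np.arctan2(pts[:, 1], pts[:, 0]) % (2.0 * np.pi)
        t = (theta / (2.0 * np.pi / geometry.n_transaxial)).astype(np.int64)
        t = np.clip(t, 0, geometry.n_transaxial - 1)
        zi = np.clip(
            ((pts[:, 2] + geometry.axial_fov_mm / 2.0) / geometry.axial_pitch_mm).astype(np.int64),
            0,
            geometry.n_axial - 1,
        )
        return t * geometry.n_axial + zi
    raise TypeError(f"unsupported geometry {type(geometry)}")


def blur_energy(
    energies_kev: np.ndarray,
    rng: np.random.Generator,
    resolution_fwhm_at_511: float = 0.10,
) -> np.ndarray:
    """Gaussian energy blur with FWHM(E) = R * 511 * sqrt(E/511), i.e.
    1/sqrt(E) fractional-resolution scaling pinned to R at 511 keV."""
    e = np.asarray(energies_kev, dtype=float)
    if resolution_fwhm_at_511 == 0:
        return e.copy()
    fwhm = resolution_fwhm_at_511 * np.sqrt(const.E511 * np.clip(e, 0.0, None))
    return e + (fwhm / const.FWHM_PER_SIGMA) * rng.standard_normal(e.shape)


def blur_time(times_ns: np.ndarray, rng: np.random.Generator, ctr_ps: float) -> np.ndarray:
    """Per-single Gaussian jitter with sigma = CTR / (2 sqrt(2 ln 2)) / sqrt(2)
    so the pair time-difference distribution has FWHM = CTR."""
    t = np.asarray(times_ns, dtype=float)
    if ctr_ps == 0:
        return t.copy()
    sigma_ns = ctr_ps * 1e-3 / const.FWHM_PER_SIGMA / np.sqrt(2.0)
    return t + sigma_ns * rng.standard_normal(t.shape)


def apply_energy_window(singles: np.ndarray, low_kev: float = 435.0, high_kev: float = 585.0) -> np.ndarray:
    e = singles["energy"]
    return singles[(e >= low_kev) & (e <= high_kev)]


@njit(cache=True)
def _pair_windows(times, win):
    """Sliding-window pairing with killAll multiple-coincidence policy.
    Returns index pairs of windows containing exactly two singles."""
    n = times.shape[0]
    out = np.empty((n, 2), dtype=np.int64)
    m = 0
    i = 0
    while i < n:
        j = i + 1
        while j < n and times[j] - times[i] <= win:
            j += 1
        cnt = j - i
        if cnt == 2:
            out[m, 0] = i
            out[m, 1] = i + 1
            m += 1
        if cnt > 1:
            i = j
        else:
            i += 1
    return out[:m]


def sort_coincidences(
    singles: np.ndarray,
    geometry: ScannerGeometry,
    policy: CoincidencePolicy,
) -> np.ndarray:
    """Pair time-sorted singles into coincidences with truth classes."""
    t = singles["time_ns"]
    if np.any(np.diff(t) < 0):
        raise ValueError("singles must be time-sorted")
    pairs = _pair_windows(np.asarray(t, dtype=np.float64), float(policy.window_ns))
    a = singles[pairs[:, 0]]
    b = singles[pairs[:, 1]]
    if isinstance(geometry, FlatPanelGeometry):
        accept = geometry.panel_of(a["crystal"]) != geometry.panel_of(b["crystal"])
    elif isinstance(geometry, RingGeometry):
        min_sd = policy.min_sector_difference or 0
        accept = geometry.sector_difference(a["crystal"], b["crystal"]) >= min_sd
        accept &= a["crystal"] != b["crystal"]
    else:
        raise TypeError(f"unsupported geometry {type(geometry)}")
    a = a[accept]
    b = b[accept]
    out = np.empty(len(a), dtype=COINCIDENCE_DTYPE)
    out["crystal1"] = a["crystal"]
    out["crystal2"] = b["crystal"]
    out["group1"] = a["group"]
    out["group2"] = b["group"]
    out["event1"] = a["event"]
    out["event2"] = b["event"]
    out["dt_ns"] = a["time_ns"] - b["time_ns"]
    out["time_ns"] = a["time_ns"]
    same = a["event"] == b["event"]
    scattered = same & ((a["nscat"] > 0) | (b["nscat"] > 0))
    out["klass"] = np.where(same, np.where(scattered, CLASS_SCATTERED, CLASS_TRUE), CLASS_RANDOM)
    return out


def count_rates(coincidences: np.ndarray, duration_s: float):
    """(T, S, R) count rates in cps."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    k = coincidences["klass"]
    t = float((k == CLASS_TRUE).sum()) / duration_s
    s = float((k == CLASS_SCATTERED).sum()) / duration_s
    r = float((k == CLASS_RANDOM).sum()) / duration_s
    return t, s, r


def process_acquisition(
    interactions: np.ndarray,
    geometry: ScannerGeometry,
    policy: CoincidencePolicy,
    seed: int,
) -> np.ndarray:
    """Full digitizer chain from interactions to coincidences."""
    rng = np.random.default_rng(seed)
    singles = group_to_singles(
        interactions,
        geometry,
        level=policy.readout_level,
        energy_policy=policy.energy_policy,
        integration_window_ns=policy.integration_ns,
    )
    singles = singles.copy()
    singles["energy"] = blur_energy(singles["energy"], rng, policy.energy_resolution_fwhm_511)
    singles["time_ns"] = blur_time(singles["time_ns"], rng, policy.ctr_ps)
    singles = singles[np.argsort(singles["time_ns"], kind="stable")]
    singles = apply_energy_window(singles, *policy.energy_window_kev)
    return sort_coincidences(singles, geometry, policy)
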