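"""Numba Siddon ray tracing with optional TOF weighting, CSR system
matrix construction, and Monte Carlo sensitivity backprojection."""

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _trace_one(
    p1x, p1y, p1z, p2x, p2y, p2z,
    ox, oy, oz, vx, vy, vz, nx, ny, nz,
    s_tof, sigma, trunc,
    out_idx, out_w,
):
    """Siddon traversal of one LOR through the grid.

    Records (linear voxel index, intersection length [mm] x optional TOF
    Gaussian factor) into out_idx/out_w; returns the entry count.
    s_tof is the most-likely annihilation position measured from p1 along
    the ray; sigma <= 0 disables TOF weighting.
    """
    dx = p2x - p1x
    dy = p2y - p1y
    dz = p2z - p1z
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < _EPS:
        return 0
    amin = 0.0
    amax = 1.0
    p1 = (p1x, p1y, p1z)
    d = (dx, dy, dz)
    o = (ox, oy, oz)
    v = (vx, vy, vz)
    n = (nx, ny, nz)
    for a in range(3):
        if abs(d[a]) < _EPS:
            if p1[a] < o[a] or p1[a] > o[a] + n[a] * v[a]:
                return 0
        else:
            t1 = (o[a] - p1[a]) / d[a]
            t2 = (o[a] + n[a] * v[a] - p1[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > amin:
                amin = t1
            if t2 < amax:
                amax = t2
    if sigma > 0.0:
        lo = (s_tof - trunc * sigma) / length
        hi = (s_tof + trunc * sigma) / length
        if lo > amin:
            amin = lo
        if hi < amax:
            amax = hi
    if amax <= amin:
        return 0
    # voxel containing the entry point (nudged inside)
    a = amin + 1e-10
    ix = int(np.floor((p1x + a * dx - ox) / vx))
    iy = int(np.floor((p1y + a * dy - oy) / vy))
    iz = int(np.floor((p1z + a * dz - oz) / vz))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= nx:
        ix = nx - 1
    if iy >= ny:
        iy = ny - 1
    if iz >= nz:
        iz = nz - 1
    # next crossing alpha and step per axis
    if dx > _EPS:
        ax_next = ((ix + 1) * vx + ox - p1x) / dx
        dax = vx / dx
        sx = 1
    elif dx < -_EPS:
        ax_next = (ix * vx + ox - p1x) / dx
        dax = -vx / dx
        sx = -1
    else:
        ax_next = 1e30
        dax = 0.0
        sx = 0
    if dy > _EPS:
        ay_next = ((iy + 1) * vy + oy - p1y) / dy
        day = vy / dy
        sy = 1
    elif dy < -_EPS:
        ay_next = (iy * vy + oy - p1y) / dy
        day = -vy / dy
        sy = -1
    else:
        ay_next = 1e30
        day = 0.0
        sy = 0
    if dz > _EPS:
        az_next = ((iz + 1) * vz + oz - p1z) / dz
        daz = vz / dz
        sz = 1
    elif dz < -_EPS:
        az_next = (iz * vz + oz - p1z) / dz
        daz = -vz / dz
        sz = -1
    else:
        az_next = 1e30
        daz = 0.0
        sz = 0
    cnt = 0
    a_cur = amin
    inv2s2 = 0.0
    if sigma > 0.0:
        inv2s2 = 1.0 / (2.0 * sigma * sigma)
    while a_cur < amax - 1e-12:
        a_next = ax_next
        axis = 0
        if ay_next < a_next:
            a_next = ay_next
            axis = 1
        if az_next < a_next:
            a_next = az_next
            axis = 2
        if a_next > amax:
            a_next = amax
            axis = -1
        seg = (a_next - a_cur) * length
        if seg > 0.0 and 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            w = seg
            if sigma > 0.0:
                s_mid = 0.5 * (a_cur + a_next) * length
                w *= np.exp(-(s_mid - s_tof) * (s_mid - s_tof) * inv2s2)
            out_idx[cnt] = (ix * ny + iy) * nz + iz
            out_w[cnt] = w
            cnt += 1
        if axis == 0:
            ix += sx
            ax_next += dax
        elif axis == 1:
            iy += sy
            ay_next += day
        elif axis == 2:
            iz += sz
            az_next += daz
        else:
            break
        a_cur = a_next
    return cnt


@njit(cache=True)
def _perp_basis(dx, dy, dz):
    # v: z-component removed from d, u: d x v
    vx = -dx * dz
    vy = -dy * dz
    vz = 1.0 - dz * dz
    n = np.sqrt(vx * vx + vy * vy + vz * vz)
    if n < 1e-6:
        return 0.0, 1.0, 0.0, 1.0, 0.0, 0.0
    vx /= n
    vy /= n
    vz /= n
    ux = dy * vz - dz * vy
    uy = dz * vx - dx * vz
    uz = dx * vy - dy * vx
    return ux, uy, uz, vx, vy, vz


@njit(cache=True)
def _trace_subrays(
    p1x, p1y, p1z, p2x, p2y, p2z,
    ox, oy, oz, vx, vy, vz, nx, ny, nz,
    s_tof, sigma, trunc, pattern,
    out_idx, out_w,
):
    """Trace the event LOR as a bundle of parallel subrays shifted in the
    plane perpendicular to the LOR (aperture-modelling tube projector);
    pattern rows are (offset_u, offset_v) in mm.  Entries are appended
    with weight 1/K each; duplicate voxel indices are allowed."""
    n_sub = pattern.shape[0]
    dx = p2x - p1x
    dy = p2y - p1y
    dz = p2z - p1z
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < _EPS:
        return 0
    dx /= length
    dy /= length
    dz /= length
    ux, uy, uz, bvx, bvy, bvz = _perp_basis(dx, dy, dz)
    total = 0
    inv = 1.0 / n_sub
    for s in range(n_sub):
        du = pattern[s, 0]
        dv = pattern[s, 1]
        sx = du * ux + dv * bvx
        sy = du * uy + dv * bvy
        sz = du * uz + dv * bvz
        c = _trace_one(
            p1x + sx, p1y + sy, p1z + sz,
            p2x + sx, p2y + sy, p2z + sz,
            ox, oy, oz, vx, vy, vz, nx, ny, nz,
            s_tof, sigma, trunc,
            out_idx[total:], out_w[total:],
        )
        for k in range(c):
            out_w[total + k] *= inv
        total += c
    return total


@njit(cache=True)
def build_system_matrix(
    p1s, p2s, s_tofs,
    ox, oy, oz, vx, vy, vz, nx, ny, nz,
    sigma, trunc, pattern,
):
    """Two-pass CSR build over all LORs; returns (indptr, indices, weights).

    ``pattern`` holds perpendicular-plane subray offsets; a single (0, 0)
    row reproduces the plain Siddon line projector."""
    n_rays = p1s.shape[0]
    maxlen = (nx + ny + nz + 4) * pattern.shape[0]
    scratch_i = np.empty(maxlen, dtype=np.int32)
    scratch_w = np.empty(maxlen)
    indptr = np.zeros(n_rays + 1, dtype=np.int64)
    for i in range(n_rays):
        c = _trace_subrays(
            p1s[i, 0], p1s[i, 1], p1s[i, 2],
            p2s[i, 0], p2s[i, 1], p2s[i, 2],
            ox, oy, oz, vx, vy, vz, nx, ny, nz,
            s_tofs[i], sigma, trunc, pattern,
            scratch_i, scratch_w,
        )
        indptr[i + 1] = indptr[i] + c
    nnz = indptr[n_rays]
    indices = np.empty(nnz, dtype=np.int32)
    weights = np.empty(nnz, dtype=np.float32)
    for i in range(n_rays):
        c = _trace_subrays(
            p1s[i, 0], p1s[i, 1], p1s[i, 2],
            p2s[i, 0], p2s[i, 1], p2s[i, 2],
            ox, oy, oz, vx, vy, vz, nx, ny, nz,
            s_tofs[i], sigma, trunc, pattern,
            scratch_i, scratch_w,
        )
        base = indptr[i]
        for k in range(c):
            indices[base + k] = scratch_i[k]
            weights[base + k] = scratch_w[k]
    return indptr, indices, weights


@njit(cache=True)
def sensitivity_backproject(
    seed, n_samples, centers, zones, n_zone_values, min_zone_diff,
    ox, oy, oz, vx, vy, vz, nx, ny, nz,
    out_flat,
):
    """Accumulate non-TOF backprojections of uniformly sampled admissible
    detector pairs; returns the number of accepted pairs."""
    np.random.seed(seed)
    n_det = centers.shape[0]
    maxlen = nx + ny + nz + 4
    scratch_i = np.empty(maxlen, dtype=np.int32)
    scratch_w = np.empty(maxlen)
    accepted = 0
    for _ in range(n_samples):
        i = int(np.random.random() * n_det)
        j = int(np.random.random() * n_det)
        if i >= n_det:
            i = n_det - 1
        if j >= n_det:
            j = n_det - 1
        if i == j:
            continue
        dz = zones[i] - zones[j]
        if dz < 0:
            dz = -dz
        circ = dz if dz <= n_zone_values - dz else n_zone_values - dz
        if circ < min_zone_diff:
            continue
        accepted += 1
        c = _trace_one(
            centers[i, 0], centers[i, 1], centers[i, 2],
            centers[j, 0], centers[j, 1], centers[j, 2],
            ox, oy, oz, vx, vy, vz, nx, ny, nz,
            0.0, -1.0, 0.0,
            scratch_i, scratch_w,
        )
        for k in range(c):
            out_flat[scratch_i[k]] += scratch_w[k]
    return accepted
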