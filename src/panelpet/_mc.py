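"""Numba Monte Carlo kernels: annihilation-pair emission, phantom
transport (Woodcock delta tracking, Compton via Klein-Nishina rejection
sampling), and detector transport with inter-crystal scatter.

All distances in mm, energies in keV, times in ns; attenuation tables
are passed in as 1/cm (hence the factor 10 when sampling free paths).
"""

import numpy as np
from numba import njit

from .constants import C_MM_PER_NS, ELECTRON_REST_KEV

_CM_TO_MM = 10.0
_EPS = 1e-9
_MAX_CHAIN = 12  # hard cap on deposits per photon

# shape codes (mirrors phantoms.py)
_SPHERE = 0
_CYLINDER = 1
_BOX = 2
_TORSO = 3


@njit(cache=True)
def _interp_loglog(log_e_tab, log_mu_row, e):
    n = log_e_tab.shape[0]
    le = np.log(e)
    if le <= log_e_tab[0]:
        return np.exp(log_mu_row[0])
    if le >= log_e_tab[n - 1]:
        return np.exp(log_mu_row[n - 1])
    i = 0
    while log_e_tab[i + 1] < le:
        i += 1
    f = (le - log_e_tab[i]) / (log_e_tab[i + 1] - log_e_tab[i])
    return np.exp(log_mu_row[i] + f * (log_mu_row[i + 1] - log_mu_row[i]))


@njit(cache=True)
def _interp_lin(log_e_tab, row, e):
    n = log_e_tab.shape[0]
    le = np.log(e)
    if le <= log_e_tab[0]:
        return row[0]
    if le >= log_e_tab[n - 1]:
        return row[n - 1]
    i = 0
    while log_e_tab[i + 1] < le:
        i += 1
    f = (le - log_e_tab[i]) / (log_e_tab[i + 1] - log_e_tab[i])
    return row[i] + f * (row[i + 1] - row[i])


@njit(cache=True)
def _inside_prim(shape, cx, cy, cz, p0, p1, p2, x, y, z):
    dx = x - cx
    dy = y - cy
    dz = z - cz
    if shape == _SPHERE:
        return dx * dx + dy * dy + dz * dz <= p0 * p0
    if shape == _CYLINDER:
        return dx * dx + dy * dy <= p0 * p0 and abs(dz) <= p1
    if shape == _BOX:
        return abs(dx) <= p0 and abs(dy) <= p1 and abs(dz) <= p2
    if shape == _TORSO:
        ax = abs(dx)
        if ax > p1:
            ax -= p1
        else:
            ax = 0.0
        return ax * ax + dy * dy <= p0 * p0 and abs(dz) <= p2
    return False


@njit(cache=True)
def _material_at(shapes, centers, params, mats, bg, x, y, z):
    m = bg
    for i in range(shapes.shape[0]):
        if _inside_prim(
            shapes[i],
            centers[i, 0],
            centers[i, 1],
            centers[i, 2],
            params[i, 0],
            params[i, 1],
            params[i, 2],
            x,
            y,
            z,
        ):
            m = mats[i]
    return m


@njit(cache=True)
def _ray_box(ox, oy, oz, dx, dy, dz, lo, hi):
    """Slab intersection; returns (tmin, tmax), tmax < tmin means miss."""
    tmin = -1e30
    tmax = 1e30
    o = (ox, oy, oz)
    d = (dx, dy, dz)
    for a in range(3):
        if abs(d[a]) < _EPS:
            if o[a] < lo[a] or o[a] > hi[a]:
                return 1.0, -1.0
        else:
            t1 = (lo[a] - o[a]) / d[a]
            t2 = (hi[a] - o[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    return tmin, tmax


@njit(cache=True)
def _rotate(dx, dy, dz, cost, phi):
    """Rotate unit vector by polar angle acos(cost) and azimuth phi."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    # orthonormal basis (u, v) perpendicular to d
    if abs(dz) < 0.999999:
        ux = -dy
        uy = dx
        uz = 0.0
    else:
        ux = 1.0
        uy = 0.0
        uz = 0.0
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un
    uy /= un
    uz /= un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    nx = sint * (cphi * ux + sphi * vx) + cost * dx
    ny = sint * (cphi * uy + sphi * vy) + cost * dy
    nz = sint * (cphi * uz + sphi * vz) + cost * dz
    nrm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / nrm, ny / nrm, nz / nrm


@njit(cache=True)
def _sample_compton(e_kev):
    """Klein-Nishina sample by rejection on uniform cos(theta).

    Returns (scattered energy keV, cos(theta)).  The KN angular density
    ~ x^2 (x + 1/x - sin^2 theta) with x = E'/E is bounded by 2 (its
    value at theta = 0), giving a simple, exact rejection scheme.
    """
    alpha = e_kev / ELECTRON_REST_KEV
    while True:
        cost = 2.0 * np.random.random() - 1.0
        x = 1.0 / (1.0 + alpha * (1.0 - cost))
        w = x * x * (x + 1.0 / x - (1.0 - cost * cost))
        if np.random.random() * 2.0 < w:
            return e_kev * x, cost


@njit(cache=True)
def _transport_phantom(
    ox,
    oy,
    oz,
    dx,
    dy,
    dz,
    e,
    shapes,
    centers,
    params,
    mats,
    bg,
    lo,
    hi,
    matset,
    log_e_tab,
    log_mu,
    pe_frac,
    e_cutoff,
    max_scatters,
):
    """Woodcock tracking through the phantom bounding box.

    Returns (status, x, y, z, dx, dy, dz, e, nscat, path) with status 1 =
    escaped (x.. = last scatter point or emission point, path = distance
    travelled up to that point), 0 = absorbed.
    """
    nscat = 0
    path = 0.0
    if shapes.shape[0] == 0:
        return 1, ox, oy, oz, dx, dy, dz, e, 0, 0.0
    while True:
        tmin, tmax = _ray_box(ox, oy, oz, dx, dy, dz, lo, hi)
        if tmax <= max(tmin, 0.0) + _EPS:
            return 1, ox, oy, oz, dx, dy, dz, e, nscat, path
        mu_max = 0.0
        for k in range(matset.shape[0]):
            m = _interp_loglog(log_e_tab, log_mu[matset[k]], e)
            if m > mu_max:
                mu_max = m
        if mu_max <= 1e-12:
            return 1, ox, oy, oz, dx, dy, dz, e, nscat, path
        t = max(tmin, 0.0)
        interacted = False
        while True:
            t += -np.log(np.random.random()) * _CM_TO_MM / mu_max
            if t >= tmax:
                break
            px = ox + t * dx
            py = oy + t * dy
            pz = oz + t * dz
            m = _material_at(shapes, centers, params, mats, bg, px, py, pz)
            mu = _interp_loglog(log_e_tab, log_mu[m], e)
            if np.random.random() * mu_max < mu:
                interacted = True
                break
        if not interacted:
            return 1, ox, oy, oz, dx, dy, dz, e, nscat, path
        # real interaction at t
        px = ox + t * dx
        py = oy + t * dy
        pz = oz + t * dz
        m = _material_at(shapes, centers, params, mats, bg, px, py, pz)
        if np.random.random() < _interp_lin(log_e_tab, pe_frac[m], e):
            return 0, px, py, pz, dx, dy, dz, 0.0, nscat, path + t
        e_new, cost = _sample_compton(e)
        nscat += 1
        path += t
        ox, oy, oz = px, py, pz
        dx, dy, dz = _rotate(dx, dy, dz, cost, 2.0 * np.pi * np.random.random())
        e = e_new
        if e < e_cutoff or nscat > max_scatters:
            return 0, ox, oy, oz, dx, dy, dz, e, nscat, path


@njit(cache=True)
def _panel_slab_interval(ox, oy, oz, dx, dy, dz, k, n_panels, face, length, half_ext):
    """Entry/exit ray parameters for panel k's bounding slab."""
    theta = 2.0 * np.pi * k / n_panels
    ct = np.cos(theta)
    st = np.sin(theta)
    orr = ox * ct + oy * st
    drr = dx * ct + dy * st
    ou = -ox * st + oy * ct
    du = -dx * st + dy * ct
    tmin = -1e30
    tmax = 1e30
    # radial slab [face, face+length]
    if abs(drr) < _EPS:
        if orr < face or orr > face + length:
            return 1.0, -1.0
    else:
        t1 = (face - orr) / drr
        t2 = (face + length - orr) / drr
        if t1 > t2:
            t1, t2 = t2, t1
        tmin = max(tmin, t1)
        tmax = min(tmax, t2)
    # transverse and axial slabs [-half_ext, half_ext]
    for a in range(2):
        oo = ou if a == 0 else oz
        dd = du if a == 0 else dz
        if abs(dd) < _EPS:
            if oo < -half_ext or oo > half_ext:
                return 1.0, -1.0
        else:
            t1 = (-half_ext - oo) / dd
            t2 = (half_ext - oo) / dd
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
    return tmin, tmax


@njit(cache=True)
def _panel_crystal_at(px, py, pz, k, n_panels, n_side, pitch, cs, half_ext):
    """Crystal flat id at a point inside panel k's slab, or -1 in a gap."""
    theta = 2.0 * np.pi * k / n_panels
    u = -px * np.sin(theta) + py * np.cos(theta)
    col = int(np.floor((u + half_ext) / pitch))
    row = int(np.floor((pz + half_ext) / pitch))
    if col < 0 or col >= n_side or row < 0 or row >= n_side:
        return -1
    duu = u - ((col + 0.5) * pitch - half_ext)
    dzz = pz - ((row + 0.5) * pitch - half_ext)
    if abs(duu) <= cs / 2.0 and abs(dzz) <= cs / 2.0:
        return (k * n_side + row) * n_side + col
    return -1


@njit(cache=True)
def _ring_crystal_at(px, py, pz, n_trans, n_axial, axial_pitch, cs_axial, axial_half):
    theta = np.arctan2(py, px)
    if theta < 0.0:
        theta += 2.0 * np.pi
    t_idx = int(theta / (2.0 * np.pi / n_trans))
    if t_idx >= n_trans:
        t_idx = n_trans - 1
    zi = int(np.floor((pz + axial_half) / axial_pitch))
    if zi < 0 or zi >= n_axial:
        return -1
    dzz = pz - ((zi + 0.5) * axial_pitch - axial_half)
    if abs(dzz) > cs_axial / 2.0:
        return -1
    return t_idx * n_axial + zi


@njit(cache=True)
def _transport_detector(
    ox,
    oy,
    oz,
    dx,
    dy,
    dz,
    e,
    path0,
    geom_type,
    gp,
    gi,
    log_e_tab,
    log_mu_lyso,
    pe_lyso,
    e_cutoff,
    out_crystal,
    out_e,
    out_path,
    ev_nout,
):
    """Track a photon through the detector; records deposits into the
    out_* scratch arrays starting at index ev_nout; returns new count.

    geom_type 0 = flat panels, gp = (face, pitch, cs, length, half_ext),
    gi = (n_panels, n_side).
    geom_type 1 = ring, gp = (r_inner, length, axial_pitch, cs_axial,
    axial_half), gi = (n_trans, n_axial).
    """
    nout = ev_nout
    e_cur = e
    path = path0
    for _chain in range(_MAX_CHAIN):
        mu = _interp_loglog(log_e_tab, log_mu_lyso, e_cur)
        hit = False
        t_hit = 0.0
        crystal = -1
        if geom_type == 0:
            n_panels = gi[0]
            n_side = gi[1]
            face = gp[0]
            pitch = gp[1]
            cs = gp[2]
            length = gp[3]
            half_ext = gp[4]
            # gather candidate slabs, process in order of entry
            tins = np.full(4, 1e30)
            touts = np.zeros(4)
            for k in range(n_panels):
                tin, tout = _panel_slab_interval(
                    ox, oy, oz, dx, dy, dz, k, n_panels, face, length, half_ext
                )
                if tout > _EPS and tin < tout:
                    tins[k] = max(tin, _EPS)
                    touts[k] = tout
            for _ord in range(n_panels):
                kbest = -1
                tbest = 1e30
                for k in range(n_panels):
                    if tins[k] < tbest:
                        tbest = tins[k]
                        kbest = k
                if kbest < 0 or tbest >= 1e29:
                    break
                t = tins[kbest]
                tout = touts[kbest]
                tins[kbest] = 1e30
                while True:
                    t += -np.log(np.random.random()) * _CM_TO_MM / mu
                    if t >= tout:
                        break
                    cid = _panel_crystal_at(
                        ox + t * dx,
                        oy + t * dy,
                        oz + t * dz,
                        kbest,
                        n_panels,
                        n_side,
                        pitch,
                        cs,
                        half_ext,
                    )
                    if cid >= 0:
                        hit = True
                        t_hit = t
                        crystal = cid
                        break
                if hit:
                    break
        else:
            r_in = gp[0]
            length = gp[1]
            axial_pitch = gp[2]
            cs_axial = gp[3]
            axial_half = gp[4]
            n_trans = gi[0]
            n_axial = gi[1]
            r_out = r_in + length
            a = dx * dx + dy * dy
            if a < _EPS:
                break
            b = 2.0 * (ox * dx + oy * dy)
            c_out = ox * ox + oy * oy - r_out * r_out
            disc = b * b - 4.0 * a * c_out
            if disc <= 0.0:
                break
            sq = np.sqrt(disc)
            to1 = (-b - sq) / (2.0 * a)
            to2 = (-b + sq) / (2.0 * a)
            c_in = ox * ox + oy * oy - r_in * r_in
            disc_i = b * b - 4.0 * a * c_in
            # shell intervals: [to1,to2] minus (ti1,ti2)
            n_iv = 0
            iv = np.zeros((2, 2))
            if disc_i > 0.0:
                sqi = np.sqrt(disc_i)
                ti1 = (-b - sqi) / (2.0 * a)
                ti2 = (-b + sqi) / (2.0 * a)
                if ti1 > to1:
                    iv[n_iv, 0] = to1
                    iv[n_iv, 1] = min(ti1, to2)
                    n_iv += 1
                if ti2 < to2:
                    iv[n_iv, 0] = max(ti2, to1)
                    iv[n_iv, 1] = to2
                    n_iv += 1
            else:
                iv[0, 0] = to1
                iv[0, 1] = to2
                n_iv = 1
            for s in range(n_iv):
                t0 = max(iv[s, 0], _EPS)
                t1 = iv[s, 1]
                if t1 <= t0:
                    continue
                # clip by axial extent
                if abs(dz) > _EPS:
                    za = (-axial_half - oz) / dz
                    zb = (axial_half - oz) / dz
                    if za > zb:
                        za, zb = zb, za
                    t0 = max(t0, za)
                    t1 = min(t1, zb)
                elif abs(oz) > axial_half:
                    continue
                if t1 <= t0:
                    continue
                t = t0
                while True:
                    t += -np.log(np.random.random()) * _CM_TO_MM / mu
                    if t >= t1:
                        break
                    cid = _ring_crystal_at(
                        ox + t * dx,
                        oy + t * dy,
                        oz + t * dz,
                        n_trans,
                        n_axial,
                        axial_pitch,
                        cs_axial,
                        axial_half,
                    )
                    if cid >= 0:
                        hit = True
                        t_hit = t
                        crystal = cid
                        break
                if hit:
                    break
        if not hit:
            return nout
        px = ox + t_hit * dx
        py = oy + t_hit * dy
        pz = oz + t_hit * dz
        path += t_hit
        if np.random.random() < _interp_lin(log_e_tab, pe_lyso, e_cur):
            out_crystal[nout] = crystal
            out_e[nout] = e_cur
            out_path[nout] = path
            nout += 1
            return nout
        e_new, cost = _sample_compton(e_cur)
        out_crystal[nout] = crystal
        out_e[nout] = e_cur - e_new
        out_path[nout] = path
        nout += 1
        if e_new < e_cutoff:
            # local absorption of the low-energy remainder
            out_crystal[nout] = crystal
            out_e[nout] = e_new
            out_path[nout] = path
            nout += 1
            return nout
        dx, dy, dz = _rotate(dx, dy, dz, cost, 2.0 * np.pi * np.random.random())
        ox, oy, oz = px, py, pz
        e_cur = e_new
    return nout


@njit(cache=True)
def run_chunk(
    seed,
    pts,
    times_ns,
    ev0,
    shapes,
    centers,
    params,
    mats,
    bg,
    lo,
    hi,
    matset,
    geom_type,
    gp,
    gi,
    log_e_tab,
    log_mu,
    pe_frac,
    mat_lyso,
    sigma_nc_rad,
    e_cutoff,
    max_scatters,
    out_ev,
    out_crystal,
    out_e,
    out_t,
    out_nscat,
):
    """Simulate one block of decays; returns number of recorded deposits."""
    np.random.seed(seed)
    nout = 0
    n = pts.shape[0]
    cap = out_ev.shape[0] - 2 * _MAX_CHAIN
    scratch_c = np.empty(_MAX_CHAIN + 1, dtype=np.int64)
    scratch_e = np.empty(_MAX_CHAIN + 1)
    scratch_p = np.empty(_MAX_CHAIN + 1)
    log_mu_lyso = log_mu[mat_lyso]
    pe_lyso = pe_frac[mat_lyso]
    for i in range(n):
        if nout >= cap:
            break
        # isotropic first photon
        cost = 2.0 * np.random.random() - 1.0
        phi = 2.0 * np.pi * np.random.random()
        sint = np.sqrt(1.0 - cost * cost)
        d1x = sint * np.cos(phi)
        d1y = sint * np.sin(phi)
        d1z = cost
        for ph in range(2):
            if ph == 0:
                dx, dy, dz = d1x, d1y, d1z
            else:
                dx, dy, dz = -d1x, -d1y, -d1z
                if sigma_nc_rad > 0.0:
                    delta = sigma_nc_rad * np.random.standard_normal()
                    dx, dy, dz = _rotate(
                        dx, dy, dz, np.cos(delta), 2.0 * np.pi * np.random.random()
                    )
            status, x, y, z, ndx, ndy, ndz, e, nscat, path = _transport_phantom(
                pts[i, 0],
                pts[i, 1],
                pts[i, 2],
                dx,
                dy,
                dz,
                511.0,
                shapes,
                centers,
                params,
                mats,
                bg,
                lo,
                hi,
                matset,
                log_e_tab,
                log_mu,
                pe_frac,
                e_cutoff,
                max_scatters,
            )
            if status == 0:
                continue
            ndep = _transport_detector(
                x,
                y,
                z,
                ndx,
                ndy,
                ndz,
                e,
                path,
                geom_type,
                gp,
                gi,
                log_e_tab,
                log_mu_lyso,
                pe_lyso,
                e_cutoff,
                scratch_c,
                scratch_e,
                scratch_p,
                0,
            )
            for k in range(ndep):
                out_ev[nout] = ev0 + i
                out_crystal[nout] = scratch_c[k]
                out_e[nout] = scratch_e[k]
                out_t[nout] = times_ns[i] + scratch_p[k] / C_MM_PER_NS
                out_nscat[nout] = nscat
                nout += 1
    return nout
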