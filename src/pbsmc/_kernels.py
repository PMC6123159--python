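"""Numba-accelerated inner stepping loop for the transport engine.

Scalar per-particle loops compiled with numba; the physics is identical to the
vectorized numpy path in :mod:`pbsmc.transport` (Bethe mean loss + Bohr
straggling, Highland MCS, nonelastic removal with one effective secondary).
Randomness comes from an internal xorshift64* stream combined with a
stratified inverse-CDF lookup table for Gaussian deviates (the scheme fast MC
dose engines use), so results are deterministic for a given seed (but not
bit-identical to the numpy path, which uses numpy Generators).

All energy lookups share a uniform log-energy grid; the log is computed once
per step and reused across tables.  The MCS deflection uses the small-angle
update (exact rotation is reserved for the rare wide-angle secondary
emission).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_MP = 938.27208816

#: stratified inverse-CDF table for Gaussian sampling (4-sigma truncation);
#: random indexing by the xorshift64* stream gives i.i.d. standard normals
_NORM_TABLE_BITS = 16


def make_norm_table() -> np.ndarray:
    from scipy.special import ndtri

    n = 1 << _NORM_TABLE_BITS
    return ndtri((np.arange(n) + 0.5) / n)


_MULT = np.uint64(2685821657736338717)
_INV53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _rng_next(s):
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    return s


@njit(cache=True, inline="always")
def _rng_norm(s, tbl):
    s = _rng_next(s)
    return tbl[(s * _MULT) >> np.uint64(64 - _NORM_TABLE_BITS)], s


@njit(cache=True, inline="always")
def _rng_unif(s):
    s = _rng_next(s)
    return float((s * _MULT) >> np.uint64(11)) * _INV53, s


@njit(cache=True, inline="always", fastmath=True)
def _findex(e, loge0, dloge, npts):
    f = (math.log(e) - loge0) / dloge
    if f < 0.0:
        f = 0.0
    elif f > npts - 1.000001:
        f = npts - 1.000001
    return f


@njit(cache=True, inline="always", fastmath=True)
def _interp_f(table, mid, f):
    k = int(f)
    fr = f - k
    return table[mid, k] * (1.0 - fr) + table[mid, k + 1] * fr


@njit(cache=True, inline="always", fastmath=True)
def _interp1_f(table, f):
    k = int(f)
    fr = f - k
    return table[k] * (1.0 - fr) + table[k + 1] * fr


@njit(cache=True, inline="always", fastmath=True)
def _rotate_scalar(dx, dy, dz, tx, ty):
    """Exact rotation by transverse angle components (used for secondaries)."""
    theta = math.sqrt(tx * tx + ty * ty)
    if theta < 1e-12:
        return dx, dy, dz
    n1 = math.sqrt(dz * dz + dy * dy)
    if n1 < 1e-12:
        e1x, e1y, e1z = 0.0, 1.0, 0.0
    else:
        e1x, e1y, e1z = 0.0, dz / n1, -dy / n1
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x
    ux = (tx * e1x + ty * e2x) / theta
    uy = (tx * e1y + ty * e2y) / theta
    uz = (tx * e1z + ty * e2z) / theta
    ct = math.cos(theta)
    st = math.sin(theta)
    ndx = dx * ct + ux * st
    ndy = dy * ct + uy * st
    ndz = dz * ct + uz * st
    norm = math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
    return ndx / norm, ndy / norm, ndz / norm


@njit(cache=True, inline="always", fastmath=True)
def _deflect_small(dx, dy, dz, tx, ty):
    """Small-angle deflection: d' = normalize(d + tx e1 + ty e2)."""
    n1 = math.sqrt(dz * dz + dy * dy)
    if n1 < 1e-12:
        e1y, e1z = 1.0, 0.0
    else:
        e1y, e1z = dz / n1, -dy / n1
    # e2 = d x e1 with e1x = 0
    e2x = dy * e1z - dz * e1y
    e2y = -dx * e1z
    e2z = dx * e1y
    ndx = dx + ty * e2x
    ndy = dy + tx * e1y + ty * e2y
    ndz = dz + tx * e1z + ty * e2z
    inv = 1.0 / math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
    return ndx * inv, ndy * inv, ndz * inv


@njit(cache=True, fastmath=True)
def step_region_kernel(
    # particle arrays (modified in place; exits compacted to the front)
    x, y, z, dx, dy, dz, e, w, sp,
    # region
    z_bot,
    is_voxel, vox_ids, vox_rho, vox_ox, vox_oy, vox_oz,
    vox_sx, vox_sy, vox_sz, vox_nx, vox_ny, vox_nz, vox_min_size,
    uni_mid, uni_rho,
    # material tables on uniform log-energy grid
    loge0, dloge, npts, s_mass, r_mass, rsp_mass, x0_mass, zoa,
    # nuclear model
    allow_nuclear, nuc_sig_grid, sec_enabled, w_sec, efr_lo, efr_hi,
    ang100_rad, ang_exp, ang_max_rad, f_local,
    # step control
    max_step, min_step, range_frac, cutoff, lat_half,
    # dose grid scorer
    dg_on, dg_energy, dg_sumsq, dg_unc, dg_ox, dg_oy, dg_oz,
    dg_sx, dg_sy, dg_sz, dg_nx, dg_ny, dg_nz,
    # IDD scorer
    idd_on, idd_energy, idd_zsurf, idd_bin, idd_r2, idd_nbins,
    # plane scorer
    pl_on, pl_z, pl_flu, pl_eflu, pl_half, pl_bin, pl_nbins,
    # secondary output buffers
    sx_, sy_, sz_, sdx_, sdy_, sdz_, se_, sw_,
    norm_tbl, seed,
):
    st = (np.uint64(seed) * np.uint64(6364136223846793005)
          + np.uint64(1442695040888963407)) | np.uint64(1)
    for _ in range(4):
        st = _rng_next(st)
    n = x.size
    n_exit = 0
    n_sec = 0
    deposited = 0.0
    esc_lat = 0.0
    esc_neut = 0.0
    sec_resid = 0.0

    for i in range(n):
        px = x[i]
        py = y[i]
        pz = z[i]
        ddx = dx[i]
        ddy = dy[i]
        ddz = dz[i]
        ei = e[i]
        wi = w[i]
        spi = sp[i]
        exited = False

        while True:
            if is_voxel:
                ix = int((px - vox_ox) / vox_sx)
                iy = int((py - vox_oy) / vox_sy)
                iz = int((pz - vox_oz) / vox_sz)
                if ix < 0:
                    ix = 0
                elif ix >= vox_nx:
                    ix = vox_nx - 1
                if iy < 0:
                    iy = 0
                elif iy >= vox_ny:
                    iy = vox_ny - 1
                if iz < 0:
                    iz = 0
                elif iz >= vox_nz:
                    iz = vox_nz - 1
                mid = vox_ids[ix, iy, iz]
                rho = vox_rho[ix, iy, iz]
                if rho < 1e-6:
                    rho = 1e-6
            else:
                mid = uni_mid
                rho = uni_rho

            fe = _findex(ei, loge0, dloge, npts)
            rres_mm = _interp_f(r_mass, mid, fe) / rho * 10.0
            step = range_frac * rres_mm
            if step > max_step:
                step = max_step
            if step < min_step:
                step = min_step
            if is_voxel and step > vox_min_size:
                step = vox_min_size
            sgeo = (pz - z_bot) / (-ddz)
            at_b = sgeo <= step
            s = sgeo if at_b else step
            if s < 0.0:
                s = 0.0
            s_cm = s * 0.1

            s1 = _interp_f(s_mass, mid, fe) * rho
            ehalf = ei - 0.5 * s1 * s_cm
            if ehalf < 0.6:
                ehalf = 0.6
            fh = _findex(ehalf, loge0, dloge, npts)
            de = _interp_f(s_mass, mid, fh) * rho * s_cm
            g, st = _rng_norm(st, norm_tbl)
            de += math.sqrt(0.1569 * zoa[mid] * rho * s_cm) * g
            if de < 0.0:
                de = 0.0
            if de > ei:
                de = ei
            enew = ei - de
            stopped = enew < cutoff

            xm = px + ddx * (s * 0.5)
            ym = py + ddy * (s * 0.5)
            zm = pz + ddz * (s * 0.5)
            edep = (ei if stopped else de) * wi

            event = False
            if allow_nuclear and not stopped:
                rsp = _interp_f(rsp_mass, mid, fh)
                sig = _interp1_f(nuc_sig_grid, fh)
                u, st = _rng_unif(st)
                if u < sig * s_cm * rsp * rho:
                    event = True
                    eav = enew
                    u, st = _rng_unif(st)
                    fr = efr_lo + (efr_hi - efr_lo) * u
                    esec = fr * eav
                    edep += f_local * (eav - esec) * wi
                    esc_neut += (1.0 - f_local) * (eav - esec) * wi
                    sec_resid += esec * wi * (1.0 - w_sec)
                    if sec_enabled:
                        if esec >= cutoff:
                            sigang = ang100_rad * (
                                100.0 / (eav if eav > 1.0 else 1.0)
                            ) ** ang_exp
                            if sigang > ang_max_rad:
                                sigang = ang_max_rad
                            g, st = _rng_norm(st, norm_tbl)
                            stx = g * sigang
                            g, st = _rng_norm(st, norm_tbl)
                            sty = g * sigang
                            ndx, ndy, ndz = _rotate_scalar(ddx, ddy, ddz, stx, sty)
                            sx_[n_sec] = xm
                            sy_[n_sec] = ym
                            sz_[n_sec] = zm
                            sdx_[n_sec] = ndx
                            sdy_[n_sec] = ndy
                            sdz_[n_sec] = ndz
                            se_[n_sec] = esec
                            sw_[n_sec] = wi * w_sec
                            n_sec += 1
                        else:
                            edep += esec * wi * w_sec
                    else:
                        sec_resid += esec * wi * w_sec

            if edep > 0.0:
                deposited += edep
                if dg_on:
                    fx = xm - dg_ox
                    fy = ym - dg_oy
                    fz = zm - dg_oz
                    if fx >= 0.0 and fy >= 0.0 and fz >= 0.0:
                        gx = int(fx / dg_sx)
                        gy = int(fy / dg_sy)
                        gz = int(fz / dg_sz)
                        if gx < dg_nx and gy < dg_ny and gz < dg_nz:
                            dg_energy[gx, gy, gz] += edep
                            if dg_unc:
                                dg_sumsq[gx, gy, gz] += edep * edep
                if idd_on:
                    depth = idd_zsurf - zm
                    if depth >= 0.0:
                        ib = int(depth / idd_bin)
                        if ib < idd_nbins and xm * xm + ym * ym <= idd_r2:
                            idd_energy[ib] += edep

            # MCS (small-angle deflection)
            xrad = rho * s_cm / x0_mass[mid]
            if xrad > 0.0:
                pv = ehalf * (ehalf + 2.0 * _MP) / (ehalf + _MP)
                th0 = 14.1 / pv * math.sqrt(xrad) * (1.0 + math.log10(xrad) / 9.0)
                if th0 > 0.0:
                    g, st = _rng_norm(st, norm_tbl)
                    mtx = g * th0
                    g, st = _rng_norm(st, norm_tbl)
                    mty = g * th0
                    ddx, ddy, ddz = _deflect_small(ddx, ddy, ddz, mtx, mty)

            z_prev = pz
            x_prev = px
            y_prev = py
            px += ddx * s
            py += ddy * s
            pz = z_bot if at_b else pz + ddz * s

            if pl_on:
                for p in range(pl_z.size):
                    zp = pl_z[p]
                    if z_prev >= zp and pz < zp:
                        t = (z_prev - zp) / (z_prev - pz)
                        xc = x_prev + t * (px - x_prev)
                        yc = y_prev + t * (py - y_prev)
                        fx = xc + pl_half
                        fy = yc + pl_half
                        if fx >= 0.0 and fy >= 0.0:
                            bx = int(fx / pl_bin)
                            by = int(fy / pl_bin)
                            if bx < pl_nbins and by < pl_nbins:
                                pl_flu[p, bx, by] += wi
                                pl_eflu[p, bx, by] += wi * enew

            if stopped or event:
                break
            if abs(px) > lat_half or abs(py) > lat_half or ddz >= -1e-3:
                esc_lat += enew * wi
                break
            ei = enew
            if at_b:
                exited = True
                break

        if exited:
            x[n_exit] = px
            y[n_exit] = py
            z[n_exit] = pz
            dx[n_exit] = ddx
            dy[n_exit] = ddy
            dz[n_exit] = ddz
            e[n_exit] = ei
            w[n_exit] = wi
            sp[n_exit] = spi
            n_exit += 1

    return n_exit, n_sec, deposited, esc_lat, esc_neut, sec_resid
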