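"""Numba-compiled inner loop of the MC docking stages.

The kernel mirrors the stage semantics exactly: uniform move-kind choice,
uniform magnitudes within the caps, Metropolis acceptance on LGFE + weighted
internal energy with a linear temperature ramp, incumbent-best tracking by
LGFE.  Scoring is nearest-voxel by default with an optional trilinear mode;
the exclusion lookup is always nearest-voxel.  Numba's internal MT19937
stream is seeded per stage call, so runs are reproducible given the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _score(coords, heavy, midx, stack, excl, origin, inv_spacing, dims,
           penalty, trilinear, com, confine_center, confine_radius):
    lg = 0.0
    nx, ny, nz = dims[0], dims[1], dims[2]
    for a in range(heavy.shape[0]):
        i = heavy[a]
        ux = (coords[i, 0] - origin[0]) * inv_spacing
        uy = (coords[i, 1] - origin[1]) * inv_spacing
        uz = (coords[i, 2] - origin[2]) * inv_spacing
        ix = int(np.floor(ux + 0.5))
        iy = int(np.floor(uy + 0.5))
        iz = int(np.floor(uz + 0.5))
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            if excl[ix, iy, iz]:
                lg += penalty
                continue
            m = midx[a]
            if m < 0:
                continue
            if not trilinear:
                lg += stack[m, ix, iy, iz]
            else:
                fx = int(np.floor(ux))
                fy = int(np.floor(uy))
                fz = int(np.floor(uz))
                tx = ux - fx
                ty = uy - fy
                tz = uz - fz
                for cx in range(2):
                    wx = tx if cx else 1.0 - tx
                    jx = fx + cx
                    if jx < 0 or jx >= nx:
                        continue
                    for cy in range(2):
                        wy = ty if cy else 1.0 - ty
                        jy = fy + cy
                        if jy < 0 or jy >= ny:
                            continue
                        for cz in range(2):
                            wz = tz if cz else 1.0 - tz
                            jz = fz + cz
                            if jz < 0 or jz >= nz:
                                continue
                            lg += wx * wy * wz * stack[m, jx, jy, jz]
        elif trilinear:
            # partially-inside trilinear support mirrors the python path:
            # corners outside the lattice contribute bulk 0
            m = midx[a]
            if m < 0:
                continue
            fx = int(np.floor(ux))
            fy = int(np.floor(uy))
            fz = int(np.floor(uz))
            tx = ux - fx
            ty = uy - fy
            tz = uz - fz
            for cx in range(2):
                wx = tx if cx else 1.0 - tx
                jx = fx + cx
                if jx < 0 or jx >= nx:
                    continue
                for cy in range(2):
                    wy = ty if cy else 1.0 - ty
                    jy = fy + cy
                    if jy < 0 or jy >= ny:
                        continue
                    for cz in range(2):
                        wz = tz if cz else 1.0 - tz
                        jz = fz + cz
                        if jz < 0 or jz >= nz:
                            continue
                        lg += wx * wy * wz * stack[m, jx, jy, jz]
    if confine_radius > 0.0:
        dx = com[0] - confine_center[0]
        dy = com[1] - confine_center[1]
        dz = com[2] - confine_center[2]
        if dx * dx + dy * dy + dz * dz > confine_radius * confine_radius:
            lg += penalty
    return lg


@njit(cache=True, fastmath=False)
def _intra(coords, tor_idx, nb_pairs, barrier, clash_d, clash_k):
    e = 0.0
    for t in range(tor_idx.shape[0]):
        i0, i1, i2, i3 = tor_idx[t, 0], tor_idx[t, 1], tor_idx[t, 2], tor_idx[t, 3]
        b0 = coords[i1] - coords[i0]
        b1 = coords[i2] - coords[i1]
        b2 = coords[i3] - coords[i2]
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        b1n = b1 / np.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
        m1 = np.cross(n1, b1n)
        phi = np.arctan2(m1 @ n2, n1 @ n2)
        e += 0.5 * barrier * (1.0 + np.cos(3.0 * phi))
    for p in range(nb_pairs.shape[0]):
        i, j = nb_pairs[p, 0], nb_pairs[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < clash_d:
            e += clash_k * (clash_d - d) ** 2
    return e


@njit(cache=True, fastmath=False)
def _com(coords, masses, mass_sum):
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(coords.shape[0]):
        cx += masses[i] * coords[i, 0]
        cy += masses[i] * coords[i, 1]
        cz += masses[i] * coords[i, 2]
    return np.array([cx / mass_sum, cy / mass_sum, cz / mass_sum])


@njit(cache=True, fastmath=False)
def mc_stage(coords0, n_steps, t_start, t_end, max_t, max_r, max_d,
             stack, excl, midx, heavy, origin, spacing, dims,
             penalty, w_intra, trilinear,
             masses, tor_idx, tor_jk, ds_flat, ds_off, nb_pairs,
             barrier, clash_d, clash_k,
             confine_center, confine_radius,
             kB, seed):
    """One MC stage; returns (final coords, lgfe, intra, best coords, lgfe, intra)."""
    np.random.seed(seed)
    inv_spacing = 1.0 / spacing
    n_dih = tor_jk.shape[0]
    n_kinds = 3 if n_dih > 0 else 2
    mass_sum = masses.sum()
    coords = coords0.copy()
    com = _com(coords, masses, mass_sum)
    cur_intra = _intra(coords, tor_idx, nb_pairs, barrier, clash_d, clash_k)
    cur_lgfe = _score(coords, heavy, midx, stack, excl, origin, inv_spacing,
                      dims, penalty, trilinear, com, confine_center, confine_radius)
    cur_e = cur_lgfe + w_intra * cur_intra
    best_coords = coords.copy()
    best_lgfe = cur_lgfe
    best_intra = cur_intra
    ramp = (t_end - t_start) / (n_steps - 1) if n_steps > 1 else 0.0
    deg2rad = np.pi / 180.0
    new_coords = coords.copy()
    all_idx = np.arange(coords.shape[0], dtype=np.int64)
    for step in range(n_steps):
        kind = np.random.randint(0, n_kinds)
        new_intra = cur_intra
        if kind == 0:
            vx = np.random.normal()
            vy = np.random.normal()
            vz = np.random.normal()
            norm = np.sqrt(vx * vx + vy * vy + vz * vz)
            mag = np.random.uniform(0.0, max_t) / norm
            for i in range(coords.shape[0]):
                new_coords[i, 0] = coords[i, 0] + vx * mag
                new_coords[i, 1] = coords[i, 1] + vy * mag
                new_coords[i, 2] = coords[i, 2] + vz * mag
            new_com = _com(new_coords, masses, mass_sum)
        elif kind == 1:
            ax = np.random.normal()
            ay = np.random.normal()
            az = np.random.normal()
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            ax /= norm
            ay /= norm
            az /= norm
            ang = np.random.uniform(-max_r, max_r) * deg2rad
            c = np.cos(ang)
            s = np.sin(ang)
            com = _com(coords, masses, mass_sum)
            _rotate_about(coords, new_coords, all_idx,
                          com, ax, ay, az, c, s)
            new_com = com
        else:
            ti = np.random.randint(0, n_dih)
            j = tor_jk[ti, 0]
            k = tor_jk[ti, 1]
            ax = coords[k, 0] - coords[j, 0]
            ay = coords[k, 1] - coords[j, 1]
            az = coords[k, 2] - coords[j, 2]
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            ax /= norm
            ay /= norm
            az /= norm
            ang = np.random.uniform(-max_d, max_d) * deg2rad
            c = np.cos(ang)
            s = np.sin(ang)
            for i in range(coords.shape[0]):
                new_coords[i, 0] = coords[i, 0]
                new_coords[i, 1] = coords[i, 1]
                new_coords[i, 2] = coords[i, 2]
            _rotate_about(coords, new_coords, ds_flat[ds_off[ti]:ds_off[ti + 1]],
                          coords[k], ax, ay, az, c, s)
            new_intra = _intra(new_coords, tor_idx, nb_pairs, barrier,
                               clash_d, clash_k)
            new_com = _com(new_coords, masses, mass_sum)
        new_lgfe = _score(new_coords, heavy, midx, stack, excl, origin,
                          inv_spacing, dims, penalty, trilinear, new_com,
                          confine_center, confine_radius)
        new_e = new_lgfe + w_intra * new_intra
        de = new_e - cur_e
        accept = False
        if de <= 0.0:
            accept = True
        else:
            temp = t_start + ramp * step
            if temp > 0.0 and np.random.random() < np.exp(-de / (kB * temp)):
                accept = True
        if accept:
            tmp = coords
            coords = new_coords
            new_coords = tmp
            cur_lgfe = new_lgfe
            cur_intra = new_intra
            cur_e = new_e
            if cur_lgfe < best_lgfe:
                best_coords = coords.copy()
                best_lgfe = cur_lgfe
                best_intra = cur_intra
    return coords, cur_lgfe, cur_intra, best_coords, best_lgfe, best_intra


@njit(cache=True, fastmath=False)
def _rotate_about(src, dst, indices, pivot, ax, ay, az, c, s):
    """Rodrigues rotation of selected points about a pivot, src -> dst."""
    oc = 1.0 - c
    r00 = c + ax * ax * oc
    r01 = ax * ay * oc - az * s
    r02 = ax * az * oc + ay * s
    r10 = ay * ax * oc + az * s
    r11 = c + ay * ay * oc
    r12 = ay * az * oc - ax * s
    r20 = az * ax * oc - ay * s
    r21 = az * ay * oc + ax * s
    r22 = c + az * az * oc
    for n in range(indices.shape[0]):
        i = indices[n]
        px = src[i, 0] - pivot[0]
        py = src[i, 1] - pivot[1]
        pz = src[i, 2] - pivot[2]
        dst[i, 0] = r00 * px + r01 * py + r02 * pz + pivot[0]
        dst[i, 1] = r10 * px + r11 * py + r12 * pz + pivot[1]
        dst[i, 2] = r20 * px + r21 * py + r22 * pz + pivot[2]
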