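"""Langevin dynamics engine for desk-scale coarse-grained chromatin.

Integration uses the BAOAB splitting of Langevin dynamics, which samples
configurations accurately even at large timesteps and damping.  Nonbonded
forces run off a Verlet pair list (skin 0.3 sigma) rebuilt on a displacement
criterion; the list itself is built by an O(n^2) scan for small systems and
by cell binning for large ones.  Everything hot is numba-compiled.

Units: Å, kcal/mol, unit mass; the ns-per-timestep mapping is metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .forcefield import Topology
from .params import SIGMA, SimulationConfig, debye_length, kbt, COULOMB_KCAL

SKIN = 0.3 * SIGMA
FORCE_BLOWUP = 1.0e5     # kcal/mol/Å; any larger |F| component aborts the run


class EngineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _min_image(d, box, pbc):
    if pbc:
        for k in range(3):
            if d[k] > 0.5 * box[k]:
                d[k] -= box[k]
            elif d[k] < -0.5 * box[k]:
                d[k] += box[k]
    return d


@njit(cache=True)
def _build_pairs_n2(pos, box, pbc, rlist2, excl_keys, pair_i, pair_j):
    n = pos.shape[0]
    m = 0
    cap = pair_i.shape[0]
    d = np.empty(3)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(3):
                d[k] = pos[j, k] - pos[i, k]
            _min_image(d, box, pbc)
            r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
            if r2 < rlist2:
                key = np.int64(i) * n + j
                lo = np.searchsorted(excl_keys, key)
                if lo < excl_keys.shape[0] and excl_keys[lo] == key:
                    continue
                if m >= cap:
                    return -1
                pair_i[m] = i
                pair_j[m] = j
                m += 1
    return m


@njit(cache=True)
def _build_pairs_cells(pos, box, pbc, rlist, excl_keys, pair_i, pair_j):
    n = pos.shape[0]
    rlist2 = rlist * rlist
    # bounding region
    if pbc:
        ox, oy, oz = -0.5 * box[0], -0.5 * box[1], -0.5 * box[2]
        lx, ly, lz = box[0], box[1], box[2]
    else:
        ox = pos[:, 0].min() - 1.0
        oy = pos[:, 1].min() - 1.0
        oz = pos[:, 2].min() - 1.0
        lx = pos[:, 0].max() - ox + 2.0
        ly = pos[:, 1].max() - oy + 2.0
        lz = pos[:, 2].max() - oz + 2.0
    ncx = max(1, int(lx / rlist))
    ncy = max(1, int(ly / rlist))
    ncz = max(1, int(lz / rlist))
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = pos[i, 0] - ox
        y = pos[i, 1] - oy
        z = pos[i, 2] - oz
        if pbc:
            x -= box[0] * math.floor(x / box[0])
            y -= box[1] * math.floor(y / box[1])
            z -= box[2] * math.floor(z / box[2])
        cx = min(ncx - 1, max(0, int(x / lx * ncx)))
        cy = min(ncy - 1, max(0, int(y / ly * ncy)))
        cz = min(ncz - 1, max(0, int(z / lz * ncz)))
        c = (cz * ncy + cy) * ncx + cx
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i
    m = 0
    cap = pair_i.shape[0]
    d = np.empty(3)
    for i in range(n):
        c = cell_of[i]
        cz0 = c // (ncx * ncy)
        cy0 = (c // ncx) % ncy
        cx0 = c % ncx
        for dz in range(-1, 2):
            for dy in range(-1, 2):
                for dx in range(-1, 2):
                    cx = cx0 + dx
                    cy = cy0 + dy
                    cz = cz0 + dz
                    if pbc:
                        cx %= ncx
                        cy %= ncy
                        cz %= ncz
                    elif cx < 0 or cy < 0 or cz < 0 or cx >= ncx \
                            or cy >= ncy or cz >= ncz:
                        continue
                    j = head[(cz * ncy + cy) * ncx + cx]
                    while j >= 0:
                        if j > i:
                            for k in range(3):
                                d[k] = pos[j, k] - pos[i, k]
                            _min_image(d, box, pbc)
                            r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
                            if r2 < rlist2:
                                key = np.int64(i) * n + j
                                lo = np.searchsorted(excl_keys, key)
                                if not (lo < excl_keys.shape[0]
                                        and excl_keys[lo] == key):
                                    if m >= cap:
                                        return -1
                                    pair_i[m] = i
                                    pair_j[m] = j
                                    m += 1
                        j = nxt[j]
    return m


@njit(cache=True)
def _forces(pos, forces, pair_i, pair_j, n_pairs, types, eps_mat, charges,
            sigma, lj_cut, dh_pref, dh_lambda, dh_cut,
            bonds, bond_r0, bond_k, morse, morse_d, morse_a, morse_r0,
            angles, angle_t0, angle_k,
            bmode, bparam, softcore,
            r_ga, r_ga_off, r_gb, r_gb_off, r_k, r_c,
            o_idx, o_off, o_k, o_tilt, box, pbc):
    """Fill ``forces``; return (potential energy, current colvar value).

    Restraints are harmonic on centroid-centroid distances of bead-group
    pairs (flattened with offset arrays); the reported colvar is the mean
    of the restrained distances.  Optional orientation restraints
    E = k (1 - (u1.u2)^2) align pairs of body axes, each axis the unit
    vector between the centroids of a bottom and a top marker group
    (o_idx/o_off pack four groups per restraint: bot1, top1, bot2, top2);
    with the tilt flag set, the axes are additionally aligned with the
    separation direction of the first distance restraint (coaxiality).
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    pe = 0.0
    d = np.empty(3)

    lj_cut2 = lj_cut * lj_cut
    dh_cut2 = dh_cut * dh_cut
    s6c = (sigma / lj_cut) ** 6
    lj_shift_unit = 4.0 * (s6c * s6c - s6c)      # per unit eps
    wca_cut = sigma * 2.0 ** (1.0 / 6.0)
    r_soft = 0.8 * sigma
    # capped-WCA force magnitude at r_soft (eps = 1)
    s6s = (sigma / r_soft) ** 6
    f_soft = 24.0 * (2.0 * s6s * s6s - s6s) / r_soft
    u_soft = 4.0 * (s6s * s6s - s6s) + 1.0

    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        for k in range(3):
            d[k] = pos[j, k] - pos[i, k]
        _min_image(d, box, pbc)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        if softcore:
            if r2 >= wca_cut * wca_cut:
                continue
            r = math.sqrt(r2)
            if r < r_soft:
                pe += u_soft + f_soft * (r_soft - r)
                fr = f_soft
            else:
                s6 = (sigma / r) ** 6
                pe += 4.0 * (s6 * s6 - s6) + 1.0
                fr = 24.0 * (2.0 * s6 * s6 - s6) / r
            for k in range(3):
                forces[i, k] -= fr * d[k] / r
                forces[j, k] += fr * d[k] / r
            continue
        if r2 >= lj_cut2:
            continue
        r = math.sqrt(r2)
        eps = eps_mat[types[i], types[j]]
        s6 = (sigma / r) ** 6
        pe += 4.0 * eps * (s6 * s6 - s6) - eps * lj_shift_unit
        fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r
        qq = charges[i] * charges[j]
        if qq != 0.0 and r2 < dh_cut2:
            e_r = dh_pref * qq * math.exp(-r / dh_lambda) / r
            e_c = dh_pref * qq * math.exp(-dh_cut / dh_lambda) / dh_cut
            pe += e_r - e_c
            fr += e_r * (1.0 / r + 1.0 / dh_lambda)
        for k in range(3):
            forces[i, k] -= fr * d[k] / r
            forces[j, k] += fr * d[k] / r

    # harmonic bonds: E = k (r - r0)^2
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        for k in range(3):
            d[k] = pos[j, k] - pos[i, k]
        _min_image(d, box, pbc)
        r = math.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        dr = r - bond_r0[b]
        pe += bond_k[b] * dr * dr
        fr = -2.0 * bond_k[b] * dr
        for k in range(3):
            forces[i, k] -= fr * d[k] / r
            forces[j, k] += fr * d[k] / r

    # Morse bonds: E = D (1 - exp(-a (r - r0)))^2
    for b in range(morse.shape[0]):
        i = morse[b, 0]
        j = morse[b, 1]
        for k in range(3):
            d[k] = pos[j, k] - pos[i, k]
        _min_image(d, box, pbc)
        r = math.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        ex = math.exp(-morse_a[b] * (r - morse_r0[b]))
        pe += morse_d[b] * (1.0 - ex) * (1.0 - ex)
        fr = -2.0 * morse_d[b] * morse_a[b] * (1.0 - ex) * ex
        for k in range(3):
            forces[i, k] -= fr * d[k] / r
            forces[j, k] += fr * d[k] / r

    # angles: E = k (theta - theta0)^2
    va = np.empty(3)
    vc = np.empty(3)
    for t in range(angles.shape[0]):
        ia = angles[t, 0]
        ib = angles[t, 1]
        ic = angles[t, 2]
        for k in range(3):
            va[k] = pos[ia, k] - pos[ib, k]
            vc[k] = pos[ic, k] - pos[ib, k]
        _min_image(va, box, pbc)
        _min_image(vc, box, pbc)
        ra = math.sqrt(va[0] ** 2 + va[1] ** 2 + va[2] ** 2)
        rc = math.sqrt(vc[0] ** 2 + vc[1] ** 2 + vc[2] ** 2)
        cs = (va[0] * vc[0] + va[1] * vc[1] + va[2] * vc[2]) / (ra * rc)
        if cs > 1.0:
            cs = 1.0
        elif cs < -1.0:
            cs = -1.0
        th = math.acos(cs)
        dth = th - angle_t0[t]
        pe += angle_k[t] * dth * dth
        sn = math.sqrt(1.0 - cs * cs)
        if sn < 1e-8:
            sn = 1e-8
        coef = 2.0 * angle_k[t] * dth / sn
        for k in range(3):
            fa = coef * (vc[k] / (ra * rc) - cs * va[k] / (ra * ra))
            fc = coef * (va[k] / (ra * rc) - cs * vc[k] / (rc * rc))
            forces[ia, k] += fa
            forces[ic, k] += fc
            forces[ib, k] -= fa + fc
    # spherical wall: purely repulsive (WCA) on distance to the wall
    if bmode == 1:
        R = bparam[0]
        for i in range(n):
            ri = math.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
            dist = R - ri
            if dist < wca_cut:
                if dist < 0.5 * sigma:
                    dist_eff = 0.5 * sigma
                    s6 = (sigma / dist_eff) ** 6
                    fw = 24.0 * (2.0 * s6 * s6 - s6) / dist_eff
                    pe += 4.0 * (s6 * s6 - s6) + 1.0 + fw * (dist_eff - dist)
                else:
                    s6 = (sigma / dist) ** 6
                    pe += 4.0 * (s6 * s6 - s6) + 1.0
                    fw = 24.0 * (2.0 * s6 * s6 - s6) / dist
                if ri > 1e-9:
                    for k in range(3):
                        forces[i, k] -= fw * pos[i, k] / ri

    # centroid-distance restraints (umbrella windows)
    colvar = -1.0
    n_rest = r_k.shape[0]
    if n_rest > 0:
        cv_sum = 0.0
        for rr in range(n_rest):
            a0 = r_ga_off[rr]
            a1 = r_ga_off[rr + 1]
            b0 = r_gb_off[rr]
            b1 = r_gb_off[rr + 1]
            na = a1 - a0
            nb = b1 - b0
            cax = cay = caz = 0.0
            for q in range(a0, a1):
                cax += pos[r_ga[q], 0]
                cay += pos[r_ga[q], 1]
                caz += pos[r_ga[q], 2]
            cax /= na
            cay /= na
            caz /= na
            cbx = cby = cbz = 0.0
            for q in range(b0, b1):
                cbx += pos[r_gb[q], 0]
                cby += pos[r_gb[q], 1]
                cbz += pos[r_gb[q], 2]
            cbx /= nb
            cby /= nb
            cbz /= nb
            dx = cbx - cax
            dy = cby - cay
            dz = cbz - caz
            dist = math.sqrt(dx * dx + dy * dy + dz * dz)
            cv_sum += dist
            dev = dist - r_c[rr]
            pe += 0.5 * r_k[rr] * dev * dev
            if dist > 1e-9:
                fmag = -r_k[rr] * dev / dist
                for q in range(a0, a1):
                    forces[r_ga[q], 0] -= fmag * dx / na
                    forces[r_ga[q], 1] -= fmag * dy / na
                    forces[r_ga[q], 2] -= fmag * dz / na
                for q in range(b0, b1):
                    forces[r_gb[q], 0] += fmag * dx / nb
                    forces[r_gb[q], 1] += fmag * dy / nb
                    forces[r_gb[q], 2] += fmag * dz / nb
        colvar = cv_sum / n_rest

    # axis-alignment + coaxiality restraints (stacked-configuration
    # conditioning; window-independent, so WHAM over the distance umbrella
    # remains exact for the conditioned ensemble)
    n_orient = o_k.shape[0]
    for rr in range(n_orient):
        g0 = 4 * rr
        P = np.zeros((2, 3))
        for body in range(2):
            b0 = o_off[g0 + 2 * body]
            b1 = o_off[g0 + 2 * body + 1]
            t0 = o_off[g0 + 2 * body + 1]
            t1 = o_off[g0 + 2 * body + 2]
            for k in range(3):
                sb = 0.0
                st = 0.0
                for q in range(b0, b1):
                    sb += pos[o_idx[q], k]
                for q in range(t0, t1):
                    st += pos[o_idx[q], k]
                P[body, k] = st / (t1 - t0) - sb / (b1 - b0)
        n1 = math.sqrt(P[0, 0] ** 2 + P[0, 1] ** 2 + P[0, 2] ** 2)
        n2 = math.sqrt(P[1, 0] ** 2 + P[1, 1] ** 2 + P[1, 2] ** 2)
        if n1 <= 1e-9 or n2 <= 1e-9:
            continue
        ko = o_k[rr]
        cdot = (P[0, 0] * P[1, 0] + P[0, 1] * P[1, 1]
                + P[0, 2] * P[1, 2]) / (n1 * n2)
        pe += ko * (1.0 - cdot * cdot)
        # dE/dP1 = -2 k c (u2 - c u1)/|P1|, and symmetrically for P2
        for body in range(2):
            other = 1 - body
            nn = n1 if body == 0 else n2
            no = n2 if body == 0 else n1
            b0 = o_off[g0 + 2 * body]
            b1 = o_off[g0 + 2 * body + 1]
            t0 = o_off[g0 + 2 * body + 1]
            t1 = o_off[g0 + 2 * body + 2]
            nb_m = b1 - b0
            nt_m = t1 - t0
            for k in range(3):
                u_self = P[body, k] / nn
                u_oth = P[other, k] / no
                dedp = -2.0 * ko * cdot * (u_oth - cdot * u_self) / nn
                for q in range(t0, t1):
                    forces[o_idx[q], k] -= dedp / nt_m
                for q in range(b0, b1):
                    forces[o_idx[q], k] += dedp / nb_m

        # coaxiality: keep the separation direction of the first distance
        # restraint's groups along each body axis
        if o_tilt[rr] != 0 and n_rest > 0:
            a0 = r_ga_off[0]
            a1 = r_ga_off[1]
            b0r = r_gb_off[0]
            b1r = r_gb_off[1]
            na = a1 - a0
            nbq = b1r - b0r
            Dx = Dy = Dz = 0.0
            for q in range(b0r, b1r):
                Dx += pos[r_gb[q], 0] / nbq
                Dy += pos[r_gb[q], 1] / nbq
                Dz += pos[r_gb[q], 2] / nbq
            for q in range(a0, a1):
                Dx -= pos[r_ga[q], 0] / na
                Dy -= pos[r_ga[q], 1] / na
                Dz -= pos[r_ga[q], 2] / na
            rD = math.sqrt(Dx * Dx + Dy * Dy + Dz * Dz)
            if rD > 1e-9:
                for body in range(2):
                    nn = n1 if body == 0 else n2
                    cb = (Dx * P[body, 0] + Dy * P[body, 1]
                          + Dz * P[body, 2]) / (rD * nn)
                    pe += ko * (1.0 - cb * cb)
                    b0 = o_off[g0 + 2 * body]
                    b1 = o_off[g0 + 2 * body + 1]
                    t0 = o_off[g0 + 2 * body + 1]
                    t1 = o_off[g0 + 2 * body + 2]
                    nb_m = b1 - b0
                    nt_m = t1 - t0
                    for k in range(3):
                        dk = (Dx, Dy, Dz)[k] / rD
                        uk = P[body, k] / nn
                        dedD = -2.0 * ko * cb * (uk - cb * dk) / rD
                        dedP = -2.0 * ko * cb * (dk - cb * uk) / nn
                        for q in range(b0r, b1r):
                            forces[r_gb[q], k] -= dedD / nbq
                        for q in range(a0, a1):
                            forces[r_ga[q], k] += dedD / na
                        for q in range(t0, t1):
                            forces[o_idx[q], k] -= dedP / nt_m
                        for q in range(b0, b1):
                            forces[o_idx[q], k] += dedP / nb_m
    return pe, colvar


@njit(cache=True)
def _integrate(pos, vel, n_steps, dt, gamma, kbt_val, seed,
               pair_i, pair_j, excl_keys, rlist, use_cells,
               types, eps_mat, charges, sigma, lj_cut,
               dh_pref, dh_lambda, dh_cut,
               bonds, bond_r0, bond_k, morse, morse_d, morse_a, morse_r0,
               angles, angle_t0, angle_k,
               bmode, bparam, softcore,
               r_ga, r_ga_off, r_gb, r_gb_off, r_k, r_c,
               o_idx, o_off, o_k, o_tilt,
               dump_interval, frames, colvar_interval, colvar_out,
               pe_out, fmax):
    """BAOAB Langevin loop.  Returns (status, ke_per_dof, n_dumped, n_colvar).
    status: 0 ok, -1 pair-list overflow, i>=1 -> force blow-up near bead i-1.
    """
    n = pos.shape[0]
    box = np.empty(3)
    pbc = bmode == 2
    if pbc:
        box[0] = bparam[0]
        box[1] = bparam[1]
        box[2] = bparam[2]
    else:
        box[0] = box[1] = box[2] = 1.0e12
    np.random.seed(seed)
    forces = np.zeros((n, 3))
    ref_pos = pos.copy()
    rlist2 = rlist * rlist

    if use_cells:
        n_pairs = _build_pairs_cells(pos, box, pbc, rlist, excl_keys,
                                     pair_i, pair_j)
    else:
        n_pairs = _build_pairs_n2(pos, box, pbc, rlist2, excl_keys,
                                  pair_i, pair_j)
    if n_pairs < 0:
        return -1, 0.0, 0, 0
    pe, colvar = _forces(pos, forces, pair_i, pair_j, n_pairs, types,
                         eps_mat, charges, sigma, lj_cut, dh_pref, dh_lambda,
                         dh_cut, bonds, bond_r0, bond_k, morse, morse_d,
                         morse_a, morse_r0, angles, angle_t0, angle_k,
                         bmode, bparam, softcore, r_ga, r_ga_off, r_gb,
                         r_gb_off, r_k, r_c, o_idx, o_off, o_k,
                         o_tilt, box, pbc)

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * kbt_val)
    half = 0.5 * dt
    skin_half2 = (0.5 * SKIN) ** 2
    ke_sum = 0.0
    ke_count = 0
    nd = 0
    ncv = 0

    for step in range(1, n_steps + 1):
        # B
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k]
        # A
        for i in range(n):
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        # O
        for i in range(n):
            for k in range(3):
                vel[i, k] = c1 * vel[i, k] + c2 * np.random.normal()
        # A
        for i in range(n):
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        # neighbour-list displacement check
        rebuild = False
        for i in range(n):
            dsq = 0.0
            for k in range(3):
                dd = pos[i, k] - ref_pos[i, k]
                dsq += dd * dd
            if dsq > skin_half2:
                rebuild = True
                break
        if rebuild:
            if use_cells:
                n_pairs = _build_pairs_cells(pos, box, pbc, rlist, excl_keys,
                                             pair_i, pair_j)
            else:
                n_pairs = _build_pairs_n2(pos, box, pbc, rlist2, excl_keys,
                                          pair_i, pair_j)
            if n_pairs < 0:
                return -1, 0.0, nd, ncv
            for i in range(n):
                for k in range(3):
                    ref_pos[i, k] = pos[i, k]
        pe, colvar = _forces(pos, forces, pair_i, pair_j, n_pairs, types,
                             eps_mat, charges, sigma, lj_cut, dh_pref,
                             dh_lambda, dh_cut, bonds, bond_r0, bond_k,
                             morse, morse_d, morse_a, morse_r0, angles,
                             angle_t0, angle_k, bmode, bparam, softcore,
                             r_ga, r_ga_off, r_gb, r_gb_off, r_k, r_c,
                             o_idx, o_off, o_k, o_tilt, box, pbc)
        # B
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k]
                v = vel[i, k]
                ke_sum += 0.5 * v * v
        ke_count += 3 * n

        if colvar_interval > 0 and step % colvar_interval == 0:
            if ncv < colvar_out.shape[0]:
                colvar_out[ncv] = colvar
                ncv += 1
        if step % dump_interval == 0 and nd < frames.shape[0]:
            for i in range(n):
                for k in range(3):
                    frames[nd, i, k] = pos[i, k]
            pe_out[nd] = pe
            nd += 1
            # blow-up guard, checked at dump granularity
            for i in range(n):
                for k in range(3):
                    if abs(forces[i, k]) > fmax or not math.isfinite(
                            forces[i, k]):
                        return i + 1, ke_sum / ke_count, nd, ncv
    ke = ke_sum / ke_count if ke_count > 0 else 0.0
    return 0, ke, nd, ncv


# ---------------------------------------------------------------------------
# python-facing API
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered frames plus run metadata.

    Frame f corresponds to step (f+1) * dump_interval and physical time
    (f+1) * dump_interval * time_scale_ns.
    """

    frames: np.ndarray            # (F, n, 3) float32
    frame_steps: np.ndarray
    config: SimulationConfig
    potential_energy: np.ndarray  # per frame, kcal/mol
    ke_per_dof: float             # mean kinetic energy per dof, kcal/mol
    colvar: Optional[np.ndarray] = None
    colvar_steps: Optional[np.ndarray] = None
    final_positions: Optional[np.ndarray] = None
    final_velocities: Optional[np.ndarray] = None
    bead_meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ns(self) -> np.ndarray:
        return self.frame_steps * self.config.time_scale_ns

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as h5:
            h5.create_dataset("frames", data=self.frames, compression="gzip")
            h5["frame_steps"] = self.frame_steps
            h5["potential_energy"] = self.potential_energy
            h5.attrs["ke_per_dof"] = self.ke_per_dof
            h5.attrs["config"] = self.config.to_yaml()
            if self.colvar is not None:
                h5["colvar"] = self.colvar
                h5["colvar_steps"] = self.colvar_steps
            for k, v in self.bead_meta.items():
                h5["meta/" + k] = v

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        import h5py
        with h5py.File(path, "r") as h5:
            colvar = h5["colvar"][:] if "colvar" in h5 else None
            cv_steps = h5["colvar_steps"][:] if "colvar_steps" in h5 else None
            meta = {}
            if "meta" in h5:
                for k in h5["meta"]:
                    meta[k] = h5["meta"][k][:]
            return cls(frames=h5["frames"][:],
                       frame_steps=h5["frame_steps"][:],
                       config=SimulationConfig.from_yaml(h5.attrs["config"]),
                       potential_energy=h5["potential_energy"][:],
                       ke_per_dof=float(h5.attrs["ke_per_dof"]),
                       colvar=colvar, colvar_steps=cv_steps, bead_meta=meta)

    def to_xyz(self, path, names=None):
        n = self.frames.shape[1]
        names = names if names is not None else ["C"] * n
        with open(path, "w") as fh:
            for f in range(self.n_frames):
                fh.write(f"{n}\nframe {f}\n")
                for i in range(n):
                    x, y, z = self.frames[f, i]
                    fh.write(f"{names[i]} {x:.3f} {y:.3f} {z:.3f}\n")


def _boundary_arrays(boundary):
    if not boundary:
        return 0, np.zeros(3)
    kind = boundary.get("kind")
    if kind == "sphere":
        return 1, np.array([float(boundary["radius"]), 0.0, 0.0])
    if kind == "slab":
        return 2, np.array([float(v) for v in boundary["box"]])
    raise EngineError(f"unsupported boundary {kind!r}")


def _pair_capacity(n: int) -> int:
    return min(n * (n - 1) // 2, max(200_000, n * 400)) + 16


def _prepare(topology: Topology, config: SimulationConfig):
    lam = debye_length(config.salt_mM, config.temperature,
                       topology.params.dielectric)
    lj_cut = topology.params.lj_cutoff_factor * topology.params.sigma
    dh_cut = topology.params.dh_cutoff_debye * lam
    if not math.isfinite(dh_cut):
        dh_cut = lj_cut
        lam = 1.0e12
    rlist = max(lj_cut, dh_cut) + SKIN
    return lam, lj_cut, dh_cut, rlist


def min_nonbonded_distance(positions: np.ndarray, topology: Topology,
                           boundary=None) -> float:
    """Minimum distance over non-excluded pairs (clash diagnostic)."""
    from scipy.spatial import cKDTree
    n = len(positions)
    if n < 2:
        return math.inf
    tree = cKDTree(positions)
    excl = set(map(tuple, topology.exclusions.tolist()))
    best = math.inf
    for i, j in tree.query_pairs(r=SIGMA, output_type="ndarray"):
        if (min(i, j), max(i, j)) in excl:
            continue
        d = float(np.linalg.norm(positions[i] - positions[j]))
        best = min(best, d)
    return best


def _pack_restraints(restraints):
    """Flatten a list of {group_a, group_b, k, center} restraints."""
    restraints = restraints or []
    ga_parts = [np.asarray(r["group_a"], dtype=np.int64) for r in restraints]
    gb_parts = [np.asarray(r["group_b"], dtype=np.int64) for r in restraints]
    r_ga = np.concatenate(ga_parts) if ga_parts else np.zeros(0, np.int64)
    r_gb = np.concatenate(gb_parts) if gb_parts else np.zeros(0, np.int64)
    r_ga_off = np.cumsum([0] + [len(g) for g in ga_parts]).astype(np.int64)
    r_gb_off = np.cumsum([0] + [len(g) for g in gb_parts]).astype(np.int64)
    r_k = np.array([float(r["k"]) for r in restraints])
    r_c = np.array([float(r["center"]) for r in restraints])
    return r_ga, r_ga_off, r_gb, r_gb_off, r_k, r_c


def _run(system_positions, topology, config, softcore=False,
         restraints=None, orient_restraint=None, colvar_interval=0,
         initial_velocities=None, boundary=None):
    n = len(system_positions)
    pos = np.array(system_positions, dtype=np.float64)
    kbt_val = kbt(config.temperature)
    rng = np.random.default_rng(config.seed)
    if initial_velocities is not None:
        vel = np.array(initial_velocities, dtype=np.float64)
    else:
        vel = rng.normal(scale=math.sqrt(kbt_val), size=(n, 3))

    lam, lj_cut, dh_cut, rlist = _prepare(topology, config)
    bmode, bparam = _boundary_arrays(boundary)
    cap = _pair_capacity(n)
    pair_i = np.empty(cap, dtype=np.int64)
    pair_j = np.empty(cap, dtype=np.int64)
    excl_keys = topology.exclusion_keys()
    use_cells = n > 2000

    r_ga, r_ga_off, r_gb, r_gb_off, r_k, r_c = _pack_restraints(restraints)
    orients = orient_restraint or []
    if isinstance(orients, dict):
        orients = [orients]
    if orients:
        groups = []
        for o in orients:
            groups.extend(np.asarray(g, dtype=np.int64)
                          for g in o["groups"])   # bot1, top1, bot2, top2
        o_idx = np.concatenate(groups)
        o_off = np.cumsum([0] + [len(g) for g in groups]).astype(np.int64)
        o_k = np.array([float(o["k"]) for o in orients])
        o_tilt = np.array([1 if o.get("tilt") else 0 for o in orients],
                          dtype=np.int8)
    else:
        o_idx = np.zeros(0, dtype=np.int64)
        o_off = np.zeros(1, dtype=np.int64)
        o_k = np.zeros(0)
        o_tilt = np.zeros(0, dtype=np.int8)

    n_frames = config.n_steps // config.dump_interval
    frames = np.zeros((max(n_frames, 1), n, 3), dtype=np.float32)
    pe_out = np.zeros(max(n_frames, 1))
    ncv = config.n_steps // colvar_interval if colvar_interval else 0
    colvar_out = np.zeros(max(ncv, 1))

    status, ke, nd, ncv_done = _integrate(
        pos, vel, config.n_steps, config.dt, config.gamma, kbt_val,
        int(config.seed) % (2 ** 31 - 1),
        pair_i, pair_j, excl_keys, rlist, use_cells,
        topology.bead_type.astype(np.int64), topology.eps_matrix,
        topology.charges.astype(np.float64), topology.params.sigma, lj_cut,
        COULOMB_KCAL / topology.params.dielectric, lam, dh_cut,
        topology.bonds, topology.bond_r0, topology.bond_k,
        topology.morse, topology.morse_d_e, topology.morse_a,
        topology.morse_r0,
        topology.angles, topology.angle_theta0, topology.angle_k,
        bmode, bparam, softcore,
        r_ga, r_ga_off, r_gb, r_gb_off, r_k, r_c,
        o_idx, o_off, o_k, o_tilt,
        int(config.dump_interval), frames,
        int(colvar_interval), colvar_out, pe_out, FORCE_BLOWUP)
    if status == -1:
        raise EngineError("pair list overflow: system too dense for the "
                          "allocated neighbour capacity")
    if status > 0:
        raise EngineError(
            f"force blow-up near bead {status - 1} at frame {nd}; the "
            f"system is likely unrelaxed (run soft_core_relax first)")
    traj = Trajectory(
        frames=frames[:nd], frame_steps=(np.arange(nd) + 1)
        * config.dump_interval,
        config=config, potential_energy=pe_out[:nd], ke_per_dof=ke,
        colvar=colvar_out[:ncv_done] if colvar_interval else None,
        colvar_steps=(np.arange(ncv_done) + 1) * colvar_interval
        if colvar_interval else None,
        final_positions=pos, final_velocities=vel)
    return traj


def run_langevin(system, topology: Topology, config: SimulationConfig,
                 check_clashes: bool = True, restraints=None,
                 colvar_interval: int = 0,
                 initial_positions=None) -> Trajectory:
    """Integrate Langevin dynamics; deterministic for a given seed."""
    pos = system.positions if initial_positions is None else initial_positions
    boundary = config.boundary if config.boundary else system.boundary
    if check_clashes and len(pos) <= 20000:
        dmin = min_nonbonded_distance(pos, topology)
        if dmin < 0.5 * SIGMA:
            raise EngineError(
                f"unrelaxed system: nonbonded pair at {dmin:.1f} Å "
                f"(< 0.5 sigma); run soft_core_relax first")
    traj = _run(pos, topology, config, restraints=restraints,
                colvar_interval=colvar_interval, boundary=boundary)
    traj.bead_meta = {"nuc_id": system.nuc_id.copy(),
                      "role": system.role.copy(),
                      "fiber_id": system.fiber_id.copy()}
    return traj


def soft_core_relax(system, topology: Topology, steps: int = 3000,
                    config: Optional[SimulationConfig] = None,
                    target: float = 0.8 * SIGMA):
    """Remove steric clashes with a force-capped purely repulsive potential
    at near-zero temperature (damped descent), leaving bonded topology
    unchanged."""
    cfg = config or SimulationConfig(n_steps=steps, dump_interval=steps,
                                     dt=0.02, seed=7, temperature=1.0)
    cfg = SimulationConfig(**{**cfg.__dict__, "n_steps": steps,
                              "dump_interval": max(steps, 1)})
    traj = _run(system.positions, topology, cfg, softcore=True,
                boundary=system.boundary)
    out = system.copy()
    out.positions = traj.final_positions
    dmin = min_nonbonded_distance(out.positions, topology) \
        if len(out.positions) <= 20000 else math.inf
    if dmin < target:
        # second pass with smaller step
        cfg2 = SimulationConfig(**{**cfg.__dict__, "dt": cfg.dt / 2,
                                   "seed": cfg.seed + 1})
        traj = _run(out.positions, topology, cfg2, softcore=True,
                    boundary=system.boundary)
        out.positions = traj.final_positions
        dmin = min_nonbonded_distance(out.positions, topology)
        if dmin < target:
            raise EngineError(
                f"soft-core relaxation left a pair at {dmin:.1f} Å "
                f"(target {target:.1f} Å) after {2 * steps} steps")
    return out


@dataclass
class UmbrellaWindow:
    center: float
    k: float
    samples: np.ndarray           # colvar time series (post-burn-in)


def run_umbrella(system, topology: Topology, group_a, group_b,
                 windows: Sequence, config: SimulationConfig,
                 colvar_interval: int = 50, burn_in_fraction: float = 0.2,
                 extra_group_pairs: Sequence = (),
                 orient_restraint=None) -> list:
    """Umbrella sampling along the center-center distance of two bead
    groups.  Windows are (center, k) pairs, run sequentially with the final
    structure of each window seeding the next.

    ``extra_group_pairs`` adds further (group_a, group_b) centroid-distance
    restraints sharing each window's center and stiffness; the recorded
    colvar is then the mean of all restrained distances and the effective
    WHAM stiffness is k times the number of restraints (the remaining bias
    component is window-independent and merely conditions the ensemble).
    """
    pairs = [(np.asarray(group_a, dtype=np.int64),
              np.asarray(group_b, dtype=np.int64))]
    pairs += [(np.asarray(a, dtype=np.int64), np.asarray(b, dtype=np.int64))
              for (a, b) in extra_group_pairs]
    results = []
    pos = system.positions.copy()
    for w, (center, k) in enumerate(windows):
        cfg = SimulationConfig(**{**config.__dict__,
                                  "seed": config.seed + 1000 * (w + 1)})
        traj = _run(pos, topology, cfg,
                    restraints=[{"group_a": a, "group_b": b,
                                 "center": float(center), "k": float(k)}
                                for (a, b) in pairs],
                    orient_restraint=orient_restraint,
                    colvar_interval=colvar_interval,
                    boundary=config.boundary or system.boundary)
        burn = int(len(traj.colvar) * burn_in_fraction)
        results.append(UmbrellaWindow(center=float(center),
                                      k=float(k) * len(pairs),
                                      samples=traj.colvar[burn:].copy()))
        pos = traj.final_positions
    # adjacent-window overlap diagnostic
    for a, b in zip(results, results[1:]):
        lo = max(a.samples.min(), b.samples.min())
        hi = min(a.samples.max(), b.samples.max())
        if hi <= lo:
            import warnings
            warnings.warn(f"umbrella windows at {a.center} and {b.center} "
                          f"do not overlap")
    return results
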