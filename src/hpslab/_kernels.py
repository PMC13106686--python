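"""Numba kernels: neighbor lists, pair forces and the Langevin integrator.

All kernels work in GROMACS-style units (nm, ps, amu, kJ/mol, e).  The
neighbor machinery guarantees exactness: the cell-list path produces the
identical pair set (hence identical energies/forces) as the all-pairs
double loop whenever the box admits at least three cells per dimension;
otherwise it falls back to the double loop automatically.

Coordinates handed to the force kernels may be unwrapped; the minimum
image convention is applied to every pair difference, which is exact for
arbitrary integer image offsets.
"""

import numpy as np
from numba import njit

TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# neighbor lists
# ---------------------------------------------------------------------------

@njit(cache=True, error_model="numpy")
def _count_fill_all_pairs(pos, box, chain_id, rlist2, pi, pj, fill):
    n = pos.shape[0]
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i == 1:
                continue  # directly bonded
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rlist2:
                if fill:
                    pi[cnt] = i
                    pj[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True, error_model="numpy")
def _build_pairs(pos, box, chain_id, rlist):
    """Return (pi, pj) index arrays of non-bonded pairs within rlist."""
    n = pos.shape[0]
    rlist2 = rlist * rlist
    ncx = int(box[0] / rlist)
    ncy = int(box[1] / rlist)
    ncz = int(box[2] / rlist)
    if ncx < 3 or ncy < 3 or ncz < 3:
        dummy = np.empty(0, dtype=np.int64)
        cnt = _count_fill_all_pairs(pos, box, chain_id, rlist2, dummy, dummy, False)
        pi = np.empty(cnt, dtype=np.int64)
        pj = np.empty(cnt, dtype=np.int64)
        _count_fill_all_pairs(pos, box, chain_id, rlist2, pi, pj, True)
        return pi, pj

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = pos[i, 0] - box[0] * np.floor(pos[i, 0] / box[0])
        y = pos[i, 1] - box[1] * np.floor(pos[i, 1] / box[1])
        z = pos[i, 2] - box[2] * np.floor(pos[i, 2] / box[2])
        a = int(x / box[0] * ncx)
        b = int(y / box[1] * ncy)
        c = int(z / box[2] * ncz)
        # clamp (also guards against non-finite coordinates, which are
        # detected by the integrator's energy check rather than here)
        if a >= ncx:
            a = ncx - 1
        elif a < 0:
            a = 0
        if b >= ncy:
            b = ncy - 1
        elif b < 0:
            b = 0
        if c >= ncz:
            c = ncz - 1
        elif c < 0:
            c = 0
        cx[i] = a
        cy[i] = b
        cz[i] = c
        cell = (a * ncy + b) * ncz + c
        nxt[i] = head[cell]
        head[cell] = i

    # two passes: count then fill
    total = 0
    for ipass in range(2):
        if ipass == 1:
            pi = np.empty(total, dtype=np.int64)
            pj = np.empty(total, dtype=np.int64)
        else:
            pi = np.empty(0, dtype=np.int64)
            pj = np.empty(0, dtype=np.int64)
        cnt = 0
        for i in range(n):
            for da in range(-1, 2):
                a = (cx[i] + da) % ncx
                for db in range(-1, 2):
                    b = (cy[i] + db) % ncy
                    for dc in range(-1, 2):
                        c = (cz[i] + dc) % ncz
                        j = head[(a * ncy + b) * ncz + c]
                        while j >= 0:
                            if j > i:
                                if not (chain_id[i] == chain_id[j] and j - i == 1):
                                    dx = pos[i, 0] - pos[j, 0]
                                    dy = pos[i, 1] - pos[j, 1]
                                    dz = pos[i, 2] - pos[j, 2]
                                    dx -= box[0] * np.rint(dx / box[0])
                                    dy -= box[1] * np.rint(dy / box[1])
                                    dz -= box[2] * np.rint(dz / box[2])
                                    if dx * dx + dy * dy + dz * dz < rlist2:
                                        if ipass == 1:
                                            pi[cnt] = i
                                            pj[cnt] = j
                                        cnt += 1
                            j = nxt[j]
        if ipass == 0:
            total = cnt
    return pi, pj


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True, error_model="numpy")
def _pair_params(pi, pj, sigma, lam, charge, eps, rc_lj, shift):
    """Precompute combined pair parameters for a neighbor list.

    Returns (sigma_ij^2, lambda_ij, q_i q_j, lj energy shift) arrays with
    arithmetic-mean combining rules; the LJ shift is the pair's potential
    value at the cutoff (zero when shifting is disabled).
    """
    m = pi.size
    sig2 = np.empty(m)
    lamij = np.empty(m)
    qq = np.empty(m)
    eshift = np.empty(m)
    inv_rc2 = 1.0 / (rc_lj * rc_lj)
    for k in range(m):
        i = pi[k]
        j = pj[k]
        sij = 0.5 * (sigma[i] + sigma[j])
        lij = 0.5 * (lam[i] + lam[j])
        s2 = sij * sij
        sig2[k] = s2
        lamij[k] = lij
        qq[k] = charge[i] * charge[j]
        if shift:
            sc6 = (s2 * inv_rc2) ** 3
            eshift[k] = lij * 4.0 * eps * (sc6 * sc6 - sc6)
        else:
            eshift[k] = 0.0
    return sig2, lamij, qq, eshift


@njit(cache=True, fastmath=True, error_model="numpy")
def _nonbonded_forces(pos, box, pi, pj, sig2, lamij, qq, eshift,
                      eps, rc_lj, rc_el, kappa, fel, shift, forces):
    """Accumulate nonbonded forces; return (energy, virial, min_r2, imin, jmin)."""
    e = 0.0
    w = 0.0
    rc_lj2 = rc_lj * rc_lj
    rc_el2 = rc_el * rc_el
    branch2 = TWO_POW_SIXTH * TWO_POW_SIXTH
    min_r2 = 1.0e30
    imin = -1
    jmin = -1
    bx = box[0]
    by = box[1]
    bz = box[2]
    ibx = 1.0 / bx
    iby = 1.0 / by
    ibz = 1.0 / bz
    four_eps = 4.0 * eps
    # electrostatic shift constant per unit charge product
    esh = fel * np.exp(-kappa * rc_el) / rc_el if shift else 0.0
    for k in range(pi.size):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
            imin = i
            jmin = j
        if r2 < 1e-12:  # coincident beads: no defined direction, avoid inf
            r2 = 1e-12
        fr = 0.0  # force / r
        if r2 < rc_lj2:
            inv_r2 = 1.0 / r2
            s2 = sig2[k] * inv_r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            lij = lamij[k]
            elj = four_eps * (s12 - s6)
            flj = 24.0 * eps * (2.0 * s12 - s6) * inv_r2
            if r2 <= branch2 * sig2[k]:
                e += elj + (1.0 - lij) * eps - eshift[k]
                fr += flj
            else:
                e += lij * elj - eshift[k]
                fr += lij * flj
        q2 = qq[k]
        if q2 != 0.0 and r2 < rc_el2:
            r = np.sqrt(r2)
            inv_r = 1.0 / r
            screened = fel * q2 * np.exp(-kappa * r) * inv_r
            e += screened - q2 * esh
            fr += screened * (inv_r + kappa) * inv_r
        if fr != 0.0:
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            w += fr * r2
    return e, w, min_r2, imin, jmin


@njit(cache=True, fastmath=True, error_model="numpy")
def _bond_forces(pos, box, bond_i, bond_j, k_bond, r0, forces):
    """Accumulate harmonic bond forces; return (energy, virial, max_bond_len)."""
    e = 0.0
    w = 0.0
    rmax = 0.0
    for m in range(bond_i.size):
        i = bond_i[m]
        j = bond_j[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > rmax:
            rmax = r
        e += 0.5 * k_bond * (r - r0) * (r - r0)
        if r > 0.0:
            fr = -k_bond * (r - r0) / r
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            w += fr * r * r
    return e, w, rmax


# ---------------------------------------------------------------------------
# Langevin / Berendsen integrator (BAOAB splitting)
# ---------------------------------------------------------------------------

@njit(cache=True, error_model="numpy")
def _run_md(pos, vel, box, mass, sigma, lam, charge, chain_id,
            bond_i, bond_j, k_bond, r0,
            eps, rc_lj, rc_el, kappa, fel, shift,
            dt, tau_t, t_start, t_end, kb,
            nsteps, seed, skin,
            npt, p_target, tau_p, compressibility, pconv,
            frame_stride, out_pos, out_box,
            diag_stride, out_kin_t, out_press):
    """Integrate nsteps of BAOAB Langevin dynamics (optionally Berendsen NPT).

    Thermostat set point moves linearly from t_start to t_end.  Records
    frames (unwrapped positions + box) every frame_stride steps and
    diagnostics (kinetic temperature, virial pressure) every diag_stride.
    Returns (status, bad_step, n_frames, n_diag): status 0 = ok,
    1 = non-finite coordinate encountered.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    inv_m = 1.0 / mass
    rlist = max(rc_lj, rc_el) + skin
    half_skin2 = 0.25 * skin * skin

    forces = np.zeros((n, 3))
    pi, pj = _build_pairs(pos, box, chain_id, rlist)
    sig2, lamij, qq, eshift = _pair_params(pi, pj, sigma, lam, charge,
                                           eps, rc_lj, shift)
    ref_pos = pos.copy()
    _nonbonded_forces(pos, box, pi, pj, sig2, lamij, qq, eshift,
                      eps, rc_lj, rc_el, kappa, fel, shift, forces)
    _bond_forces(pos, box, bond_i, bond_j, k_bond, r0, forces)

    c1 = np.exp(-dt / tau_t)
    c2 = np.sqrt(1.0 - c1 * c1)

    nframe = 0
    ndiag = 0
    dof = 3.0 * n
    for step in range(nsteps):
        t_set = t_start + (t_end - t_start) * (step + 0.5) / nsteps
        # B: half kick
        for i in range(n):
            f = 0.5 * dt * inv_m[i]
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]
        # A: half drift
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # O: Ornstein-Uhlenbeck velocity update
        if tau_t > 0.0 and t_set > 0.0:
            noise = np.random.standard_normal((n, 3))
            for i in range(n):
                sv = c2 * np.sqrt(kb * t_set * inv_m[i])
                vel[i, 0] = c1 * vel[i, 0] + sv * noise[i, 0]
                vel[i, 1] = c1 * vel[i, 1] + sv * noise[i, 1]
                vel[i, 2] = c1 * vel[i, 2] + sv * noise[i, 2]
        # A: half drift
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # neighbor-list refresh when any bead moved more than skin/2
        need = False
        for i in range(n):
            ddx = pos[i, 0] - ref_pos[i, 0]
            ddy = pos[i, 1] - ref_pos[i, 1]
            ddz = pos[i, 2] - ref_pos[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > half_skin2:
                need = True
                break
        if need:
            pi, pj = _build_pairs(pos, box, chain_id, rlist)
            sig2, lamij, qq, eshift = _pair_params(pi, pj, sigma, lam,
                                                   charge, eps, rc_lj, shift)
            for i in range(n):
                ref_pos[i, 0] = pos[i, 0]
                ref_pos[i, 1] = pos[i, 1]
                ref_pos[i, 2] = pos[i, 2]
        # forces at new positions
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        enb, wnb, _, _, _ = _nonbonded_forces(
            pos, box, pi, pj, sig2, lamij, qq, eshift,
            eps, rc_lj, rc_el, kappa, fel, shift, forces)
        eb, wb, _ = _bond_forces(pos, box, bond_i, bond_j, k_bond, r0, forces)
        # B: half kick
        for i in range(n):
            f = 0.5 * dt * inv_m[i]
            vel[i, 0] += f * forces[i, 0]
            vel[i, 1] += f * forces[i, 1]
            vel[i, 2] += f * forces[i, 2]

        if not (np.isfinite(enb) and np.isfinite(eb)
                and np.isfinite(pos[0, 0])):
            return 1, step, nframe, ndiag
        # Berendsen pressure coupling
        if npt:
            mv2 = 0.0
            for i in range(n):
                mv2 += mass[i] * (vel[i, 0] * vel[i, 0]
                                  + vel[i, 1] * vel[i, 1]
                                  + vel[i, 2] * vel[i, 2])
            vol = box[0] * box[1] * box[2]
            press = (mv2 + wnb + wb) / (3.0 * vol) * pconv  # bar
            mu3 = 1.0 - dt / tau_p * compressibility * (p_target - press)
            if mu3 < 0.97:
                mu3 = 0.97
            elif mu3 > 1.03:
                mu3 = 1.03
            mu = mu3 ** (1.0 / 3.0)
            for i in range(n):
                pos[i, 0] *= mu
                pos[i, 1] *= mu
                pos[i, 2] *= mu
                ref_pos[i, 0] *= mu
                ref_pos[i, 1] *= mu
                ref_pos[i, 2] *= mu
            box[0] *= mu
            box[1] *= mu
            box[2] *= mu

        if diag_stride > 0 and (step + 1) % diag_stride == 0:
            mv2 = 0.0
            for i in range(n):
                mv2 += mass[i] * (vel[i, 0] * vel[i, 0]
                                  + vel[i, 1] * vel[i, 1]
                                  + vel[i, 2] * vel[i, 2])
            out_kin_t[ndiag] = mv2 / (dof * kb)
            vol = box[0] * box[1] * box[2]
            out_press[ndiag] = (mv2 + wnb + wb) / (3.0 * vol) * pconv
            ndiag += 1
        if frame_stride > 0 and (step + 1) % frame_stride == 0:
            for i in range(n):
                out_pos[nframe, i, 0] = pos[i, 0]
                out_pos[nframe, i, 1] = pos[i, 1]
                out_pos[nframe, i, 2] = pos[i, 2]
            out_box[nframe, 0] = box[0]
            out_box[nframe, 1] = box[1]
            out_box[nframe, 2] = box[2]
            nframe += 1
    for i in range(n):
        for d in range(3):
            if not np.isfinite(pos[i, d]):
                return 1, nsteps - 1, nframe, ndiag
    return 0, -1, nframe, ndiag
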