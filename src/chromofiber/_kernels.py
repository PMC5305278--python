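"""Numba kernels for the bead-spring Brownian-dynamics engine.

All arrays are in reduced units (lengths rs, energies kBT, time dt).
The integrator is Euler-Maruyama for the overdamped Langevin equation
dr/dt = -mu grad(U) + xi with <xi_i xi_j> = 6 kBT mu delta_ij
delta(t-t'), i.e. each Cartesian displacement component per step is
N(0, 2 kBT mu dt).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_UNSTABLE = 3
STATUS_LJ_OVERLAP = 4
STATUS_LIST_OVERFLOW = 5


@njit(cache=True, fastmath=True)
def _harmonic_forces(pos, f, bi, bj, bk, br0):
    for n in range(len(bi)):
        i, j = bi[n], bj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        c = -bk[n] * (r - br0[n]) / r
        f[i, 0] += c * dx; f[i, 1] += c * dy; f[i, 2] += c * dz
        f[j, 0] -= c * dx; f[j, 1] -= c * dy; f[j, 2] -= c * dz


@njit(cache=True, fastmath=True)
def _bend_forces(pos, f, ta, tb, tc, tk):
    """Discrete WLC term K (1 - cos theta) per triplet (a, b, c)."""
    for n in range(len(ta)):
        a, b, c = ta[n], tb[n], tc[n]
        ux = pos[b, 0] - pos[a, 0]; uy = pos[b, 1] - pos[a, 1]
        uz = pos[b, 2] - pos[a, 2]
        vx = pos[c, 0] - pos[b, 0]; vy = pos[c, 1] - pos[b, 1]
        vz = pos[c, 2] - pos[b, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        dot = ux * vx + uy * vy + uz * vz
        ct = dot / (lu * lv)
        K = tk[n]
        # d(cos)/du and d(cos)/dv
        gux = vx / (lu * lv) - ct * ux / (lu * lu)
        guy = vy / (lu * lv) - ct * uy / (lu * lu)
        guz = vz / (lu * lv) - ct * uz / (lu * lu)
        gvx = ux / (lu * lv) - ct * vx / (lv * lv)
        gvy = uy / (lu * lv) - ct * vy / (lv * lv)
        gvz = uz / (lu * lv) - ct * vz / (lv * lv)
        # E = K (1 - cos); F = -dE/dr
        f[a, 0] -= K * gux; f[a, 1] -= K * guy; f[a, 2] -= K * guz
        f[c, 0] += K * gvx; f[c, 1] += K * gvy; f[c, 2] += K * gvz
        f[b, 0] += K * (gux - gvx)
        f[b, 1] += K * (guy - gvy)
        f[b, 2] += K * (guz - gvz)


@njit(cache=True, fastmath=True)
def _angle_forces(pos, f, aa, ab, ac, kA, alpha_n):
    """Effective nucleosome term K (1 - cos(alpha - alpha_n)) with
    alpha the angle between the rays (a-b) and (c-b) at bead b."""
    for n in range(len(aa)):
        a, b, c = aa[n], ab[n], ac[n]
        ux = pos[a, 0] - pos[b, 0]; uy = pos[a, 1] - pos[b, 1]
        uz = pos[a, 2] - pos[b, 2]
        vx = pos[c, 0] - pos[b, 0]; vy = pos[c, 1] - pos[b, 1]
        vz = pos[c, 2] - pos[b, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            continue
        ca = (ux * vx + uy * vy + uz * vz) / (lu * lv)
        if ca > 1.0:
            ca = 1.0
        elif ca < -1.0:
            ca = -1.0
        alpha = np.arccos(ca)
        sa = np.sin(alpha)
        if sa < 1e-8:
            sa = 1e-8
        # dE/d(cos alpha) = -K sin(alpha - alpha_n) / sin(alpha)
        dEdc = -kA[n] * np.sin(alpha - alpha_n) / sa
        gux = vx / (lu * lv) - ca * ux / (lu * lu)
        guy = vy / (lu * lv) - ca * uy / (lu * lu)
        guz = vz / (lu * lv) - ca * uz / (lu * lu)
        gvx = ux / (lu * lv) - ca * vx / (lv * lv)
        gvy = uy / (lu * lv) - ca * vy / (lv * lv)
        gvz = uz / (lu * lv) - ca * vz / (lv * lv)
        f[a, 0] -= dEdc * gux; f[a, 1] -= dEdc * guy; f[a, 2] -= dEdc * guz
        f[c, 0] -= dEdc * gvx; f[c, 1] -= dEdc * gvy; f[c, 2] -= dEdc * gvz
        f[b, 0] += dEdc * (gux + gvx)
        f[b, 1] += dEdc * (guy + gvy)
        f[b, 2] += dEdc * (guz + gvz)


@njit(cache=True, fastmath=True)
def _lj_forces(pos, f, pi, pj, n_pairs, eps, two_a):
    """Repulsive truncated-shifted LJ on listed DNA pairs, zero beyond 2a."""
    status = STATUS_OK
    for n in range(n_pairs):
        i, j = pi[n], pj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= two_a * two_a:
            continue
        if r2 < 1e-20:
            status = STATUS_LJ_OVERLAP
            continue
        s2 = (two_a * two_a) / r2
        s6 = s2 * s2 * s2
        c = 12.0 * eps * s6 * (s6 - 1.0) / r2
        f[i, 0] += c * dx; f[i, 1] += c * dy; f[i, 2] += c * dz
        f[j, 0] -= c * dx; f[j, 1] -= c * dy; f[j, 2] -= c * dz
    return status


@njit(cache=True, fastmath=True)
def _pair_spring_forces(pos, f, pi, pj, n_pairs, kh, rh, use_morse, D):
    for n in range(n_pairs):
        i, j = pi[n], pj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        if use_morse:
            alpha = np.sqrt(kh / (2.0 * D))
            e = np.exp(-alpha * (r - rh))
            dEdr = 2.0 * D * alpha * e * (1.0 - e)
        else:
            dEdr = kh * (r - rh)
        c = -dEdr / r
        f[i, 0] += c * dx; f[i, 1] += c * dy; f[i, 2] += c * dz
        f[j, 0] -= c * dx; f[j, 1] -= c * dy; f[j, 2] -= c * dz


@njit(cache=True, fastmath=True)
def build_lj_list(pos, n_dna, cutoff, pi, pj):
    """All DNA-DNA pairs within ``cutoff``, excluding chain neighbors.
    Returns the pair count, or -1 on capacity overflow."""
    cap = len(pi)
    n = 0
    c2 = cutoff * cutoff
    for i in range(n_dna):
        for j in range(i + 2, n_dna):       # skip self and bonded neighbor
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                if n >= cap:
                    return -1
                pi[n] = i
                pj[n] = j
                n += 1
    return n


@njit(cache=True, fastmath=True)
def greedy_pairs(pos, idx, cutoff, max_partners, pi, pj):
    """Greedy distance-ordered matching of nucleosome pairs.

    Candidate pairs (members of ``idx``) closer than ``cutoff`` are
    accepted in order of increasing distance while both members have
    fewer than ``max_partners`` accepted partners.  Returns the number
    of accepted pairs written into ``pi``/``pj`` (bead indices).
    """
    m = len(idx)
    cap = m * (m - 1) // 2
    di = np.empty(cap, dtype=np.int64)
    dj = np.empty(cap, dtype=np.int64)
    dd = np.empty(cap)
    n_cand = 0
    c2 = cutoff * cutoff
    for u in range(m):
        i = idx[u]
        for v in range(u + 1, m):
            j = idx[v]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < c2:
                di[n_cand] = u
                dj[n_cand] = v
                dd[n_cand] = r2
                n_cand += 1
    order = np.argsort(dd[:n_cand])
    counts = np.zeros(m, dtype=np.int64)
    n = 0
    for o in range(n_cand):
        u = di[order[o]]
        v = dj[order[o]]
        if counts[u] < max_partners and counts[v] < max_partners:
            counts[u] += 1
            counts[v] += 1
            pi[n] = idx[u]
            pj[n] = idx[v]
            n += 1
    return n


@njit(cache=True, fastmath=True)
def compute_forces(pos, f, n_dna,
                   bi, bj, bk, br0,
                   ta, tb, tc, tk,
                   aa, ab, ac, kA, alpha_n,
                   lj_i, lj_j, n_lj, eps, two_a,
                   hp_i, hp_j, n_hp, kh, rh, use_morse, morse_D):
    f[:] = 0.0
    _harmonic_forces(pos, f, bi, bj, bk, br0)
    _bend_forces(pos, f, ta, tb, tc, tk)
    _angle_forces(pos, f, aa, ab, ac, kA, alpha_n)
    status = _lj_forces(pos, f, lj_i, lj_j, n_lj, eps, two_a)
    _pair_spring_forces(pos, f, hp_i, hp_j, n_hp, kh, rh, use_morse, morse_D)
    return status


@njit(cache=True, fastmath=True)
def integrate_chunk(pos, mu, n_dna, noise, step0, sample_every,
                    bi, bj, bk, br0,
                    ta, tb, tc, tk,
                    aa, ab, ac, kA, alpha_n,
                    eps, two_a,
                    nuc_idx, pair_cutoff, max_partners, kh, rh,
                    use_morse, morse_D,
                    pair_every, skin, lj_cap, abort_disp, limit_disp,
                    frames, frames_written):
    """Euler-Maruyama BD over one chunk of pre-drawn noise increments
    (``noise`` has shape (chunk_steps, n, 3) and already carries the
    sqrt(2 mu dt) scale).  Samples into ``frames`` whenever the global
    step count (step0 + local step) is a multiple of ``sample_every``.
    Returns (status, steps_done, frames_written).

    ``limit_disp`` > 0 enables a capped-displacement (push-off) mode
    that clamps per-bead moves instead of aborting on large forces;
    used to relax residual overlaps of freshly built conformations.
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    f = np.zeros((n, 3))
    lj_i = np.empty(lj_cap, dtype=np.int64)
    lj_j = np.empty(lj_cap, dtype=np.int64)
    m = len(nuc_idx)
    hp_cap = max(1, m * max_partners)
    hp_i = np.empty(hp_cap, dtype=np.int64)
    hp_j = np.empty(hp_cap, dtype=np.int64)
    verlet_cut = two_a + skin
    ref_pos = pos.copy()
    n_lj = build_lj_list(pos, n_dna, verlet_cut, lj_i, lj_j)
    if n_lj < 0:
        return STATUS_LIST_OVERFLOW, 0, frames_written
    n_hp = 0
    use_pairs = len(nuc_idx) > 1 and (kh > 0.0 or use_morse)
    if use_pairs:
        n_hp = greedy_pairs(pos, nuc_idx, pair_cutoff, max_partners,
                            hp_i, hp_j)
    for step_i in range(n_steps):
        # neighbor-list maintenance
        max_d2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            dz = pos[i, 2] - ref_pos[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > 0.25 * skin * skin:
            n_lj = build_lj_list(pos, n_dna, verlet_cut, lj_i, lj_j)
            if n_lj < 0:
                return STATUS_LIST_OVERFLOW, step_i, frames_written
            ref_pos[:] = pos
        if use_pairs and (step0 + step_i) % pair_every == 0:
            n_hp = greedy_pairs(pos, nuc_idx, pair_cutoff, max_partners,
                                hp_i, hp_j)
        status = compute_forces(pos, f, n_dna, bi, bj, bk, br0,
                                ta, tb, tc, tk, aa, ab, ac, kA, alpha_n,
                                lj_i, lj_j, n_lj, eps, two_a,
                                hp_i, hp_j, n_hp, kh, rh, use_morse, morse_D)
        if status != STATUS_OK:
            return status, step_i, frames_written
        max_disp2 = 0.0
        for i in range(n):
            ddx = mu[i] * f[i, 0] + noise[step_i, i, 0]
            ddy = mu[i] * f[i, 1] + noise[step_i, i, 1]
            ddz = mu[i] * f[i, 2] + noise[step_i, i, 2]
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if limit_disp > 0.0 and d2 > limit_disp * limit_disp:
                s = limit_disp / np.sqrt(d2)
                ddx *= s; ddy *= s; ddz *= s
                d2 = limit_disp * limit_disp
            if d2 > max_disp2:
                max_disp2 = d2
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
        if limit_disp <= 0.0 and max_disp2 > abort_disp * abort_disp:
            return STATUS_UNSTABLE, step_i + 1, frames_written
        if sample_every > 0 and (step0 + step_i + 1) % sample_every == 0 \
                and frames_written < frames.shape[0]:
            frames[frames_written] = pos
            frames_written += 1
    return STATUS_OK, n_steps, frames_written
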