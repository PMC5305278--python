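"""Bead-spring Brownian-dynamics model of chromatin.

DNA is a chain of type-1 beads (diameter 2a = one helical repeat)
joined by stiff harmonic springs, with a discrete worm-like-chain
bending energy.  Each nucleosome wraps 14 DNA beads (147 bp) in about
1.7 left-handed turns around a type-2 histone-core bead, held by wrap
springs; a linker-histone (H1) spring clamps the DNA beads entering
and exiting the wrap.  Non-histone DNA-bending proteins are springs
that bridge 2 or 3 bonds in the middle of a linker and pull its ends
together; nucleosome cores closer than 9a pair up (at most
``max_tail_partners`` each, mimicking the finite number of histone
tails) via harmonic (or Morse) tail springs.  An alternative
"effective angle" mode replaces the wrapped nucleosome by a single
bead that constrains its entry/exit DNA rays to the angle alpha_n.

Dynamics are overdamped Langevin (Euler-Maruyama) with type-specific
mobilities; see ``_kernels`` for the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels as K
from .core import BP_PER_RS, DEG, ModelParams, bend_angle_to_chord, spawn_seeds

WRAP_BEADS = 14          # 147 bp of wrapped DNA
WRAP_TURNS = 1.7


class BDInstabilityError(RuntimeError):
    """Integration became unstable (a bead moved further than a in one
    step); re-run with a smaller timestep or softer parameters."""


@dataclass
class BeadSystem:
    """Topology and coordinates of one bead-spring chromatin system.

    ``pos`` stacks the N DNA beads first, then (in explicit-core mode)
    the M core beads.  Bond index arrays refer into ``pos``.
    """

    mode: str                      # "explicit_core" | "effective_angle"
    params: ModelParams
    pos: np.ndarray                # (n_beads, 3)
    n_dna: int
    M: int
    linker_nl: np.ndarray          # (M-1,) bonds per linker
    wrapped: np.ndarray            # (M, 14) DNA indices, explicit mode
    nucleosome_beads: np.ndarray   # (M,) bead indices used for contacts
    bonds_dna: np.ndarray          # (N-1, 2)
    bonds_wrap: np.ndarray         # (14M, 2) explicit mode, else (0, 2)
    bonds_h1: np.ndarray
    bonds_protein: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    angle_triplets: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    bend_triplets: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    linker_occupancy: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=bool))
    linker_beads: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def nucleosome_positions(self) -> np.ndarray:
        return self.pos[self.nucleosome_beads]

    def mobilities(self) -> np.ndarray:
        mu = np.full(self.n_beads, self.params.mu0_dna)
        if self.mode == "explicit_core":
            mu[self.n_dna:] = self.params.mu0_core
        else:
            mu[self.nucleosome_beads] = self.params.mu0_core
        return mu


@dataclass
class EnergyReport:
    """Energy components in kBT; Utot is the fixed-order sum
    Us + Un + Ul + Up + Uh + ULJ + Ub."""

    Us: float
    Un: float
    Ul: float
    Up: float
    Uh: float
    ULJ: float
    Ub: float

    @property
    def Utot(self) -> float:
        return (((((self.Us + self.Un) + self.Ul) + self.Up)
                 + self.Uh) + self.ULJ + self.Ub)


# ---------------------------------------------------------------------------
# construction


def _helix_local(params: ModelParams):
    """Local coordinates of one left-handed 14-bead wrap, its core, and
    the unit entry/exit tangents.

    The wrap makes 1.7 turns around the core with a pitch that
    separates adjacent turns by one bead diameter; each bead sits
    exactly at distance rn from the core (the wrap-spring rest length),
    so the radius tapers slightly toward the helix ends."""
    k = np.arange(WRAP_BEADS, dtype=float)
    gamma = WRAP_TURNS * 2.0 * math.pi / (WRAP_BEADS - 1)
    rise = WRAP_TURNS * params.rs / (WRAP_BEADS - 1)   # 1 rs per turn
    core = np.array([0.0, 0.0, rise * (WRAP_BEADS - 1) / 2.0])
    dz = rise * k - core[2]
    rad = np.sqrt(params.rn**2 - dz**2)
    ang = -gamma * k                                   # left-handed
    beads = np.stack([rad * np.cos(ang), rad * np.sin(ang),
                      rise * k], axis=1)
    t_in = beads[1] - beads[0]
    t_out = beads[-1] - beads[-2]
    return (beads, core, t_in / np.linalg.norm(t_in),
            t_out / np.linalg.norm(t_out))


def _frame_from(t: np.ndarray) -> np.ndarray:
    """Orthonormal frame (columns) whose third axis is ``t``."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, t)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return np.stack([e1, e2, t], axis=1)


def init_conformation(M: int, linker_bp, params: ModelParams | None = None,
                      mode: str = "explicit_core",
                      seed: int | None = None,
                      max_retries: int = 120,
                      occupied_linkers: np.ndarray | None = None
                      ) -> BeadSystem:
    """Build an overlap-free initial conformation.

    Explicit-core mode places, for each nucleosome, 14 wrapped beads on
    a left-handed helix at radius rn around the core bead, with
    straight linkers continuing along the local exit tangent; the
    azimuth of each wrap about the incoming tangent is chosen
    deterministically and re-drawn (bounded retries) if it would place
    non-bonded DNA beads closer than one bead diameter.
    Effective-angle mode builds a planar zig-zag of single nucleosome
    beads with straight linkers.

    ``occupied_linkers`` marks linkers that carry a bound bending
    protein: these start pre-bent by theta_p (split over the protein
    span, in a random plane) so that, like every other bonded term, the
    protein spring begins at its rest length.  Protein *bonds* are
    attached separately (:func:`place_proteins` /
    :func:`attach_protein_bonds`).
    """
    params = params or ModelParams()
    if M < 1:
        raise ValueError("M must be >= 1")
    if mode not in ("explicit_core", "effective_angle"):
        raise ValueError(f"unknown mode {mode!r}")
    n_linkers = max(M - 1, 0)
    nl = np.asarray(linker_bp, float)
    nl = np.full(n_linkers, float(linker_bp)) if nl.ndim == 0 \
        else nl.astype(float)
    if nl.shape != (n_linkers,):
        raise ValueError(f"linker_bp must be scalar or length {n_linkers}")
    nl_bonds = nl / BP_PER_RS
    nl_int = np.rint(nl_bonds).astype(np.int64)
    if n_linkers and (np.any(np.abs(nl_bonds - nl_int) > 1e-9)
                      or np.any(nl_int < 1)):
        raise ValueError("linker lengths must be positive multiples of 10.5 bp")

    occ = np.zeros(n_linkers, dtype=bool) if occupied_linkers is None \
        else np.asarray(occupied_linkers, dtype=bool)
    if occ.shape != (n_linkers,):
        raise ValueError(f"occupied_linkers must have length {n_linkers}")
    if mode == "explicit_core":
        return _init_explicit(M, nl_int, params, seed, max_retries, occ)
    return _init_effective(M, nl_int, params, occ)


def _bend_turns(params: ModelParams, n_l: int) -> tuple[int, list, float]:
    """Kink plan for a pre-bent occupied linker: (protein span, list of
    local bead indices after which the tangent turns, turn angle)."""
    span = params.protein_span
    tp = params.theta_p_deg
    ang = float(tp) if np.isscalar(tp) else 0.5 * (tp[0] + tp[1])
    off = (n_l - 1 - span) // 2
    if span == 2:
        return span, [off + 1], math.radians(ang)
    return span, [off + 1, off + 2], math.radians(ang) / 2.0


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    ax = axis / np.linalg.norm(axis)
    Kx = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]],
                   [-ax[1], ax[0], 0]])
    return np.eye(3) + math.sin(angle) * Kx + (1 - math.cos(angle)) * Kx @ Kx


def _init_explicit(M, nl_int, params, seed, max_retries, occ):
    rs = params.rs
    N = M * WRAP_BEADS + int(nl_int.sum())
    beads_l, core_l, t_in_l, t_out_l = _helix_local(params)
    F_local = _frame_from(t_in_l)

    rng = np.random.default_rng(0 if seed is None else seed)
    dna = np.empty((N, 3))
    cores = np.empty((M, 3))
    wrapped = np.empty((M, WRAP_BEADS), dtype=np.int64)

    min_sep = 0.98 * 2.0 * params.a      # preferred clearance
    # pre-bent fibers are inherently crowded; residual proximity above
    # this floor is relaxed by the capped-displacement push-off phase
    hard_floor = 0.05 * params.rs

    def make_wrap(t, p, azim):
        """Wrap beads/core/rotation for incoming tangent t at entry p."""
        Fw = _frame_from(t)
        ca, sa = math.cos(azim), math.sin(azim)
        Raz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        R = Fw @ Raz @ F_local.T
        wb = (beads_l - beads_l[0]) @ R.T + p
        cb = (core_l - beads_l[0]) @ R.T + p
        return R, wb, cb

    def make_linker(t, p, n_l, bent, axis_phi):
        """Linker bead positions and the outgoing (t, p)."""
        out = np.empty((n_l, 3))
        kinks, rot = [], np.eye(3)
        if bent:
            _, kinks, turn = _bend_turns(params, n_l)
            F = _frame_from(t)
            axis = math.cos(axis_phi) * F[:, 0] + math.sin(axis_phi) * F[:, 1]
            rot = _rodrigues(axis, turn)
        for j in range(n_l):
            out[j] = p
            if j in kinks:
                t = rot @ t
            p = p + rs * t
        return out, t, p

    def clearance(cand, prev):
        """Min distance of candidate beads to placed beads (excluding
        the direct bond) and among non-consecutive candidate beads."""
        sep = np.inf
        if len(prev):
            d = np.sqrt(((cand[:, None, :] - prev[None, :, :])**2).sum(-1))
            d[0, -1] = np.inf               # bonded neighbor
            sep = d.min()
        if len(cand) > 2:
            dc = np.sqrt(((cand[:, None, :] - cand[None, :, :])**2).sum(-1))
            iu = np.triu_indices(len(cand), 2)
            sep = min(sep, dc[iu].min())
        return sep

    idx = 0
    t = np.array([1.0, 0.0, 0.0])
    p = np.zeros(3)
    R, wb, cb = make_wrap(t, p, 0.0)
    dna[:WRAP_BEADS] = wb
    wrapped[0] = np.arange(WRAP_BEADS)
    cores[0] = cb
    idx = WRAP_BEADS
    t = R @ t_out_l
    p = wb[-1] + rs * t
    for m in range(1, M):
        n_l = int(nl_int[m - 1])
        best, best_sep = None, -1.0
        for attempt in range(max_retries):
            azim = 0.0 if attempt == 0 else rng.uniform(0.0, 2.0 * math.pi)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            lk, tl, pl = make_linker(t, p, n_l, occ[m - 1], phi)
            Rw, wbn, cbn = make_wrap(tl, pl, azim)
            cand = np.vstack([lk, wbn])
            sep = clearance(cand, dna[:idx])
            if sep > best_sep:
                best_sep = sep
                best = (lk, tl, Rw, wbn, cbn)
            if sep > min_sep:
                break
        if best_sep <= hard_floor:
            raise RuntimeError(
                f"could not place nucleosome {m} without overlaps after "
                f"{max_retries} retries (best clearance {best_sep:.2f} rs)")
        lk, tl, Rw, wbn, cbn = best
        dna[idx:idx + n_l] = lk
        idx += n_l
        dna[idx:idx + WRAP_BEADS] = wbn
        wrapped[m] = np.arange(idx, idx + WRAP_BEADS)
        cores[m] = cbn
        idx += WRAP_BEADS
        t = Rw @ t_out_l
        p = wbn[-1] + rs * t

    pos = np.vstack([dna, cores])
    sys_ = _assemble(M, nl_int, params, "explicit_core", pos, N, wrapped)
    return sys_


def _init_effective(M, nl_int, params, occ):
    rs = params.rs
    # leading/trailing stub beads give every nucleosome an entry and exit
    N = M + int(nl_int.sum()) + 2
    rng = np.random.default_rng(0)
    pos = np.empty((N, 3))
    turn = math.pi - params.alpha_n_deg * DEG
    heading = 0.0
    p = np.zeros(3)
    sign = 1.0
    nuc_beads = np.empty(M, dtype=np.int64)
    i = 0
    pos[i] = p; i += 1                       # leading stub
    p = p + rs * np.array([math.cos(heading), math.sin(heading), 0.0])
    for m in range(M):
        pos[i] = p
        nuc_beads[m] = i
        i += 1
        heading += sign * turn
        sign = -sign
        p = p + rs * np.array([math.cos(heading), math.sin(heading), 0.0])
        if m < M - 1:
            steps = int(nl_int[m])
            kinks, kturn = [], 0.0
            if occ[m]:
                _, kinks, kturn = _bend_turns(params, steps)
                kturn *= 1.0 if rng.random() < 0.5 else -1.0
        else:
            steps, kinks, kturn = 1, [], 0.0      # trailing stub
        for j in range(steps):
            pos[i] = p
            i += 1
            if j in kinks:
                heading += kturn
            p = p + rs * np.array([math.cos(heading), math.sin(heading), 0.0])
    sys_ = _assemble(M, nl_int, params, "effective_angle", pos, N,
                     np.empty((M, 0), dtype=np.int64), nuc_beads)
    return sys_


def _assemble(M, nl_int, params, mode, pos, n_dna, wrapped, nuc_beads=None):
    bonds_dna = np.stack([np.arange(n_dna - 1), np.arange(1, n_dna)], axis=1)
    if mode == "explicit_core":
        nuc_beads = n_dna + np.arange(M)
        bw = []
        for m in range(M):
            for k in range(WRAP_BEADS):
                bw.append((n_dna + m, wrapped[m, k]))
        bonds_wrap = np.array(bw, dtype=np.int64)
        h1 = []
        for m in range(M):
            entry = wrapped[m, 0] - 1
            exit_ = wrapped[m, -1] + 1
            if entry >= 0 and exit_ < n_dna:
                h1.append((entry, exit_))
        bonds_h1 = np.array(h1, dtype=np.int64).reshape(-1, 2)
        angle_triplets = np.empty((0, 3), dtype=np.int64)
        lb = []
        for m in range(M - 1):
            lb.append((wrapped[m, -1] + 1, int(nl_int[m])))
        linker_beads = np.array(lb, dtype=np.int64).reshape(-1, 2)
        wrapped_mask = np.zeros(n_dna, dtype=bool)
        wrapped_mask[wrapped.ravel()] = True
    else:
        bonds_wrap = np.empty((0, 2), dtype=np.int64)
        bonds_h1 = np.empty((0, 2), dtype=np.int64)
        angle_triplets = np.stack([nuc_beads - 1, nuc_beads, nuc_beads + 1],
                                  axis=1)
        lb = []
        for m in range(M - 1):
            lb.append((nuc_beads[m] + 1, int(nl_int[m])))
        linker_beads = np.array(lb, dtype=np.int64).reshape(-1, 2)
        wrapped_mask = np.zeros(n_dna, dtype=bool)

    centers = np.arange(1, n_dna - 1)
    if not params.bend_in_wrap:
        centers = centers[~wrapped_mask[centers]]
    bend_triplets = np.stack([centers - 1, centers, centers + 1], axis=1)

    return BeadSystem(
        mode=mode, params=params, pos=pos, n_dna=n_dna, M=M,
        linker_nl=nl_int, wrapped=wrapped, nucleosome_beads=nuc_beads,
        bonds_dna=bonds_dna, bonds_wrap=bonds_wrap, bonds_h1=bonds_h1,
        angle_triplets=angle_triplets, bend_triplets=bend_triplets,
        linker_occupancy=np.zeros(max(M - 1, 0), dtype=bool),
        linker_beads=linker_beads)


def place_proteins(system: BeadSystem, rho: float, seed: int,
                   span: int | None = None) -> None:
    """Occupy each linker with one protein spring with probability rho.

    The spring of ``span`` bonds (default ``params.protein_span``) sits
    centred in the linker, strictly inside it (never touching wrapped
    beads); its rest length encodes the bend angle theta_p.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    occ = rng.random(max(system.M - 1, 0)) < rho
    attach_protein_bonds(system, occ, span)


def attach_protein_bonds(system: BeadSystem, occupancy: np.ndarray,
                         span: int | None = None) -> None:
    """Attach one protein spring per occupied linker (see
    :func:`place_proteins`)."""
    span = span or system.params.protein_span
    occ = np.asarray(occupancy, dtype=bool)
    bonds = []
    for m in np.nonzero(occ)[0]:
        start, n_l = system.linker_beads[m]
        if n_l - 1 < span:
            raise ValueError(
                f"linker {m} has {n_l} beads; cannot host a protein "
                f"spanning {span} bonds")
        off = (n_l - 1 - span) // 2
        bonds.append((start + off, start + off + span))
    system.linker_occupancy = occ
    system.bonds_protein = np.array(bonds, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# energies (reference implementation; forces live in the numba kernels)


def _harmonic(pos, bonds, k, r0) -> float:
    if len(bonds) == 0:
        return 0.0
    d = np.linalg.norm(pos[bonds[:, 0]] - pos[bonds[:, 1]], axis=1)
    return float(0.5 * k * np.sum((d - r0)**2))


def pair_nucleosomes(core_pos: np.ndarray,
                     params: ModelParams) -> np.ndarray:
    """Greedy distance-ordered matching of nucleosome pairs.

    All pairs closer than ``nucl_pair_cutoff`` are considered in order
    of increasing distance; a pair is accepted while both members have
    fewer than ``max_tail_partners`` accepted partners.  Returns an
    (n_pairs, 2) array of indices into ``core_pos``.
    """
    m = len(core_pos)
    if m < 2:
        return np.empty((0, 2), dtype=np.int64)
    iu, ju = np.triu_indices(m, 1)
    d = np.linalg.norm(core_pos[iu] - core_pos[ju], axis=1)
    near = d < params.nucl_pair_cutoff
    iu, ju, d = iu[near], ju[near], d[near]
    order = np.argsort(d, kind="stable")
    counts = np.zeros(m, dtype=np.int64)
    out = []
    for o in order:
        i, j = iu[o], ju[o]
        if counts[i] < params.max_tail_partners \
                and counts[j] < params.max_tail_partners:
            counts[i] += 1
            counts[j] += 1
            out.append((i, j))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def energy_harmonic(system: BeadSystem, pos: np.ndarray | None = None,
                    pairs: np.ndarray | None = None) -> EnergyReport:
    """Harmonic components Us, Un, Ul, Up, Uh (Un only in explicit
    mode; in effective mode Un is the entry/exit angle energy).  ULJ
    and Ub are left at zero in the returned report."""
    p = system.params
    pos = system.pos if pos is None else pos
    Us = _harmonic(pos, system.bonds_dna, p.ks, p.rs)
    if system.mode == "explicit_core":
        Un = _harmonic(pos, system.bonds_wrap, p.kn, p.rn)
    else:
        Un = energy_nucl_angle(system, pos)
    Ul = _harmonic(pos, system.bonds_h1, p.kl, p.rl)
    Up = _harmonic(pos, system.bonds_protein, p.kp,
                   p.protein_rest_length())
    Uh = energy_pairs(system, pos, pairs)
    return EnergyReport(Us=Us, Un=Un, Ul=Ul, Up=Up, Uh=Uh, ULJ=0.0, Ub=0.0)


def energy_pairs(system: BeadSystem, pos: np.ndarray | None = None,
                 pairs: np.ndarray | None = None) -> float:
    """Inter-nucleosome tail energy over currently paired nucleosomes
    (harmonic, or Morse when enabled)."""
    p = system.params
    pos = system.pos if pos is None else pos
    if p.kh == 0.0 and not p.morse:
        return 0.0
    if pairs is None:
        pairs = pair_nucleosomes(pos[system.nucleosome_beads], p)
    if len(pairs) == 0:
        return 0.0
    beads = system.nucleosome_beads[pairs]
    d = np.linalg.norm(pos[beads[:, 0]] - pos[beads[:, 1]], axis=1)
    if p.morse:
        alpha = math.sqrt(p.kh / (2.0 * p.morse_D))
        return float(np.sum(p.morse_D * (1.0 - np.exp(-alpha * (d - p.rh)))**2))
    return float(0.5 * p.kh * np.sum((d - p.rh)**2))


def energy_morse(system: BeadSystem, pos: np.ndarray | None = None,
                 pairs: np.ndarray | None = None) -> float:
    """Morse inter-nucleosome energy D (1 - exp(-alpha (r - rh)))^2 with
    curvature matched to the harmonic spring: 2 D alpha^2 = kh."""
    if not system.params.morse:
        raise ValueError("Morse mode is not enabled (params.morse=False)")
    return energy_pairs(system, pos, pairs)


def energy_lj(system: BeadSystem, pos: np.ndarray | None = None) -> float:
    """Repulsive truncated-shifted LJ over non-bonded DNA bead pairs;
    exactly zero at and beyond r = 2a."""
    p = system.params
    pos = system.pos if pos is None else pos
    two_a = 2.0 * p.a
    dna = pos[:system.n_dna]
    iu, ju = np.triu_indices(system.n_dna, 2)   # exclude bonded neighbors
    d = np.linalg.norm(dna[iu] - dna[ju], axis=1)
    if np.any(d < 1e-10):
        raise FloatingPointError("coincident DNA beads: LJ diverges")
    mask = d < two_a
    if not mask.any():
        return 0.0
    s6 = (two_a / d[mask])**6
    return float(p.epsilon * np.sum(s6 * s6 - 2.0 * s6 + 1.0))


def energy_bend(system: BeadSystem, pos: np.ndarray | None = None) -> float:
    """Discrete WLC bending energy (kb/2a) sum(1 - cos theta_i) over
    consecutive DNA bond pairs (N-2 internal angles)."""
    pos = system.pos if pos is None else pos
    t = system.bend_triplets
    if len(t) == 0:
        return 0.0
    u = pos[t[:, 1]] - pos[t[:, 0]]
    v = pos[t[:, 2]] - pos[t[:, 1]]
    ct = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return float(system.params.kb * np.sum(1.0 - np.clip(ct, -1.0, 1.0)))


def energy_nucl_angle(system: BeadSystem,
                      pos: np.ndarray | None = None) -> float:
    """Effective nucleosome energy kn_eff sum(1 - cos(alpha_i - alpha_n))
    with alpha_i the angle between entry and exit rays at nucleosome i."""
    if system.mode != "effective_angle":
        raise ValueError("energy_nucl_angle requires effective_angle mode")
    p = system.params
    pos = system.pos if pos is None else pos
    t = system.angle_triplets
    v1 = pos[t[:, 0]] - pos[t[:, 1]]
    v2 = pos[t[:, 2]] - pos[t[:, 1]]
    ca = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    alpha = np.arccos(np.clip(ca, -1.0, 1.0))
    return float(p.kn_eff * np.sum(1.0 - np.cos(alpha - p.alpha_n_deg * DEG)))


def total_energy(system: BeadSystem, pos: np.ndarray | None = None,
                 pairs: np.ndarray | None = None) -> EnergyReport:
    """Full energy report; Utot = Us + Un + Ul + Up + Uh + ULJ + Ub."""
    rep = energy_harmonic(system, pos, pairs)
    rep.ULJ = energy_lj(system, pos)
    rep.Ub = energy_bend(system, pos)
    return rep


# ---------------------------------------------------------------------------
# dynamics


def _kernel_args(system: BeadSystem):
    p = system.params
    bonds = [(system.bonds_dna, p.ks, p.rs)]
    if system.mode == "explicit_core":
        bonds.append((system.bonds_wrap, p.kn, p.rn))
    bonds.append((system.bonds_h1, p.kl, p.rl))
    if len(system.bonds_protein):
        bonds.append((system.bonds_protein, p.kp, p.protein_rest_length()))
    bi = np.concatenate([b[:, 0] for b, _, _ in bonds]).astype(np.int64)
    bj = np.concatenate([b[:, 1] for b, _, _ in bonds]).astype(np.int64)
    bk = np.concatenate([np.full(len(b), k) for b, k, _ in bonds])
    br0 = np.concatenate([np.full(len(b), r) for b, _, r in bonds])

    t = system.bend_triplets
    ta, tb, tc = (t[:, 0].astype(np.int64), t[:, 1].astype(np.int64),
                  t[:, 2].astype(np.int64))
    tk = np.full(len(t), p.kb)

    at = system.angle_triplets
    aa, ab, ac = (at[:, 0].astype(np.int64), at[:, 1].astype(np.int64),
                  at[:, 2].astype(np.int64))
    kA = np.full(len(at), p.kn_eff)
    return (bi, bj, bk, br0, ta, tb, tc, tk, aa, ab, ac, kA,
            p.alpha_n_deg * DEG)


def forces(system: BeadSystem, pos: np.ndarray | None = None,
           pairs: np.ndarray | None = None) -> np.ndarray:
    """-grad(Utot) for the current (or given) coordinates.

    ``pairs`` freezes the inter-nucleosome pair list (indices into the
    nucleosome list); by default it is recomputed greedily."""
    p = system.params
    pos = np.ascontiguousarray(system.pos if pos is None else pos)
    (bi, bj, bk, br0, ta, tb, tc, tk, aa, ab, ac, kA, an) = \
        _kernel_args(system)
    two_a = 2.0 * p.a
    cap = max(system.n_dna * 60, 1024)
    lj_i = np.empty(cap, dtype=np.int64)
    lj_j = np.empty(cap, dtype=np.int64)
    n_lj = K.build_lj_list(pos, system.n_dna, two_a, lj_i, lj_j)
    if n_lj < 0:
        raise RuntimeError("LJ pair list overflow")
    if pairs is None:
        pairs = pair_nucleosomes(pos[system.nucleosome_beads], p)
    beads = system.nucleosome_beads[pairs].astype(np.int64) if len(pairs) \
        else np.empty((0, 2), dtype=np.int64)
    f = np.zeros_like(pos)
    use_pairs = p.kh > 0.0 or p.morse
    status = K.compute_forces(
        pos, f, system.n_dna, bi, bj, bk, br0, ta, tb, tc, tk,
        aa, ab, ac, kA, an, lj_i, lj_j, n_lj, p.epsilon, two_a,
        beads[:, 0].copy(), beads[:, 1].copy(),
        len(beads) if use_pairs else 0,
        p.kh, p.rh, p.morse, p.morse_D)
    if status == K.STATUS_LJ_OVERLAP:
        raise FloatingPointError("coincident DNA beads: LJ diverges")
    return f


@dataclass
class BDResult:
    """Trajectory frames and diagnostics of one BD run."""

    system: BeadSystem
    frames: np.ndarray             # (F, n_beads, 3)
    sample_every: int
    equil_steps: int
    n_steps: int
    energies: pd.DataFrame
    steady: bool
    drift: dict

    @property
    def nucleosome_trajectory(self) -> np.ndarray:
        return self.frames[:, self.system.nucleosome_beads, :]


_NOISE_CHUNK = 4000


def _integrate(system, n_steps, sample_every, seed, noise, frames,
               limit_disp=0.0):
    p = system.params
    (bi, bj, bk, br0, ta, tb, tc, tk, aa, ab, ac, kA, an) = \
        _kernel_args(system)
    mu = system.mobilities()
    sigma = np.sqrt(2.0 * mu)[None, :, None]
    rng = np.random.default_rng(seed)
    nuc_idx = system.nucleosome_beads.astype(np.int64)
    nf = 0
    status = K.STATUS_OK
    done = 0
    pos = system.pos
    if not pos.flags.c_contiguous:
        pos = np.ascontiguousarray(pos)
        system.pos = pos
    while done < n_steps:
        chunk = min(_NOISE_CHUNK, n_steps - done)
        if noise:
            eta = rng.standard_normal((chunk, system.n_beads, 3)) * sigma
        else:
            eta = np.zeros((chunk, system.n_beads, 3))
        status, steps, nf = K.integrate_chunk(
            pos, mu, system.n_dna, eta, done, sample_every,
            bi, bj, bk, br0, ta, tb, tc, tk, aa, ab, ac, kA, an,
            p.epsilon, 2.0 * p.a,
            nuc_idx, p.nucl_pair_cutoff,
            p.max_tail_partners, p.kh, p.rh, p.morse, p.morse_D,
            10, 1.5 * p.rs, max(system.n_dna * 60, 1024), p.a,
            limit_disp, frames, nf)
        done += steps
        if status != K.STATUS_OK:
            break
    if status == K.STATUS_UNSTABLE:
        raise BDInstabilityError(
            f"bead displacement exceeded a = {p.a} rs at step {done}; "
            "reduce the timestep (dt) or soften stiff parameters")
    if status == K.STATUS_LJ_OVERLAP:
        raise BDInstabilityError(
            f"coincident DNA beads at step {done}: LJ force diverged; "
            "reduce the timestep (dt)")
    if status == K.STATUS_LIST_OVERFLOW:
        raise RuntimeError("neighbor list overflow; system collapsed?")
    return nf


def dna_chain_system(n_beads: int, params: ModelParams | None = None,
                     ) -> BeadSystem:
    """A bare, straight DNA chain (no nucleosomes): backbone springs,
    WLC bending and excluded volume only.  Used to validate the
    integrator against analytic references (bond-length equipartition,
    free diffusion, persistence length)."""
    params = params or ModelParams()
    pos = np.zeros((n_beads, 3))
    pos[:, 0] = np.arange(n_beads) * params.rs
    empty2 = np.empty((0, 2), dtype=np.int64)
    centers = np.arange(1, n_beads - 1)
    bend = np.stack([centers - 1, centers, centers + 1], axis=1) \
        if n_beads >= 3 else np.empty((0, 3), dtype=np.int64)
    bonds = np.stack([np.arange(n_beads - 1), np.arange(1, n_beads)],
                     axis=1) if n_beads >= 2 else empty2
    return BeadSystem(
        mode="effective_angle", params=params, pos=pos, n_dna=n_beads,
        M=0, linker_nl=np.empty(0, dtype=np.int64),
        wrapped=np.empty((0, WRAP_BEADS), dtype=np.int64),
        nucleosome_beads=np.empty(0, dtype=np.int64),
        bonds_dna=bonds, bonds_wrap=empty2, bonds_h1=empty2,
        angle_triplets=np.empty((0, 3), dtype=np.int64),
        bend_triplets=bend)


def integrate_system(system: BeadSystem, n_steps: int, sample_every: int,
                     seed: int, noise: bool = True) -> np.ndarray:
    """Integrate in place, returning sampled frames
    (n_steps // sample_every, n_beads, 3)."""
    n_frames = n_steps // sample_every if sample_every > 0 else 0
    frames = np.empty((n_frames, system.n_beads, 3))
    nf = _integrate(system, n_steps, sample_every, seed, noise, frames)
    return frames[:nf]


def step(system: BeadSystem, seed: int, noise: bool = True) -> np.ndarray:
    """Advance the system by a single Euler-Maruyama step in place and
    return the new coordinates."""
    frames = np.empty((0, system.n_beads, 3))
    _integrate(system, 1, 0, seed, noise, frames)
    return system.pos


def _drift_test(series: np.ndarray) -> tuple[bool, float]:
    """Sliding-window slope test: drift of the window mean over the
    last half of the series, relative to its standard deviation."""
    n = len(series)
    if n < 8:
        return False, float("nan")
    half = series[n // 2:]
    res = stats.linregress(np.arange(len(half)), half)
    sd = half.std()
    rel = abs(res.slope) * len(half) / sd if sd > 0 else 0.0
    return bool(rel < 1.0), float(rel)


def run(M: int, linker_bp, rho: float, theta_p_deg, params: ModelParams,
        n_steps: int, sample_every: int, seed: int,
        mode: str = "explicit_core", equil_steps: int = 0,
        noise: bool = True) -> BDResult:
    """Build, equilibrate and sample one chromatin system.

    Protein springs are placed on a fraction ``rho`` of linkers (rest
    length from ``theta_p_deg`` and the protein span), the system is
    integrated for ``equil_steps`` without sampling and then for
    ``n_steps`` recording a frame every ``sample_every`` steps.
    Steady state is declared when the windowed means of Utot and the
    radius of gyration are drift-free over the sampled frames.
    """
    if np.isscalar(theta_p_deg):
        params = params.with_(theta_p_deg=float(theta_p_deg), rho=rho)
    else:
        params = params.with_(theta_p_deg=tuple(theta_p_deg), rho=rho)
    seeds = spawn_seeds(seed, 3)
    rng = np.random.default_rng(seeds[1])
    occ = rng.random(max(M - 1, 0)) < rho
    system = init_conformation(M, linker_bp, params, mode=mode,
                               seed=seeds[0],
                               occupied_linkers=occ if rho > 0 else None)
    if rho > 0.0:
        attach_protein_bonds(system, occ)
    if n_steps == 0:
        frames = system.pos[None].copy()
        nf = 1
    else:
        # push-off: relax residual construction overlaps with capped
        # displacements before free dynamics
        _integrate(system, 4000, 0, seeds[2] + 2, noise,
                   np.empty((0, system.n_beads, 3)),
                   limit_disp=0.05 * params.rs)
        if equil_steps > 0:
            _integrate(system, equil_steps, 0, seeds[2], noise,
                       np.empty((0, system.n_beads, 3)))
        n_frames = n_steps // sample_every if sample_every > 0 else 0
        frames = np.empty((n_frames, system.n_beads, 3))
        nf = _integrate(system, n_steps, sample_every, seeds[2] + 1, noise,
                        frames)
    frames = frames[:nf]
    reports = [total_energy(system, f) for f in frames]
    energies = pd.DataFrame(
        {c: [getattr(r, c) for r in reports]
         for c in ("Us", "Un", "Ul", "Up", "Uh", "ULJ", "Ub")})
    energies["Utot"] = [r.Utot for r in reports]
    from .contacts import radius_of_gyration
    energies["Rg"] = [radius_of_gyration(f[system.nucleosome_beads])
                      if M > 1 else np.nan for f in frames]
    steady_u, drift_u = _drift_test(energies["Utot"].to_numpy())
    steady_r, drift_r = _drift_test(energies["Rg"].to_numpy()) \
        if M > 1 else (True, 0.0)
    return BDResult(system=system, frames=frames, sample_every=sample_every,
                    equil_steps=equil_steps, n_steps=n_steps,
                    energies=energies, steady=steady_u and steady_r,
                    drift={"Utot": drift_u, "Rg": drift_r})
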