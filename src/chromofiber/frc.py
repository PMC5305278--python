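"""Freely-rotating-chain (FRC) chromatin conformation generator.

Chromatin is modelled as a chain of unit tangent vectors of bond length
b = 2a (one helical repeat, 10.5 bp).  Three kinds of internal joints
set the polar angle between consecutive tangents:

* DNA joints turn by the small angle ``theta_d`` (default
  sqrt(4a/Lp), which reproduces a 150 bp persistence length) with the
  azimuth drawn uniformly on [0, 2pi);
* nucleosome joints turn by ``theta_n = pi - alpha_n`` (120 deg for the
  default entry/exit angle of 60 deg) with the azimuth restricted to
  +-10 deg about the anti-parallel-transported bend direction of the
  previous nucleosome, which produces the familiar zig-zag;
* protein joints -- with probability ``rho`` the middle joint of a
  linker is bent by ``theta_p`` (a fixed angle or an angle drawn
  uniformly from a range), emulating a bound DNA-bending non-histone
  protein such as nhp6 or HMG-B.

Each nucleosome vertex is flanked by ``wrap_bonds_per_side``
histone-bound bonds (default 1 per side): the entry/exit DNA segments
whose relative orientation the histone core constrains.

The ensemble builder is vectorized across realizations and only
retains nucleosome vertex positions; ``build_chain_3d`` /
``build_chain_2d`` return a fully annotated single chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .core import BP_PER_RS, DEG, ModelParams

JOINT_DNA = 0
JOINT_NUCLEOSOME = 1
JOINT_PROTEIN = 2

JOINT_NAMES = {JOINT_DNA: "DNA", JOINT_NUCLEOSOME: "NUCLEOSOME",
               JOINT_PROTEIN: "PROTEIN"}

_PHI_RESTRICT = 10.0 * DEG   # azimuth half-range at restricted joints


class LinkerError(ValueError):
    """A linker is too short for the requested construction."""


@dataclass
class FRCChain:
    """A single FRC conformation.

    ``vertices`` has one more row than ``tangents``; internal joint
    ``i`` (between tangents ``i-1`` and ``i``) is described by
    ``joint_kind[i-1]`` and ``joint_theta[i-1]``.  Coordinates are in
    units of rs (= 2a = 3.57 nm).
    """

    tangents: np.ndarray
    vertices: np.ndarray
    joint_kind: np.ndarray
    joint_theta: np.ndarray
    nucleosome_index: np.ndarray
    linker_bp: np.ndarray

    @property
    def n_bonds(self) -> int:
        return len(self.tangents)

    @property
    def nucleosome_positions(self) -> np.ndarray:
        return self.vertices[self.nucleosome_index]

    @property
    def n_proteins(self) -> int:
        return int(np.sum(self.joint_kind == JOINT_PROTEIN))

    def measured_joint_angles(self) -> np.ndarray:
        """Angle between consecutive tangents at every internal joint."""
        c = np.einsum("ij,ij->i", self.tangents[:-1], self.tangents[1:])
        return np.arccos(np.clip(c, -1.0, 1.0))


def theta_d(params: ModelParams) -> float:
    """DNA joint turn angle (rad); see :attr:`ModelParams.theta_d`."""
    return params.theta_d


def _resolve_linkers(linker_bp, M: int, R: int, rng) -> np.ndarray:
    """Per-(realization, linker) bond counts, shape (R, M-1)."""
    if callable(linker_bp):
        bp = np.asarray(linker_bp((R * (M - 1)), rng), float).reshape(R, M - 1)
    else:
        bp = np.asarray(linker_bp, float)
        if bp.ndim == 0:
            bp = np.full((R, M - 1), float(bp))
        elif bp.shape == (M - 1,):
            bp = np.broadcast_to(bp, (R, M - 1)).copy()
        else:
            raise ValueError(
                f"linker_bp must be scalar or length M-1={M-1}, got {bp.shape}")
    n_l = bp / BP_PER_RS
    n_int = np.rint(n_l)
    if np.any(np.abs(n_l - n_int) > 1e-9) or np.any(n_int < 1):
        raise ValueError("linker lengths must be positive multiples of 10.5 bp")
    return n_int.astype(np.int64)


def _theta_p_sampler(theta_p_deg, shape, rng) -> np.ndarray:
    if np.isscalar(theta_p_deg):
        return np.full(shape, float(theta_p_deg) * DEG)
    lo, hi = theta_p_deg
    return rng.uniform(float(lo) * DEG, float(hi) * DEG, shape)


def build_ensemble(R: int, M: int, linker_bp, rho: float, theta_p_deg,
                   params: ModelParams, seed: int,
                   two_d: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``R`` independent chains; return nucleosome positions.

    Parameters
    ----------
    R, M : int
        Number of realizations and of nucleosomes per chain.
    linker_bp : float, sequence or callable
        Uniform linker length in bp (multiple of 10.5), a per-linker
        sequence, or a sampler ``f(n, rng) -> bp array`` applied per
        realization and linker.
    rho : float
        Probability that a linker carries one bound bending protein.
    theta_p_deg : float or (lo, hi)
        Protein bend angle (degrees), fixed or uniform in a range.
    two_d : bool
        Build planar chains (random turn sides for DNA and protein
        joints, alternating sides for nucleosomes).

    Returns
    -------
    positions : ndarray, shape (R, M, 3)
        Nucleosome vertex coordinates in rs units.
    protein_counts : ndarray, shape (R,)
        Number of protein joints placed in each realization.
    """
    if M < 2:
        raise ValueError("need at least 2 nucleosomes")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_l = _resolve_linkers(linker_bp, M, R, rng)
    if rho > 0.0:
        short = n_l < 3
        if np.any(short):
            r, m = np.argwhere(short)[0]
            raise LinkerError(
                f"linker {m} (realization {r}) has {n_l[r, m]} bonds; "
                "at least 3 are needed to host a protein joint")

    nb = params.wrap_bonds_per_side
    th_d = params.theta_d
    th_n = params.theta_n
    prot = rng.random((R, M - 1)) < rho
    th_p = _theta_p_sampler(theta_p_deg, (R, M - 1), rng)

    out = np.empty((R, M, 3))
    if two_d:
        _grow_2d(R, M, n_l, nb, th_d, th_n, prot, th_p, rng, out)
    else:
        _grow_3d(R, M, n_l, nb, th_d, th_n, prot, th_p,
                 params.protein_azimuth, rng, out)
    return out, prot.sum(axis=1)


def _grow_3d(R, M, n_l, nb, th_d, th_n, prot, th_p, protein_azimuth, rng, out,
             record=None):
    """Vectorized 3D growth.  ``record`` optionally collects
    (tangent, joint_kind, joint_theta) tuples for R == 1."""
    t = np.zeros((R, 3)); t[:, 0] = 1.0
    u = np.zeros((R, 3)); u[:, 1] = 1.0   # zig-zag bend reference, unit, _|_ t
    p = np.zeros((R, 3))
    run_len = n_l + nb                    # linker bonds + next entry bonds
    mid = (run_len - 1) // 2              # protein-eligible joint of the run
    local_prot = protein_azimuth == "local"

    def advance(theta, phi, restricted, flip, active=None):
        """Turn by polar ``theta`` at azimuth ``phi`` about the current
        reference frame, then advance one bond.  ``flip`` marks joints
        that reset the reference to the anti-bend direction (zig-zag
        alternation); other joints parallel-transport it."""
        nonlocal t, u, p
        b = np.cross(t, u)
        d = np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * b
        tn = np.cos(theta)[:, None] * t + np.sin(theta)[:, None] * d
        tn /= np.linalg.norm(tn, axis=1, keepdims=True)
        un_flip = np.sin(theta)[:, None] * t - np.cos(theta)[:, None] * d
        un_par = u - np.einsum("ij,ij->i", u, tn)[:, None] * tn
        nrm = np.linalg.norm(un_par, axis=1, keepdims=True)
        np.clip(nrm, 1e-300, None, out=nrm)
        un_par /= nrm
        un = np.where(flip[:, None], un_flip, un_par)
        if active is None:
            t, u, p = tn, un, p + tn
        else:
            am = active[:, None]
            t = np.where(am, tn, t)
            u = np.where(am, un, u)
            p = p + np.where(am, tn, 0.0)

    ones = np.ones(R, bool)
    zeros = np.zeros(R, bool)

    def dna_step(active=None):
        advance(np.full(R, th_d), rng.uniform(0, 2 * np.pi, R), zeros, zeros,
                active)
        if record is not None:
            record.append((t[0].copy(), JOINT_DNA, th_d))

    # entry bonds of nucleosome 0; the very first bond is the free initial
    # direction and has no joint before it
    p += t
    if record is not None:
        record.append((t[0].copy(), None, None))
    for _ in range(nb - 1):
        dna_step()

    for m in range(M):
        out[:, m] = p
        advance(np.full(R, th_n),
                rng.uniform(-_PHI_RESTRICT, _PHI_RESTRICT, R), ones, ones)
        if record is not None:
            record.append((t[0].copy(), JOINT_NUCLEOSOME, th_n))
        for _ in range(nb - 1):
            dna_step()
        if m == M - 1:
            break
        rl_m = run_len[:, m]
        mid_m = mid[:, m]
        for j in range(int(rl_m.max())):
            active = j < rl_m
            is_mid = prot[:, m] & (j == mid_m) & active
            if is_mid.any():
                theta = np.where(is_mid, th_p[:, m], th_d)
                if local_prot:
                    phi_p = rng.uniform(0, 2 * np.pi, R)
                else:
                    phi_p = rng.uniform(-_PHI_RESTRICT, _PHI_RESTRICT, R)
                phi = np.where(is_mid, phi_p, rng.uniform(0, 2 * np.pi, R))
                advance(theta, phi, is_mid, zeros, active)
                if record is not None:
                    kind = JOINT_PROTEIN if is_mid[0] else JOINT_DNA
                    record.append((t[0].copy(), kind, theta[0]))
            else:
                dna_step(active)


def _grow_2d(R, M, n_l, nb, th_d, th_n, prot, th_p, rng, out, record=None):
    """Planar growth via heading angles.  Nucleosome turn sides
    alternate (zig-zag); DNA and protein turn sides are random."""
    psi = np.zeros(R)                    # heading
    sigma = np.ones(R)                   # next nucleosome turn side
    p = np.zeros((R, 3))
    run_len = n_l + nb
    mid = (run_len - 1) // 2

    def advance(turn, active=None):
        nonlocal psi, p
        psi = psi + (turn if active is None else np.where(active, turn, 0.0))
        step = np.stack([np.cos(psi), np.sin(psi), np.zeros(R)], axis=1)
        if active is not None:
            step = np.where(active[:, None], step, 0.0)
        p += step
        if record is not None:
            record.append((np.array([np.cos(psi[0]), np.sin(psi[0]), 0.0]),
                           None, None))

    def rand_sign():
        return np.where(rng.random(R) < 0.5, 1.0, -1.0)

    advance(np.zeros(R))                 # first entry bond, free direction
    if record is not None:
        record[-1] = (record[-1][0], None, None)
    for _ in range(nb - 1):
        advance(rand_sign() * th_d)
        if record is not None:
            record[-1] = (record[-1][0], JOINT_DNA, th_d)

    for m in range(M):
        out[:, m] = p
        advance(sigma * th_n)
        sigma = -sigma
        if record is not None:
            record[-1] = (record[-1][0], JOINT_NUCLEOSOME, th_n)
        for _ in range(nb - 1):
            advance(rand_sign() * th_d)
            if record is not None:
                record[-1] = (record[-1][0], JOINT_DNA, th_d)
        if m == M - 1:
            break
        rl_m = run_len[:, m]
        mid_m = mid[:, m]
        for j in range(int(rl_m.max())):
            active = j < rl_m
            is_mid = prot[:, m] & (j == mid_m) & active
            turn = np.where(is_mid, th_p[:, m], th_d) * rand_sign()
            advance(turn, active)
            if record is not None:
                kind = JOINT_PROTEIN if is_mid[0] else JOINT_DNA
                record[-1] = (record[-1][0],
                              kind, th_p[0, m] if is_mid[0] else th_d)


def _build_single(M, linker_bp, rho, theta_p_deg, params, seed, two_d):
    if M < 2:
        raise ValueError("need at least 2 nucleosomes")
    rng = np.random.default_rng(seed)
    n_l = _resolve_linkers(linker_bp, M, 1, rng)
    if rho > 0.0 and np.any(n_l < 3):
        m = int(np.argwhere(n_l[0] < 3)[0][0])
        raise LinkerError(
            f"linker {m} has {n_l[0, m]} bonds; at least 3 are needed to "
            "host a protein joint")
    nb = params.wrap_bonds_per_side
    prot = rng.random((1, M - 1)) < rho
    th_p = _theta_p_sampler(theta_p_deg, (1, M - 1), rng)
    out = np.empty((1, M, 3))
    record: list = []
    if two_d:
        _grow_2d(1, M, n_l, nb, params.theta_d, params.theta_n, prot, th_p,
                 rng, out, record=record)
    else:
        _grow_3d(1, M, n_l, nb, params.theta_d, params.theta_n, prot, th_p,
                 params.protein_azimuth, rng, out, record=record)

    tangents = np.array([r[0] for r in record])
    joint_kind = np.array([r[1] for r in record[1:]], dtype=np.int8)
    joint_theta = np.array([r[2] for r in record[1:]], dtype=float)
    vertices = np.vstack([np.zeros(3), np.cumsum(tangents, axis=0)])
    # nucleosome vertices: nb entry bonds precede the first; each period
    # then adds nb exit bonds plus the (n_l + nb)-bond inter-nucleosome run
    nucleosome_index = nb + np.concatenate(
        [[0], np.cumsum(n_l[0] + 2 * nb)]).astype(np.int64)
    chain = FRCChain(tangents=tangents, vertices=vertices,
                     joint_kind=joint_kind, joint_theta=joint_theta,
                     nucleosome_index=nucleosome_index,
                     linker_bp=n_l[0] * BP_PER_RS)
    # internal consistency: recorded vertices must match the fast path
    assert np.allclose(chain.nucleosome_positions, out[0], atol=1e-9)
    return chain


def build_chain_3d(M: int, linker_bp, rho: float, theta_p_deg,
                   params: ModelParams, seed: int) -> FRCChain:
    """Build one fully annotated 3D FRC chain (see module docstring)."""
    return _build_single(M, linker_bp, rho, theta_p_deg, params, seed,
                         two_d=False)


def build_chain_2d(M: int, linker_bp, rho: float, theta_p_deg,
                   params: ModelParams, seed: int) -> FRCChain:
    """Build one planar FRC chain (random turn sides, alternating
    nucleosome sides), as used for quick visual inspection of the
    zig-zag and its loss under protein binding."""
    return _build_single(M, linker_bp, rho, theta_p_deg, params, seed,
                         two_d=True)


def dna_tangent_ensemble(R: int, n_bonds: int, params: ModelParams,
                         seed: int) -> np.ndarray:
    """Tangent vectors of protein- and nucleosome-free DNA chains.

    Used to validate the theta_d mapping: the tangent autocorrelation
    of these chains must decay as exp(-s/Lp).
    """
    rng = np.random.default_rng(seed)
    th = params.theta_d
    t = np.zeros((R, 3)); t[:, 0] = 1.0
    u = np.zeros((R, 3)); u[:, 1] = 1.0
    out = np.empty((R, n_bonds, 3))
    out[:, 0] = t
    for i in range(1, n_bonds):
        phi = rng.uniform(0, 2 * np.pi, R)
        b = np.cross(t, u)
        d = np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * b
        t = np.cos(th) * t + np.sin(th) * d
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        u = u - np.einsum("ij,ij->i", u, t)[:, None] * t
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        out[:, i] = t
    return out


def fit_persistence_length(tangents: np.ndarray, bond_bp: float = BP_PER_RS,
                           s_max: int | None = None) -> float:
    """Persistence length (bp) from <t(0).t(s)> = exp(-s/Lp).

    Fits log of the ensemble-averaged tangent correlation against
    separation by least squares over separations ``1..s_max``.
    """
    R, N, _ = tangents.shape
    s_max = s_max or min(N - 1, 30)
    corr = np.empty(s_max)
    for s in range(1, s_max + 1):
        corr[s - 1] = np.einsum("rij,rij->", tangents[:, :-s],
                                tangents[:, s:]) / (R * (N - s))
    s = np.arange(1, s_max + 1) * bond_bp
    mask = corr > 0
    slope = np.polyfit(s[mask], np.log(corr[mask]), 1)[0]
    return -1.0 / slope


def sample_linker_lengths(mean_bp: float = 42.0,
                          range_bp: Sequence[float] = (31.5, 73.5),
                          n: int = 1, seed: int | None = None,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw linker lengths from a discrete distribution with a given mean.

    The support is the set of multiples of 10.5 bp spanning
    ``range_bp``; probabilities follow the maximum-entropy (truncated
    geometric) distribution p_j ~ q**j whose mean equals ``mean_bp``.
    With the defaults the support is {31.5, 42, 52.5, 63, 73.5} bp and
    the mean 42 bp, emulating in-vivo nucleosome-repeat-length
    heterogeneity.
    """
    lo, hi = float(range_bp[0]), float(range_bp[1])
    for x in (lo, hi):
        if abs(x / BP_PER_RS - round(x / BP_PER_RS)) > 1e-9:
            raise ValueError("range endpoints must be multiples of 10.5 bp")
    if hi < lo:
        raise ValueError("empty linker range")
    support = np.arange(lo, hi + 0.5 * BP_PER_RS, BP_PER_RS)
    k = len(support)
    if not (support[0] - 1e-9 <= mean_bp <= support[-1] + 1e-9):
        raise ValueError(
            f"mean {mean_bp} bp is infeasible for support "
            f"[{support[0]}, {support[-1]}] bp")
    if rng is None:
        rng = np.random.default_rng(seed)
    if k == 1 or abs(mean_bp - support[0]) < 1e-9:
        probs = np.zeros(k)
        probs[0] = 1.0
    elif abs(mean_bp - support[-1]) < 1e-9:
        probs = np.zeros(k)
        probs[-1] = 1.0
    else:
        target = (mean_bp - support[0]) / BP_PER_RS  # mean index in 0..k-1
        j = np.arange(k)

        def mean_index(log_q):
            w = np.exp(j * log_q)
            return float(j @ w / w.sum()) - target

        log_q = brentq(mean_index, -50.0, 50.0)
        w = np.exp(j * log_q)
        probs = w / w.sum()
    return rng.choice(support, size=n, p=probs)


def linker_sampler(mean_bp: float = 42.0,
                   range_bp: Sequence[float] = (31.5, 73.5)) -> Callable:
    """A ``linker_bp`` callable for :func:`build_ensemble` drawing from
    the variable linker-length distribution."""
    def sampler(n, rng):
        return sample_linker_lengths(mean_bp, range_bp, n, rng=rng)
    return sampler
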