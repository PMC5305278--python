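"""Units, model parameters, and shared geometry helpers.

Internal unit system
--------------------
All simulation code works in reduced units: lengths in units of ``rs``
(one DNA helical repeat, 10.5 bp = 3.57 nm, which is also the DNA bead
diameter ``2a``), energies in units of ``kBT`` (T = 300 K), and time in
units of the Brownian-dynamics timestep ``dt`` (0.04 ns).  Conversions
to nm / bp / ns happen only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict, replace

import numpy as np

# unit conversions (I/O boundary only)
BP_PER_RS = 10.5          # one helical repeat of B-DNA
NM_PER_BP = 0.34
NM_PER_RS = BP_PER_RS * NM_PER_BP   # 3.57 nm

DEG = math.pi / 180.0


class ParameterError(ValueError):
    """Raised when a model parameter violates its physical constraints."""


def kh_from_tilde(kh_tilde: float, a: float = 0.5) -> float:
    """Spring constant kh (kBT/rs^2) from the dimensionless k~h = 2 kh a^2 / kBT."""
    return kh_tilde / (2.0 * a * a)


def kh_to_tilde(kh: float, a: float = 0.5) -> float:
    """Dimensionless inter-nucleosome strength k~h = 2 kh a^2 / kBT."""
    return 2.0 * kh * a * a


@dataclass
class ModelParams:
    """Physical constants and options for the FRC and bead-spring models.

    Lengths are in units of rs (= 2a = 10.5 bp), energies in kBT, and
    times in dt, unless the field name carries an explicit unit suffix.

    Attributes
    ----------
    a : float
        DNA bead radius; 2a is the bead diameter, one helical repeat.
    rs : float
        Rest length of the DNA backbone springs (= 2a).
    ks, kn, kp : float
        Stiffness of the DNA backbone, DNA-core wrapping, and bending
        protein springs (kBT/rs^2).  All default to 100 so that these
        bonds are effectively inextensible.
    kl : float
        Linker-histone (H1) spring stiffness, physically sensible in
        the range 30-100 kBT/rs^2.  The default sits at the stiff end,
        where the H1 clamp holds the entry/exit stems firmly enough
        that the zig-zag survives desk-scale run lengths.
    kh_tilde : float
        Dimensionless inter-nucleosome (histone tail) strength,
        k~h = 2 kh a^2/kBT; 0, 10, 30 and 50 are the studied values.
    kb_kBT_nm : float
        DNA bending stiffness in kBT*nm; 50 kBT*nm reproduces the
        150 bp persistence length.
    kn_eff : float
        Stiffness of the effective nucleosome entry/exit angle term (kBT).
    rn, rl, rh : float
        Rest lengths (rs) of the wrap, H1 and inter-nucleosome springs.
    rp : float or None
        Rest length of the protein spring; computed from ``theta_p``
        and ``protein_span`` via :func:`bend_angle_to_chord` when None.
    epsilon : float
        Depth scale of the repulsive (truncated, shifted) LJ potential.
    Lp_bp : float
        DNA persistence length in bp.
    alpha_n_deg : float
        Nucleosome entry/exit angle alpha_n; the FRC nucleosome joint
        turns the tangent by theta_n = 180 - alpha_n degrees.
    theta_p_deg : float or (lo, hi)
        Protein bend angle, or a uniform range of angles, in degrees.
    rho : float
        Probability that a linker carries one bound bending protein.
    protein_span : int
        Number of bonds bridged by the protein spring in the bead-spring
        model: 3 (~30 bp footprint) or 2 (~20 bp, nhp6/HMG-B sized).
    mu0_dna, mu0_core : float
        Bead mobilities in rs^2/(kBT*dt).
    dt_ns : float
        Physical timestep (information only; dynamics use dt = 1).
    contact_cutoff : float
        Nucleosome contact distance for I(k), 9a = 16 nm.
    nucl_pair_cutoff : float
        Distance below which two nucleosomes may pair via tail springs.
    max_tail_partners : int
        Maximum simultaneous tail partners per nucleosome (2 or 4).
    wrap_bonds_per_side : int
        FRC only: histone-bound bonds flanking each nucleosome vertex.
    theta_d_literal : bool
        Use the linear DNA joint angle 4a/Lp instead of sqrt(4a/Lp).
    protein_azimuth : str
        FRC protein-bend azimuth frame: "local" (isotropic, the bend
        plane follows the preceding joint's own uniformly distributed
        frame) or "zigzag" (restricted to the nucleosome zig-zag frame).
    morse : bool
        Replace the harmonic inter-nucleosome spring by a Morse well.
    morse_D : float
        Morse well depth (kBT); the width is set by 2 D alpha^2 = kh.
    bend_in_wrap : bool
        Apply the WLC bending term at joints inside the wrapped region.
    seed : int
        RNG seed; required for any stochastic operation.
    """

    a: float = 0.5
    rs: float = 1.0
    ks: float = 100.0
    kn: float = 100.0
    kp: float = 100.0
    kl: float = 100.0
    kh_tilde: float = 50.0
    kb_kBT_nm: float = 50.0
    kn_eff: float = 50.0
    rn: float = 8.0 / math.pi
    rl: float = 2.5
    rh: float = 4.2
    rp: float | None = None
    epsilon: float = 1.0
    Lp_bp: float = 150.0
    alpha_n_deg: float = 60.0
    theta_p_deg: float | tuple[float, float] = 90.0
    rho: float = 0.0
    protein_span: int = 3
    mu0_dna: float = 2.0e-4
    mu0_core: float = 1.5e-4
    dt_ns: float = 0.04
    contact_cutoff: float = 4.5
    nucl_pair_cutoff: float = 4.5
    max_tail_partners: int = 2
    wrap_bonds_per_side: int = 1
    theta_d_literal: bool = False
    protein_azimuth: str = "local"
    morse: bool = False
    morse_D: float = 100.0
    bend_in_wrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def kh(self) -> float:
        """Inter-nucleosome spring constant in kBT/rs^2."""
        return kh_from_tilde(self.kh_tilde, self.a)

    @property
    def kb(self) -> float:
        """Discrete WLC bending prefactor kb/(2a) in kBT."""
        return self.kb_kBT_nm / (2.0 * self.a * NM_PER_RS)

    @property
    def theta_n(self) -> float:
        """Tangent turn angle at a nucleosome joint, pi - alpha_n (rad)."""
        return math.pi - self.alpha_n_deg * DEG

    @property
    def theta_d(self) -> float:
        """Tangent turn angle at a DNA joint (rad).

        The default sqrt(4a/Lp) is the freely-rotating-chain relation
        Lp ~ 2b/theta^2 with bond length b = 2a; ``theta_d_literal``
        selects the linear form 4a/Lp instead.
        """
        x = 4.0 * (self.a * BP_PER_RS) / self.Lp_bp
        return x if self.theta_d_literal else math.sqrt(x)

    def theta_p_rad(self) -> float | tuple[float, float]:
        tp = self.theta_p_deg
        if np.isscalar(tp):
            return float(tp) * DEG
        lo, hi = tp
        return (float(lo) * DEG, float(hi) * DEG)

    def protein_rest_length(self) -> float:
        if self.rp is not None:
            return self.rp
        tp = self.theta_p_deg
        ang = float(tp) if np.isscalar(tp) else 0.5 * (tp[0] + tp[1])
        return bend_angle_to_chord(ang * DEG, self.protein_span, self.rs)

    # -- plumbing -----------------------------------------------------------

    def validate(self) -> None:
        for name in ("ks", "kn", "kp", "kl", "kh_tilde", "kb_kBT_nm", "kn_eff",
                     "epsilon", "morse_D"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("a", "rs", "rn", "rl", "rh", "Lp_bp", "mu0_dna",
                     "mu0_core", "dt_ns", "contact_cutoff", "nucl_pair_cutoff"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.rp is not None and self.rp <= 0:
            raise ParameterError("rp must be > 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ParameterError("rho must lie in [0, 1]")
        if not 0.0 < self.alpha_n_deg < 180.0:
            raise ParameterError("alpha_n_deg must lie in (0, 180)")
        tp = self.theta_p_deg
        vals = (tp,) if np.isscalar(tp) else tuple(tp)
        for v in vals:
            if not 0.0 <= v <= 180.0:
                raise ParameterError("theta_p_deg must lie in [0, 180]")
        if self.protein_span not in (2, 3):
            raise ParameterError("protein_span must be 2 or 3")
        if self.max_tail_partners < 1:
            raise ParameterError("max_tail_partners must be >= 1")
        if self.wrap_bonds_per_side < 1:
            raise ParameterError("wrap_bonds_per_side must be >= 1")
        if self.protein_azimuth not in ("local", "zigzag"):
            raise ParameterError("protein_azimuth must be 'local' or 'zigzag'")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["theta_p_deg"], tuple):
            d["theta_p_deg"] = list(d["theta_p_deg"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(
                "unknown parameter key(s): " + ", ".join(sorted(unknown)))
        d = dict(d)
        if "theta_p_deg" in d and isinstance(d["theta_p_deg"], (list, tuple)):
            d["theta_p_deg"] = tuple(float(x) for x in d["theta_p_deg"])
        return cls(**d)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def nondimensionalize(params: ModelParams) -> dict:
    """Dimensionless groups of the bead-spring model.

    Lengths are expressed in units of rs, energies in kBT and times in
    dt; the inter-nucleosome strength is reported as k~h = 2 kh a^2/kBT.
    """
    p = params
    return {
        "kh_tilde": kh_to_tilde(p.kh, p.a),
        "ks": p.ks, "kn": p.kn, "kp": p.kp, "kl": p.kl,
        "kb_over_2a": p.kb,
        "kn_eff": p.kn_eff,
        "rs": p.rs, "rn": p.rn, "rl": p.rl, "rh": p.rh,
        "rp": p.protein_rest_length(),
        "epsilon": p.epsilon,
        "mu0_dna": p.mu0_dna, "mu0_core": p.mu0_core,
        "dt": 1.0,
        "contact_cutoff": p.contact_cutoff,
        "theta_d": p.theta_d,
        "theta_n": p.theta_n,
    }


def bend_angle_to_chord(theta_p: float, span: int, rs: float = 1.0) -> float:
    """Rest length of a protein spring bridging ``span`` bonds bent by ``theta_p``.

    ``theta_p`` (radians) is the total tangent turn the bound protein
    imposes, i.e. the deviation from a straight continuation.  For a
    2-bond protein the whole turn sits at the single internal joint and
    the chord follows from the law of cosines; for a 3-bond protein the
    turn is split equally over the two internal joints (planar arc).
    At 90 and 120 degrees the 3-bond chord evaluates to 2.414 rs and
    2 rs, the nhp6 / HMG-B geometries.

    Monotonically decreasing in theta_p for each span.
    """
    if span == 2:
        return rs * math.sqrt(max(2.0 + 2.0 * math.cos(theta_p), 0.0))
    if span == 3:
        val = 3.0 + 4.0 * math.cos(0.5 * theta_p) + 2.0 * math.cos(theta_p)
        return rs * math.sqrt(max(val, 0.0))
    raise ValueError(f"protein span must be 2 or 3 bonds, got {span}")


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]
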