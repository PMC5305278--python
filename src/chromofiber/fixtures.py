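"""Deterministic synthetic nucleosome geometries.

These are not physical conformations; they exercise the contact
counting logic with pairwise distances placed safely off the 9a
contact boundary (6a, 9.5a, 10a), so every expected I(k) value is
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KINDS = ("ideal_zigzag", "straight_dilute", "collapsed", "random_coil")


@dataclass
class FixtureSpec:
    """Specification of a synthetic geometry.

    ``spacings`` are in units of a (half the DNA bead diameter), the
    unit in which the contact cutoff is 9; coordinates are returned in
    rs units (1 rs = 2 a) to match the simulators.
    """

    kind: str
    M: int
    spacings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {KINDS}")
        if self.M < 2 or (self.kind == "ideal_zigzag" and self.M < 3):
            raise ValueError(f"{self.kind} needs at least "
                             f"{3 if self.kind == 'ideal_zigzag' else 2} points")


def make_fixture(spec: FixtureSpec) -> np.ndarray:
    """Nucleosome coordinates (M, 3) in rs units for ``spec``.

    * ``ideal_zigzag``: planar alternating arrangement with
      |r_i - r_{i+2}| = 6a (stacked next neighbors, in contact) and
      |r_i - r_{i+1}| = 9.5a (neighbors out of contact) exactly.
    * ``straight_dilute``: collinear points spaced 10a; no contacts.
    * ``collapsed``: all points inside a ball of radius a; every pair
      in contact.
    * ``random_coil``: seeded Gaussian walk (step std ``sigma_a``,
      default 3a).
    """
    M = spec.M
    a = 0.5                               # rs units
    if spec.kind == "ideal_zigzag":
        dx = spec.spacings.get("next_neighbor_a", 6.0) * a / 2.0
        d1 = spec.spacings.get("neighbor_a", 9.5) * a
        dy = np.sqrt(d1**2 - dx**2)
        pos = np.zeros((M, 3))
        pos[:, 0] = np.arange(M) * dx
        pos[:, 1] = np.where(np.arange(M) % 2 == 1, dy, 0.0)
        return pos
    if spec.kind == "straight_dilute":
        d = spec.spacings.get("spacing_a", 10.0) * a
        pos = np.zeros((M, 3))
        pos[:, 0] = np.arange(M) * d
        return pos
    if spec.kind == "collapsed":
        r = spec.spacings.get("radius_a", 1.0) * a
        # deterministic spiral on a sphere of radius r/2, all pairwise
        # distances <= r < cutoff
        i = np.arange(M)
        th = np.arccos(1 - 2 * (i + 0.5) / M)
        ph = np.pi * (1 + 5**0.5) * i
        return 0.5 * r * np.stack([np.sin(th) * np.cos(ph),
                                   np.sin(th) * np.sin(ph),
                                   np.cos(th)], axis=1)
    # random_coil
    sigma = spec.spacings.get("sigma_a", 3.0) * a
    rng = np.random.default_rng(spec.seed)
    return np.cumsum(rng.normal(0.0, sigma / np.sqrt(3.0), (M, 3)), axis=0)
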