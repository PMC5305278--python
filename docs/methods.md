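# Methods

`chromofiber` simulates nucleosome-resolved chromatin with two
complementary models and quantifies the resulting fiber geometry
through the neighbor contact statistic I(k).  This note records the
models, the parameter choices, and the numerical decisions, so that
every number the package produces can be traced to an assumption.

## Units

Internal calculations use reduced units: length in `rs` (one DNA
helical repeat, 10.5 bp = 3.57 nm, equal to the DNA bead diameter
`2a`), energy in `kBT` (T = 300 K), and time in the integration step
`dt` (0.04 ns).  Conversions to nm/bp happen only in the I/O layer.
The inter-nucleosome strength is quoted as the dimensionless
`k~h = 2 kh a^2 / kBT`.

## Freely rotating chain (FRC)

The fiber is a chain of unit bonds of length `2a`.  Consecutive bonds
meet at joints with a prescribed polar (turn) angle; the azimuth
convention depends on the joint:

* **DNA joints** turn by `theta_d = sqrt(4a/Lp)` (0.374 rad for
  Lp = 150 bp) with isotropic azimuth.  The square-root form is the
  standard FRC relation `Lp ~ 2b/theta^2`; the package also exposes a
  `theta_d_literal` linear variant (`4a/Lp`), but only the square-root
  mapping reproduces the 150 bp persistence length in the
  tangent-correlation test, so it is the default.
* **Nucleosome joints** turn by `theta_n = 180 - alpha_n` degrees (120
  for the default entry/exit angle `alpha_n` = 60 deg).  The azimuth is
  drawn within +-10 deg of the *anti*-parallel-transported bend
  direction of the previous nucleosome.  This is the unique frame
  choice that produces the two-start zig-zag in which nucleosome i
  stacks near i+2; any other reference degrades into a coil or ring.
* **Protein joints** -- with probability `rho`, independently per
  linker, the middle joint of the inter-nucleosome DNA run is bent by
  `theta_p` (a fixed angle, or drawn uniformly from a range such as
  90-135 deg, the span of bend angles reported for nhp6, HMG-B and
  LEF1).  The +-10 deg azimuth restriction is applied in the local
  dihedral frame of the preceding joint; because that joint is a DNA
  joint with isotropic azimuth, the protein bend direction is
  effectively isotropic, and it is implemented as such
  (`protein_azimuth="local"`).  A `"zigzag"` option instead inherits
  the nucleosome frame, which makes protein bends nearly coplanar with
  the fiber and markedly accelerates the loss of I(2).

Each nucleosome vertex is flanked by one histone-bound bond per side
(`wrap_bonds_per_side`), representing the direction in which the DNA
enters and exits the wrapped superhelix.  Consecutive nucleosomes are
therefore separated by `linker_bp/10.5 + 2` bonds (six bonds, 21.4 nm,
for the canonical 42 bp linker).  This matters quantitatively: without
the flanking bonds, ideal zig-zag geometry places both the i+1 and the
i+2 neighbor at exactly one bond-unit (14.3 nm), inside the 16 nm
contact cutoff, and I(1) saturates at 1 -- the zig-zag signature
I(2) > I(1) would be unobtainable.

With an even number of eligible joints the "middle" of a linker is the
lower-index central joint (deterministic tie-break).  Linkers shorter
than three bonds cannot host a protein joint and raise an error when
`rho > 0`.

The 2D builder (used for quick visual confirmation of the zig-zag and
its destruction) is the planar restriction: DNA and protein joints turn
to a uniformly random side, nucleosome turn sides alternate strictly.

**Variable linker lengths** are drawn from the maximum-entropy
(truncated-geometric) distribution on the multiples of 10.5 bp within
31.5-73.5 bp constrained to a 42 bp mean.  The maximum-entropy form is
the least-informative choice given only the support and the mean;
empirically it is indistinguishable in I(k) from other unimodal choices
with the same mean.

**Ensembles** are generated vectorized across realizations; every
ensemble consumes an independent `SeedSequence`-spawned child seed, so
runs are reproducible bit-exactly for a fixed (seed, realization
count).

## Bead-spring Brownian dynamics

DNA is a chain of N type-1 beads (diameter `2a`) with stiff harmonic
backbone springs (`ks` = 100 kBT/rs^2, rest `rs`) and the discrete
worm-like-chain bending energy `(kb/2a) * sum(1 - cos theta_i)` over
all N-2 internal angles (`kb` = 50 kBT nm).  Although the bending
sum is sometimes written with N-1 terms, a chain of N beads has only
N-2 angles; the extra term is undefined and is not included.  Bending
is applied uniformly, including joints inside the wrapped region,
where the wrap springs dominate anyway; `bend_in_wrap=False` excludes
them.

Each of the M nucleosomes wraps 14 consecutive DNA beads (147 bp) in
~1.7 left-handed turns around a type-2 core bead, held by springs
(`kn` = 100, rest `rn = 8rs/pi`).  A linker-histone (H1) spring
(`kl`, rest `rl = 2.5rs`) clamps the DNA beads immediately before and
after each wrap; the first and last nucleosome of an open chain lack
one of these flanking beads and carry no H1 spring.  The H1 stiffness
defaults to 100 kBT/rs^2, the stiff end of the physically sensible
30-100 range.  The choice matters at desk scale: with a soft clamp
(30) the entry/exit stems of a nucleosome can splay thermally, the
fold between consecutive linkers opens, and the purely geometric
(k~h = 0) zig-zag washes out within the ~10^6-step runs used here;
the stiff clamp preserves it, as it does in the full-length regime.

Excluded volume acts between non-bonded DNA beads through the
repulsive, truncated-and-shifted Lennard-Jones potential
`eps [ (2a/r)^12 - 2 (2a/r)^6 + 1 ]` for r < 2a and exactly zero
beyond.  Chain-bonded neighbor pairs are excluded: their spring fixes
the spacing at `2a`, where the potential vanishes anyway, and the
exclusion avoids force noise at contact.  `eps` = 1 kBT.

**Bending proteins** are springs (`kp` = 100) bridging `span` bonds in
the middle of a linker: span 3 (~30 bp footprint, default) or span 2
(~20 bp, the nhp6/HMG-B size).  The rest length encodes the imposed
bend through the planar-arc chord, `rs*sqrt(2+2cos t)` for span 2 and
`rs*sqrt(3+4cos(t/2)+2cos t)` for span 3; the latter evaluates to
2.414 rs at 90 deg and exactly 2 rs at 120 deg, matching the published
rest lengths for these two proteins at the printed precision.  Using
the closed form everywhere (instead of special-casing those two
angles) keeps the chord strictly monotone in the bend angle.

**Inter-nucleosome (histone tail) attraction**: at every pairing
update, all core pairs closer than `9a` are considered in order of
increasing distance and accepted while both members have fewer than
`max_tail_partners` (default 2, reflecting the finite number of tails;
4 reproduces the many-tail variant) accepted partners.  Accepted pairs
interact through a harmonic spring (`kh = k~h kBT/(2a^2)`, rest
`rh = 4.2rs`) or, optionally, a Morse well with curvature matched to
the same `kh` (`2 D alpha^2 = kh`).  The Morse depth `D` defaults to
100 kBT so that the well is harmonic to within a few percent over the
displacements at which the two forms are compared; only the curvature
is physically constrained.  The pair list is refreshed every 10 steps
by default (configurable down to every step; at M = 20 the choice is
not measurable in I(k)).

**Effective-angle mode** removes the core beads and wrapped DNA:
each nucleosome is a single bead whose entry/exit rays are constrained
by `kn_eff (1 - cos(alpha_i - alpha_n))` with `kn_eff` = 50 kBT.  One
stub bead at each chain end gives every nucleosome a defined angle.
H1 springs are omitted in this mode -- the angle term already encodes
the entry/exit constraint, and a 2.5 rs rest length between beads that
are at most 2 rs apart would be contradictory.

**Dynamics** are overdamped Langevin integrated with Euler-Maruyama:
`r += mu F dt + eta`, each Cartesian noise component
N(0, 2 kBT mu dt), with `mu0 = 2e-4` (DNA) and `1.5e-4` (core) in
rs^2/(kBT dt).  The printed mobility unit "rs/kBT dt" is dimensionally
inconsistent for a mobility; rs^2/(kBT dt) is the reading under which
`mu F dt` is a length.  A step that moves any bead farther than `a`
aborts with a diagnostic suggesting a smaller timestep.

**Initial conformation.**  Wraps are placed as left-handed barrel
helices whose beads sit exactly at `rn` from the core (so the wrap
springs start at rest), with straight linkers continuing along the
local exit tangent.  Linkers designated to carry a protein start
pre-bent by `theta_p` (split over the protein span, in a random
plane), so protein springs also start at rest -- the same principle
applied to every bonded term.  Wrap azimuth and linker bend plane are
retried jointly (bounded retries) to maximize clearance; because bent
fibers are inherently crowded, residual clearances down to 0.3 rs are
accepted and relaxed by a short push-off phase (2000 steps with
per-bead displacements capped at 0.05 rs) before free dynamics.
Without pre-bending, desk-scale runs started from an ideal zig-zag
remain kinetically trapped in it: the tail springs lock the initial
i/i+2 pairs long past 10^6-10^7 steps, a regime the full-scale
(~10^9-step) simulations equilibrate out of but scaled-down runs do
not.

**Steady state** is monitored by a sliding-window slope test on the
sampled total energy and radius of gyration (drift of the fitted
trend over the last half of the series, relative to the series'
standard deviation, below 1).  The flag is diagnostic; it does not
gate sampling.

## Contact statistic

`I(k)` is the fraction of (i, i+k) nucleosome pairs closer than the
contact cutoff (9a = 16 nm, the approximate reach of histone tails),
pooled over pairs and realizations.  Contact is strict inequality;
boundary equality counts as non-contact.  Per-realization
probabilities are retained for uncertainty estimates.  `k_peak` is the
argmax over k >= 1 with ties broken toward smaller k; k_peak = 2
signals zig-zag, k_peak = 1 an irregular locally-bent fiber.  Pooled
counting and per-realization averaging coincide in expectation; both
are available.

## Phase boundary

The transition density `rho*` is the I(1) = I(2) crossing, located by
bisection on fresh ensembles (default 2000 chains of 2000 nucleosomes
per evaluation) until the bracket is below 0.01.  No smoothing is
applied to the order parameter; instead a bootstrap (over
realizations) standard error of I(1) - I(2) at the final midpoint is
propagated through the locally estimated slope.  Non-bracketing
endpoints return a "no transition" result rather than raising.  The
k_peak-based transition definition changes sign at the same point and
is reported alongside in phase scans.

## Problem sizes

Default study sizes are chosen so a full verification pass runs on one
CPU core in minutes: transition densities use >= 2000 realizations of
M = 2000 nucleosomes per bisection evaluation (bisection to a 0.01
bracket); contact-peak checks use >= 1000 realizations; BD runs use
M = 20 nucleosomes with ~10^6-step equilibration followed by >= 50
sampled frames.  These are orders of magnitude below exhaustive
long-run BD (the physical run time of 0.04 s corresponds to ~10^9
steps), which is why BD observables are validated at the level of peak
locations rather than full I(k) curves.

## What the synthetic fixtures do and do not show

The `fixtures` module generates idealized nucleosome geometries
(perfect zig-zag with 6a/9.5a spacings, collinear dilute points,
collapsed clusters, seeded Gaussian coils) whose I(k) values are exact
by construction.  They validate the counting logic completely but say
nothing about chromatin physics; distances are placed safely off the
9a cutoff so no floating-point boundary case can flip a count.

## Known limitations

* The FRC is an ideal chain: no excluded volume and no
  inter-nucleosome attraction; I(k) overlap between distant segments
  is not penalized.
* Proteins are static: occupancy is drawn once per realization or run;
  binding/unbinding kinetics are out of scope.
* Nucleosomes neither slide nor disassemble; no hydrodynamic
  interactions; open chain ends mean terminal nucleosomes lack H1.
* Scaled-down BD runs sample the neighborhood of a mechanically
  relaxed initial state rather than the full conformational ensemble;
  peak locations of I(k) are robust to this (when pooled over
  replicas), absolute I(k) values less so.
* Bead discreteness quantizes the protein-kink geometry: the bent
  half-segments of a 42/52.5/63/73.5 bp linker are 3|3, 3|4, 4|4 and
  4|5 bonds, and the chord of a 90-120 deg kink crosses the 16 nm
  contact cutoff between these cases.  As a result the transition
  density rho*(linker length) is not strictly monotone: it rises
  again at 73.5 bp, where only the strongest bends produce an i/i+1
  contact.
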