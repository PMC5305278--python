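# chromofiber

Coarse-grained simulation of chromatin fiber structure, built to ask a
specific question: what do DNA-bending non-histone proteins (nhp6,
HMG-B, LEF1 and relatives) do to the regular "30-nm" zig-zag
arrangement of nucleosomes?

Stiff linker DNA plus the restricted angle between the DNA entering
and exiting a nucleosome favor a two-start zig-zag in which nucleosome
*i* stacks against *i+2*.  Architectural proteins that bind linker DNA
and kink it by 90-135 degrees disrupt exactly the geometry that
sustains this order.  `chromofiber` quantifies the competition with
two models:

* **FRC** (`chromofiber.frc`) — chromatin as a freely rotating chain
  of 10.5 bp tangent vectors: DNA joints turn by
  `theta_d = sqrt(4a/Lp)`, nucleosome joints by
  `theta_n = 180deg - alpha_n` within a zig-zag-preserving azimuthal
  frame, and, with probability `rho` per linker, a mid-linker joint is
  kinked by the protein bend angle `theta_p`.  Thousands of
  2000-nucleosome equilibrium conformations per second.
* **Bead-spring BD** (`chromofiber.bd`) — an overdamped-Langevin
  (Euler-Maruyama) engine where each nucleosome wraps 14 DNA beads
  (147 bp) around a histone core bead, with linker-histone springs,
  excluded volume, worm-like-chain bending, histone-tail springs
  between nearby cores, and bending proteins as springs that pull
  linker ends together.

Structure is quantified by the contact statistic **I(k)** — the
probability that a nucleosome lies within 16 nm (9a) of its k-th
neighbor.  `k_peak = 2` is the zig-zag signature; `k_peak = 1` marks
the irregular, locally bent fiber.  The phase module locates the
critical protein density `rho*` where `I(1) = I(2)`, as a function of
linker length and bend angle.

See `docs/methods.md` for the full model definitions, parameter
defaults and numerical choices.

## Worked example

```python
import numpy as np
from chromofiber import (ModelParams, build_ensemble, contact_profile,
                         k_peak, critical_rho)

params = ModelParams()          # 42 bp linkers, alpha_n = 60 deg, Lp = 150 bp

# 500 chains of 1000 nucleosomes, no proteins vs. proteins on half the
# linkers (90-degree bends)
for rho in (0.0, 0.5):
    pos, nprot = build_ensemble(500, 1000, linker_bp=42.0, rho=rho,
                                theta_p_deg=90.0, params=params, seed=1)
    prof = contact_profile(pos, cutoff=params.contact_cutoff, k_max=6)
    print(f"rho={rho}: I(k) = {np.round(prof.I, 3)}  k_peak = {k_peak(prof)}")

# critical protein density for the zig-zag -> irregular transition
crit = critical_rho(linker_bp=42.0, theta_p_deg=90.0, M=1000,
                    realizations=500, seed=2)
print(f"rho* = {crit.rho_star:.3f} +- {crit.se:.3f}")
```

Output:

```
rho=0.0: I(k) = [0.    0.253 0.005 0.015 0.001 0.003]  k_peak = 2
rho=0.5: I(k) = [0.376 0.294 0.092 0.052 0.032 0.026]  k_peak = 1
rho* = 0.371 +- 0.001
```

Without proteins, one nucleosome in four sits within 16 nm of its
next-nearest neighbor while essentially none touches its direct
neighbor — the zig-zag.  With proteins on half the linkers the
pattern inverts (`k_peak` moves from 2 to 1), and the crossing point
`rho*` of I(1) and I(2) marks the transition density.

## Command line

```sh
chromofiber frc build -M 24 --linker-bp 42 --rho 0.24 --theta-p 120 \
    --two-d --seed 1 --out out/frc
chromofiber bd run -M 20 --rho 0.5 --theta-p 120 --kh-tilde 50 \
    --steps 1e6 --equil-steps 1e6 --seed 1 --out out/bd
chromofiber contacts ik --in out/bd/nucleosomes.xyz --out out/ik.csv
chromofiber phase scan --axis2 linker:42,52.5,63,73.5 --rho 0:1:0.1 \
    --seed 1 --out out/phase
chromofiber fixtures make --kind ideal_zigzag -M 24 --out zz.xyz
```

Exit codes: 0 success, 2 validation error, 3 numerical instability.
Every output directory carries a `manifest.json` (parameters, seeds,
checksums) sufficient to reproduce the run.

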