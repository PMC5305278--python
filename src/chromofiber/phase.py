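"""Zig-zag -> irregular phase boundary of the FRC chromatin model.

The order parameter is the difference I(1) - I(2): negative in the
zig-zag phase (next-neighbor contacts dominate), positive in the
irregular phase.  The critical protein density rho* is the I(1) = I(2)
crossing, located by bisection on ensembles of FRC chains; the
alternative order parameter based on the I(k) peak position (k_peak
leaving 2) changes sign at the same point and is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import contact_profile, k_peak
from .core import ModelParams, spawn_seeds
from .frc import build_ensemble


@dataclass
class CriticalDensity:
    """Result of a transition-density search."""

    rho_star: float
    se: float
    bracket: tuple[float, float]
    transition: bool
    n_evaluations: int
    status: str = "ok"


@dataclass
class PhaseGrid:
    """Per-cell contact statistics over (rho x linker) or (rho x theta_p)."""

    rho_values: np.ndarray
    axis2_values: np.ndarray
    axis2_kind: str                      # "linker_bp" or "theta_p_deg"
    I1: np.ndarray                       # (len(axis2), len(rho))
    I2: np.ndarray
    kpeak: np.ndarray
    realizations: int
    boundary: list = field(default_factory=list)   # CriticalDensity per column

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, a2 in enumerate(self.axis2_values):
            crit = self.boundary[i] if self.boundary else None
            for j, rho in enumerate(self.rho_values):
                rows.append({
                    "rho": rho, self.axis2_kind: a2,
                    "I1": self.I1[i, j], "I2": self.I2[i, j],
                    "k_peak": self.kpeak[i, j],
                    "rho_star": crit.rho_star if crit else np.nan,
                    "rho_star_se": crit.se if crit else np.nan,
                    "realizations": self.realizations,
                })
        return pd.DataFrame(rows)


def _order_parameter(rho, linker_bp, theta_p_deg, M, realizations, params,
                     seed, return_profile=False):
    pos, _ = build_ensemble(realizations, M, linker_bp, rho, theta_p_deg,
                            params, seed)
    prof = contact_profile(pos, cutoff=params.contact_cutoff, k_max=3)
    diff = prof.I[0] - prof.I[1]
    return (diff, prof) if return_profile else diff


def _bootstrap_se_diff(prof, n_boot=200, seed=0):
    """Bootstrap (over realizations) standard error of I(1) - I(2)."""
    rng = np.random.default_rng(seed)
    per = prof.per_realization
    R = per.shape[0]
    idx = rng.integers(0, R, size=(n_boot, R))
    d = per[:, 0] - per[:, 1]
    return float(d[idx].mean(axis=1).std(ddof=1))


def critical_rho(linker_bp=42.0, theta_p_deg=90.0, M: int = 2000,
                 realizations: int = 2000,
                 params: ModelParams | None = None, seed: int = 0,
                 tol: float = 0.01,
                 rho_bracket: tuple[float, float] = (0.0, 1.0)
                 ) -> CriticalDensity:
    """Locate the critical protein density rho* where I(1) = I(2).

    Bisects the I(1) - I(2) sign change over ``rho_bracket`` until the
    bracket is narrower than ``tol``.  Every evaluation generates a
    fresh ensemble of ``realizations`` chains of ``M`` nucleosomes from
    an independent child seed.  If the endpoints do not bracket a sign
    change the result reports ``transition=False`` (no exception).

    The returned standard error propagates the bootstrap spread of
    I(1) - I(2) at the final midpoint through the local slope of the
    order parameter across the final bracket.
    """
    params = params or ModelParams()
    n_evals = int(np.ceil(np.log2(
        (rho_bracket[1] - rho_bracket[0]) / tol))) + 8
    seeds = spawn_seeds(seed, n_evals)
    it = iter(seeds)

    lo, hi = rho_bracket
    f_lo = _order_parameter(lo, linker_bp, theta_p_deg, M, realizations,
                            params, next(it))
    f_hi = _order_parameter(hi, linker_bp, theta_p_deg, M, realizations,
                            params, next(it))
    evals = 2
    if not (f_lo < 0.0 < f_hi):
        return CriticalDensity(rho_star=float("nan"), se=float("nan"),
                               bracket=(lo, hi), transition=False,
                               n_evaluations=evals,
                               status="no transition in range")
    prof_mid = None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid, prof_mid = _order_parameter(
            mid, linker_bp, theta_p_deg, M, realizations, params, next(it),
            return_profile=True)
        evals += 1
        if f_mid < 0.0:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    rho_star = 0.5 * (lo + hi)
    if prof_mid is not None:
        se_diff = _bootstrap_se_diff(prof_mid, seed=seeds[-1])
        slope = (f_hi - f_lo) / max(hi - lo, 1e-12)
        se = se_diff / abs(slope) if slope != 0 else float("nan")
    else:
        se = float("nan")
    return CriticalDensity(rho_star=rho_star, se=se, bracket=(lo, hi),
                           transition=True, n_evaluations=evals)


def scan_phase(rho_values, axis2_values, axis2_kind: str = "linker_bp",
               M: int = 2000, realizations: int = 500,
               params: ModelParams | None = None, seed: int = 0,
               theta_p_deg=(90.0, 135.0), linker_bp: float = 42.0,
               locate_boundary: bool = True,
               boundary_realizations: int | None = None) -> PhaseGrid:
    """Fill a (rho x linker-length) or (rho x bend-angle) phase grid.

    Per cell, an FRC ensemble is generated and I(1), I(2) and k_peak
    recorded; per column of ``axis2`` the critical density is located
    with :func:`critical_rho`.  When scanning linker lengths, protein
    angles follow ``theta_p_deg``; when scanning bend angles, the
    linker length is ``linker_bp``.
    """
    if axis2_kind not in ("linker_bp", "theta_p_deg"):
        raise ValueError("axis2_kind must be 'linker_bp' or 'theta_p_deg'")
    params = params or ModelParams()
    rho_values = np.asarray(rho_values, float)
    axis2_values = np.asarray(axis2_values, float)
    if rho_values.size == 0 or axis2_values.size == 0:
        raise ValueError("grids must be nonempty")
    n1, n2 = len(axis2_values), len(rho_values)
    I1 = np.empty((n1, n2)); I2 = np.empty((n1, n2))
    kp = np.zeros((n1, n2), dtype=np.int64)
    seeds = spawn_seeds(seed, n1 * (n2 + 1))
    boundary = []
    for i, a2 in enumerate(axis2_values):
        lb = a2 if axis2_kind == "linker_bp" else linker_bp
        tp = theta_p_deg if axis2_kind == "linker_bp" else a2
        for j, rho in enumerate(rho_values):
            pos, _ = build_ensemble(realizations, M, lb, rho, tp, params,
                                    seeds[i * (n2 + 1) + j])
            prof = contact_profile(pos, cutoff=params.contact_cutoff,
                                   k_max=min(10, M - 1))
            I1[i, j], I2[i, j] = prof.I[0], prof.I[1]
            try:
                kp[i, j] = k_peak(prof)
            except ValueError:
                kp[i, j] = 0
        if locate_boundary and len(rho_values) > 1:
            crit = critical_rho(
                lb, tp, M=M,
                realizations=boundary_realizations or realizations,
                params=params, seed=seeds[i * (n2 + 1) + n2],
                rho_bracket=(float(rho_values.min()),
                             float(rho_values.max())))
            boundary.append(crit)
    return PhaseGrid(rho_values=rho_values, axis2_values=axis2_values,
                     axis2_kind=axis2_kind, I1=I1, I2=I2, kpeak=kp,
                     realizations=realizations, boundary=boundary)
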