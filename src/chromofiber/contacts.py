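"""Nucleosome contact statistic I(k) and polymer size measures.

I(k) is the probability that a nucleosome lies within a contact cutoff
(16 nm = 9a, the estimated reach of histone-tail interactions) of its
k-th neighbor along the chain.  A peak at k = 2 signals the zig-zag
("30-nm") arrangement in which next neighbors stack; a peak at k = 1
signals an irregular, locally bent fiber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ContactProfile:
    """Pooled contact probabilities I(k) for k = 1..k_max.

    ``contacts[k-1]`` / ``totals[k-1]`` are pooled over all (i, i+k)
    pairs and realizations; ``per_realization`` holds the realization-
    resolved probabilities (realizations x k_max) from which the
    spread of I(k) can be estimated.
    """

    I: np.ndarray
    contacts: np.ndarray
    totals: np.ndarray
    cutoff: float
    realizations: int
    per_realization: np.ndarray

    @property
    def k(self) -> np.ndarray:
        return np.arange(1, len(self.I) + 1)

    def sem(self) -> np.ndarray:
        """Standard error of I(k) across realizations."""
        if self.realizations < 2:
            return np.full_like(self.I, np.nan)
        return self.per_realization.std(axis=0, ddof=1) / np.sqrt(
            self.realizations)


def _as_ensemble(positions) -> np.ndarray:
    pos = np.asarray(positions, float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.ndim != 3 or pos.shape[-1] != 3 or pos.shape[0] == 0:
        raise ValueError("positions must have shape (R, M, 3) or (M, 3)")
    return pos


def contact_profile(positions, cutoff: float = 4.5,
                    k_max: int | None = None) -> ContactProfile:
    """Compute I(k) from nucleosome coordinates.

    Parameters
    ----------
    positions : array-like, (R, M, 3) or (M, 3)
        Nucleosome coordinates per realization, in the same length unit
        as ``cutoff`` (rs units and cutoff 4.5 = 9a by default).
    cutoff : float
        Contact distance; a pair is in contact when strictly closer
        than this (boundary equality counts as non-contact).
    k_max : int, optional
        Largest neighbor offset, default min(20, M-1).
    """
    pos = _as_ensemble(positions)
    R, M, _ = pos.shape
    if M < 2:
        raise ValueError("need at least 2 nucleosomes")
    k_max = k_max if k_max is not None else min(20, M - 1)
    if not 1 <= k_max <= M - 1:
        raise ValueError(f"k_max must lie in [1, {M - 1}]")
    contacts = np.empty(k_max, dtype=np.int64)
    totals = np.empty(k_max, dtype=np.int64)
    per_real = np.empty((R, k_max))
    for k in range(1, k_max + 1):
        d = np.linalg.norm(pos[:, k:] - pos[:, :-k], axis=2)
        hit = d < cutoff
        contacts[k - 1] = int(hit.sum())
        totals[k - 1] = R * (M - k)
        per_real[:, k - 1] = hit.mean(axis=1)
    return ContactProfile(I=contacts / totals, contacts=contacts,
                          totals=totals, cutoff=cutoff, realizations=R,
                          per_realization=per_real)


def k_peak(profile: ContactProfile) -> int:
    """Neighbor offset at which I(k) is maximal; ties break toward
    smaller k.  Raises on an all-zero profile (no contacts at all)."""
    if not np.any(profile.I > 0):
        raise ValueError("contact profile is identically zero; "
                         "k_peak is undefined")
    return int(np.argmax(profile.I)) + 1


def radius_of_gyration(positions) -> float:
    """Root-mean-square distance of points from their centroid,
    averaged (in the squared sense) over realizations."""
    pos = _as_ensemble(positions)
    if pos.shape[1] < 2:
        raise ValueError("need at least 2 points")
    dev = pos - pos.mean(axis=1, keepdims=True)
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=2))))


def end_to_end_rms(positions) -> float:
    """sqrt(<|r_last - r_first|^2>) over realizations."""
    pos = _as_ensemble(positions)
    if pos.shape[1] < 2:
        raise ValueError("need at least 2 points")
    return float(np.sqrt(np.mean(np.sum(
        (pos[:, -1] - pos[:, 0])**2, axis=1))))


def scaling_exponent(sizes, values) -> tuple[float, float]:
    """Fitted exponent nu (and its standard error) of value ~ size**nu
    by least squares on log-log axes.  A rigid rod gives nu = 1, an
    ideal chain nu = 0.5."""
    sizes = np.asarray(sizes, float)
    values = np.asarray(values, float)
    res = stats.linregress(np.log(sizes), np.log(values))
    return float(res.slope), float(res.stderr)
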