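"""Observables of a GSC stationary state: contact maps, P_c(s) scaling, gyration.

Everything here derives from the squared-distance matrix D.  Under the
Gaussian ansatz the vector between beads i and j is isotropic Gaussian
with per-axis variance D_ij, so the probability that they lie within a
capture radius r_c is the 3D Gaussian radial CDF

    P_ij = erf(u) - (2/sqrt(pi)) u exp(-u^2),    u = r_c / sqrt(2 D_ij).

The sequence-averaged contact probability P_c(s) over pairs at genomic
separation s, and the slope of log P_c vs log s over an intermediate
window, diagnose the folding regime: s^-2 for a swollen coil, s^-3/2 at
the theta point, a plateau for the equilibrium globule and s^-1 for the
crumpled state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from .model import ChromatinAnnotation

__all__ = [
    "ContactMap",
    "ScalingFit",
    "GyrationReport",
    "contact_probability",
    "mean_contact_curve",
    "fit_scaling_exponent",
    "gyration",
    "radius_of_gyration",
]

DEFAULT_CAPTURE_RADIUS = 1.0  # l


@dataclass
class ContactMap:
    """Pairwise contact probabilities (model) or normalized counts (data)."""

    P: np.ndarray
    r_c: Optional[float] = None  # capture radius (model maps only)
    resolution: int = 10_000  # bp per bin
    mask: Optional[np.ndarray] = None  # bins excluded (e.g. zero coverage)

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("contact map must be square")
        if not np.allclose(P, P.T, atol=1e-8, equal_nan=True):
            raise ValueError("contact map must be symmetric")
        self.P = P

    @property
    def N(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class ScalingFit:
    """OLS slope of log P_c vs log s over [s_min, s_max]."""

    exponent: float
    stderr: float
    s_min: int
    s_max: int
    n_points: int


@dataclass(frozen=True)
class GyrationReport:
    """Radius of gyration of the whole chain and of annotated subsets (l units)."""

    whole: float
    per_domain: tuple = ()  # ((start, stop, state, R_g), ...)
    per_state: dict = None  # state -> R_g over all beads of that state

    def __post_init__(self) -> None:
        if self.per_state is None:
            object.__setattr__(self, "per_state", {})


def contact_probability(D: np.ndarray, r_c: float = DEFAULT_CAPTURE_RADIUS) -> ContactMap:
    """Contact map P(|r_ij| <= r_c) of the Gaussian state with variances D."""
    if r_c <= 0:
        raise ValueError("capture radius must be positive")
    D = np.asarray(D, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r_c / np.sqrt(2.0 * D)
        P = special.erf(u) - (2.0 / np.sqrt(np.pi)) * u * np.exp(-(u**2))
    P[~np.isfinite(u)] = 1.0  # D -> 0 limit
    np.fill_diagonal(P, 1.0)
    return ContactMap(P=P, r_c=r_c)


def mean_contact_curve(cmap: ContactMap | np.ndarray) -> np.ndarray:
    """Sequence-averaged P_c(s), returned as an array of (s, P_c) rows.

    P_c(s) averages P_ij over all pairs with |i - j| = s, for
    s = 1 ... N-1.  Masked bins (experimental maps) are excluded.
    """
    P = cmap.P if isinstance(cmap, ContactMap) else np.asarray(cmap, dtype=float)
    mask = getattr(cmap, "mask", None)
    N = P.shape[0]
    if N < 3:
        raise ValueError("need N >= 3 for a contact curve")
    W = np.ones_like(P)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        W = np.outer(keep, keep).astype(float)
    idx = np.abs(np.subtract.outer(np.arange(N), np.arange(N))).ravel()
    num = np.bincount(idx, weights=(P * W).ravel(), minlength=N)
    den = np.bincount(idx, weights=W.ravel(), minlength=N)
    s = np.arange(1, N)
    with np.errstate(invalid="ignore"):
        pc = num[1:] / den[1:]
    return np.column_stack([s, pc])


def fit_scaling_exponent(
    curve: np.ndarray | Sequence, s_min: int, s_max: int
) -> ScalingFit:
    """Least-squares slope of log P_c(s) vs log s over s_min <= s <= s_max."""
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("curve must be (s, P_c) rows")
    if s_min >= s_max:
        raise ValueError("require s_min < s_max")
    s, pc = arr[:, 0], arr[:, 1]
    sel = (s >= s_min) & (s <= s_max) & np.isfinite(pc)
    if np.count_nonzero(sel) < 5:
        raise ValueError("need at least 5 points inside the fit window")
    if np.any(pc[sel] <= 0):
        raise ValueError("P_c must be positive over the fit window")
    res = stats.linregress(np.log(s[sel]), np.log(pc[sel]))
    return ScalingFit(
        exponent=float(res.slope),
        stderr=float(res.stderr),
        s_min=int(s_min),
        s_max=int(s_max),
        n_points=int(np.count_nonzero(sel)),
    )


def radius_of_gyration(D: np.ndarray, subset: Optional[np.ndarray] = None) -> float:
    """R_g = sqrt( (1 / (2 n^2)) sum_{ij in subset} D_ij )."""
    D = np.asarray(D, dtype=float)
    if subset is not None:
        sub = np.asarray(subset)
        if sub.dtype == bool:
            sub = np.flatnonzero(sub)
        if sub.size < 2:
            raise ValueError("gyration subset must contain at least 2 beads")
        D = D[np.ix_(sub, sub)]
    n = D.shape[0]
    return float(np.sqrt(np.sum(D) / (2.0 * n * n)))


def gyration(
    D: np.ndarray, annotation: Optional[ChromatinAnnotation] = None
) -> GyrationReport:
    """Whole-chain, per-block and per-state radii of gyration.

    Subset values apply the same D-sum formula restricted to the relevant
    beads, with the subset size as the normalisation.
    """
    whole = radius_of_gyration(D)
    if annotation is None:
        return GyrationReport(whole=whole)
    if len(annotation) != D.shape[0]:
        raise ValueError("annotation length must match D")
    per_domain = []
    for start, stop, state in annotation.blocks():
        if stop - start >= 2:
            rg = radius_of_gyration(D, np.arange(start, stop))
            per_domain.append((start, stop, state, rg))
    per_state = {}
    for state in annotation.alphabet:
        m = annotation.mask(state)
        if m.sum() >= 2:
            per_state[state] = radius_of_gyration(D, m)
    return GyrationReport(whole=whole, per_domain=tuple(per_domain), per_state=per_state)
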