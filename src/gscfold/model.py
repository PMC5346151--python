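"""Chain definition: a bead-spring chromatin polymer with Gaussian pair interactions.

The chain is a sequence of ``N`` beads, each representing a fixed genomic
span (10 kbp by default).  Its energy is a sum of

* harmonic bond springs between consecutive beads (``k/2 * r_{i,i+1}^2``),
* a soft Gaussian excluded-volume repulsion ``U_ev * exp(-r^2 / (2 r_e^2))``
  acting between every pair,
* optional Gaussian terms of range ``r_o``: a non-specific amplitude
  ``U_ns``, a genomic-distance-dependent "crumpling" amplitude
  ``U_crumpling(|i-j|)``, and a chromatin-state-specific amplitude
  ``U_s(e_i, e_j)``.

Energies are expressed in units of ``k_B T`` and lengths in units of the
bead diameter ``l`` (both set to 1 internally).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "PolymerParams",
    "ChromatinAnnotation",
    "SpecificInteraction",
    "CrumplingTable",
    "ChainModel",
    "pair_potentials",
    "build_from_segmentation",
]


@dataclass(frozen=True)
class PolymerParams:
    """Constants of the bead-spring chain.

    Parameters
    ----------
    N : int
        Number of beads (monomers).
    l : float
        Bead diameter; the internal length unit.
    bp_per_monomer : int
        Genomic span of one bead, in base pairs.
    k : float
        Bond spring constant, in k_BT / l**2.
    U_ev : float
        Excluded-volume amplitude, in k_BT (repulsive, >= 0).
    r_e : float
        Excluded-volume Gaussian range, in l.
    U_ns : float or None
        Non-specific interaction amplitude at range ``r_o`` (k_BT); sign
        free (attraction < 0).  ``None`` disables the term.
    r_o : float
        Range of the non-specific / specific / crumpling terms, in l.
    """

    N: int
    l: float = 1.0
    bp_per_monomer: int = 10_000
    k: float = 3.0
    U_ev: float = 10.0
    r_e: float = 0.3
    U_ns: Optional[float] = None
    r_o: float = 0.5

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.l <= 0 or self.r_e <= 0 or self.r_o <= 0:
            raise ValueError("l, r_e and r_o must be positive")
        if self.U_ev < 0:
            raise ValueError("U_ev must be non-negative (repulsive)")


@dataclass(frozen=True)
class ChromatinAnnotation:
    """One chromatin-state label per bead."""

    states: tuple

    def __init__(self, states: Sequence) -> None:
        object.__setattr__(self, "states", tuple(states))
        if len(self.states) == 0:
            raise ValueError("annotation must be non-empty")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def alphabet(self) -> tuple:
        seen: dict = {}
        for s in self.states:
            seen.setdefault(s, None)
        return tuple(seen)

    def blocks(self) -> list[tuple[int, int, object]]:
        """Maximal runs of an identical state as (start, stop, state), stop exclusive."""
        out = []
        start = 0
        for i in range(1, len(self.states) + 1):
            if i == len(self.states) or self.states[i] != self.states[start]:
                out.append((start, i, self.states[start]))
                start = i
        return out

    def mask(self, state) -> np.ndarray:
        return np.array([s == state for s in self.states], dtype=bool)


class SpecificInteraction:
    """Symmetric state-pair interaction table ``(a, b) -> U_s`` in k_BT.

    The default construction (:meth:`diagonal`) makes only same-state pairs
    interact, all with the same strength.
    """

    def __init__(self, table: Mapping[tuple, float]) -> None:
        tab: dict = {}
        for (a, b), u in table.items():
            key = (a, b)
            rkey = (b, a)
            if rkey in tab and tab[rkey] != u:
                raise ValueError(f"asymmetric table: {key} vs {rkey}")
            tab[key] = float(u)
            tab[rkey] = float(u)
        self.table = tab

    @classmethod
    def diagonal(cls, alphabet: Sequence, u: float) -> "SpecificInteraction":
        return cls({(a, a): float(u) for a in alphabet})

    def amplitude(self, a, b) -> float:
        return self.table.get((a, b), 0.0)

    def matrix(self, annotation: ChromatinAnnotation) -> np.ndarray:
        states = annotation.states
        alphabet = annotation.alphabet
        idx = {s: i for i, s in enumerate(alphabet)}
        code = np.array([idx[s] for s in states])
        small = np.zeros((len(alphabet), len(alphabet)))
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                small[i, j] = self.amplitude(a, b)
        return small[np.ix_(code, code)]


@dataclass(frozen=True)
class CrumplingTable:
    """Amplitude ``U_crumpling(s)`` (k_BT) for each genomic separation ``s``.

    ``values[s]`` holds the amplitude at separation ``s``; ``values[0]`` is
    unused and kept at 0.  The term acts between every pair (i, j) with
    ``s = |j - i|`` at range ``r_o``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("values must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("crumpling amplitudes must be finite")
        object.__setattr__(self, "values", v)

    def __call__(self, s) -> np.ndarray:
        return self.values[np.asarray(s)]

    def matrix(self, N: int) -> np.ndarray:
        if self.values.size < N:
            raise ValueError(f"crumpling table covers s < {self.values.size}, need N = {N}")
        col = self.values[:N].copy()
        col[0] = 0.0
        return toeplitz(col)


@dataclass(frozen=True)
class ChainModel:
    """Full interaction specification of one chain.

    ``annotation``/``specific``/``crumpling`` are optional; a model with
    none of them is a homopolymer.  ``extra`` is a free per-pair amplitude
    matrix (k_BT) acting at range ``r_o`` — used by the coupled
    epigenome-folding model, where the amplitude depends on the current
    epigenomic field rather than on a fixed state table.
    """

    params: PolymerParams
    annotation: Optional[ChromatinAnnotation] = None
    specific: Optional[SpecificInteraction] = None
    crumpling: Optional[CrumplingTable] = None
    extra: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        N = self.params.N
        if self.annotation is not None and len(self.annotation) != N:
            raise ValueError(
                f"annotation length {len(self.annotation)} != N = {N}"
            )
        if self.specific is not None and self.annotation is None:
            raise ValueError("specific interactions require an annotation")
        if self.extra is not None:
            e = np.asarray(self.extra, dtype=float)
            if e.shape != (N, N):
                raise ValueError(f"extra amplitude matrix must be {N}x{N}")
            if not np.allclose(e, e.T):
                raise ValueError("extra amplitude matrix must be symmetric")
            object.__setattr__(self, "extra", e)

    # -- assembled per-pair Gaussian amplitudes ------------------------------

    def gaussian_terms(self) -> list[tuple[np.ndarray | float, float]]:
        """Every Gaussian pair term as (amplitude, range).

        Amplitudes are scalars (uniform over pairs) or N x N matrices;
        ranges are in l.  Bond springs are not included (they are harmonic,
        not Gaussian; see :attr:`PolymerParams.k`).
        """
        p = self.params
        terms: list[tuple[np.ndarray | float, float]] = [(p.U_ev, p.r_e)]
        if p.U_ns is not None:
            terms.append((float(p.U_ns), p.r_o))
        if self.crumpling is not None:
            terms.append((self.crumpling.matrix(p.N), p.r_o))
        if self.specific is not None:
            terms.append((self.specific.matrix(self.annotation), p.r_o))
        if self.extra is not None:
            terms.append((self.extra, p.r_o))
        return terms

    def amplitude_matrix(self) -> dict[float, np.ndarray]:
        """Total Gaussian amplitude per pair, grouped by range sigma."""
        N = self.params.N
        grouped: dict[float, np.ndarray] = {}
        for U, sigma in self.gaussian_terms():
            A = grouped.setdefault(sigma, np.zeros((N, N)))
            A += U if np.ndim(U) else np.full((N, N), U)
        for A in grouped.values():
            np.fill_diagonal(A, 0.0)
        return grouped

    def total_energy(self, coords: np.ndarray) -> float:
        """Energy (k_BT) of one explicit configuration, shape (N, 3).

        Reference evaluation used by tests; O(N^2), not meant for large N.
        """
        x = np.asarray(coords, dtype=float)
        N = self.params.N
        if x.shape != (N, 3):
            raise ValueError(f"coords must be ({N}, 3)")
        d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
        e = 0.5 * self.params.k * np.sum(np.diag(d2, 1))
        iu = np.triu_indices(N, 1)
        for sigma, A in self.amplitude_matrix().items():
            e += np.sum(A[iu] * np.exp(-d2[iu] / (2.0 * sigma**2)))
        return float(e)


def pair_potentials(model: ChainModel, i: int, j: int) -> list[tuple[float, float]]:
    """All Gaussian terms (amplitude U in k_BT, range sigma in l) acting on (i, j).

    The harmonic bond spring between adjacent beads is reported separately
    via ``model.params.k`` and is not part of the returned list.
    """
    N = model.params.N
    if not (0 <= i < N and 0 <= j < N):
        raise IndexError(f"indices ({i}, {j}) out of range for N = {N}")
    if i == j:
        raise ValueError("pair potentials are defined for distinct beads")
    p = model.params
    out = [(p.U_ev, p.r_e)]
    if p.U_ns is not None:
        out.append((float(p.U_ns), p.r_o))
    if model.crumpling is not None:
        out.append((float(model.crumpling(abs(j - i))), p.r_o))
    if model.specific is not None:
        ei = model.annotation.states[i]
        ej = model.annotation.states[j]
        out.append((model.specific.amplitude(ei, ej), p.r_o))
    if model.extra is not None:
        out.append((float(model.extra[i, j]), p.r_o))
    return out


def build_from_segmentation(
    records: Sequence[tuple[int, int, object]],
    params: PolymerParams,
    state_map: Optional[Mapping] = None,
) -> ChainModel:
    """Build an annotated chain from BED-like (start, end, label) records.

    Records must tile a contiguous region (sorted, no gaps or overlaps,
    coordinates in bp, half-open).  Each bead spans ``bp_per_monomer``;
    its state is the label covering the majority of the bin, ties broken
    toward the earlier-starting record.  ``N`` is inferred from the region
    length (partial trailing bins are dropped).
    """
    if not records:
        raise ValueError("empty segmentation")
    recs = sorted(records, key=lambda r: (r[0], r[1]))
    for (s0, e0, _), (s1, e1, _) in zip(recs, recs[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping records at {s1} < {e0}")
        if s1 > e0:
            raise ValueError(f"gap in segmentation between {e0} and {s1}")
    for s, e, _ in recs:
        if e <= s:
            raise ValueError(f"empty or inverted record ({s}, {e})")
    start = recs[0][0]
    end = recs[-1][1]
    bp = params.bp_per_monomer
    N = (end - start) // bp
    if N < 2:
        raise ValueError(f"region of {end - start} bp yields N = {N} < 2 beads")
    states = []
    for b in range(N):
        lo, hi = start + b * bp, start + (b + 1) * bp
        best_label, best_cov = None, -1
        for s, e, label in recs:  # records sorted: first max wins ties
            cov = min(e, hi) - max(s, lo)
            if cov > best_cov:
                best_cov, best_label = cov, label
        if state_map is not None:
            if best_label not in state_map:
                raise KeyError(f"label {best_label!r} missing from state_map")
            best_label = state_map[best_label]
        states.append(best_label)
    return ChainModel(params=replace(params, N=N), annotation=ChromatinAnnotation(states))
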