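"""The "living chromatin" model: coupled epigenome spreading and folding.

Monomer states e_i in {-1, +1} (repressive/active) evolve under an
Ising-like Hamiltonian H_epi = -(J_e/N) sum_{contacts} e_i e_j whose
couplings live on the 3D contact graph of the chain, while the chain
itself feels a same-state attraction
H_inter = - sum J_i (e_i e_j + 1)/2 exp(-r_ij^2/(2 r_o^2)).  Spreading
strengthens compaction, compaction concentrates contacts and strengthens
spreading: the reader-writer positive feedback.

Two treatments are provided:

* a continuous mean-field mode (:func:`coupled_solve`), where the
  magnetisations m_i = <e_i> satisfy m_i = tanh((J_e/N) sum_j c_ij m_j)
  with c_ij the Gaussian contact probability of the current stationary
  fold, alternated with GSC solves of the polymer under amplitudes
  -J_i (m_i m_j + 1)/2;
* a stochastic mode (:func:`magnetization_histogram`), Glauber
  single-spin-flip Monte Carlo on discrete spins with the structure
  refreshed periodically, for the distribution of the global state
  M = (sum e_i)/N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .model import ChainModel, CrumplingTable, PolymerParams
from .observables import contact_probability
from .solver import SolverSettings, solve_stationary

__all__ = [
    "LCParams",
    "EpiField",
    "CoupledState",
    "coupled_solve",
    "phase_boundary",
    "magnetization_histogram",
]


@dataclass(frozen=True)
class LCParams:
    """Region size and couplings of the living chromatin model.

    ``J_e`` (k_BT) scales the contact-weighted spreading; ``J_i`` (k_BT)
    the same-state attraction fed back into the fold.
    """

    N: int = 100
    J_e: float = 0.0
    J_i: float = 0.0
    r_c: float = 1.0
    crumpling: Optional[CrumplingTable] = None
    polymer: PolymerParams = None  # chain constants; N is taken from here if set

    def __post_init__(self) -> None:
        if self.J_e < 0 or self.J_i < 0:
            raise ValueError("J_e and J_i must be non-negative")
        if self.polymer is None:
            object.__setattr__(self, "polymer", PolymerParams(N=self.N))
        elif self.polymer.N != self.N:
            raise ValueError("polymer.N must equal N")


@dataclass
class EpiField:
    """Epigenomic field: mean-field magnetisations in [-1, 1] or spins."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.ndim != 1:
            raise ValueError("m must be a vector")
        if np.any(np.abs(m) > 1 + 1e-9):
            raise ValueError("magnetisations must lie in [-1, 1]")
        self.m = np.clip(m, -1.0, 1.0)

    @property
    def M(self) -> float:
        """Global epigenomic state, mean of m."""
        return float(self.m.mean())


@dataclass
class CoupledState:
    D: np.ndarray
    field: EpiField
    converged: bool
    iterations: int
    residual_m: float
    residual_D: float


def _pair_amplitudes(J_i: float, m: np.ndarray) -> np.ndarray:
    """State-coupling amplitudes U_ij = -J_i (m_i m_j + 1)/2 (k_BT)."""
    U = -J_i * (np.outer(m, m) + 1.0) / 2.0
    np.fill_diagonal(U, 0.0)
    return 0.5 * (U + U.T)


def _chain(params: LCParams, m: np.ndarray) -> ChainModel:
    return ChainModel(
        params=params.polymer,
        crumpling=params.crumpling,
        extra=_pair_amplitudes(params.J_i, m),
    )


def contact_weights(D: np.ndarray, r_c: float) -> np.ndarray:
    """Annealed contact indicator: Gaussian contact probability, zero diagonal.

    The binary contact delta of the spreading Hamiltonian is replaced by
    its average over the Gaussian fold; self-coupling is excluded.
    """
    c = contact_probability(D, r_c).P.copy()
    np.fill_diagonal(c, 0.0)
    return c


def coupled_solve(
    params: LCParams,
    init_m: EpiField | np.ndarray | float = 0.1,
    settings: Optional[SolverSettings] = None,
    m_damping: float = 0.5,
    m_tol: float = 1e-6,
    max_outer: int = 400,
) -> CoupledState:
    """Alternating self-consistency of fold and mean-field epigenome.

    Repeats: (1) contact weights from the current D; (2) damped mean-field
    update m_i <- tanh((J_e/N) sum_j c_ij m_j); (3) stationary GSC solve
    under the amplitudes implied by m.  Converged when both the
    magnetisation update and the polymer residual are below tolerance.
    Deterministic given the initial field.
    """
    if settings is None:
        settings = SolverSettings()
    N = params.N
    if isinstance(init_m, EpiField):
        m = init_m.m.copy()
    elif np.ndim(init_m) == 0:
        m = np.full(N, float(init_m))
    else:
        m = np.asarray(init_m, dtype=float).copy()
    if m.shape != (N,):
        raise ValueError(f"init_m must have length {N}")

    res = solve_stationary(_chain(params, m), settings)
    D = res.D
    dm = np.inf
    it = 0
    osc = 0
    damping = m_damping
    prev_dm = np.inf
    for it in range(1, max_outer + 1):
        c = contact_weights(D, params.r_c)
        target = np.tanh((params.J_e / N) * (c @ m))
        m_new = (1.0 - damping) * m + damping * target
        dm = float(np.max(np.abs(m_new - m)))
        if dm > prev_dm * 1.000001:
            osc += 1
            if osc >= 3:  # oscillation: damp harder
                damping = max(damping * 0.5, 0.05)
                osc = 0
        prev_dm = dm
        m = m_new
        res = solve_stationary(_chain(params, m), replace(settings, init=D))
        D = res.D
        if dm <= m_tol and res.converged:
            return CoupledState(D, EpiField(m), True, it, dm, res.residual_max)
    return CoupledState(D, EpiField(m), False, it, dm, res.residual_max)


def phase_boundary(
    J_e_grid: Sequence[float],
    J_i: float,
    base: Optional[LCParams] = None,
    init_m: float = 0.1,
    coherence: float = 0.5,
    **solve_kwargs,
) -> tuple[float, np.ndarray]:
    """Critical spreading strength J_e^c at fixed J_i.

    Scans the J_e grid upward from a weakly polarised initial field and
    returns the smallest grid value whose converged |M| exceeds the
    coherence threshold, together with the (J_e, |M|) scan.  Raises if the
    bifurcation is not bracketed.
    """
    if base is None:
        base = LCParams()
    grid = np.sort(np.asarray(J_e_grid, dtype=float))
    Ms = np.empty_like(grid)
    for i, je in enumerate(grid):
        p = replace(base, J_e=float(je), J_i=float(J_i))
        state = coupled_solve(p, init_m=init_m, **solve_kwargs)
        Ms[i] = abs(state.field.M)
    above = Ms > coherence
    if not above.any() or above.all():
        raise ValueError(
            f"bifurcation not bracketed by the J_e grid (|M| in "
            f"{Ms.min():.3f}..{Ms.max():.3f})"
        )
    jc = float(grid[np.argmax(above)])
    return jc, np.column_stack([grid, Ms])


def ising_critical_spreading(D: np.ndarray, r_c: float, N: int) -> float:
    """Independent linear-stability estimate of J_e^c on a fixed fold.

    The paramagnetic fixed point m = 0 of the mean-field update loses
    stability when (J_e/N) lambda_max(c) = 1, so
    J_e^c = N / lambda_max(c).
    """
    c = contact_weights(D, r_c)
    lam = float(np.linalg.eigvalsh(c).max())
    return N / lam


def magnetization_histogram(
    params: LCParams,
    n_sweeps: int = 2000,
    structure_update_period: int = 50,
    seed: int = 0,
    burn_in: int = 200,
    settings: Optional[SolverSettings] = None,
    bins: int = 21,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Glauber Monte Carlo sampling of the global state M = (sum e_i)/N.

    Single-spin-flip dynamics on e in {-1, +1}^N with couplings
    (J_e/N) c_ij; the contact weights c are refreshed every
    ``structure_update_period`` sweeps by a warm-started stationary solve
    under the mean pair amplitudes of the current spins.  Returns
    (M per recorded sweep, histogram densities, bin edges); fully seeded.
    """
    if settings is None:
        settings = SolverSettings()
    rng = np.random.default_rng(seed)
    N = params.N
    e = rng.choice([-1.0, 1.0], size=N)
    res = solve_stationary(_chain(params, e), settings)
    D = res.D
    c = contact_weights(D, params.r_c)
    beta_c = (params.J_e / N) * c
    Ms = np.empty(n_sweeps)
    for sweep in range(n_sweeps):
        if sweep > 0 and structure_update_period > 0 and sweep % structure_update_period == 0:
            res = solve_stationary(_chain(params, e), replace(settings, init=D))
            D = res.D
            c = contact_weights(D, params.r_c)
            beta_c = (params.J_e / N) * c
        order = rng.integers(0, N, size=N)
        us = rng.random(N)
        for i, u in zip(order, us):
            h = beta_c[i] @ e  # local field (diagonal of c is zero)
            p_up = 1.0 / (1.0 + np.exp(-2.0 * h))
            e[i] = 1.0 if u < p_up else -1.0
        Ms[sweep] = e.mean()
    kept = Ms[burn_in:]
    hist, edges = np.histogram(kept, bins=bins, range=(-1.0, 1.0), density=True)
    return kept, hist, edges
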