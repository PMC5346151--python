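"""Gaussian self-consistent (GSC) stationary states.

The variational scheme approximates the chain's configurational
distribution by a zero-mean multivariate Gaussian, fully characterised by
the per-coordinate mean squared distance matrix

    D_ij = (1/3) <(X_i - X_j)^2>  (units l^2).

Under this ansatz every Gaussian pair term averages in closed form,

    <U exp(-r_ij^2 / (2 sigma^2))> = U (1 + D_ij / sigma^2)^(-3/2),

and the chain behaves as an effective harmonic network whose spring
constants J_ij = (2/3) d<H_pair(i,j)>/dD_ij depend on D itself:

    J_ij = k [|i-j| = 1]  -  sum over terms (U, sigma) of
           (U / sigma^2) (1 + D_ij / sigma^2)^(-5/2),

with the Laplacian diagonal convention J_ii = -sum_{k != i} J_ik.  The
stationary state satisfies, for every pair i != j,

    0 = 4 k_BT - sum_k (J_ik - J_jk)(D_ik - D_jk).

At fixed couplings this is solved exactly by the equilibrium of the
harmonic network, D = dist(k_BT L^+) with L = -J, which yields the damped
fixed-point iteration used by :func:`solve_stationary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .model import ChainModel

__all__ = [
    "SolverSettings",
    "GSCResult",
    "ideal_chain_distances",
    "effective_couplings",
    "residual",
    "solve_stationary",
    "sample_configurations",
]

D_FLOOR = 1e-6  # positivity floor on off-diagonal D, l^2


@dataclass
class SolverSettings:
    """Iteration controls for the stationary solve.

    ``tol`` is on the maximum absolute stationarity residual (k_BT);
    ``damping`` is the largest mixing fraction of the fixed-point map (the
    solver adapts the actual fraction downward when the residual grows).
    ``init`` may be a previously converged D for warm starts.
    """

    tol: float = 1e-4
    max_iter: int = 5000
    damping: float = 0.5
    init: Optional[np.ndarray] = None
    seed: Optional[int] = None
    perturb: float = 0.0  # amplitude of optional random init perturbation

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")


@dataclass
class GSCResult:
    """Stationary squared-distance matrix plus solver diagnostics."""

    D: np.ndarray
    converged: bool
    iterations: int
    residual_max: float
    clipped_mass: float = 0.0  # negative-eigenvalue mass clipped in the network solve

    def __post_init__(self) -> None:
        if not self.converged and self.residual_max > 1.0:
            # flagrant non-convergence is worth surfacing early
            import warnings

            warnings.warn(
                f"GSC solve not converged: max residual {self.residual_max:.3g} k_BT",
                stacklevel=2,
            )


def _check_D(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    off = D[~np.eye(D.shape[0], dtype=bool)]
    if np.any(off < 0):
        raise ValueError("off-diagonal D entries must be non-negative")
    return D


def ideal_chain_distances(N: int, k: float = 3.0) -> np.ndarray:
    """Exact free-ends harmonic-chain D: D_ij = |i - j| k_BT / k."""
    s = np.abs(np.subtract.outer(np.arange(N), np.arange(N)))
    return s / k


def effective_couplings(
    D: np.ndarray,
    model: ChainModel,
    *,
    check: bool = True,
    amplitudes: Optional[dict] = None,
) -> np.ndarray:
    """Effective harmonic-network couplings J(D) (k_BT / l^2).

    Off-diagonal entries follow the closed form in the module docstring;
    the diagonal carries the Laplacian convention J_ii = -sum_{k!=i} J_ik.
    Attractive terms (U < 0) contribute positive effective springs,
    repulsive terms negative ones.  ``amplitudes`` may carry a
    precomputed ``model.amplitude_matrix()`` (the matrices are constant
    across a solve; hoisting them out of the iteration saves rebuilding).
    """
    if check:
        D = _check_D(D)
    N = model.params.N
    if D.shape != (N, N):
        raise ValueError(f"D must be {N}x{N}")
    if amplitudes is None:
        amplitudes = model.amplitude_matrix()
    J = np.zeros((N, N))
    idx = np.arange(N - 1)
    J[idx, idx + 1] = model.params.k
    J[idx + 1, idx] = model.params.k
    for sigma, A in amplitudes.items():
        J -= (A / sigma**2) * (1.0 + D / sigma**2) ** (-2.5)
    np.fill_diagonal(J, 0.0)
    np.fill_diagonal(J, -J.sum(axis=1))
    return J


def residual(
    D: np.ndarray, model: ChainModel, J: Optional[np.ndarray] = None
) -> np.ndarray:
    """Stationarity residual R_ij = 4 k_BT - sum_k (J_ik - J_jk)(D_ik - D_jk).

    Zero on the diagonal by convention (the stationary condition applies to
    distinct pairs only).  The sum over k runs over all beads, with the
    Laplacian diagonal of J included.
    """
    D = _check_D(D)
    if J is None:
        J = effective_couplings(D, model, check=False)
    # sum_k (J_ik - J_jk)(D_ik - D_jk) = u_i + u_j - (JD)_ij - (JD)_ji
    # with u = diag(J D); row sums of J vanish so the (C_ii - C_jj) part drops.
    JD = J @ D
    u = np.diag(JD)
    R = 4.0 - (u[:, None] + u[None, :] - JD - JD.T)
    np.fill_diagonal(R, 0.0)
    return R


def _network_distances(J: np.ndarray, eig_floor: float = 0.0) -> tuple[np.ndarray, float]:
    """Equilibrium D of the harmonic network with couplings J.

    Solves C = k_BT (L + 11^T/N)^{-1} with L = -J (the 11^T shift fills the
    centre-of-mass null space and leaves D unchanged), then
    D_ij = C_ii + C_jj - 2 C_ij.  When the shifted Laplacian is not
    positive definite (transiently possible while strong repulsion
    dominates the effective couplings) the eigenvalue solve clips modes
    below ``eig_floor`` — a fraction of the slowest bond-chain Rouse mode,
    so no mode is softer than the connectivity allows — and reports the
    clipped relative eigenvalue mass.
    """
    N = J.shape[0]
    M = -J + 1.0 / N
    clipped = 0.0
    try:
        cf = linalg.cho_factor(M, check_finite=False)
        C = linalg.cho_solve(cf, np.eye(N), check_finite=False)
    except linalg.LinAlgError:
        w, V = linalg.eigh(M, check_finite=False)
        floor = max(eig_floor, 1e-12)
        bad = w < floor
        clipped = float(np.sum(np.abs(w[bad])) / max(np.sum(np.abs(w)), 1e-300))
        w = np.where(bad, floor, w)
        C = (V / w) @ V.T
    c = np.diag(C)
    D = c[:, None] + c[None, :] - 2.0 * C
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0), clipped


def solve_stationary(model: ChainModel, settings: Optional[SolverSettings] = None) -> GSCResult:
    """Iterate the damped GSC fixed-point map to the stationary D.

    Starting from the ideal-chain D (or ``settings.init`` for warm starts),
    alternate computing the couplings J(D) and the equilibrium distances of
    the resulting harmonic network, mixing old and new D with an adaptive
    damping fraction.  Convergence is certified on the stationarity
    residual, max |R_ij| <= tol.  Deterministic unless ``perturb`` > 0.
    """
    if settings is None:
        settings = SolverSettings()
    N = model.params.N
    if settings.init is not None:
        D = _check_D(settings.init).copy()
        if D.shape != (N, N):
            raise ValueError("init D has wrong shape")
    else:
        D = ideal_chain_distances(N, model.params.k)
    if settings.perturb > 0:
        rng = np.random.default_rng(settings.seed)
        noise = rng.normal(0.0, settings.perturb, size=(N, N))
        noise = 0.5 * (noise + noise.T)
        np.fill_diagonal(noise, 0.0)
        D = np.maximum(D * (1.0 + noise), D_FLOOR)
        np.fill_diagonal(D, 0.0)

    # The fixed-point map is iterated in log space: D spans orders of
    # magnitude between the bond and coil scales and collapse is a
    # multiplicative contraction, so geometric mixing contracts far faster
    # (and far more stably) than linear mixing.  The mixing fraction alpha
    # adapts under a ratcheting trust cap: every residual increase halves
    # the step and shrinks the cap, so the iteration settles at the
    # largest stably contractive fraction.  Fully deterministic.
    off = ~np.eye(N, dtype=bool)
    eig_floor = 0.01 * model.params.k * (np.pi / N) ** 2
    amps = model.amplitude_matrix()
    alpha = settings.damping
    alpha_max = settings.damping
    calm = 0
    prev_r = np.inf
    clipped = 0.0
    best = (np.inf, D.copy(), 0.0)
    it = 0
    for it in range(1, settings.max_iter + 1):
        J = effective_couplings(D, model, check=False, amplitudes=amps)
        R = residual(D, model, J)
        r = float(np.max(np.abs(R)))
        if r < best[0]:
            best = (r, D.copy(), clipped)
        if r <= settings.tol:
            return GSCResult(D, True, it, r, clipped)
        if r > prev_r * 1.000001:
            alpha = max(alpha * 0.5, 0.01)
            alpha_max = max(alpha_max * 0.7, 0.01)
            calm = 0
        else:
            alpha = min(alpha * 1.05, alpha_max)
            calm += 1
            if calm >= 30:  # sustained monotone progress: relax the cap
                alpha_max = min(alpha_max * 1.3, settings.damping)
                calm = 0
        prev_r = r
        D_map, clipped = _network_distances(J, eig_floor)
        D_map = np.maximum(D_map, D_FLOOR)  # diagonal re-zeroed after mixing
        D_new = np.exp(
            (1.0 - alpha) * np.log(np.maximum(D, D_FLOOR)) + alpha * np.log(D_map)
        )
        D_new[~off] = 0.0
        D = D_new
    # Polish fallback: the inverse map cannot represent marginally soft
    # global modes (its surrogate network would need a near-zero or
    # negative eigenvalue), which can stall the residual in strongly
    # swollen states.  A slow additive relaxation of D along the residual
    # has no such restriction and mops up what remains.
    r, D, clipped = best
    eps = 2e-3
    prev_r = r
    off = ~np.eye(N, dtype=bool)
    for it2 in range(1, settings.max_iter + 1):
        R = residual(D, model)
        r = float(np.max(np.abs(R)))
        if r < best[0]:
            best = (r, D.copy(), clipped)
        if r <= settings.tol:
            return GSCResult(D, True, it + it2, r, clipped)
        if r > prev_r:
            eps = max(eps * 0.7, 1e-4)
        else:
            eps = min(eps * 1.002, 5e-3)
        prev_r = r
        D = D + eps * R
        D = 0.5 * (D + D.T)
        D[off] = np.maximum(D[off], D_FLOOR)
        np.fill_diagonal(D, 0.0)
    r, D, clipped = best
    return GSCResult(D, False, it + it2, r, clipped)


def sample_configurations(
    D: np.ndarray, n: int, seed: int, *, clip_warn: float = 0.05
) -> np.ndarray:
    """Draw ``n`` centred 3D configurations consistent with D, shape (n, N, 3).

    The centred per-coordinate covariance C = -1/2 H D H (H the centering
    projector) is eigen-decomposed; negative eigenvalues are clipped at 0
    (their relative mass beyond ``clip_warn`` signals an inconsistent D)
    and x, y, z are drawn independently as zero-mean Gaussians with
    covariance C.
    """
    D = _check_D(D)
    N = D.shape[0]
    H = np.eye(N) - 1.0 / N
    C = -0.5 * H @ D @ H
    w, V = linalg.eigh(C)
    neg = float(np.sum(np.abs(w[w < 0])) / max(np.sum(np.abs(w)), 1e-300))
    if neg > clip_warn:
        import warnings

        warnings.warn(
            f"clipped {neg:.1%} negative-eigenvalue mass reconstructing C from D",
            stacklevel=2,
        )
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)  # C = A A^T
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n, 3, N))
    coords = np.einsum("ij,nkj->nik", A, z)  # (n, N, 3)
    return coords - coords.mean(axis=1, keepdims=True)
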