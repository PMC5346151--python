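"""Phase behaviour of the block copolymer over (U_ns, U_s).

Each grid point is a stationary GSC solve; the point is classified from
three families of radii of gyration (whole chain, per contiguous block,
per chromatin state) relative to their values at the zero-interaction
reference (U_ns = 0, U_s = 0, other terms of the template unchanged),
plus the checkerboard contrast of its contact map:

* coil          — no unit collapsed;
* globule       — whole chain collapsed without state segregation;
* intermediate  — individual blocks collapsed but same-state aggregates
                  not collapsed / contrast moderate;
* microphase    — same-state radii collapsed and contrast high.

"Collapsed" means R_g^2 below a fraction ``theta`` (default 0.5) of the
same unit's reference value.  The contrast threshold separating
microphase from intermediate is anchored at run time to the two exemplar
regimes rather than to an arbitrary constant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .model import ChainModel, PolymerParams, SpecificInteraction
from .observables import contact_probability, radius_of_gyration
from .solver import SolverSettings, solve_stationary

__all__ = [
    "PhasePoint",
    "PhaseDiagram",
    "checkerboard_contrast",
    "point_metrics",
    "point_metrics_path",
    "exemplar_thresholds",
    "classify",
    "sweep",
    "find_collapse_point",
]

COLLAPSE_THETA = 0.5


@dataclass(frozen=True)
class PhasePoint:
    U_ns: float
    U_s: float
    label: str
    rg2_whole: float
    rg2_blocks: tuple  # per contiguous block, chain order
    rg2_states: dict  # state -> R_g^2 over all beads of the state
    contrast: float
    converged: bool
    block_ratio: Optional[float] = None  # mean per-block R_g^2 relative to
    #   the same-U_ns, U_s = 0 background (isolates the specific-attraction
    #   compaction from the non-specific swelling/compaction)


@dataclass
class PhaseDiagram:
    points: list  # list[PhasePoint], row-major over (U_ns_grid, U_s_grid)
    U_ns_grid: np.ndarray
    U_s_grid: np.ndarray
    reference: PhasePoint
    theta: float
    contrast_threshold: float
    block_theta: Optional[float] = None


def checkerboard_contrast(P: np.ndarray, model: ChainModel) -> float:
    """Mean same-state inter-block contact probability minus mean cross-state.

    Pairs within the same contiguous block are excluded; the statistic
    isolates long-range compartmental mixing from intra-domain compaction.
    """
    ann = model.annotation
    if ann is None:
        raise ValueError("checkerboard contrast requires an annotated chain")
    N = model.params.N
    block_id = np.empty(N, dtype=int)
    for b, (start, stop, _) in enumerate(ann.blocks()):
        block_id[start:stop] = b
    states = np.asarray(ann.states, dtype=object)
    same_state = np.equal.outer(states, states)
    diff_block = np.not_equal.outer(block_id, block_id)
    iu = np.triu_indices(N, 1)
    same = same_state[iu] & diff_block[iu]
    cross = ~same_state[iu]
    if not same.any() or not cross.any():
        raise ValueError("need both same-state inter-block and cross-state pairs")
    return float(P[iu][same].mean() - P[iu][cross].mean())


def point_metrics(
    model: ChainModel,
    U_ns: float,
    U_s: float,
    settings: SolverSettings,
    r_c: float = 1.0,
    background: Optional[PhasePoint] = None,
) -> tuple[PhasePoint, np.ndarray]:
    """Solve one (U_ns, U_s) point of a two-state template and measure it.

    ``background`` may carry the metrics of the same template at the same
    U_ns but U_s = 0; the per-block compaction ratio relative to it is
    then recorded (the signature of TAD formation on any backbone).
    """
    ann = model.annotation
    params = replace(model.params, U_ns=float(U_ns))
    spec = SpecificInteraction.diagonal(ann.alphabet, float(U_s))
    m = ChainModel(
        params=params, annotation=ann, specific=spec, crumpling=model.crumpling
    )
    res = solve_stationary(m, settings)
    P = contact_probability(res.D, r_c).P
    rg2_blocks = tuple(
        radius_of_gyration(res.D, np.arange(start, stop)) ** 2
        for start, stop, _ in ann.blocks()
        if stop - start >= 2
    )
    rg2_states = {
        s: radius_of_gyration(res.D, ann.mask(s)) ** 2 for s in ann.alphabet
    }
    block_ratio = None
    if background is not None and background.rg2_blocks:
        block_ratio = float(
            np.mean(np.array(rg2_blocks) / np.array(background.rg2_blocks))
        )
    pt = PhasePoint(
        U_ns=float(U_ns),
        U_s=float(U_s),
        label="",
        rg2_whole=radius_of_gyration(res.D) ** 2,
        rg2_blocks=rg2_blocks,
        rg2_states=rg2_states,
        contrast=checkerboard_contrast(P, m),
        converged=res.converged,
        block_ratio=block_ratio,
    )
    return pt, res.D


def classify(
    pt: PhasePoint,
    reference: PhasePoint,
    theta: float = COLLAPSE_THETA,
    contrast_threshold: float = 0.0,
    block_theta: Optional[float] = None,
) -> str:
    """Label one phase point from its metrics relative to the reference.

    Whole-chain and per-state collapse are judged against the
    zero-interaction reference (fraction ``theta``).  Block (TAD)
    formation is judged by the compaction ratio against the same-U_ns
    background when available (threshold ``block_theta``, anchored to the
    exemplar regimes by :func:`exemplar_thresholds`), falling back to the
    per-block comparison against the reference otherwise.
    """
    chain_collapsed = pt.rg2_whole < theta * reference.rg2_whole
    if pt.block_ratio is not None and block_theta is not None:
        blocks_collapsed = pt.block_ratio < block_theta
    else:
        blk = np.array(pt.rg2_blocks) < theta * np.array(reference.rg2_blocks)
        blocks_collapsed = blk.size > 0 and np.mean(blk) >= 0.5
    state_collapsed = all(
        pt.rg2_states[s] < theta * reference.rg2_states[s] for s in pt.rg2_states
    )
    high_contrast = pt.contrast >= contrast_threshold
    if state_collapsed and high_contrast:
        return "microphase"
    if chain_collapsed and not high_contrast:
        return "globule"
    if blocks_collapsed or chain_collapsed:
        return "intermediate"
    return "coil"


def point_metrics_path(
    model: ChainModel,
    U_ns: float,
    U_s: float,
    settings: SolverSettings,
    r_c: float = 1.0,
    du: float = 0.5,
) -> tuple[PhasePoint, np.ndarray]:
    """Solve one point by continuation along U_s from 0 with warm starts.

    Single cold solves can land on the wrong branch where strong specific
    attraction competes with non-specific repulsion; following the
    adiabatic branch from weak attraction (as the full sweep does)
    resolves the ambiguity deterministically.  The U_s = 0 starting point
    doubles as the background for the block-compaction ratio.
    """
    steps = np.arange(0.0, abs(U_s) + du / 2, du) * np.sign(U_s or 1.0)
    if steps.size == 0 or steps[-1] != U_s:
        steps = np.append(steps, U_s)
    background, warm = point_metrics(model, U_ns, 0.0, settings, r_c)
    for u in steps[1:-1]:
        _, warm = point_metrics(
            model, U_ns, float(u), replace(settings, init=warm), r_c
        )
    return point_metrics(
        model, U_ns, U_s, replace(settings, init=warm), r_c, background=background
    )


def exemplar_thresholds(
    template: ChainModel, settings: SolverSettings, r_c: float = 1.0
) -> tuple[float, float]:
    """Anchor the free classification thresholds to the exemplar regimes.

    Returns (contrast_threshold, block_theta): the contrast threshold is
    the midpoint of the checkerboard contrasts of the microphase and
    intermediate exemplars; the block-compaction threshold is the
    midpoint of the mean block-compaction ratios of the coil and
    intermediate exemplars on the strongly repulsive background.  This
    ties the operational phase boundaries to the model's own behaviour
    on this chain instead of arbitrary constants.
    """
    micro, _ = point_metrics_path(template, 1.0, -3.4, settings, r_c)
    inter, _ = point_metrics_path(template, 3.0, -3.4, settings, r_c)
    coil, _ = point_metrics_path(template, 3.0, -1.0, settings, r_c)
    contrast_threshold = 0.5 * (micro.contrast + inter.contrast)
    block_theta = 0.5 * (coil.block_ratio + inter.block_ratio)
    return contrast_threshold, block_theta


def _exemplar_contrast_threshold(
    template: ChainModel, settings: SolverSettings, r_c: float
) -> float:
    return exemplar_thresholds(template, settings, r_c)[0]


def sweep(
    model_template: ChainModel,
    U_ns_grid: Sequence[float],
    U_s_grid: Sequence[float],
    settings: Optional[SolverSettings] = None,
    theta: float = COLLAPSE_THETA,
    r_c: float = 1.0,
    contrast_threshold: Optional[float] = None,
    block_theta: Optional[float] = None,
) -> PhaseDiagram:
    """Classify every grid point of a two-state copolymer template.

    Points are scanned from weak to strong specific attraction at each
    U_ns, warm-starting every solve from its weaker-attraction neighbour
    (hysteresis control near the continuous transitions); the U_s = 0
    point of each column is the background for the block-compaction
    ratio.  Thresholds not supplied are anchored to the exemplar regimes
    (:func:`exemplar_thresholds`).
    """
    ann = model_template.annotation
    if ann is None or len(ann.alphabet) < 2:
        raise ValueError("phase sweep requires a template with >= 2 states")
    if sum(1 for _ in ann.blocks()) < 4:
        raise ValueError("template should contain >= 2 blocks of each state")
    if settings is None:
        settings = SolverSettings()
    U_ns_grid = np.asarray(U_ns_grid, dtype=float)
    U_s_grid = np.asarray(sorted(U_s_grid, key=abs), dtype=float)

    reference, _ = point_metrics(model_template, 0.0, 0.0, settings, r_c)
    if contrast_threshold is None or block_theta is None:
        anchored = exemplar_thresholds(model_template, settings, r_c)
        if contrast_threshold is None:
            contrast_threshold = anchored[0]
        if block_theta is None:
            block_theta = anchored[1]

    points = []
    for u_ns in U_ns_grid:
        background, warm = point_metrics(model_template, u_ns, 0.0, settings, r_c)
        for u_s in U_s_grid:
            sv = replace(settings, init=warm)
            pt, D = point_metrics(
                model_template, u_ns, u_s, sv, r_c, background=background
            )
            warm = D
            label = (
                classify(pt, reference, theta, contrast_threshold, block_theta)
                if pt.converged
                else "not-converged"
            )
            points.append(replace(pt, label=label))
    return PhaseDiagram(
        points=points,
        U_ns_grid=U_ns_grid,
        U_s_grid=U_s_grid,
        reference=reference,
        theta=theta,
        contrast_threshold=contrast_threshold,
        block_theta=block_theta,
    )


def find_collapse_point(
    params: PolymerParams,
    U_ns_grid: Sequence[float],
    settings: Optional[SolverSettings] = None,
    min_drop: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Locate the homopolymer coil-globule transition on a U_ns grid.

    Scans from weak to strong attraction with warm starts and returns the
    grid point with the steepest R_g^2 change (central differences at
    interior points), together with the (U_ns, R_g^2) scan.  Raises if the
    grid does not bracket a drop (R_g^2 never falls below ``min_drop`` of
    its maximum).
    """
    if settings is None:
        settings = SolverSettings()
    grid = np.asarray(sorted(U_ns_grid, reverse=True), dtype=float)  # weak -> strong
    if grid.size < 3:
        raise ValueError("need at least 3 grid points")
    rg2 = np.empty_like(grid)
    warm = None
    for idx, u in enumerate(grid):
        m = ChainModel(params=replace(params, U_ns=float(u)))
        res = solve_stationary(m, replace(settings, init=warm))
        warm = res.D
        rg2[idx] = radius_of_gyration(res.D) ** 2
    if np.min(rg2) > min_drop * np.max(rg2):
        raise ValueError(
            "collapse drop not bracketed by the grid "
            f"(R_g^2 range {np.min(rg2):.3g}..{np.max(rg2):.3g})"
        )
    slope = np.abs((rg2[2:] - rg2[:-2]) / (grid[2:] - grid[:-2]))
    u_c = float(grid[1:-1][np.argmax(slope)])
    return u_c, np.column_stack([grid, rg2])
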