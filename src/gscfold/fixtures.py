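"""Synthetic inputs with known ground truth.

Generates two-state (active/null) Drosophila-like chromatin segmentations
— alternating blocks with geometrically distributed lengths at 10 kbp per
bead — and forward-simulated contact maps with Poisson count noise, so
that segmentation building, TAD calling and interaction inference are all
testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import ChainModel, ChromatinAnnotation, PolymerParams
from .observables import ContactMap, contact_probability
from .solver import SolverSettings, solve_stationary

__all__ = [
    "FixtureSpec",
    "make_segmentation",
    "fig_region_segmentation",
    "make_noisy_map",
    "write_fixture_dir",
]

ACTIVE = "active"
NULL = "null"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic genome.

    ``mean_block``/``min_block`` define the geometric block-length
    distribution (in beads); ``depth`` is the expected count at a
    probability-1 contact (sequencing depth proxy) for the noisy map.
    """

    N: int = 130
    alphabet: tuple = (ACTIVE, NULL)
    mean_block: float = 10.0
    min_block: int = 3
    depth: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_block < 1 or self.mean_block < self.min_block:
            raise ValueError("need mean_block >= min_block >= 1")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


def make_segmentation(spec: FixtureSpec, alternating: bool = True) -> ChromatinAnnotation:
    """Draw a blockwise segmentation of N beads; seeded and reproducible.

    Block lengths are ``min_block`` plus a geometric excess with the
    requested mean; states alternate through the alphabet (``alternating``)
    or are drawn uniformly with no immediate repeat otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    p = 1.0 / max(spec.mean_block - spec.min_block + 1.0, 1.0)
    states: list = []
    k = rng.integers(len(spec.alphabet))
    while len(states) < spec.N:
        length = spec.min_block + int(rng.geometric(p)) - 1
        states.extend([spec.alphabet[k]] * length)
        if alternating:
            k = (k + 1) % len(spec.alphabet)
        else:
            k = (k + 1 + rng.integers(len(spec.alphabet) - 1)) % len(spec.alphabet)
    states = states[: spec.N]
    # truncation at N must not leave a block below the minimum length
    tail = 1
    while tail < len(states) and states[-tail - 1] == states[-1]:
        tail += 1
    if tail < spec.min_block and len(states) > tail:
        for i in range(1, tail + 1):
            states[-i] = states[-tail - 1]
    return ChromatinAnnotation(states)


def fig_region_segmentation(N: int = 130, seed: int = 4) -> ChromatinAnnotation:
    """A deterministic two-state ~1.3 Mbp segmentation.

    Emulates the simplified active/null block structure of a fly
    chromosome-arm region at 10 kbp per bead (alternating blocks, mean
    length ~10 beads = 100 kbp, typical of Drosophila TADs).
    """
    return make_segmentation(FixtureSpec(N=N, mean_block=10.0, min_block=4, seed=seed))


def make_noisy_map(
    model: ChainModel,
    depth: float,
    seed: int,
    r_c: float = 1.0,
    solver: Optional[SolverSettings] = None,
    overdispersion: float = 0.0,
) -> tuple[np.ndarray, ContactMap]:
    """Forward-solve the model and return (raw counts, true contact map).

    Counts are drawn per pair as Poisson(depth * P_ij) (symmetrised from
    the upper triangle); ``overdispersion`` > 0 switches to a
    gamma-mixed Poisson with that squared coefficient of excess variation,
    for robustness tests.
    """
    res = solve_stationary(model, solver or SolverSettings())
    truth = contact_probability(res.D, r_c)
    rng = np.random.default_rng(seed)
    N = truth.N
    lam = depth * truth.P
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, lam / shape)
    counts = np.zeros((N, N))
    iu = np.triu_indices(N, 0)
    counts[iu] = rng.poisson(lam[iu])
    counts = np.triu(counts) + np.triu(counts, 1).T
    return counts, truth


def write_fixture_dir(
    path: str | Path,
    spec: FixtureSpec,
    model: ChainModel,
    counts: np.ndarray,
    truth: ContactMap,
    extra_meta: Optional[dict] = None,
) -> None:
    """Emit a self-contained fixture directory: BED + maps + truth JSON."""
    from . import io as _io

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _io.write_segmentation(model.annotation, path / "segmentation.bed",
                           bp_per_bin=model.params.bp_per_monomer)
    _io.write_contact_map(ContactMap(P=counts), path / "counts.tsv", fmt="dense")
    _io.write_contact_map(truth, path / "truth.tsv", fmt="dense")
    meta = {
        "N": spec.N,
        "alphabet": list(spec.alphabet),
        "mean_block": spec.mean_block,
        "min_block": spec.min_block,
        "depth": spec.depth,
        "seed": spec.seed,
    }
    if extra_meta:
        meta.update(extra_meta)
    (path / "truth.json").write_text(json.dumps(meta, indent=2) + "\n")
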