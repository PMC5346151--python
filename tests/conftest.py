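"""Shared fixtures: small solved chains reused across the suite."""

import warnings

import numpy as np
import pytest

from gscfold import (
    ChainModel,
    ChromatinAnnotation,
    PolymerParams,
    SolverSettings,
    SpecificInteraction,
    solve_stationary,
)

# non-converged warnings are asserted explicitly where relevant
warnings.filterwarnings("ignore", message="GSC solve not converged")


@pytest.fixture(scope="session")
def coil_state_n200():
    """Stationary state of the N = 200 homopolymer at U_ns = -1.9 (coil side)."""
    model = ChainModel(params=PolymerParams(N=200, U_ns=-1.9))
    res = solve_stationary(model, SolverSettings())
    assert res.converged
    return model, res


@pytest.fixture(scope="session")
def two_state_annotation():
    """Alternating 15/15 two-state annotation, N = 30."""
    return ChromatinAnnotation(["a"] * 15 + ["b"] * 15)


@pytest.fixture(scope="session")
def blocky_state_n30(two_state_annotation):
    """Strongly blocked two-state copolymer and its stationary state."""
    model = ChainModel(
        params=PolymerParams(N=30, U_ns=0.0),
        annotation=two_state_annotation,
        specific=SpecificInteraction.diagonal(("a", "b"), -3.0),
    )
    res = solve_stationary(model, SolverSettings())
    assert res.converged
    return model, res


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
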