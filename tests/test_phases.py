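"""Phase classification of the block copolymer and collapse-point location."""

import numpy as np
import pytest

from gscfold import (
    ChainModel,
    ChromatinAnnotation,
    PolymerParams,
    SolverSettings,
    SpecificInteraction,
    contact_probability,
    solve_stationary,
)
from gscfold.phases import (
    PhasePoint,
    checkerboard_contrast,
    classify,
    find_collapse_point,
    point_metrics,
    sweep,
)


def make_point(rg2_whole, rg2_blocks, rg2_states, contrast):
    return PhasePoint(
        U_ns=0.0, U_s=0.0, label="", rg2_whole=rg2_whole,
        rg2_blocks=tuple(rg2_blocks), rg2_states=rg2_states,
        contrast=contrast, converged=True,
    )


REF = make_point(100.0, [10.0, 10.0, 10.0, 10.0], {"a": 50.0, "b": 50.0}, 0.0)


class TestClassify:
    """The label is a pure function of the metrics and thresholds."""

    @pytest.mark.parametrize(
        "pt,expected",
        [
            (make_point(120.0, [11, 12, 10, 11], {"a": 55, "b": 60}, 0.001), "coil"),
            (make_point(30.0, [4, 4, 4, 4], {"a": 15, "b": 15}, 0.001), "globule"),
            (make_point(60.0, [4, 4, 4, 4], {"a": 20, "b": 20}, 0.02), "microphase"),
            (make_point(80.0, [4, 4, 11, 11], {"a": 20, "b": 55}, 0.001), "intermediate"),
        ],
    )
    def test_labels(self, pt, expected):
        assert classify(pt, REF, theta=0.5, contrast_threshold=0.01) == expected

    def test_threshold_is_relative_to_reference(self):
        pt = make_point(49.0, [11, 11, 11, 11], {"a": 55, "b": 55}, 0.0)
        assert classify(pt, REF, theta=0.5, contrast_threshold=0.01) == "globule"
        assert classify(pt, REF, theta=0.4, contrast_threshold=0.01) == "coil"


class TestCheckerboardContrast:
    @pytest.fixture(scope="class")
    def crumpled_copolymer_scan(self):
        """U_s scan of a crumpled 4-block two-state copolymer.

        The crumpled background keeps distant blocks spatially close, so
        same-state aggregation (and hence contrast) is reachable — on a
        swollen chain the Gaussian coupling between far blocks is
        exponentially small and they never merge.
        """
        from gscfold.calibration import CrumplingFitSettings, calibrate_crumpling

        ann = ChromatinAnnotation((["a"] * 8 + ["b"] * 8) * 4)
        N = 64
        table, _ = calibrate_crumpling(
            PolymerParams(N=N, U_ns=0.0), CrumplingFitSettings(n_bins=8)
        )
        out = []
        warm = None
        for u_s in (0.0, -2.0, -4.0):
            model = ChainModel(
                params=PolymerParams(N=N, U_ns=0.0),
                annotation=ann,
                specific=SpecificInteraction.diagonal("ab", u_s),
                crumpling=table,
            )
            res = solve_stationary(model, SolverSettings(init=warm))
            assert res.converged
            warm = res.D
            out.append(
                (model, checkerboard_contrast(contact_probability(res.D).P, model))
            )
        return out

    def test_segregated_vs_uniform(self, crumpled_copolymer_scan):
        """A microphase-separated fold has positive contrast; a uniform
        map none."""
        model, contrast = crumpled_copolymer_scan[-1]
        assert contrast > 0.1
        uniform = np.full((64, 64), 0.3)
        assert checkerboard_contrast(uniform, model) == pytest.approx(0.0)

    def test_two_blocks_rejected(self, blocky_state_n30):
        """With a single block per state there are no same-state
        inter-block pairs and the statistic is undefined."""
        model, res = blocky_state_n30
        with pytest.raises(ValueError, match="same-state inter-block"):
            checkerboard_contrast(contact_probability(res.D).P, model)

    def test_requires_annotation(self):
        model = ChainModel(params=PolymerParams(N=10))
        with pytest.raises(ValueError):
            checkerboard_contrast(np.eye(10), model)

    def test_monotone_in_specific_attraction(self, crumpled_copolymer_scan):
        """Contrast grows toward the microphase as same-state attraction
        strengthens (small numerical dips at weak coupling tolerated)."""
        contrasts = [c for _, c in crumpled_copolymer_scan]
        assert contrasts[1] >= contrasts[0] - 5e-3
        assert contrasts[2] >= contrasts[1] - 5e-3
        assert contrasts[2] > contrasts[0] + 0.05


class TestFindCollapsePoint:
    def test_drop_location_small_chain(self):
        """The steepest R_g^2 drop of an N = 100 chain sits at stronger
        attraction than the infinite-chain theta point (finite-size shift)."""
        grid = np.arange(-3.4, -1.9, 0.1)
        u_c, scan = find_collapse_point(PolymerParams(N=100), grid)
        assert -3.4 <= u_c <= -2.2
        assert scan.shape[1] == 2

    def test_finite_size_ordering(self):
        """The detected collapse for a shorter chain is at equal or stronger
        attraction than for a longer one."""
        grid = np.arange(-3.4, -1.7, 0.1)
        u_small, _ = find_collapse_point(PolymerParams(N=60), grid)
        u_large, _ = find_collapse_point(PolymerParams(N=160), grid)
        assert u_small <= u_large + 1e-9

    def test_unbracketed_drop_raises(self):
        with pytest.raises(ValueError, match="not bracketed"):
            find_collapse_point(PolymerParams(N=60), [0.0, 0.5, 1.0])


class TestBlockCooperativity:
    @pytest.fixture(scope="class")
    def mixed_block_scan(self):
        """U_s scan of a crumpled chain with attractive blocks of sizes
        5/10/20 separated by neutral blocks."""
        from gscfold.calibration import CrumplingFitSettings, calibrate_crumpling
        from gscfold.observables import radius_of_gyration

        layout = [("y", 6), ("x", 5), ("y", 8), ("x", 10), ("y", 8), ("x", 20), ("y", 8)]
        states = [s for s, n in layout for _ in range(n)]
        N = len(states)
        ann = ChromatinAnnotation(states)
        table, _ = calibrate_crumpling(
            PolymerParams(N=N, U_ns=0.0), CrumplingFitSettings(n_bins=8)
        )
        xb = [(a, b) for a, b, s in ann.blocks() if s == "x"]
        yb = [(a, b) for a, b, s in ann.blocks() if s == "y"]
        out = {}
        warm = None
        for u_s in (0.0, -0.5, -1.0, -1.5, -2.0):
            model = ChainModel(
                params=PolymerParams(N=N, U_ns=0.0),
                annotation=ann,
                specific=SpecificInteraction({("x", "x"): u_s}),
                crumpling=table,
            )
            res = solve_stationary(model, SolverSettings(init=warm))
            assert res.converged
            warm = res.D
            out[u_s] = {
                "x_rg2": [radius_of_gyration(res.D, np.arange(a, b)) ** 2 for a, b in xb],
                "x_dens": [(b - a) / radius_of_gyration(res.D, np.arange(a, b)) ** 3
                           for a, b in xb],
                "y_dens": [(b - a) / radius_of_gyration(res.D, np.arange(a, b)) ** 3
                           for a, b in yb],
            }
        return out

    def test_larger_blocks_collapse_at_weaker_attraction(self, mixed_block_scan):
        """Collective effects: the 20-bead block crosses half its reference
        size at weaker |U_s| than the 10-bead block, which precedes the
        5-bead block."""
        ref = mixed_block_scan[0.0]["x_rg2"]
        crossing = {}
        for size_idx in range(3):  # blocks ordered 5, 10, 20 along the chain
            for u_s in (-0.5, -1.0, -1.5, -2.0):
                if mixed_block_scan[u_s]["x_rg2"][size_idx] < 0.5 * ref[size_idx]:
                    crossing[size_idx] = u_s
                    break
        # larger block -> less negative crossing
        assert crossing[2] > crossing[1] >= crossing[0] - 1e-9
        assert crossing[2] > crossing[0]

    def test_density_grows_with_size_for_attractive_blocks(self, mixed_block_scan):
        """Partial-collapse regime: internal density N_b / R_g^3 increases
        with block size for the attractive state, while neutral blocks on
        the crumpled backbone stay near size-independent density."""
        dx = mixed_block_scan[-2.0]["x_dens"]
        assert dx[0] < dx[1] < dx[2]
        dy = mixed_block_scan[-2.0]["y_dens"]
        assert max(dy) / min(dy) < 1.6  # flat within block-to-block scatter
        assert (dx[2] / dx[0]) > 2.0  # vs a strong trend for attractive blocks


class TestSweep:
    def test_minimal_grid_labels_and_metrics(self):
        """A 2x2 sweep records metrics for every point and classifies with
        the run-time contrast threshold."""
        ann = ChromatinAnnotation((["a"] * 8 + ["b"] * 8) * 2)
        template = ChainModel(params=PolymerParams(N=32), annotation=ann)
        diagram = sweep(template, [0.0, -0.4], [0.0, -2.0])
        assert len(diagram.points) == 4
        labels = {(pt.U_ns, pt.U_s): pt.label for pt in diagram.points}
        assert labels[(0.0, 0.0)] == "coil"
        assert all(pt.rg2_whole > 0 for pt in diagram.points)
        assert diagram.reference.rg2_whole > 0

    def test_requires_blocky_two_state_template(self):
        homo = ChainModel(params=PolymerParams(N=32))
        with pytest.raises(ValueError):
            sweep(homo, [0.0], [0.0])
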