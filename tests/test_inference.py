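"""TAD partitioning, map normalisation and block-interaction inference."""

import dataclasses

import numpy as np
import pytest

from gscfold import (
    ChainModel,
    ChromatinAnnotation,
    PolymerParams,
    SpecificInteraction,
    contact_probability,
    solve_stationary,
)
from gscfold.fixtures import FixtureSpec, make_noisy_map, make_segmentation
from gscfold.inference import (
    BlockInteractionModel,
    BlockParams,
    FitSettings,
    TadSegmentation,
    classify_inferred,
    infer_interactions,
    normalize_experimental,
    partition_tads,
)
from gscfold.observables import ContactMap


class TestTadSegmentation:
    def test_assignment(self):
        tads = TadSegmentation([0, 3, 7, 10])
        assert tads.T == 3
        assert list(tads.assignment()) == [0] * 3 + [1] * 4 + [2] * 3

    @pytest.mark.parametrize("bad", [[1, 5], [0, 5, 5, 8], [0, 7, 3, 10]])
    def test_invalid_boundaries(self, bad):
        with pytest.raises(ValueError):
            TadSegmentation(bad)


class TestPartitionTads:
    def test_two_block_map_recovered(self, blocky_state_n30):
        """Dense-intra / sparse-inter two-block map yields exactly the two
        true TADs."""
        _, res = blocky_state_n30
        tads = partition_tads(contact_probability(res.D))
        assert tads.boundaries == (0, 15, 30)

    def test_constant_map_single_tad(self):
        cmap = ContactMap(P=np.full((25, 25), 0.3))
        assert partition_tads(cmap).boundaries == (0, 25)

    def test_deterministic(self, blocky_state_n30):
        _, res = blocky_state_n30
        cmap = contact_probability(res.D)
        assert partition_tads(cmap).boundaries == partition_tads(cmap).boundaries

    def test_user_segmentation_bypasses(self, blocky_state_n30):
        """A supplied segmentation is used as-is by the model constructor."""
        model, res = blocky_state_n30
        tads = TadSegmentation([0, 10, 30])
        fit_model = BlockInteractionModel(
            contact_probability(res.D), tads, model
        )
        assert fit_model.tads is tads


class TestNormalizeExperimental:
    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20.0, size=(15, 15)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        ref = ContactMap(P=np.exp(-np.abs(np.subtract.outer(range(15), range(15))) / 4.0))
        a, _ = normalize_experimental(counts, ref)
        b, _ = normalize_experimental(2.0 * counts, ref)
        assert np.allclose(a.P, b.P)

    def test_probability_map_scale_recovered(self):
        """Counts proportional to a probability map come back on the
        reference scale (no coverage correction applied)."""
        ref = ContactMap(P=np.exp(-np.abs(np.subtract.outer(range(12), range(12))) / 3.0))
        counts = 500.0 * ref.P
        normed, scale = normalize_experimental(counts, ref, coverage=False)
        assert scale == pytest.approx(1 / 500.0, rel=1e-9)
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(normed.P[off], ref.P[off], rtol=1e-9)

    def test_zero_coverage_bin_masked(self):
        ref = ContactMap(P=np.full((10, 10), 0.5))
        counts = np.full((10, 10), 8.0)
        counts[4, :] = counts[:, 4] = 0.0
        normed, _ = normalize_experimental(counts, ref)
        assert normed.mask[4]
        assert normed.mask.sum() == 1
        assert np.all(normed.P[4, :4] == 0)  # masked row zero off the diagonal

    def test_negative_counts_rejected(self):
        ref = ContactMap(P=np.full((5, 5), 0.5))
        with pytest.raises(ValueError):
            normalize_experimental(np.full((5, 5), -1.0), ref)


@pytest.fixture(scope="module")
def two_tad_problem():
    """Forward-generated noiseless recovery problem with known V."""
    N = 60
    tads = TadSegmentation([0, 30, 60])
    Vtrue = np.array([[-0.4, 0.0], [0.0, 0.0]])
    base = ChainModel(params=PolymerParams(N=N, U_ns=0.0))
    truth_model = dataclasses.replace(
        base, extra=BlockParams(V=Vtrue, tads=tads).expand()
    )
    res = solve_stationary(truth_model)
    target = contact_probability(res.D)
    return base, tads, Vtrue, target


class TestInferInteractions:
    def test_noiseless_recovery(self, two_tad_problem):
        """Forward-generate from known V and recover every entry within
        0.1 k_BT (attraction in the reported heterochromatin range)."""
        base, tads, Vtrue, target = two_tad_problem
        result = infer_interactions(target, tads, base)
        assert np.max(np.abs(result.params.V - Vtrue)) < 0.1

    def test_chi2_descent(self, two_tad_problem):
        base, tads, _, target = two_tad_problem
        result = infer_interactions(target, tads, base)
        traj = result.chi2_trajectory
        assert all(b <= a + 1e-12 for a, b in zip(traj, traj[1:]))
        assert result.chi2 <= traj[0]

    def test_tad_label_equivariance(self, two_tad_problem):
        """Reversing the chain (and hence the TAD order) permutes V."""
        base, tads, _, target = two_tad_problem
        result = infer_interactions(target, tads, base)
        flipped = ContactMap(P=target.P[::-1, ::-1].copy())
        result_flipped = infer_interactions(flipped, tads, base)
        assert np.allclose(
            result_flipped.params.V, result.params.V[::-1, ::-1], atol=0.05
        )

    def test_summary_mentions_estimates(self, two_tad_problem):
        base, tads, _, target = two_tad_problem
        result = infer_interactions(target, tads, base)
        text = result.summary()
        assert "chi2" in text and "TADs: 2" in text

    def test_noisy_recovery_single_genome(self):
        """End-to-end: segmentation, forward map with count noise, Poisson
        deviance fit; intra-TAD amplitudes within 0.15 k_BT."""
        spec = FixtureSpec(N=60, mean_block=12, min_block=5, seed=103)
        ann = make_segmentation(spec)
        blocks = ann.blocks()
        tads = TadSegmentation([0] + [b[1] for b in blocks])
        rng = np.random.default_rng(7)
        Vtrue = np.zeros((tads.T, tads.T))
        for t, (_, _, state) in enumerate(blocks):
            Vtrue[t, t] = rng.uniform(-0.6, -0.2) if state == "null" else 0.0
        base = ChainModel(params=PolymerParams(N=60, U_ns=0.0))
        truth_model = dataclasses.replace(
            base, extra=BlockParams(V=Vtrue, tads=tads).expand()
        )
        counts, truth = make_noisy_map(truth_model, spec.depth, seed=17)
        normed, scale = normalize_experimental(counts, truth, coverage=False)
        result = BlockInteractionModel(normed, tads, base).fit(
            FitSettings(count_scale=scale, objective="poisson", ridge=5.0)
        )
        diag_err = np.abs(np.diag(result.params.V) - np.diag(Vtrue))
        assert np.median(diag_err) < 0.15


class TestClassifyInferred:
    def test_majority_and_ties(self):
        ann = ChromatinAnnotation(["active"] * 7 + ["null"] * 3 + ["active"] * 5 + ["null"] * 5)
        tads = TadSegmentation([0, 10, 20])
        V = np.diag([-0.1, -0.5])
        out = classify_inferred(BlockParams(V=V, tads=tads), ann)
        assert out[0] == ("active", -0.1)
        # 5/5 tie in the second TAD: earlier state in the alphabet order wins
        assert out[1] == ("active", -0.5)

    def test_single_tad(self):
        ann = ChromatinAnnotation(["null"] * 8)
        tads = TadSegmentation([0, 8])
        out = classify_inferred(BlockParams(V=np.array([[-0.3]]), tads=tads), ann)
        assert out == [("null", -0.3)]
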