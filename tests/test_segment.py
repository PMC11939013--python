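import itertools

import numpy as np
import pytest
from scipy import ndimage as ndi

from casdn import (
    CasdnConfig,
    DimensionError,
    FIT_GRIDS,
    ValidationError,
    adaptive_weighting,
    casdn_loss,
    cell_relevances,
    context_loss,
    decompose_grid,
    fit,
    fuse_cells,
    fusion_weights,
    generate_phantom,
    hierarchical_integrate,
    predict,
    process_cell,
    refine,
    run_aipt,
    spatial_loss,
    PhantomSpec,
)
from casdn.segment import _ImageContext


class TestGridDecomposition:
    def test_exact_division(self):
        d = decompose_grid(np.zeros((64, 64)), 16)
        assert len(d.cells) == 16
        assert all(c.block.shape == (16, 16) for c in d.cells)

    def test_remainder_absorbed_exact_tiling(self):
        img = np.zeros((65, 65))
        d = decompose_grid(img, 4)
        cover = np.zeros_like(img, dtype=int)
        sizes = set()
        for c in d.cells:
            r0, r1, c0, c1 = c.box
            cover[r0:r1, c0:c1] += 1
            sizes.add((r1 - r0, c1 - c0))
        assert np.all(cover == 1)
        assert sizes == {(32, 32), (32, 33), (33, 32), (33, 33)}

    def test_non_square_count_rejected(self):
        with pytest.raises(ValidationError):
            decompose_grid(np.zeros((64, 64)), 6)


class TestCellFeatures:
    def test_constant_block(self):
        feats = process_cell(np.full((8, 8), 0.3))
        assert np.allclose(feats, [0.3, 0.0, 0.0, 0.0])

    def test_checkerboard_entropy_one_bit(self):
        block = np.indices((8, 8)).sum(axis=0) % 2
        feats = process_cell(block.astype(np.float64))
        assert np.isclose(feats[3], 1.0)

    def test_mean_and_entropy_transpose_invariant(self, rng):
        block = rng.random((6, 9))
        a, b = process_cell(block), process_cell(block.T)
        assert np.isclose(a[0], b[0]) and np.isclose(a[3], b[3])

    def test_entropy_bounded(self, rng):
        feats = process_cell(rng.random((16, 16)))
        assert 0.0 <= feats[3] <= 4.0


class TestRelevance:
    def test_identical_cells_zero(self):
        feats = [np.array([0.5, 0.1, 0.2, 1.0])] * 4
        assert np.allclose(cell_relevances(feats), 0.0)

    def test_textured_cell_strictly_largest(self, rng):
        flat = [process_cell(np.full((8, 8), 0.4) + 1e-3 * rng.random((8, 8)))
                for _ in range(3)]
        textured = process_cell(rng.random((8, 8)))
        rel = cell_relevances(flat + [textured])
        assert np.argmax(rel) == 3
        assert rel[3] > max(rel[:3])

    def test_sums_to_zero_with_variance(self, rng):
        feats = [process_cell(rng.random((8, 8))) for _ in range(5)]
        assert abs(cell_relevances(feats).sum()) < 1e-9

    def test_single_cell_rejected(self):
        with pytest.raises(ValidationError):
            cell_relevances([np.zeros(4)])


class TestFusionWeights:
    def test_zero_sharpness_uniform(self, rng):
        w = fusion_weights(rng.random(16), 0.0)
        assert np.allclose(w, 1 / 16)

    def test_equal_relevances_uniform(self):
        w = fusion_weights(np.full(9, 2.7), 3.0)
        assert np.allclose(w, 1 / 9)

    def test_closed_form_softmax(self):
        w = fusion_weights(np.array([0.0, np.log(3.0)]), 1.0)
        assert np.allclose(w, [0.25, 0.75])

    def test_always_sums_to_one(self, rng):
        for alpha in (0.0, 0.5, 4.0):
            assert abs(fusion_weights(rng.normal(size=25), alpha).sum() - 1) < 1e-9


class TestFuseCells:
    def test_uniform_weights_neutral_assembly(self, rng):
        img = rng.random((32, 32))
        d = decompose_grid(img, 16)
        fused = fuse_cells(img, d, np.full(16, 1 / 16))
        # neutral element: plain per-cell min-max contrast assembly
        want = np.empty_like(img)
        for c in d.cells:
            r0, r1, c0, c1 = c.box
            blk = img[r0:r1, c0:c1]
            want[r0:r1, c0:c1] = (blk - blk.min()) / (blk.max() - blk.min())
        assert np.allclose(fused, want)

    def test_single_cell_support(self, rng):
        img = rng.random((32, 32))
        d = decompose_grid(img, 16)
        w = np.zeros(16)
        w[5] = 1.0
        fused = fuse_cells(img, d, w)
        r0, r1, c0, c1 = d.cells[5].box
        outside = fused.copy()
        outside[r0:r1, c0:c1] = 0
        assert np.all(outside == 0)

    def test_two_cell_arithmetic(self):
        img = np.zeros((8, 16))
        img[:, :8] = np.linspace(0, 1, 8)[None, :].repeat(8, axis=0)
        img[:, 8:] = np.linspace(0, 0.5, 8)[None, :].repeat(8, axis=0)
        d = decompose_grid(img, 4)
        w = np.array([0.125, 0.375, 0.125, 0.375])
        fused = fuse_cells(img, d, w)
        for i, cell in enumerate(d.cells):
            r0, r1, c0, c1 = cell.box
            blk = img[r0:r1, c0:c1]
            contrast = (blk - blk.min()) / (blk.max() - blk.min())
            assert np.allclose(fused[r0:r1, c0:c1],
                               np.clip(4 * w[i] * contrast, 0, 1))


class TestAdaptiveWeighting:
    def test_zero_strength_identity(self, rng):
        f = rng.random((16, 16))
        assert np.array_equal(adaptive_weighting(f, rng.random((16, 16)), 0.0), f)

    def test_unit_saliency_identity(self, rng):
        f = rng.random((16, 16))
        assert np.allclose(adaptive_weighting(f, np.ones_like(f), 0.7), f)

    def test_full_gating_arithmetic(self):
        f = np.full((8, 8), 0.8)
        s = np.full((8, 8), 0.5)
        assert np.allclose(adaptive_weighting(f, s, 1.0), 0.4)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            adaptive_weighting(np.zeros((8, 8)), np.zeros((8, 9)), 0.5)


class TestHierarchicalIntegration:
    def test_constant_unchanged(self):
        f = np.full((32, 32), 0.6)
        for levels in (1, 2, 3):
            assert np.allclose(hierarchical_integrate(f, levels), f)

    def test_single_level_closed_form(self, rng):
        from skimage import transform

        f = rng.random((32, 32))
        got = hierarchical_integrate(f, 1)
        coarse = transform.resize(f, (16, 16), order=1, mode="reflect",
                                  anti_aliasing=True, preserve_range=True)
        coarse = ndi.gaussian_filter(coarse, 1.0, mode="reflect")
        up = transform.resize(coarse, (32, 32), order=1, mode="reflect",
                              anti_aliasing=False, preserve_range=True)
        assert np.allclose(got, np.clip(0.5 * f + 0.5 * up, 0, 1))

    def test_total_variation_non_increasing(self, rng):
        f = rng.random((32, 32))

        def tv(x):
            return np.abs(np.diff(x, axis=0)).sum() + np.abs(np.diff(x, axis=1)).sum()

        assert tv(hierarchical_integrate(f, 3)) <= tv(f)


class TestRefinement:
    def test_zero_step_identity(self, rng):
        f = rng.random((16, 16))
        assert np.array_equal(refine(f, 0.0), f)

    def test_half_fixed_point(self):
        f = np.full((16, 16), 0.5)
        assert np.allclose(refine(f, 0.9), 0.5)

    def test_sigmoid_closed_form(self):
        f = np.full((8, 8), 0.9)
        want = 1.0 / (1.0 + np.exp(-4.0))
        assert np.allclose(refine(f, 1.0), want)


class TestLosses:
    def test_spatial_loss_on_exact_binary_scores(self, rng):
        truth = (rng.random((16, 16)) < 0.4).astype(np.uint8)
        scores = truth.astype(np.float64)
        d0 = np.abs(np.diff(scores, axis=0))
        d1 = np.abs(np.diff(scores, axis=1))
        tv = (d0.sum() + d1.sum()) / (d0.size + d1.size)
        assert np.isclose(spatial_loss(scores, truth), tv, atol=1e-6)

    def test_spatial_loss_all_zero_scores(self):
        truth = np.ones((8, 8), dtype=np.uint8)
        assert np.isclose(spatial_loss(np.zeros((8, 8)), truth), 1.0, atol=1e-6)

    def test_context_loss_half_scores_ln2(self, rng):
        truth = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        assert np.isclose(context_loss(np.full((16, 16), 0.5), truth),
                          np.log(2), atol=1e-9)

    def test_context_loss_perfect_scores_near_zero(self, rng):
        truth = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        assert context_loss(truth.astype(np.float64), truth) <= 1e-5

    def test_losses_match_brute_force(self, rng):
        # independent re-implementation on random 8x8 instances
        for _ in range(20):
            scores = rng.random((8, 8))
            truth = (rng.random((8, 8)) < 0.5).astype(np.uint8)
            t = truth.astype(np.float64)
            dice_term = 1 - 2 * (scores * t).sum() / (scores.sum() + t.sum() + 1e-6)
            diffs = [abs(scores[i + 1, j] - scores[i, j])
                     for i in range(7) for j in range(8)]
            diffs += [abs(scores[i, j + 1] - scores[i, j])
                      for i in range(8) for j in range(7)]
            want_spatial = dice_term + np.mean(diffs)
            s = np.clip(scores, 1e-6, 1 - 1e-6)
            want_context = -np.mean(t * np.log(s) + (1 - t) * np.log(1 - s))
            assert abs(spatial_loss(scores, truth) - want_spatial) < 1e-9
            assert abs(context_loss(scores, truth) - want_context) < 1e-9

    def test_combined_loss_algebra(self, rng):
        scores = rng.random((8, 8))
        truth = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        base = CasdnConfig()
        v = casdn_loss(scores, truth, base)
        doubled = CasdnConfig(lambda_loss=2.0)
        assert np.isclose(casdn_loss(scores, truth, doubled), 2 * v)
        spatial_only = CasdnConfig(alpha_context_weight=0.0)
        assert np.isclose(
            casdn_loss(scores, truth, spatial_only),
            base.lambda_loss * base.alpha_spatial * spatial_loss(scores, truth),
        )


class TestFit:
    @pytest.fixture(scope="class")
    @staticmethod
    def training_pair():
        img, mask = generate_phantom(
            PhantomSpec(height=64, width=64, radius_range=(6.0, 10.0), seed=3)
        )
        pre, trace = run_aipt(img)
        return pre, trace["S_map"], mask

    def test_accepted_history_non_increasing(self, training_pair):
        pre, sal, mask = training_pair
        _, history = fit([pre], [mask], CasdnConfig(), saliencies=[sal])
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_matches_exhaustive_grid_minimum(self, training_pair):
        pre, sal, mask = training_pair
        fitted, history = fit([pre], [mask], CasdnConfig(), saliencies=[sal])
        ctx = _ImageContext(pre, sal, fitted.n_cells)
        best = np.inf
        for a, bc, br, t in itertools.product(*FIT_GRIDS.values()):
            cfg = CasdnConfig(alpha_context=a, beta_context=bc,
                              beta_refine=br, score_threshold=t)
            best = min(best, casdn_loss(ctx.scores(cfg), mask, cfg))
        assert np.isclose(history[-1], best, atol=1e-12)

    def test_duplicate_pairs_same_fit(self, training_pair):
        pre, sal, mask = training_pair
        one, _ = fit([pre], [mask], CasdnConfig(), saliencies=[sal])
        two, _ = fit([pre, pre], [mask, mask], CasdnConfig(), saliencies=[sal, sal])
        assert one == two

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            fit([], [], CasdnConfig())


class TestPredict:
    def test_zero_saliency_flat_image_empty_mask(self):
        img = np.full((32, 32), 0.5)
        res = predict(img, CasdnConfig(), np.zeros((32, 32)))
        assert res.mask.sum() == 0 and len(res.boundary) == 0

    def test_phantom_single_component(self):
        # representative fixed-seed phantom: one disk lesion in, one
        # connected component out after fitting
        img, mask = generate_phantom(PhantomSpec(seed=10))
        pre, trace = run_aipt(img)
        fitted, _ = fit([pre], [mask], CasdnConfig(), saliencies=[trace["S_map"]])
        res = predict(pre, fitted, trace["S_map"])
        _, n = ndi.label(res.mask)
        assert n == 1

    def test_boundary_of_solid_square(self):
        # combinatorial check: an n x n solid square has 4n - 4 boundary px
        from casdn.segment import _boundary_set

        for n in (2, 5, 9):
            m = np.zeros((16, 16), dtype=np.uint8)
            m[3:3 + n, 4:4 + n] = 1
            assert len(_boundary_set(m)) == 4 * n - 4

    def test_loss_reported_with_truth(self, small_phantom):
        img, mask = small_phantom
        pre, trace = run_aipt(img)
        res = predict(pre, CasdnConfig(), trace["S_map"], truth=mask)
        assert res.loss is not None and res.loss >= 0

    def test_deterministic(self, small_phantom):
        img, _ = small_phantom
        pre, trace = run_aipt(img)
        r1 = predict(pre, CasdnConfig(), trace["S_map"])
        r2 = predict(pre, CasdnConfig(), trace["S_map"])
        assert np.array_equal(r1.scores, r2.scores)
        assert np.array_equal(r1.mask, r2.mask)
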