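import numpy as np
import pytest
from shapely.geometry import box

from fusionyield.errors import (
    CoverageError,
    DegenerateClassError,
    InterpolationError,
)
from fusionyield.fsdaf import (
    FusionInputs,
    FusionParams,
    classify_fine,
    coarse_change,
    delineate,
    distribute_residuals,
    fsdaf_fuse,
    neighborhood_refine,
    temporal_prediction,
    tps_prediction,
)
from fusionyield.io_grid import GridRaster, PlotPolygon, block_aggregate


def grid(vals, ps=30.0):
    vals = np.asarray(vals, dtype=float)
    return GridRaster(vals, 0.0, vals.shape[0] * ps, ps)


class TestDelineate:
    def test_full_extent_identity(self):
        r = grid(np.random.default_rng(0).uniform(0, 1, (8, 8)))
        d = delineate(r, None, 4)
        np.testing.assert_array_equal(d.raster.values, r.values)
        assert d.inside.all()

    def test_snap_out_to_whole_coarse_pixels(self):
        r = grid(np.arange(64, dtype=float).reshape(8, 8) / 100)
        # region covers fine cells (0..5)^2 -> x,y in [0, 180]; raster is
        # 240 m tall so the region sits in the upper-left corner
        region = PlotPolygon("p", box(0, 60, 180, 240))
        d = delineate(r, region, 4)
        assert d.raster.shape == (8, 8)  # snapped out to whole 4x4 blocks
        np.testing.assert_array_equal(d.raster.values, r.values)
        assert d.inside[:6, :6].all()
        assert not d.inside[6:, :].any()

    def test_disjoint_region(self):
        r = grid(np.zeros((8, 8)))
        with pytest.raises(CoverageError):
            delineate(r, PlotPolygon("p", box(10000, 10000, 10010, 10010)), 4)


class TestClassifyFine:
    def test_two_valued_image_separates(self):
        vals = np.full((4, 4), 0.2)
        vals[:, 2:] = 0.8
        cmap = classify_fine(grid(vals), 2, seed=0, ratio=2)
        left = cmap.labels[0, 0]
        right = cmap.labels[0, 3]
        assert left != right
        assert (cmap.labels[:, :2] == left).all()
        assert (cmap.labels[:, 2:] == right).all()
        # fractions per 2x2 block are pure
        np.testing.assert_allclose(cmap.fractions.sum(axis=2), 1.0)
        assert cmap.fractions[0, 0, left] == 1.0
        assert cmap.fractions[0, 1, right] == 1.0

    def test_constant_image_single_class(self):
        cmap = classify_fine(grid(np.full((4, 4), 0.5)), 1, seed=0, ratio=2)
        assert (cmap.labels == 0).all()
        np.testing.assert_allclose(cmap.fractions[:, :, 0], 1.0)

    def test_fraction_counting_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([0.1, 0.5, 0.9], size=(4, 4))
        while np.unique(vals).size < 3:
            vals = rng.choice([0.1, 0.5, 0.9], size=(4, 4))
        cmap = classify_fine(grid(vals), 3, seed=0, ratio=4)
        # exhaustive counting oracle over the single 4x4 block
        for k in range(3):
            assert cmap.fractions[0, 0, k] == (cmap.labels == k).sum() / 16

    def test_too_many_classes(self):
        with pytest.raises(DegenerateClassError):
            classify_fine(grid(np.full((4, 4), 0.5)), 2, seed=0, ratio=2)

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 1, (8, 8))
        a = classify_fine(grid(vals), 3, seed=5, ratio=4)
        b = classify_fine(grid(vals), 3, seed=5, ratio=4)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestCoarseChange:
    def test_identity_zero(self):
        c = grid(np.full((2, 2), 0.4), ps=240.0)
        np.testing.assert_array_equal(
            coarse_change(c, c.copy()).values, np.zeros((2, 2))
        )

    def test_uniform(self):
        c1 = grid(np.full((2, 2), 0.3), ps=240.0)
        c2 = grid(np.full((2, 2), 0.4), ps=240.0)
        np.testing.assert_allclose(coarse_change(c1, c2).values, 0.1)

    def test_elementwise_mixed_signs(self):
        c1 = grid(np.array([[0.2, 0.4], [0.6, 0.8]]), ps=240.0)
        c2 = grid(np.array([[0.1, 0.5], [0.6, 0.7]]), ps=240.0)
        np.testing.assert_allclose(
            coarse_change(c1, c2).values,
            np.array([[-0.1, 0.1], [0.0, -0.1]]),
        )


class TestTemporalPrediction:
    def test_single_class_uniform_change(self):
        fine = grid(np.linspace(0.1, 0.8, 16).reshape(4, 4))
        cmap = classify_fine(fine, 1, seed=0, ratio=2)
        delta_c = grid(np.full((2, 2), 0.05), ps=60.0)
        tp = temporal_prediction(fine, delta_c, cmap, 2)
        np.testing.assert_allclose(tp.delta_class, [0.05])
        np.testing.assert_allclose(tp.tp_fine.values, fine.values + 0.05)
        np.testing.assert_allclose(tp.residual.values, 0.0, atol=1e-12)

    def test_block_diagonal_two_classes(self):
        vals = np.full((4, 4), 0.2)
        vals[:, 2:] = 0.8  # class regions coincide with coarse pixels
        fine = grid(vals)
        cmap = classify_fine(fine, 2, seed=0, ratio=2)
        left, right = cmap.labels[0, 0], cmap.labels[0, 3]
        dvals = np.zeros((2, 2))
        dvals[:, 0] = 0.03  # change of the left class
        dvals[:, 1] = -0.07
        tp = temporal_prediction(fine, grid(dvals, ps=60.0), cmap, 2)
        assert tp.delta_class[left] == pytest.approx(0.03)
        assert tp.delta_class[right] == pytest.approx(-0.07)

    def test_mixed_fraction_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.choice([0.2, 0.8], size=(4, 4))
        while np.unique(vals).size < 2:
            vals = rng.choice([0.2, 0.8], size=(4, 4))
        fine = grid(vals)
        cmap = classify_fine(fine, 2, seed=0, ratio=2)
        dvals = rng.uniform(-0.1, 0.1, (2, 2))
        tp = temporal_prediction(fine, grid(dvals, ps=60.0), cmap, 2)
        F = cmap.fractions.reshape(-1, 2)
        expected = np.linalg.solve(F.T @ F, F.T @ dvals.ravel())
        np.testing.assert_allclose(tp.delta_class, expected, atol=1e-10)

    def test_residual_invariant(self):
        rng = np.random.default_rng(2)
        fine = grid(rng.uniform(0.1, 0.9, (8, 8)))
        cmap = classify_fine(fine, 3, seed=0, ratio=4)
        c2 = grid(rng.uniform(0.1, 0.9, (2, 2)), ps=120.0)
        c1 = block_aggregate(fine, 4)
        delta_c = coarse_change(c1, c2)
        tp = temporal_prediction(fine, delta_c, cmap, 4, coarse_t2=c2)
        implied = block_aggregate(tp.tp_fine, 4)
        np.testing.assert_allclose(
            tp.residual.values, c2.values - implied.values, atol=1e-9
        )


class TestTPS:
    def test_constant_field(self):
        coarse = grid(np.full((3, 3), 0.42), ps=120.0)
        fine = grid(np.zeros((12, 12)))
        out = tps_prediction(coarse, fine)
        np.testing.assert_allclose(out.values, 0.42, atol=1e-8)

    def test_affine_field(self):
        coarse = grid(np.zeros((4, 4)), ps=120.0)
        cx = coarse.x_centers()
        cy = coarse.y_centers()
        gx, gy = np.meshgrid(cx, cy)
        coarse = coarse.with_values(1e-4 * gx + 2e-4 * gy + 0.1)
        fine = grid(np.zeros((16, 16)))
        out = tps_prediction(coarse, fine)
        fgx, fgy = np.meshgrid(fine.x_centers(), fine.y_centers())
        np.testing.assert_allclose(
            out.values, 1e-4 * fgx + 2e-4 * fgy + 0.1, atol=1e-8
        )

    def test_interpolates_control_points(self):
        # odd ratio: every coarse pixel center coincides with a fine
        # pixel center, so the surface must reproduce the control values
        rng = np.random.default_rng(5)
        coarse = grid(rng.uniform(0, 1, (3, 3)), ps=90.0)
        fine = grid(np.zeros((9, 9)))
        out = tps_prediction(coarse, fine, smoothing=0.0)
        np.testing.assert_allclose(
            out.values[1::3, 1::3], coarse.values, atol=1e-8
        )

    def test_too_few_points(self):
        coarse = grid(np.zeros((1, 2)), ps=120.0)
        fine = grid(np.zeros((4, 8)))
        with pytest.raises(InterpolationError):
            tps_prediction(coarse, fine)

    def test_collinear_points(self):
        coarse = grid(np.zeros((1, 5)), ps=120.0)
        fine = grid(np.zeros((4, 20)))
        with pytest.raises(InterpolationError):
            tps_prediction(coarse, fine)


class TestDistributeResiduals:
    def _setup(self, fine_vals, resid_vals, ratio):
        fine = grid(np.asarray(fine_vals, dtype=float))
        cmap = classify_fine(fine, 1, seed=0, ratio=ratio)
        delta_c = grid(np.zeros_like(np.asarray(resid_vals, float)),
                       ps=fine.pixel_size * ratio)
        tp = temporal_prediction(fine, delta_c, cmap, ratio)
        tp = tp._replace(residual=tp.residual.with_values(
            np.asarray(resid_vals, dtype=float)))
        return fine, cmap, tp

    def test_zero_residual_zero_allocation(self):
        fine, cmap, tp = self._setup(np.full((4, 4), 0.5), np.zeros((2, 2)), 2)
        sp = fine.with_values(fine.values + 0.1)
        out = distribute_residuals(tp, sp, fine, 2, cmap)
        np.testing.assert_allclose(out.values, 0.0)

    def test_homogeneous_block_uniform_allocation(self):
        fine, cmap, tp = self._setup(
            np.full((4, 4), 0.5), np.array([[0.08, 0.0], [0.0, 0.0]]), 2
        )
        sp = fine.copy()  # zero discrepancy everywhere
        out = distribute_residuals(tp, sp, fine, 2, cmap)
        np.testing.assert_allclose(out.values[:2, :2], 0.08)
        np.testing.assert_allclose(out.values[2:, :], 0.0)

    def test_unequal_scores_hand_oracle(self):
        # single coarse pixel, ratio 2, one class; discrepancies differ so
        # weights follow 1 - d/max(d); computed by direct arithmetic
        fine, cmap, tp = self._setup(np.full((2, 2), 0.5), np.array([[0.1]]), 2)
        sp_vals = fine.values + np.array([[0.00, 0.01], [0.02, 0.04]])
        sp = fine.with_values(sp_vals)
        out = distribute_residuals(tp, sp, fine, 2, cmap)
        d = np.array([[0.00, 0.01], [0.02, 0.04]])
        score = np.maximum(1e-6, 1.0 * (1 - d / 0.04))
        expected = score / score.sum() * 4 * 0.1
        np.testing.assert_allclose(out.values, expected)
        # block mean of the allocation equals the coarse residual
        assert out.values.mean() == pytest.approx(0.1)


class TestNeighborhoodRefine:
    def test_uniform_change_preserved(self):
        rng = np.random.default_rng(0)
        fine = grid(rng.uniform(0.1, 0.9, (6, 6)))
        prelim = fine.with_values(fine.values + 0.07)
        out = neighborhood_refine(prelim, fine, FusionParams(), ratio=2)
        np.testing.assert_allclose(out.values, fine.values + 0.07, atol=1e-12)

    def test_n_similar_1_keeps_own_change(self):
        rng = np.random.default_rng(1)
        fine = grid(rng.uniform(0.1, 0.9, (6, 6)))
        change = rng.uniform(-0.1, 0.1, (6, 6))
        prelim = fine.with_values(fine.values + change)
        out = neighborhood_refine(
            prelim, fine, FusionParams(n_similar=1), ratio=2
        )
        np.testing.assert_allclose(out.values, prelim.values, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        fine_vals = rng.uniform(0.1, 0.9, (5, 5))
        change = rng.uniform(-0.1, 0.1, (5, 5))
        fine = grid(fine_vals)
        prelim = fine.with_values(fine_vals + change)
        params = FusionParams(n_similar=3, window_radius=2)
        out = neighborhood_refine(prelim, fine, params)
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                cands = []
                for dy in range(-2, 3):
                    for dx in range(-2, 3):
                        r, c = i + dy, j + dx
                        if 0 <= r < 5 and 0 <= c < 5:
                            cands.append(
                                (
                                    abs(fine_vals[r, c] - fine_vals[i, j]),
                                    np.hypot(dy, dx),
                                    (dy + 2) * 5 + (dx + 2),
                                    change[r, c],
                                )
                            )
                cands.sort(key=lambda t: (t[0], t[1], t[2]))
                sel = cands[:3]
                w = np.array([1.0 / (1.0 + s[1]) for s in sel])
                ch = np.array([s[3] for s in sel])
                expected[i, j] = fine_vals[i, j] + np.sum(w * ch) / w.sum()
        np.testing.assert_allclose(out.values, expected, atol=1e-12)


class TestFuseProperties:
    def test_identity(self, noise_free_scene):
        scene = noise_free_scene
        f1 = scene.fine[206]
        c1 = scene.coarse[8][206]
        fused = fsdaf_fuse(FusionInputs(f1, c1, c1.copy(), 8))
        assert np.max(np.abs(fused.values - f1.values)) < 1e-6

    def test_uniform_shift_equivariance(self, noise_free_scene):
        scene = noise_free_scene
        f1 = scene.fine[206]
        c1 = scene.coarse[8][206]
        c2 = c1.with_values(c1.values + 0.1)
        fused = fsdaf_fuse(FusionInputs(f1, c1, c2, 8))
        assert np.max(np.abs(fused.values - (f1.values + 0.1))) < 1e-6

    def test_determinism(self, noise_free_scene):
        scene = noise_free_scene
        inputs = FusionInputs(
            scene.fine[206], scene.coarse[8][206], scene.coarse[8][230], 8
        )
        a = fsdaf_fuse(inputs)
        b = fsdaf_fuse(inputs)
        np.testing.assert_array_equal(a.values, b.values)

    def test_coarse_consistency(self, noise_free_scene):
        scene = noise_free_scene
        c2 = scene.coarse[8][230]
        fused = fsdaf_fuse(
            FusionInputs(scene.fine[206], scene.coarse[8][206], c2, 8)
        )
        err = np.abs(block_aggregate(fused, 8).values - c2.values)
        assert err.mean() < 0.01

    def test_output_clipped(self, noise_free_scene):
        scene = noise_free_scene
        fused = fsdaf_fuse(
            FusionInputs(
                scene.fine[206], scene.coarse[8][206], scene.coarse[8][230], 8
            )
        )
        assert fused.values.min() >= -1.0 and fused.values.max() <= 1.0
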