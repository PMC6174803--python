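import itertools
import warnings

import numpy as np
import pytest

from ropseg.coarse import (ClusteringError, FusionError, FusionWeights,
                           fcm_cluster, fcm_liver_mask, fuse, fusion_weights)
from ropseg.io import BBox2D, tight_bbox
from ropseg.phantom import PhantomParams, generate_phantom
from ropseg.preprocess import preprocess_slice


def exhaustive_1d_2means(x):
    """Optimal 2-partition of 1D data by enumerating contiguous splits
    (the optimal k-means partition of sorted 1D data is contiguous)."""
    xs = np.sort(x)
    best = (np.inf, None)
    for cut in range(1, xs.size):
        a, b = xs[:cut], xs[cut:]
        sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if sse < best[0]:
            best = (sse, (a.mean(), b.mean()))
    return best[1]


class TestFCM:
    def test_membership_rows_sum_to_one(self, rng):
        x = rng.uniform(0, 255, 200)
        res = fcm_cluster(x, c=4, seed=0)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_default_cluster_count_is_four(self, rng):
        res = fcm_cluster(rng.uniform(0, 255, 100), seed=0)
        assert res.centers.size == 4

    def test_objective_non_increasing(self, rng):
        x = rng.uniform(0, 255, 500)
        res = fcm_cluster(x, c=4, seed=1)
        assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_two_separated_groups_recovered_exactly(self, rng):
        x = np.concatenate([rng.normal(100, 1.0, 10), rng.normal(200, 1.0, 10)])
        res = fcm_cluster(x, c=2, seed=0)
        c_lo, c_hi = np.sort(res.centers)
        o_lo, o_hi = exhaustive_1d_2means(x)
        assert abs(c_lo - o_lo) < 1.0 and abs(c_hi - o_hi) < 1.0
        hard = np.argmax(res.memberships, axis=1)
        assert len(set(hard[:10])) == 1 and len(set(hard[10:])) == 1
        assert hard[0] != hard[-1]

    def test_coincident_pixel_gets_hard_membership(self):
        x = np.array([0.0, 0.0, 10.0, 20.0, 30.0, 40.0])
        res = fcm_cluster(x, c=4, seed=0)
        on_centre = np.isclose(np.abs(x[:, None] - res.centers).min(axis=1), 0)
        if on_centre.any():
            np.testing.assert_allclose(
                res.memberships[on_centre].max(axis=1), 1.0)

    def test_too_few_distinct_values(self):
        with pytest.raises(ClusteringError):
            fcm_cluster(np.array([1.0, 1.0, 2.0]), c=4)


class TestFCMMask:
    def test_phantom_liver_recall(self):
        vol, liver, _ = generate_phantom(PhantomParams.fast_2d(seed=0,
                                                               n_tumors=0))
        prep = preprocess_slice(vol.slice(0))
        box = tight_bbox(liver.voxels[0]).expand(5, prep.shape)
        mask = fcm_liver_mask(prep, box, seed=0)
        recall = (mask.voxels & liver.voxels[0]).sum() / liver.voxels[0].sum()
        assert recall >= 0.95  # oversegmentation tolerated, undercoverage not

    def test_out_of_window_image_gives_empty_mask(self):
        img = np.zeros((64, 64))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = fcm_liver_mask(img, BBox2D(0, 0, 64, 64), seed=0)
        assert mask.count() == 0


class TestFusionWeights:
    def test_printed_formula_single_slice(self):
        w = fusion_weights([0.8], [0.6])
        assert w.w_F == pytest.approx(4 / 7, abs=1e-12)
        assert w.w_E == pytest.approx(3 / 7, abs=1e-12)

    def test_equal_accuracies_give_half_half(self, rng):
        a = rng.uniform(0.5, 1.0, 20)
        w = fusion_weights(a, a.copy())
        assert w.w_F == pytest.approx(0.5) and w.w_E == pytest.approx(0.5)

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            aF = rng.uniform(0.01, 1.0, 15)
            aE = rng.uniform(0.01, 1.0, 15)
            w = fusion_weights(aF, aE)
            assert w.w_F + w.w_E == pytest.approx(1.0, abs=1e-12)

    def test_top_k_selection(self):
        # with K=1 only the best slice (max accuracy 0.9) contributes
        w = fusion_weights([0.9, 0.1], [0.3, 0.8], top_k=1)
        assert w.w_F == pytest.approx(0.9 / 1.2)

    def test_zero_accuracy_pair_rejected(self):
        with pytest.raises(FusionError):
            fusion_weights([0.0, 0.5], [0.0, 0.5])


class TestFuse:
    def test_identical_masks_are_fixed_point(self, rng):
        m = (rng.random((40, 40)) < 0.4).astype(float)
        for wf in (0.1, 0.5, 0.9):
            out = fuse(m, m, FusionWeights(wf, 1 - wf))
            from scipy.ndimage import median_filter
            expected = (median_filter(m, 5, mode="nearest") >= 0.5)
            np.testing.assert_array_equal(out.voxels, expected.astype(np.uint8))

    def test_disagreement_resolved_by_weights(self):
        F = np.ones((16, 16))
        E = np.zeros((16, 16))
        out = fuse(F, E, FusionWeights(0.571, 0.429))
        assert np.all(out.voxels == 1)  # 0.571 >= 0.5 -> foreground
        out2 = fuse(F, E, FusionWeights(0.429, 0.571))
        assert np.all(out2.voxels == 0)

    def test_monotone_in_each_input(self, rng):
        F = rng.random((32, 32))
        E = rng.random((32, 32))
        w = FusionWeights(0.6, 0.4)
        base = fuse(F, E, w).voxels
        raised = fuse(np.clip(F + 0.2, 0, 1), E, w).voxels
        assert np.all(raised >= base)

    def test_degenerate_weights_reproduce_single_stage(self, rng):
        from scipy.ndimage import median_filter
        F = (rng.random((32, 32)) < 0.5).astype(float)
        E = (rng.random((32, 32)) < 0.5).astype(float)
        outF = fuse(F, E, FusionWeights(1.0, 0.0)).voxels
        outE = fuse(F, E, FusionWeights(0.0, 1.0)).voxels
        np.testing.assert_array_equal(
            outF, (median_filter(F, 5, mode="nearest") >= 0.5).astype(np.uint8))
        np.testing.assert_array_equal(
            outE, (median_filter(E, 5, mode="nearest") >= 0.5).astype(np.uint8))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FusionError):
            fuse(np.zeros((4, 4)), np.zeros((5, 5)), FusionWeights(0.5, 0.5))
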