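import numpy as np
import pytest

from ropseg.metrics import (MetricError, asd, dice, evaluate_all, msd, rmsd,
                            rvd, surface_voxels, voe)


def brute_force_surface(mask):
    """Independent surface-voxel oracle: explicit face-neighbour scan."""
    arr = np.asarray(mask).astype(bool)
    out = []
    for idx in np.argwhere(arr):
        on_surface = False
        for d in range(arr.ndim):
            for step in (-1, 1):
                nb = idx.copy()
                nb[d] += step
                if not (0 <= nb[d] < arr.shape[d]) or not arr[tuple(nb)]:
                    on_surface = True
        if on_surface:
            out.append(tuple(idx))
    return set(out)


def brute_force_distances(A, B, spacing):
    """All-pairs nearest-surface distances, O(|S(A)|.|S(B)|)."""
    sp = np.asarray(spacing, float)
    sa = np.array(sorted(brute_force_surface(A)), float) * sp
    sb = np.array(sorted(brute_force_surface(B)), float) * sp
    d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1)
    d_ab = np.sqrt(d2.min(axis=1))
    d_ba = np.sqrt(d2.min(axis=0))
    return d_ab, d_ba


def random_blob(shape, seed, thresh=0.5):
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter
    f = gaussian_filter(rng.standard_normal(shape), 2.0)
    m = f > np.quantile(f, 1 - 0.2)
    return m.astype(np.uint8)


class TestSurface:
    def test_cube_surface_count(self):
        cube = np.zeros((5, 5, 5), dtype=np.uint8)
        cube[1:4, 1:4, 1:4] = 1
        assert len(surface_voxels(cube)) == 26  # all but the centre voxel

    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        m[1, 1, 1] = 1
        np.testing.assert_array_equal(surface_voxels(m), [[1, 1, 1]])

    def test_thin_sheet_all_surface(self):
        m = np.zeros((4, 6, 6), dtype=np.uint8)
        m[2] = 1
        assert len(surface_voxels(m)) == 36

    def test_matches_brute_force_scan(self):
        m = random_blob((10, 10, 10), seed=3)
        got = set(map(tuple, surface_voxels(m)))
        assert got == brute_force_surface(m)


class TestOverlapMetrics:
    def test_identity(self):
        m = random_blob((8, 8, 8), seed=0)
        assert voe(m, m) == 0.0
        assert rvd(m, m) == 0.0
        assert dice(m, m) == 100.0

    def test_counting_example(self):
        A = np.zeros((1, 1, 4), np.uint8)
        B = np.zeros((1, 1, 4), np.uint8)
        A[0, 0, :2] = 1          # {0,1}
        B[0, 0, 1:3] = 1         # {1,2}; intersection 1, union 3
        assert voe(A, B) == pytest.approx(100 * (1 - 1 / 3))
        assert dice(A, B) == pytest.approx(50.0)

    def test_rvd_sign_and_asymmetry(self):
        A = np.zeros((1, 2, 4), np.uint8)
        B = np.zeros((1, 2, 4), np.uint8)
        A[0, 0, :4] = 1                       # |A| = 4
        B[0, 0, :4] = 1
        B[0, 1, 0] = 1                        # |B| = 5
        assert rvd(A, B) == pytest.approx(25.0)
        assert rvd(B, A) == pytest.approx(-20.0)
        assert rvd(A, B) != -rvd(B, A)

    def test_disjoint_masks(self):
        A = np.zeros((1, 4, 4), np.uint8)
        B = np.zeros((1, 4, 4), np.uint8)
        A[0, 0, 0] = 1
        B[0, 3, 3] = 1
        assert voe(A, B) == 100.0
        assert dice(A, B) == 0.0

    def test_empty_inputs_raise(self):
        z = np.zeros((2, 2, 2), np.uint8)
        with pytest.raises(MetricError):
            voe(z, z)
        with pytest.raises(MetricError):
            rvd(z, z)

    def test_dice_monotone_under_true_positive_growth(self):
        A = random_blob((8, 8, 8), seed=1)
        B = np.zeros_like(A)
        prev = 0.0
        fg = np.argwhere(A)
        for stop in (len(fg) // 3, 2 * len(fg) // 3, len(fg)):
            B[:] = 0
            B[tuple(fg[:stop].T)] = 1
            d = dice(A, B)
            assert d >= prev
            prev = d


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        m = random_blob((8, 8, 8), seed=2)
        sp = (1.0, 1.0, 1.0)
        assert asd(m, m, sp) == 0.0 and rmsd(m, m, sp) == 0.0 \
            and msd(m, m, sp) == 0.0

    def test_two_voxels_three_mm_apart(self):
        A = np.zeros((1, 1, 5), np.uint8)
        B = np.zeros((1, 1, 5), np.uint8)
        A[0, 0, 0] = 1
        B[0, 0, 1] = 1
        sp = (1.0, 1.0, 3.0)
        assert asd(A, B, sp) == pytest.approx(3.0)
        assert rmsd(A, B, sp) == pytest.approx(3.0)
        assert msd(A, B, sp) == pytest.approx(3.0)

    def test_anisotropic_spacing_respected(self):
        A = np.zeros((3, 3, 3), np.uint8)
        B = np.zeros((3, 3, 3), np.uint8)
        A[0, 0, 0] = 1
        B[1, 0, 0] = 1                        # one step along z
        assert msd(A, B, (2.5, 1.0, 1.0)) == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        A = random_blob((12, 12, 12), seed=seed)
        B = random_blob((12, 12, 12), seed=seed + 100)
        sp = (1.6, 0.78, 0.78)
        d_ab, d_ba = brute_force_distances(A, B, sp)
        n = d_ab.size + d_ba.size
        assert asd(A, B, sp) == pytest.approx(
            (d_ab.sum() + d_ba.sum()) / n, abs=1e-9)
        assert rmsd(A, B, sp) == pytest.approx(
            np.sqrt((d_ab ** 2).sum() + (d_ba ** 2).sum()) / np.sqrt(n), abs=1e-9)
        assert msd(A, B, sp) == pytest.approx(
            max(d_ab.max(), d_ba.max()), abs=1e-9)

    def test_symmetry(self):
        A = random_blob((10, 10, 10), seed=7)
        B = random_blob((10, 10, 10), seed=8)
        sp = (1.0, 1.0, 1.0)
        assert asd(A, B, sp) == pytest.approx(asd(B, A, sp))
        assert msd(A, B, sp) == pytest.approx(msd(B, A, sp))
        assert voe(A, B) == pytest.approx(voe(B, A))
        assert dice(A, B) == pytest.approx(dice(B, A))


class TestReport:
    def test_identical_masks_full_report(self):
        m = random_blob((8, 8, 8), seed=9)
        r = evaluate_all(m, m, (1.6, 0.78, 0.78))
        assert (r.voe, r.rvd, r.asd, r.rmsd, r.msd, r.dice) == \
            (0.0, 0.0, 0.0, 0.0, 0.0, 100.0)

    def test_report_consistent_with_individual_ops(self):
        A = random_blob((10, 10, 10), seed=10)
        B = random_blob((10, 10, 10), seed=11)
        sp = (1.0, 1.0, 1.0)
        r = evaluate_all(A, B, sp)
        assert r.voe == pytest.approx(voe(A, B))
        assert r.rvd == pytest.approx(rvd(A, B))
        assert r.asd == pytest.approx(asd(A, B, sp))
        assert r.dice == pytest.approx(dice(A, B))
        assert r.n_voxels_A == int(A.sum())
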