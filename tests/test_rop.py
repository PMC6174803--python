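import numpy as np
import pytest

import ropseg.rop as rop
from ropseg.io import BBox2D, GeometryError, Mask, Volume, tight_bbox
from ropseg.metrics import dice
from ropseg.phantom import PhantomParams, generate_cohort
from ropseg.preprocess import preprocess_slice
from ropseg.rop import (AffineTransform2D, PositioningError,
                        convex_hull_volume, interpolate_z, position_liver,
                        propagate_bbox, register_slice, select_template)


def solid_box_mask(a, b, c, pad=2):
    m = np.zeros((a + 2 * pad, b + 2 * pad, c + 2 * pad), np.uint8)
    m[pad:pad + a, pad:pad + b, pad:pad + c] = 1
    return m


class TestConvexHull:
    def test_solid_box_closed_form(self):
        # hull of voxel centres of an a.b.c box spans (a-1)(b-1)(c-1)
        m = solid_box_mask(4, 5, 6)
        vol = convex_hull_volume(m, (1.0, 1.0, 1.0))
        assert vol == pytest.approx(3 * 4 * 5 / 1000.0)

    def test_spacing_scales_volume(self):
        m = solid_box_mask(4, 4, 4)
        v1 = convex_hull_volume(m, (1.0, 1.0, 1.0))
        v2 = convex_hull_volume(m, (2.0, 1.0, 1.0))
        assert v2 == pytest.approx(2 * v1)

    def test_collinear_points_degenerate(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[1:4, 2, 2] = 1
        with pytest.raises(GeometryError):
            convex_hull_volume(m, (1, 1, 1))

    def test_hull_bounds_voxel_volume_on_random_blobs(self):
        from scipy.ndimage import gaussian_filter
        from ropseg.rop import voxel_count_volume
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = gaussian_filter(rng.standard_normal((14, 14, 14)), 2.0)
            m = (f > np.quantile(f, 0.8)).astype(np.uint8)
            if m.sum() < 8:
                continue
            sp = (1.0, 1.0, 1.0)
            hull = convex_hull_volume(m, sp)
            # hull of centres loses a half-voxel rind: allow that correction
            n = m.sum()
            rind = 1.0 - (n ** (1 / 3) - 1) ** 3 / n   # ~ surface fraction
            assert hull >= voxel_count_volume(m, sp) * (1 - rind) - 1e-9


class TestTemplateSelection:
    @staticmethod
    def _cohort_with_box_livers(sizes):
        cohort = []
        for i, s in enumerate(sizes):
            m = solid_box_mask(s, s, s, pad=2)
            vol = Volume(np.full(m.shape, 100.0), spacing=(1, 1, 1),
                         id=f"s{i}")
            cohort.append((vol, Mask(m, spacing=(1, 1, 1))))
        return cohort

    def test_mean_attained_exactly(self):
        cohort = self._cohort_with_box_livers([3, 5, 7])
        # hull volumes (s-1)^3: 8, 64, 216 -> mean 96 -> closest is 64 (s=5)
        assert select_template(cohort).subject_id == "s1"

    def test_argmin_of_distance_to_mean(self):
        cohort = self._cohort_with_box_livers([3, 5, 6])
        # hulls 8, 64, 125 -> mean 65.67 -> closest 64
        assert select_template(cohort).subject_id == "s1"

    def test_tie_broken_by_lowest_index(self):
        cohort = self._cohort_with_box_livers([3, 3, 5])
        # hulls 8, 8, 64: s0 and s1 are equidistant from the mean -> s0 wins
        assert select_template(cohort).subject_id == "s0"

    def test_empty_cohort_rejected(self):
        with pytest.raises(PositioningError):
            select_template([])

    def test_template_bboxes_are_tight(self):
        cohort = generate_cohort(3, PhantomParams(shape=(16, 64, 64),
                                                  spacing=(2.5, 1.6, 1.6),
                                                  seed=4, n_tumors=0,
                                                  liver_axes_mm=(16, 44, 36)))
        pack = select_template([(v, l) for v, l, _ in cohort])
        for k, box in pack.bboxes.items():
            assert box == tight_bbox(pack.standard_label.voxels[k])


class TestZInterpolation:
    def test_identity_when_dz_matches(self, rng):
        vol = Volume(rng.random((6, 8, 8)), spacing=(2.0, 1.0, 1.0))
        lab = Mask((rng.random((6, 8, 8)) < 0.5).astype(np.uint8),
                   spacing=vol.spacing)
        v2, l2 = interpolate_z(vol, lab, 2.0)
        np.testing.assert_allclose(v2.voxels, vol.voxels)
        np.testing.assert_array_equal(l2.voxels, lab.voxels)

    def test_midpoint_is_elementwise_mean(self, rng):
        vox = rng.random((2, 4, 4))
        vol = Volume(vox, spacing=(2.0, 1.0, 1.0))
        lab = Mask(np.ones((2, 4, 4), np.uint8), spacing=vol.spacing)
        v2, l2 = interpolate_z(vol, lab, 1.0)
        assert v2.n_slices == 3
        np.testing.assert_allclose(v2.voxels[1], vox.mean(axis=0))
        assert np.all(l2.voxels == 1)  # all-ones label survives re-binarization

    def test_single_slice_rejected(self, rng):
        vol = Volume(rng.random((1, 4, 4)))
        lab = Mask(np.ones((1, 4, 4), np.uint8))
        with pytest.raises(PositioningError):
            interpolate_z(vol, lab, 1.0)


@pytest.fixture(scope="module")
def slice_pair():
    cohort = generate_cohort(2, PhantomParams.fast_2d(seed=2))
    return [(preprocess_slice(v.slice(0)), l.voxels[0])
            for v, l, _ in cohort]


class TestRegistration:
    def test_self_registration_is_identity(self, slice_pair):
        img = slice_pair[0][0]
        T = register_slice(img, img)
        centre = np.array([64.0, 64.0])
        assert np.linalg.norm(T.apply(centre) - centre) <= 0.5
        np.testing.assert_allclose(T.linear, np.eye(2), atol=1e-2)

    def test_known_translation_recovered(self, slice_pair):
        img = slice_pair[0][0]
        shifted = np.roll(img, (6, -4), axis=(0, 1))
        T = register_slice(shifted, img)
        recovered = T.apply([[64.0, 64.0]])[0] - [64.0, 64.0]
        assert np.linalg.norm(recovered - [6.0, -4.0]) <= 0.5

    def test_cross_subject_label_transfer(self, slice_pair):
        (img_a, lab_a), (img_b, lab_b) = slice_pair
        T = register_slice(img_a, img_b)   # b floats onto a
        moved = np.rint(T.apply(np.argwhere(lab_b))).astype(int)
        m = np.zeros_like(lab_a)
        ok = ((moved >= 0) & (moved < np.array(lab_a.shape))).all(axis=1)
        m[moved[ok, 0], moved[ok, 1]] = 1
        from scipy.ndimage import binary_closing
        m = binary_closing(m, np.ones((3, 3))).astype(np.uint8)
        assert dice(lab_a, m) >= 70.0

    def test_constant_reference_rejected(self):
        with pytest.raises(PositioningError):
            register_slice(np.zeros((32, 32)), np.ones((32, 32)))


class TestPropagation:
    def test_identity_reproduces_tight_box(self):
        lab = np.zeros((32, 32), np.uint8)
        lab[5:12, 8:20] = 1
        box = propagate_bbox(AffineTransform2D.identity(), lab, (32, 32))
        assert box == tight_bbox(lab)

    def test_pure_translation_shifts_box(self):
        lab = np.zeros((40, 40), np.uint8)
        lab[5:12, 8:20] = 1
        T = AffineTransform2D(np.array([[1.0, 0, 5.0], [0, 1.0, 7.0]]))
        box = propagate_bbox(T, lab, (40, 40))
        t = tight_bbox(lab)
        assert box == BBox2D(t.row_min + 5, t.col_min + 7,
                             t.row_max + 5, t.col_max + 7)

    def test_rotation_swaps_bar_dimensions(self):
        lab = np.zeros((40, 40), np.uint8)
        lab[10:12, 20:26] = 1   # 2 rows x 6 cols, off-centre
        # 90 degrees about the image centre (19.5, 19.5)
        c = 19.5
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        t = np.array([c, c]) - R @ np.array([c, c])
        box = propagate_bbox(AffineTransform2D(np.column_stack([R, t])),
                             lab, (40, 40))
        # oracle: transform every labelled pixel, box the result
        pts = np.argwhere(lab) @ R.T + t
        assert box.row_min == int(np.floor(pts[:, 0].min()))
        assert box.col_min == int(np.floor(pts[:, 1].min()))
        assert box.row_max == int(np.ceil(pts[:, 0].max())) + 1
        assert box.col_max == int(np.ceil(pts[:, 1].max())) + 1
        assert (box.height, box.width) == (6, 2)  # bar dimensions swapped

    def test_margin_monotone(self):
        lab = np.zeros((32, 32), np.uint8)
        lab[10:20, 10:20] = 1
        box = propagate_bbox(AffineTransform2D.identity(), lab, (32, 32))
        assert box.expand(4, (32, 32)).contains(box.expand(2, (32, 32)))

    def test_all_points_outside_frame_rejected(self):
        lab = np.zeros((16, 16), np.uint8)
        lab[2:4, 2:4] = 1
        T = AffineTransform2D(np.array([[1.0, 0, 500.0], [0, 1.0, 500.0]]))
        with pytest.raises(PositioningError):
            propagate_bbox(T, lab, (16, 16))


class TestApiShape:
    def test_no_inverse_registration_call_path(self):
        """Box propagation pushes the template forward; the public API never
        inverts a registration."""
        public = [n for n in dir(rop) if not n.startswith("_")]
        assert not any("inverse" in n.lower() for n in public)
        assert not hasattr(AffineTransform2D, "inverse")


class TestPositioning:
    def test_self_positioning_covers_template_liver(self):
        cohort = generate_cohort(2, PhantomParams(shape=(12, 96, 96),
                                                  spacing=(2.5, 1.6, 1.6),
                                                  seed=3, n_tumors=0,
                                                  liver_axes_mm=(13, 60, 50)))
        pack = select_template([(v, l) for v, l, _ in cohort])
        vol, lab = pack.standard_volume, pack.standard_label
        boxes = position_liver(vol, pack, margin=5)
        for k, box in boxes.items():
            if box is None or not lab.voxels[k].any():
                continue
            assert box.contains(tight_bbox(lab.voxels[k]))

    def test_empty_volume_yields_no_boxes(self):
        cohort = generate_cohort(2, PhantomParams(shape=(8, 64, 64),
                                                  spacing=(2.5, 1.6, 1.6),
                                                  seed=3, n_tumors=0,
                                                  liver_axes_mm=(9, 40, 34)))
        pack = select_template([(v, l) for v, l, _ in cohort])
        blank = Volume(np.full((8, 64, 64), 20.0), spacing=(2.5, 1.6, 1.6))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boxes = position_liver(blank, pack)
        assert all(b is None for b in boxes.values())
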