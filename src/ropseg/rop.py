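"""Registration-based organ positioning (ROP).

A *standard* subject — the cohort member whose convex-hull liver volume is
closest to the cohort mean — serves as a template.  For every slice of an
unseen volume, the corresponding template slice is registered *onto* the
slice (the template is the float image, the unseen slice the reference), and
the template's liver-label support is pushed through the recovered affine
transform; the min/max of the transformed label coordinates, rounded
outward, give the liver bounding box for that slice.  Because the template
is always the float image, one registration per slice suffices and no
inverse transform is ever computed.

Registration is two-stage: a coarse stage driven by cross-correlation
(FFT phase correlation for translation, then a normalized-cross-correlation
Powell polish with a large step), and a fine stage minimizing mean squared
intensity difference with a 10× smaller step and 4× the iteration budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import ConvexHull, QhullError

from .io import BBox2D, GeometryError, Mask, Volume, tight_bbox
from .preprocess import LiverWindow, preprocess_slice


class PositioningError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transforms

@dataclass
class AffineTransform2D:
    """p_ref = A·p_float + t on (row, col) points; matrix is the 2×3 [A | t]."""

    matrix: np.ndarray
    converged: bool = True

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) <= 1e-8:
            raise GeometryError("affine linear part is singular")

    @classmethod
    def identity(cls):
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @property
    def linear(self):
        return self.matrix[:, :2]

    @property
    def translation(self):
        return self.matrix[:, 2]

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        return pts @ self.linear.T + self.translation


def _params_to_transform(p, centre):
    """[ty, tx, theta, sr, sc, shear] → forward affine about `centre`."""
    ty, tx, theta, sr, sc, shear = p
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    A = rot @ np.array([[sr, shear], [0.0, sc]])
    t = centre + np.array([ty, tx]) - A @ centre
    return AffineTransform2D(np.column_stack([A, t]))


def _warp_float(float_img, transform: AffineTransform2D, shape):
    """Render the float image in the reference frame (p_ref = A p_float + t)."""
    inv = np.linalg.inv(transform.linear)
    offset = -inv @ transform.translation
    return ndimage.affine_transform(float_img, inv, offset=offset,
                                    output_shape=shape, order=1,
                                    mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# template selection

def convex_hull_volume(mask, spacing) -> float:
    """Convex-hull volume (cm³) of foreground voxel centres, spacing-scaled.

    Singleton axes are dropped, so a single-slice mask yields the hull *area*
    in cm² — the same selection rule then applies in 2D fast mode.  Fewer
    than 4 points, or a degenerate (collinear/coplanar) cloud, is an error.
    """
    arr = np.asarray(getattr(mask, "voxels", mask)).astype(bool)
    pts = np.argwhere(arr).astype(np.float64)
    if pts.shape[0] == 0:
        raise GeometryError("empty mask has no convex hull")
    sp = np.asarray(spacing, dtype=np.float64)
    if sp.size == arr.ndim:
        pts = pts * sp
    keep = [d for d in range(pts.shape[1])
            if np.ptp(pts[:, d]) > 0]
    pts = pts[:, keep]
    if pts.shape[1] < 2 or pts.shape[0] < pts.shape[1] + 1:
        raise GeometryError("degenerate point cloud: convex hull undefined")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate point cloud: {exc}") from exc
    return float(hull.volume) / 10.0 ** pts.shape[1]


def voxel_count_volume(mask, spacing) -> float:
    arr = np.asarray(getattr(mask, "voxels", mask)).astype(bool)
    sp = np.asarray(spacing, dtype=np.float64)
    dims = [d for d in range(arr.ndim) if arr.shape[d] > 1]
    factor = np.prod(sp[dims]) if sp.size == arr.ndim else np.prod(sp)
    return float(arr.sum()) * factor / 10.0 ** len(dims)


@dataclass
class TemplatePack:
    """The standard subject used as registration float image."""

    standard_volume: Volume
    standard_label: Mask
    bboxes: dict                    # slice index -> BBox2D (tight label box)
    subject_id: str = ""
    hull_volume_cm3: float = 0.0

    def __post_init__(self):
        if not self.standard_label.voxels.any():
            raise PositioningError("template label is empty")


def _slice_boxes(label: Mask) -> dict:
    boxes = {}
    for k in range(label.voxels.shape[0]):
        if label.voxels[k].any():
            boxes[k] = tight_bbox(label.voxels[k])
    return boxes


def select_template(cohort) -> TemplatePack:
    """Pick the subject whose convex-hull liver volume is nearest the cohort
    mean (ties → lowest index) and package it with per-slice tight boxes."""
    if len(cohort) == 0:
        raise PositioningError("empty cohort")
    vols = []
    for vol, label, *_ in cohort:
        vols.append(convex_hull_volume(label, vol.spacing))
    vols = np.asarray(vols)
    mean = vols.mean()
    idx = int(np.argmin(np.abs(vols - mean)))   # argmin takes the lowest index on ties
    vol, label = cohort[idx][0], cohort[idx][1]
    return TemplatePack(standard_volume=vol, standard_label=label,
                        bboxes=_slice_boxes(label), subject_id=vol.id,
                        hull_volume_cm3=float(vols[idx]))


def interpolate_z(volume: Volume, label: Mask, target_dz: float):
    """Resample volume and label along z to `target_dz` mm slice thickness.

    Intensities are linearly interpolated; the label is interpolated then
    re-binarized at 0.5.  Output slice count is round(extent_z/target_dz)+1.
    """
    if target_dz <= 0:
        raise PositioningError("target_dz must be positive")
    nz = volume.n_slices
    if nz < 2:
        raise PositioningError("cannot interpolate a single-slice volume")
    dz = volume.spacing[0]
    extent = (nz - 1) * dz
    n_out = int(round(extent / target_dz)) + 1
    src = np.arange(nz) * dz
    dst = np.linspace(0.0, extent, n_out)
    idx = np.interp(dst, src, np.arange(nz))
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, nz - 1)
    w = (idx - lo)[:, None, None]
    vox = (1 - w) * volume.voxels[lo] + w * volume.voxels[hi]
    lab = (1 - w) * label.voxels[lo].astype(float) + w * label.voxels[hi]
    spacing = (float(target_dz),) + volume.spacing[1:]
    return (Volume(vox, spacing=spacing, id=volume.id),
            Mask((lab >= 0.5).astype(np.uint8), label_name=label.label_name,
                 spacing=spacing))


# ---------------------------------------------------------------------------
# registration

def _downsample(img, factor):
    if factor <= 1:
        return img
    return ndimage.zoom(ndimage.gaussian_filter(img, factor / 2.0,
                                                mode="nearest"),
                        1.0 / factor, order=1)


def _ncc(a, b):
    av, bv = a - a.mean(), b - b.mean()
    denom = np.sqrt((av * av).sum() * (bv * bv).sum())
    return float((av * bv).sum() / denom) if denom > 0 else 0.0


def register_slice(reference, float_img, coarse_then_fine: bool = True,
                   downsample: int = 2, max_iter_coarse: int = 25,
                   max_iter_fine: int = 100) -> AffineTransform2D:
    """Two-stage affine registration of the float image onto the reference.

    Coarse: FFT cross-correlation translation estimate plus a Powell polish
    of translation/scale driven by normalized cross-correlation at a large
    step.  Fine: Powell over the full 6-parameter affine minimizing mean
    squared difference, with a 10× smaller step and 4× the iterations.
    A run that exhausts the fine-stage budget returns the best transform
    found, flagged ``converged=False`` with a warning.
    """
    ref = np.asarray(reference, dtype=np.float64)
    flt = np.asarray(float_img, dtype=np.float64)
    if ref.shape != flt.shape:
        raise PositioningError("reference and float images must share a shape")
    if np.ptp(ref) == 0:
        raise PositioningError("constant reference image cannot be registered")

    ds = max(int(downsample), 1)
    ref_s, flt_s = _downsample(ref, ds), _downsample(flt, ds)
    centre = (np.asarray(ref_s.shape, dtype=float) - 1) / 2.0

    # coarse translation by cross-correlation (FFT)
    from skimage.registration import phase_cross_correlation
    shift, _, _ = phase_cross_correlation(ref_s, flt_s, upsample_factor=4,
                                          normalization=None)
    p = np.array([shift[0], shift[1], 0.0, 1.0, 1.0, 0.0])

    def objective(params, metric):
        T = _params_to_transform(params, centre)
        warped = _warp_float(flt_s, T, ref_s.shape)
        if metric == "ncc":
            return 1.0 - _ncc(ref_s, warped)
        return float(np.mean((ref_s - warped) ** 2))

    coarse_step = np.array([2.0, 2.0, 0.05, 0.05, 0.05, 0.02])
    if coarse_then_fine:
        res = optimize.minimize(
            objective, p, args=("ncc",), method="Powell",
            options={"maxiter": max_iter_coarse, "xtol": 0.1, "ftol": 1e-3,
                     "direc": np.diag(coarse_step)})
        p = res.x
    fine = optimize.minimize(
        objective, p, args=("ms",), method="Powell",
        options={"maxiter": max_iter_fine, "xtol": 0.01, "ftol": 1e-6,
                 "direc": np.diag(coarse_step / 10.0)})
    converged = bool(fine.success)
    if not converged:
        warnings.warn("fine registration hit its iteration budget; "
                      "returning best transform found")
    # lift from the downsampled grid (q = p/ds): linear part unchanged,
    # translation scales by ds
    T_small = _params_to_transform(fine.x, centre)
    out = AffineTransform2D(np.column_stack([T_small.linear,
                                             ds * T_small.translation]))
    out.converged = converged
    return out


def propagate_bbox(transform: AffineTransform2D, standard_label_slice,
                   reference_shape) -> BBox2D:
    """Push the template label support through the transform and box it.

    All label-1 pixel coordinates are transformed; the box is the min/max of
    the transformed coordinates rounded outward (floor on mins, ceil on
    maxes), clipped to the reference frame, converted to half-open.
    """
    lab = np.asarray(getattr(standard_label_slice, "voxels",
                             standard_label_slice)).astype(bool)
    pts = np.argwhere(lab)
    if pts.shape[0] == 0:
        raise PositioningError("empty label slice cannot be propagated")
    moved = transform.apply(pts)
    r0, c0 = np.floor(moved.min(axis=0))
    r1, c1 = np.ceil(moved.max(axis=0)) + 1
    r0, c0 = max(int(r0), 0), max(int(c0), 0)
    r1 = min(int(r1), int(reference_shape[0]))
    c1 = min(int(c1), int(reference_shape[1]))
    if r1 <= r0 or c1 <= c0:
        raise PositioningError("transformed label lies outside the reference frame")
    return BBox2D(r0, c0, r1, c1)


# ---------------------------------------------------------------------------
# whole-volume positioning

def _z_correspondence(k, n_ref, dz_ref, n_tpl, dz_tpl):
    """Proportional physical-z matching of a reference slice to a template slice."""
    if n_ref == 1 or n_tpl == 1:
        return 0
    frac = (k * dz_ref) / ((n_ref - 1) * dz_ref)
    return int(round(frac * (n_tpl - 1)))


def position_liver(volume: Volume, template: TemplatePack, margin: int = 5,
                   window: LiverWindow = None, preprocess: bool = True,
                   downsample: int = 2) -> dict:
    """Per-slice liver bounding boxes for an unseen volume.

    Each slice is matched to a template slice by proportional z position; the
    (preprocessed) template slice is registered onto the (preprocessed)
    subject slice and the template's label support propagated.  Slices whose
    template counterpart holds no liver get no box; per-slice failures are
    flagged (box ``None``) and the loop continues.
    Returns {slice index: BBox2D or None}.
    """
    window = window or LiverWindow()
    tpl_vol, tpl_lab = template.standard_volume, template.standard_label
    prep = (lambda im: preprocess_slice(im, window=window)) if preprocess \
        else (lambda im: np.asarray(im, dtype=np.float64))
    tpl_cache = {}
    boxes = {}
    for k in range(volume.n_slices):
        j = _z_correspondence(k, volume.n_slices, volume.spacing[0],
                              tpl_vol.n_slices, tpl_vol.spacing[0])
        if j not in template.bboxes:
            continue
        if j not in tpl_cache:
            tpl_cache[j] = prep(tpl_vol.slice(j))
        ref_img = prep(volume.slice(k))
        try:
            if np.ptp(ref_img) == 0:
                raise PositioningError("empty reference slice")
            T = register_slice(ref_img, tpl_cache[j], downsample=downsample)
            box = propagate_bbox(T, tpl_lab.voxels[j], ref_img.shape)
            boxes[k] = box.expand(margin, shape=ref_img.shape)
        except PositioningError as exc:
            warnings.warn(f"slice {k}: positioning failed ({exc})")
            boxes[k] = None
    return boxes
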