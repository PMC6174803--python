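"""Coarse liver segmentation: fuzzy c-means stage, ELM stage, weighted fusion.

The FCM stage clusters the preprocessed gray values inside the liver
bounding box into c=4 fuzzy clusters (Bezdek alternating updates, fuzzifier
m=2), hard-assigns pixels, keeps the largest connected component of the
cluster whose centre is nearest the mapped liver-window midpoint, and
cleans it morphologically.  The ELM stage classifies every box pixel from
its 126-d feature vector.  The two stages fail in opposite directions —
intensity clustering oversegments (neighbouring organs share the liver
window), pixel classification undersegments — so their outputs are fused
with weights proportional to each stage's training accuracy,
median-filtered and thresholded at 0.5 (ties to foreground).  ``fuse``
accepts any score maps in [0, 1]; the pipeline feeds it the binarized
stage decisions, under which the accuracy-weighted threshold acts as a
weighted vote that keeps the better stage's foreground.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BBox2D, Mask, crop
from .elm import ELMModel, elm_predict
from .features import extract_features, feature_spec


class ClusteringError(ValueError):
    pass


class FusionError(ValueError):
    pass


@dataclass
class FCMResult:
    memberships: np.ndarray    # n_pixels × c, rows sum to 1
    centers: np.ndarray        # c gray values
    n_iter: int
    converged: bool
    objective_trace: np.ndarray


def fcm_cluster(pixels, c: int = 4, m: float = 2.0, tol: float = 1e-5,
                max_iter: int = 300, seed: int = 0) -> FCMResult:
    """Fuzzy c-means on 1D gray values (Bezdek alternating updates).

    Memberships follow u_ik = 1 / Σ_j (|x_k − v_i| / |x_k − v_j|)^{2/(m−1)};
    centres are the membership^m-weighted means.  Iterates until the largest
    centre shift drops below `tol`.  A pixel coinciding with a centre gets
    hard membership 1 there.  The objective J_m is recorded per iteration
    and is non-increasing.
    """
    x = np.asarray(pixels, dtype=np.float64).ravel()
    if np.unique(x).size < c:
        raise ClusteringError(f"need at least {c} distinct values, "
                              f"got {np.unique(x).size}")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(), x.max()
    centers = np.sort(lo + (hi - lo) * rng.random(c))
    exponent = 2.0 / (m - 1.0)
    trace = []
    converged = False
    U = None
    for it in range(1, max_iter + 1):
        dist = np.abs(x[:, None] - centers[None, :])        # n × c
        U = _memberships(dist, exponent)
        trace.append(float(np.sum((U ** m) * dist ** 2)))
        um = U ** m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            converged = True
            break
    dist = np.abs(x[:, None] - centers[None, :])
    U = _memberships(dist, exponent)
    return FCMResult(memberships=U, centers=centers, n_iter=it,
                     converged=converged, objective_trace=np.asarray(trace))


def _memberships(dist, exponent):
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = dist ** -exponent
    coincident = ~np.isfinite(inv)
    U = inv / inv.sum(axis=1, keepdims=True)
    rows = coincident.any(axis=1)
    if rows.any():
        U[rows] = 0.0
        # hard-assign to the first coincident centre of each such pixel
        first = np.argmax(coincident[rows], axis=1)
        U[np.nonzero(rows)[0], first] = 1.0
    return U


def _postprocess_component(binary, closing_radius=3):
    """Largest 8-connected component, closed (disk r=3), holes filled."""
    structure = np.ones((3, 3), dtype=bool)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return np.zeros_like(binary, dtype=np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size > 1:
        # tie: keep the component whose (row, col) minimum is lexicographically lowest
        mins = [tuple(np.argwhere(labels == b).min(axis=0)) for b in best]
        best = [best[int(np.argmin([m[0] * binary.shape[1] + m[1] for m in mins]))]]
    comp = labels == best[0]
    r = closing_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy ** 2 + xx ** 2) <= r ** 2
    comp = ndimage.binary_closing(comp, structure=disk)
    comp = ndimage.binary_fill_holes(comp)
    return comp.astype(np.uint8)


def fcm_liver_mask(image, bbox: BBox2D, c: int = 4, dark_threshold: float = 40.0,
                   seed: int = 0, return_score: bool = False):
    """FCM stage: cluster box pixels, keep the liver-like tissue's main blob.

    After windowing the liver band is stretched over most of the gray range,
    so the liver typically spans more than one of the c=4 clusters while the
    zeroed background forms a distinct dark cluster.  The candidate tissue is
    therefore the union of clusters whose centre exceeds `dark_threshold`
    (preprocessed gray units); its largest 8-connected component, closed and
    hole-filled, is the stage mask — deliberately permissive, since a
    same-window neighbouring organ may survive (the fusion and contour
    stages deal with that oversegmentation).
    Returns a Mask in image frame; with `return_score` also the summed
    membership map of the selected clusters (zero outside the box).
    """
    img = np.asarray(image, dtype=np.float64)
    patch = crop(img, bbox)
    score = np.zeros_like(img)
    mask = np.zeros(img.shape, dtype=np.uint8)
    try:
        res = fcm_cluster(patch.ravel(), c=c, seed=seed)
    except ClusteringError:
        out = Mask(mask, label_name="fcm")
        return (out, score) if return_score else out
    tissue = np.flatnonzero(res.centers > dark_threshold)
    if tissue.size == 0:
        warnings.warn("no cluster centre above the dark threshold; empty mask")
        out = Mask(mask, label_name="fcm")
        return (out, score) if return_score else out
    member = res.memberships[:, tissue].sum(axis=1).reshape(patch.shape)
    hard = np.isin(np.argmax(res.memberships, axis=1),
                   tissue).reshape(patch.shape)
    comp = _postprocess_component(hard)
    # soft score restricted to the retained component
    score[bbox.row_min:bbox.row_max, bbox.col_min:bbox.col_max] = member * comp
    mask[bbox.row_min:bbox.row_max, bbox.col_min:bbox.col_max] = comp
    out = Mask(mask, label_name="fcm")
    return (out, score) if return_score else out


def elm_liver_mask(image, bbox: BBox2D, model: ELMModel,
                   return_score: bool = False):
    """ELM stage: per-pixel classification inside the box, median-smoothed.

    The model's feature-spec hash must match the current feature bank.
    """
    if model.spec_hash and model.spec_hash != feature_spec().hash():
        raise FusionError("model feature spec does not match this feature bank")
    img = np.asarray(image, dtype=np.float64)
    patch = crop(img, bbox)
    fm = extract_features(patch, BBox2D(0, 0, patch.shape[0], patch.shape[1]))
    scores = elm_predict(model, fm.values)[:, 0].reshape(patch.shape)
    smoothed = ndimage.median_filter(scores, size=5, mode="nearest")
    binary = (smoothed >= 0.5).astype(np.uint8)
    mask = np.zeros(img.shape, dtype=np.uint8)
    score = np.zeros_like(img)
    mask[bbox.row_min:bbox.row_max, bbox.col_min:bbox.col_max] = binary
    score[bbox.row_min:bbox.row_max, bbox.col_min:bbox.col_max] = \
        np.clip(smoothed, 0.0, 1.0)
    out = Mask(mask, label_name="elm")
    return (out, score) if return_score else out


@dataclass(frozen=True)
class FusionWeights:
    w_F: float
    w_E: float

    def __post_init__(self):
        if not (0.0 <= self.w_F <= 1.0 and 0.0 <= self.w_E <= 1.0):
            raise FusionError(f"weights outside [0,1]: {self}")
        if abs(self.w_F + self.w_E - 1.0) > 1e-12:
            raise FusionError(f"weights must sum to 1: {self}")


def fusion_weights(acc_F, acc_E, top_k: int = 100) -> FusionWeights:
    """Accuracy-ratio fusion weights from per-training-slice stage accuracies.

    Per slice i the weights are A_F^i/(A_F^i+A_E^i) and A_E^i/(A_F^i+A_E^i);
    the final pair is the mean over the top-K slices ranked by
    max(A_F^i, A_E^i), K = min(top_k, n).
    """
    aF = np.asarray(acc_F, dtype=np.float64)
    aE = np.asarray(acc_E, dtype=np.float64)
    if aF.size == 0 or aF.shape != aE.shape:
        raise FusionError("accuracy lists must be equal-length and non-empty")
    if np.any((aF < 0) | (aF > 1)) or np.any((aE < 0) | (aE > 1)):
        raise FusionError("accuracies must lie in [0, 1]")
    tot = aF + aE
    if np.any(tot == 0):
        raise FusionError("a slice has zero accuracy in both stages")
    k = min(top_k, aF.size)
    order = np.argsort(-np.maximum(aF, aE), kind="stable")[:k]
    wF = float(np.mean(aF[order] / tot[order]))
    wE = float(np.mean(aE[order] / tot[order]))
    return FusionWeights(w_F=wF, w_E=wE)


def fuse(score_F, score_E, weights: FusionWeights) -> Mask:
    """Weighted soft fusion, 5×5 median, threshold 0.5 (ties → foreground)."""
    F = np.asarray(getattr(score_F, "voxels", score_F), dtype=np.float64)
    E = np.asarray(getattr(score_E, "voxels", score_E), dtype=np.float64)
    if F.shape != E.shape:
        raise FusionError(f"shape mismatch {F.shape} vs {E.shape}")
    if F.min() < 0 or F.max() > 1 or E.min() < 0 or E.max() > 1:
        raise FusionError("fusion inputs must lie in [0, 1]")
    fused = weights.w_F * F + weights.w_E * E
    smoothed = ndimage.median_filter(fused, size=5, mode="nearest")
    return Mask((smoothed >= 0.5).astype(np.uint8), label_name="coarse")
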