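"""Volumetric and surface evaluation criteria for segmentation quality.

Given a ground-truth object A and a prediction B the report carries six
numbers: volumetric overlap error (VOE, the complement of the Jaccard
coefficient, in %), signed relative volume difference (RVD, %, asymmetric),
the average / root-mean-square / maximum symmetric surface distances
(ASD, RMSD, MSD, in mm, computed between surface-voxel centres with the
anisotropic voxel spacing applied), and the Dice score (%).

A *surface voxel* is a foreground voxel with at least one background or
out-of-grid face neighbour (6-connectivity in 3D, 4-connectivity in 2D).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


class MetricError(ValueError):
    """Undefined metric (e.g. both masks empty)."""


def _as_binary(mask) -> np.ndarray:
    arr = getattr(mask, "voxels", mask)
    return np.asarray(arr).astype(bool)


def surface_voxels(mask) -> np.ndarray:
    """Coordinates (n, ndim) of foreground voxels with a background face-neighbour.

    Out-of-grid counts as background, so voxels on the grid boundary are
    surface voxels. Empty mask returns an empty (0, ndim) array.
    """
    arr = _as_binary(mask)
    if not arr.any():
        return np.empty((0, arr.ndim), dtype=np.int64)
    footprint = ndimage.generate_binary_structure(arr.ndim, 1)  # faces only
    interior = ndimage.binary_erosion(arr, structure=footprint, border_value=0)
    return np.argwhere(arr & ~interior)


def voe(A, B) -> float:
    """Volumetric overlap error, 100·(1 − |A∩B| / |A∪B|)."""
    a, b = _as_binary(A), _as_binary(B)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise MetricError("VOE undefined for two empty masks")
    inter = np.logical_and(a, b).sum()
    return 100.0 * (1.0 - inter / union)


def rvd(A, B) -> float:
    """Signed relative volume difference, 100·(|B| − |A|)/|A|. Asymmetric."""
    a, b = _as_binary(A), _as_binary(B)
    na = a.sum()
    if na == 0:
        raise MetricError("RVD undefined for empty reference mask")
    return 100.0 * (int(b.sum()) - int(na)) / int(na)


def dice(A, B) -> float:
    """Dice score, 100·2|A∩B| / (|A| + |B|)."""
    a, b = _as_binary(A), _as_binary(B)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise MetricError("Dice undefined for two empty masks")
    return 100.0 * 2.0 * np.logical_and(a, b).sum() / total


def _surface_distances(A, B, spacing):
    """Directed nearest-surface distances (d(sA→S(B)), d(sB→S(A))) in mm."""
    a, b = _as_binary(A), _as_binary(B)
    if not a.any() or not b.any():
        raise MetricError("surface distances undefined for an empty mask")
    if a.shape != b.shape:
        raise MetricError(f"shape mismatch {a.shape} vs {b.shape}")
    sp = np.asarray(spacing, dtype=float)
    if sp.size != a.ndim:
        raise MetricError(f"spacing has {sp.size} components for {a.ndim}D masks")
    sa = surface_voxels(a) * sp
    sb = surface_voxels(b) * sp
    d_ab = cKDTree(sb).query(sa, k=1)[0]
    d_ba = cKDTree(sa).query(sb, k=1)[0]
    return d_ab, d_ba


def asd(A, B, spacing) -> float:
    """Average symmetric surface distance in mm."""
    d_ab, d_ba = _surface_distances(A, B, spacing)
    return float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))


def rmsd(A, B, spacing) -> float:
    """Root-mean-square symmetric surface distance in mm."""
    d_ab, d_ba = _surface_distances(A, B, spacing)
    return float(np.sqrt((np.square(d_ab).sum() + np.square(d_ba).sum())
                         / (d_ab.size + d_ba.size)))


def msd(A, B, spacing) -> float:
    """Maximum symmetric surface distance (Hausdorff between surfaces) in mm."""
    d_ab, d_ba = _surface_distances(A, B, spacing)
    return float(max(d_ab.max(), d_ba.max()))


@dataclass
class MetricsReport:
    voe: float
    rvd: float
    asd: float
    rmsd: float
    msd: float
    dice: float
    n_voxels_A: int
    n_voxels_B: int
    spacing: tuple

    def to_dict(self):
        d = asdict(self)
        d["spacing"] = list(self.spacing)
        return d

    def __str__(self):
        return (f"VOE {self.voe:6.2f}%  RVD {self.rvd:+7.2f}%  "
                f"ASD {self.asd:6.3f}mm  RMSD {self.rmsd:6.3f}mm  "
                f"MSD {self.msd:6.3f}mm  DSC {self.dice:6.2f}%")


def evaluate_all(A, B, spacing) -> MetricsReport:
    """All six criteria for a (truth, prediction) mask pair."""
    a, b = _as_binary(A), _as_binary(B)
    d_ab, d_ba = _surface_distances(a, b, spacing)
    n = d_ab.size + d_ba.size
    return MetricsReport(
        voe=voe(a, b),
        rvd=rvd(a, b),
        asd=float((d_ab.sum() + d_ba.sum()) / n),
        rmsd=float(np.sqrt((np.square(d_ab).sum() + np.square(d_ba).sum()) / n)),
        msd=float(max(d_ab.max(), d_ba.max())),
        dice=dice(a, b),
        n_voxels_A=int(a.sum()),
        n_voxels_B=int(b.sum()),
        spacing=tuple(float(s) for s in np.atleast_1d(spacing)),
    )
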