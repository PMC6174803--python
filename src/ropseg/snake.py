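"""Active-contour (snake) refinement of the coarse liver boundary.

A closed polyline initialized on the coarse-mask boundary is evolved to
minimize the energy

    E = Σ_i  alpha·|p_{i+1} − p_i|²  +  beta·|p_{i−1} − 2p_i + p_{i+1}|²
           −  w_edge · G(p_i),

where G is the gradient magnitude of the Gaussian-smoothed image (σ=2),
normalized to [0, 1].  Internal terms keep the contour short and smooth;
the external term attracts it to strong edges.  Evolution is the classic
semi-implicit Kass scheme — the internal (quadratic) part is solved
implicitly through a cyclic banded system, the external force is evaluated
explicitly — wrapped in a backtracking line search: a step is accepted only
if it lowers E, otherwise the step size is halved, so the recorded energy
trace is non-increasing by construction.  There is no balloon force: the
coarse contour stays authoritative, which suits a refinement stage whose
initialization is already near the target boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.draw import polygon as draw_polygon

from .io import Mask


class ContourError(ValueError):
    pass


@dataclass
class SnakeParams:
    alpha: float = 0.1        # continuity (contraction) weight
    beta: float = 0.5         # smoothness (curvature) weight
    gamma: float = 0.5        # move step, pixels
    w_edge: float = 1.0       # external (edge attraction) weight
    max_iter: int = 500
    tol: float = 0.1          # mean point displacement per sweep, px
    sigma: float = 2.0        # Gaussian smoothing for the edge map

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.w_edge) < 0:
            raise ValueError("snake weights must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Contour:
    """Closed polyline of subpixel (row, col) points."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2 \
                or self.points.shape[0] < 8:
            raise ContourError("contour needs >= 8 (row, col) points")

    @property
    def n_points(self):
        return self.points.shape[0]

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def mask_to_contour(mask, n_points: int = 200) -> Contour:
    """Trace the boundary of the (largest) foreground component and resample
    it to `n_points` equally spaced by arc length."""
    arr = np.asarray(getattr(mask, "voxels", mask)).astype(bool)
    if not arr.any():
        raise ContourError("empty mask has no contour")
    labels, n = ndimage.label(arr, structure=np.ones((3, 3)))
    if n > 1:
        warnings.warn("mask has multiple components; tracing the largest")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        arr = labels == (int(np.argmax(sizes)) + 1)
    contours = skmeasure.find_contours(arr.astype(float), 0.5)
    boundary = max(contours, key=lambda c: c.shape[0])
    return Contour(_resample_closed(boundary, n_points))


def _resample_closed(points, n_points):
    pts = np.asarray(points, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n_points, endpoint=False)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(target, s, closed[:, 0])
    out[:, 1] = np.interp(target, s, closed[:, 1])
    return out


def contour_to_mask(contour: Contour, shape) -> Mask:
    rr, cc = draw_polygon(contour.points[:, 0], contour.points[:, 1], shape)
    arr = np.zeros(shape, dtype=np.uint8)
    arr[rr, cc] = 1
    return Mask(arr, label_name="fine")


def edge_map(image, sigma: float = 2.0) -> np.ndarray:
    """Gradient magnitude of the σ-smoothed image, scaled to [0, 1]."""
    img = np.asarray(image, dtype=np.float64)
    gr = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    gc = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    g = np.hypot(gr, gc)
    top = g.max()
    return g / top if top > 0 else g


def _snake_energy(points, G, params):
    nxt = np.roll(points, -1, axis=0)
    prv = np.roll(points, 1, axis=0)
    cont = np.sum((nxt - points) ** 2, axis=1)
    curv = np.sum((prv - 2 * points + nxt) ** 2, axis=1)
    ext = ndimage.map_coordinates(G, points.T, order=1, mode="nearest")
    return float(np.sum(params.alpha * cont + params.beta * curv
                        - params.w_edge * ext))


def _internal_operator(n, alpha, beta):
    """Gradient operator of the internal energy: 2·(alpha·A + beta·B) with A
    the cyclic graph Laplacian and B = (Δ²)ᵀ(Δ²)."""
    idx = np.arange(n)
    A = np.zeros((n, n))
    A[idx, idx] = 2.0
    A[idx, (idx + 1) % n] = -1.0
    A[idx, (idx - 1) % n] = -1.0
    D2 = np.zeros((n, n))
    D2[idx, idx] = -2.0
    D2[idx, (idx + 1) % n] = 1.0
    D2[idx, (idx - 1) % n] = 1.0
    return 2.0 * (alpha * A + beta * (D2.T @ D2))


def evolve_snake(image, contour: Contour, params: SnakeParams = None):
    """Semi-implicit snake evolution; returns (Contour, energy trace).

    Per iteration the internal terms are solved implicitly,
    ``(I + s·γ·K) p⁺ = p + s·γ·w_edge·∇G(p)``, and the step is accepted only
    if the total energy decreases; otherwise the scale ``s`` is halved (up
    to 10 times) before giving up.  Stops when the mean displacement
    accumulated over a 10-iteration window drops below `tol` (a slow steady
    drift must not read as convergence), when no decreasing step exists, or
    after `max_iter`.
    """
    params = params or SnakeParams()
    G = edge_map(image, params.sigma)
    Gr, Gc = np.gradient(G)
    pts = contour.points.copy()
    n = pts.shape[0]
    shape = np.asarray(image).shape
    K = _internal_operator(n, params.alpha, params.beta)
    eye = np.eye(n)

    def force(p):
        coords = p.T
        return np.column_stack([
            ndimage.map_coordinates(Gr, coords, order=1, mode="nearest"),
            ndimage.map_coordinates(Gc, coords, order=1, mode="nearest")])

    trace = [_snake_energy(pts, G, params)]
    window = [pts.copy()]
    for _ in range(params.max_iter):
        f = params.w_edge * force(pts)
        scale = 1.0
        accepted = None
        for _attempt in range(10):
            step = scale * params.gamma
            cand = np.linalg.solve(eye + step * K, pts + step * f)
            np.clip(cand[:, 0], 0, shape[0] - 1, out=cand[:, 0])
            np.clip(cand[:, 1], 0, shape[1] - 1, out=cand[:, 1])
            e = _snake_energy(cand, G, params)
            if e <= trace[-1] + 1e-12:
                accepted = (cand, e)
                break
            scale *= 0.5
        if accepted is None:
            break  # local minimum at this resolution
        pts, e = accepted
        trace.append(e)
        window.append(pts.copy())
        if len(window) > 10:
            window.pop(0)
            drift = np.linalg.norm(pts - window[0], axis=1).mean()
            if drift < params.tol:
                break
    if np.unique(np.round(pts, 3), axis=0).shape[0] < 8:
        raise ContourError("contour collapsed to fewer than 8 distinct points")
    return Contour(pts), np.asarray(trace)


def refine(image, coarse, params: SnakeParams = None, n_points: int = 200):
    """Coarse mask → contour → snake → refined mask.

    Fail-safe: any refinement failure returns the coarse mask flagged as
    fallback (the snake is sensitive to its initialization, so a broken
    refinement must never lose the coarse result).
    Returns (Mask, info dict with 'fallback' and 'energy_trace').
    """
    arr = np.asarray(getattr(coarse, "voxels", coarse)).astype(np.uint8)
    info = {"fallback": False, "energy_trace": None}
    if not arr.any():
        info["fallback"] = True
        return Mask(arr, label_name="fine"), info
    try:
        contour = mask_to_contour(arr, n_points=n_points)
        evolved, trace = evolve_snake(image, contour, params)
        refined = contour_to_mask(evolved, arr.shape)
        if not refined.voxels.any():
            raise ContourError("refined mask is empty")
        info["energy_trace"] = trace
        return refined, info
    except (ContourError, ValueError) as exc:
        warnings.warn(f"snake refinement failed ({exc}); keeping coarse mask")
        info["fallback"] = True
        return Mask(arr, label_name="fine"), info
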