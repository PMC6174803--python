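"""Per-pixel texture/edge feature bank feeding the ELM classifiers.

Seventeen classical feature families — gray intensity, Gaussian derivative
filters, local statistics, morphology, phase congruency, Canny/Harris
responses, local binary patterns, Gabor and Hessian responses, co-occurrence
statistics, Laws' texture energies and sum-and-difference histogram
statistics — are stacked into a fixed 126-dimensional descriptor per pixel.
The family list is fixed; the per-family dimensionalities and filter scales
are this package's frozen convention, declared in :func:`feature_spec` and
fingerprinted (``spec_hash``) so a trained model refuses mismatched
configurations.

Everything here is deterministic and translation-covariant away from image
borders; there is no randomness anywhere in the bank.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage.filters import rank as skrank
from skimage.morphology import disk, footprint_rectangle

from .io import BBox2D

TOTAL_DIMS = 126

GAUSS_SIGMAS = (1.0, 2.0, 4.0)
STD_WINDOWS = (3, 5, 9)
BOTTOMHAT_RADII = (3, 5)
GABOR_FREQS = (0.1, 0.2, 0.4)          # cycles / pixel
GABOR_THETAS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
HESSIAN_SIGMAS = (1.0, 2.0)
MEANVAR_WINDOWS = (3, 5, 9)
ENTROPY_WINDOWS = (5, 9)
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
GLCM_LEVELS = 16
GLCM_WINDOW = 9
LBP_WINDOW = 9
LAWS_WINDOW = 9
SDH_DIRECTIONS = ((0, 1), (1, 0), (1, 1))
SDH_OFFSETS = (1, 2)
TEXTURE_RANGE = 255.0                   # gray range the quantizers assume


class FeatureComputationError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered block table of the feature bank; total dimensionality 126."""

    blocks: tuple

    @property
    def total_dims(self):
        return sum(b[1] for b in self.blocks)

    @property
    def names(self):
        return tuple(b[0] for b in self.blocks)

    def to_json(self) -> str:
        return json.dumps([{"name": n, "n_dims": d, "params": p}
                           for n, d, p in self.blocks], indent=1)

    @classmethod
    def from_json(cls, text) -> "FeatureSpec":
        return cls(blocks=tuple((b["name"], b["n_dims"], b["params"])
                                for b in json.loads(text)))

    def hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:16]


def feature_spec() -> FeatureSpec:
    """The fixed, versioned block table (names, dims, parameters)."""
    blocks = (
        ("gray_intensity", 1, {}),
        ("gaussian_derivative_1st", 6,
         {"sigmas": list(GAUSS_SIGMAS), "orientations": ["row", "col"]}),
        ("gaussian_derivative_2nd", 6,
         {"sigmas": list(GAUSS_SIGMAS), "orientations": ["row", "col"]}),
        ("local_std", 3, {"windows": list(STD_WINDOWS)}),
        ("bottom_hat", 2, {"radii": list(BOTTOMHAT_RADII)}),
        ("phase_congruency", 1, {"orientations": 4, "frequencies": [0.1, 0.2]}),
        ("canny_edge", 1, {"sigma": 2.0}),
        ("harris_response", 1, {"sigma": 1.0}),
        ("lbp_histogram", 10, {"P": 8, "R": 1, "window": LBP_WINDOW,
                               "method": "uniform"}),
        ("gabor_magnitude", 12, {"frequencies": list(GABOR_FREQS),
                                 "orientations": len(GABOR_THETAS)}),
        ("hessian_eigenvalues", 4, {"sigmas": list(HESSIAN_SIGMAS)}),
        ("neighborhood_mean_variance", 6, {"windows": list(MEANVAR_WINDOWS)}),
        ("local_entropy", 2, {"windows": list(ENTROPY_WINDOWS)}),
        ("cooccurrence", 16, {"stats": ["contrast", "correlation", "energy",
                                        "homogeneity"],
                              "offsets": [list(o) for o in GLCM_OFFSETS],
                              "levels": GLCM_LEVELS, "window": GLCM_WINDOW}),
        ("laws_texture_energy", 25, {"kernels": "L5 E5 S5 W5 R5 outer products",
                                     "window": LAWS_WINDOW}),
        ("sum_difference_histogram", 30,
         {"stats": ["sum_mean", "sum_var", "diff_abs_mean", "diff_var",
                    "diff_homogeneity"],
          "directions": [list(d) for d in SDH_DIRECTIONS],
          "offsets": list(SDH_OFFSETS)}),
    )
    spec = FeatureSpec(blocks=blocks)
    assert spec.total_dims == TOTAL_DIMS
    return spec


@dataclass
class FeatureMatrix:
    """n_pixels × 126 feature rows plus the (row, col) index of each pixel."""

    values: np.ndarray
    pixel_index: np.ndarray       # (n, 2) int
    spec: FeatureSpec


# ---------------------------------------------------------------------------
# block computations (each returns a list of 2D response maps)

def _windowed_mean(img, size):
    return ndimage.uniform_filter(img, size=size, mode="nearest")


def _windowed_var(img, size):
    m = _windowed_mean(img, size)
    return np.maximum(_windowed_mean(img * img, size) - m * m, 0.0)


def _gaussian_derivs_1st(img):
    out = []
    for s in GAUSS_SIGMAS:
        out.append(ndimage.gaussian_filter(img, s, order=(1, 0), mode="nearest"))
        out.append(ndimage.gaussian_filter(img, s, order=(0, 1), mode="nearest"))
    return out


def _gaussian_derivs_2nd(img):
    out = []
    for s in GAUSS_SIGMAS:
        out.append(ndimage.gaussian_filter(img, s, order=(2, 0), mode="nearest"))
        out.append(ndimage.gaussian_filter(img, s, order=(0, 2), mode="nearest"))
    return out


def _bottom_hat(img):
    # closing minus image: responds to dark details on brighter surroundings
    return [ndimage.grey_closing(img, footprint=disk(r), mode="nearest") - img
            for r in BOTTOMHAT_RADII]


def _phase_congruency(img):
    """Simplified multi-orientation phase congruency from quadrature Gabor pairs."""
    eps = 1e-6
    energy_total = np.zeros_like(img)
    amp_total = np.zeros_like(img)
    hp = img - ndimage.gaussian_filter(img, 5.0, mode="nearest")  # drop DC
    for theta in GABOR_THETAS:
        sum_even = np.zeros_like(img)
        sum_odd = np.zeros_like(img)
        for f in (0.1, 0.2):
            even, odd = skfilters.gabor(hp, frequency=f, theta=theta)
            sum_even += even
            sum_odd += odd
            amp_total += np.hypot(even, odd)
        energy_total += np.hypot(sum_even, sum_odd)
    return [energy_total / (amp_total + eps)]


def _lbp_u8(img):
    return np.clip(img, 0, TEXTURE_RANGE).astype(np.uint8)


def lbp_codes(image) -> np.ndarray:
    """Raw 8-neighbour LBP codes (0–255), threshold: neighbour >= centre."""
    return skfeature.local_binary_pattern(
        _lbp_u8(np.asarray(image, dtype=np.float64)), P=8, R=1, method="default")


def _lbp_histogram(img):
    codes = skfeature.local_binary_pattern(_lbp_u8(img), P=8, R=1,
                                           method="uniform")
    return [_windowed_mean((codes == b).astype(np.float64), LBP_WINDOW)
            for b in range(10)]


def _gabor_bank(img):
    out = []
    for f in GABOR_FREQS:
        for theta in GABOR_THETAS:
            real, imag = skfilters.gabor(img, frequency=f, theta=theta)
            out.append(np.hypot(real, imag))
    return out


def _hessian_eigs(img):
    out = []
    for s in HESSIAN_SIGMAS:
        H = skfeature.hessian_matrix(img, sigma=s, order="rc",
                                     use_gaussian_derivatives=True)
        out.extend(skfeature.hessian_matrix_eigvals(H))
    return out


def _entropy(img):
    u8 = np.clip(img, 0, TEXTURE_RANGE) * (255.0 / TEXTURE_RANGE)
    u8 = u8.astype(np.uint8)
    return [skrank.entropy(u8, footprint_rectangle((w, w))).astype(np.float64)
            for w in ENTROPY_WINDOWS]


def _shift(img, dr, dc):
    """Shift with edge replication: out[p] = img[p + (dr, dc)] clamped."""
    r = np.clip(np.arange(img.shape[0]) + dr, 0, img.shape[0] - 1)
    c = np.clip(np.arange(img.shape[1]) + dc, 0, img.shape[1] - 1)
    return img[np.ix_(r, c)]


def _quantize(img, levels):
    q = np.floor(np.clip(img, 0, TEXTURE_RANGE) / (TEXTURE_RANGE + 1e-9) * levels)
    return q.astype(np.int64)


def _cooccurrence(img):
    """Windowed gray-level co-occurrence contrast/correlation/energy/homogeneity."""
    eps = 1e-9
    q = _quantize(img, GLCM_LEVELS).astype(np.float64)
    out = []
    for dr, dc in GLCM_OFFSETS:
        i, j = q, _shift(q, dr, dc)
        d = i - j
        mi, mj = _windowed_mean(i, GLCM_WINDOW), _windowed_mean(j, GLCM_WINDOW)
        vi = np.maximum(_windowed_mean(i * i, GLCM_WINDOW) - mi * mi, 0.0)
        vj = np.maximum(_windowed_mean(j * j, GLCM_WINDOW) - mj * mj, 0.0)
        contrast = _windowed_mean(d * d, GLCM_WINDOW)
        correlation = ((_windowed_mean(i * j, GLCM_WINDOW) - mi * mj)
                       / (np.sqrt(vi * vj) + eps))
        homogeneity = _windowed_mean(1.0 / (1.0 + d * d), GLCM_WINDOW)
        # energy = sum over co-occurring pairs of squared joint frequency
        codes = (i * GLCM_LEVELS + j).astype(np.int64)
        energy = np.zeros_like(img, dtype=np.float64)
        for code in np.unique(codes):
            p = _windowed_mean((codes == code).astype(np.float64), GLCM_WINDOW)
            energy += p * p
        out.extend([contrast, correlation, energy, homogeneity])
    return out


_LAWS_1D = {
    "L5": np.array([1.0, 4, 6, 4, 1]),
    "E5": np.array([-1.0, -2, 0, 2, 1]),
    "S5": np.array([-1.0, 0, 2, 0, -1]),
    "W5": np.array([-1.0, 2, 0, -2, 1]),
    "R5": np.array([1.0, -4, 6, -4, 1]),
}


def _laws(img):
    out = []
    names = ("L5", "E5", "S5", "W5", "R5")
    for a in names:
        for b in names:
            kernel = np.outer(_LAWS_1D[a], _LAWS_1D[b])
            resp = ndimage.convolve(img, kernel, mode="nearest")
            out.append(_windowed_mean(np.abs(resp), LAWS_WINDOW))
    return out


def _sum_difference(img):
    out = []
    for dr, dc in SDH_DIRECTIONS:
        for k in SDH_OFFSETS:
            j = _shift(img, dr * k, dc * k)
            s, d = img + j, img - j
            out.append(_windowed_mean(s, GLCM_WINDOW))
            out.append(_windowed_var(s, GLCM_WINDOW))
            out.append(_windowed_mean(np.abs(d), GLCM_WINDOW))
            out.append(_windowed_var(d, GLCM_WINDOW))
            out.append(_windowed_mean(1.0 / (1.0 + d * d), GLCM_WINDOW))
    return out


_PAD = 8  # edge-replication margin: keeps library filters free of zero-pad artifacts


def feature_stack(image) -> np.ndarray:
    """Full (H, W, 126) response stack of the feature bank, block order fixed."""
    raw = np.asarray(image, dtype=np.float64)
    if raw.ndim != 2:
        raise FeatureComputationError("feature bank expects a 2D image")
    img = np.pad(raw, _PAD, mode="edge")
    spec = feature_spec()
    maps = []
    producers = {
        "gray_intensity": lambda: [img],
        "gaussian_derivative_1st": lambda: _gaussian_derivs_1st(img),
        "gaussian_derivative_2nd": lambda: _gaussian_derivs_2nd(img),
        "local_std": lambda: [np.sqrt(_windowed_var(img, w)) for w in STD_WINDOWS],
        "bottom_hat": lambda: _bottom_hat(img),
        "phase_congruency": lambda: _phase_congruency(img),
        "canny_edge": lambda: [skfeature.canny(
            img / TEXTURE_RANGE, sigma=2.0).astype(np.float64)],
        "harris_response": lambda: [skfeature.corner_harris(img, sigma=1.0)],
        "lbp_histogram": lambda: _lbp_histogram(img),
        "gabor_magnitude": lambda: _gabor_bank(img),
        "hessian_eigenvalues": lambda: _hessian_eigs(img),
        "neighborhood_mean_variance": lambda: [
            f for w in MEANVAR_WINDOWS
            for f in (_windowed_mean(img, w), _windowed_var(img, w))],
        "local_entropy": lambda: _entropy(img),
        "cooccurrence": lambda: _cooccurrence(img),
        "laws_texture_energy": lambda: _laws(img),
        "sum_difference_histogram": lambda: _sum_difference(img),
    }
    for name, n_dims, _ in spec.blocks:
        block = producers[name]()
        if len(block) != n_dims:
            raise FeatureComputationError(
                f"block {name} produced {len(block)} maps, expected {n_dims}")
        for m in block:
            if not np.all(np.isfinite(m)):
                raise FeatureComputationError(f"non-finite values in block {name}")
        maps.extend(m[_PAD:-_PAD, _PAD:-_PAD] for m in block)
    return np.stack(maps, axis=-1)


def extract_features(image, pixel_selection) -> FeatureMatrix:
    """One 126-d row per selected pixel.

    `pixel_selection` is a binary 2D mask (array or Mask) or a BBox2D.
    """
    img = np.asarray(image, dtype=np.float64)
    if isinstance(pixel_selection, BBox2D):
        sel = np.zeros(img.shape, dtype=bool)
        sel[pixel_selection.row_min:pixel_selection.row_max,
            pixel_selection.col_min:pixel_selection.col_max] = True
    else:
        sel = np.asarray(getattr(pixel_selection, "voxels", pixel_selection),
                         dtype=bool)
        if sel.shape != img.shape:
            raise FeatureComputationError(
                f"selection shape {sel.shape} does not match image {img.shape}")
    if not sel.any():
        raise FeatureComputationError("empty pixel selection")
    stack = feature_stack(img)
    idx = np.argwhere(sel)
    return FeatureMatrix(values=stack[sel], pixel_index=idx, spec=feature_spec())
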