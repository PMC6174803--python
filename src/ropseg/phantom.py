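"""Synthetic abdominal CT phantoms for exercising the segmentation pipeline.

Each phantom is a simplified axial abdomen: an elliptic body cross-section on
an air background, a liver modelled as a smoothly deformed ellipsoid whose
gray values sit inside the 130–150 liver window, optional darker tumor blobs
strictly inside the liver, and a spleen-like confounder organ whose intensity
overlaps the liver window (so that intensity-only clustering oversegments,
as it does on real CT).  A cohort applies an independent in-plane affine
(scale, rotation, translation) per subject on top of a shared base anatomy,
emulating inter-patient size and pose differences; the shared anatomy means
a cohort generated with a zero-range affine is voxel-identical across
subjects.

Default 3D geometry (64×128×128 voxels at (2.5, 1.6, 1.6) mm) is scaled so
the mean cohort liver volume is near 1720 cm³.  A single-slice 128×128
"fast 2D" mode serves unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import Volume, Mask

_AIR, _BODY, _LIVER, _TUMOR, _SPLEEN = 0, 1, 2, 3, 4


class PhantomParameterError(ValueError):
    pass


@dataclass
class PhantomParams:
    """Geometry, intensity and randomness settings for phantom generation.

    Intensities are scanner gray units; the liver mean must sit inside the
    [130, 150] liver window and the tumor mean below its low edge so the
    window-based preprocessing behaves as it does on patient data.
    """

    shape: tuple = (64, 128, 128)
    spacing: tuple = (2.5, 1.6, 1.6)
    liver_mean: float = 140.0
    liver_sd: float = 4.0
    tumor_mean: float = 112.0
    tumor_sd: float = 4.0
    n_tumors: int = 1
    tumor_radius_mm: float = 14.0
    organ_contrast: float = 5.0     # spleen mean = 140 + organ_contrast
    body_intensity: float = 95.0
    air_intensity: float = 20.0
    noise_sd: float = 2.0
    deform_amp: float = 0.10        # relative perturbation of the implicit surface
    # per-subject affine ranges: uniform in ±range
    scale_range: float = 0.06
    rotation_range_deg: float = 8.0
    translation_range_mm: float = 4.0
    # liver / spleen ellipsoid semi-axes in mm (z, row, col)
    liver_axes_mm: tuple = (62.0, 90.0, 72.0)
    spleen_axes_mm: tuple = (40.0, 35.0, 18.0)
    seed: int = 0

    def __post_init__(self):
        if not (130.0 <= self.liver_mean <= 150.0):
            raise PhantomParameterError(
                f"liver_mean {self.liver_mean} outside the liver window [130, 150]")
        if self.tumor_mean >= 130.0:
            raise PhantomParameterError(
                f"tumor_mean {self.tumor_mean} must lie below the window low edge 130")
        if self.noise_sd < 0:
            raise PhantomParameterError("noise_sd must be >= 0")
        if self.n_tumors < 0:
            raise PhantomParameterError("n_tumors must be >= 0")
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def is_2d(self) -> bool:
        return self.shape[0] == 1

    @classmethod
    def fast_2d(cls, **kw) -> "PhantomParams":
        """Single-slice 128×128 configuration used by fast tests."""
        kw.setdefault("shape", (1, 128, 128))
        kw.setdefault("spacing", (1.6, 1.6, 1.6))
        return cls(**kw)


# ---------------------------------------------------------------------------
# base anatomy (shared across a cohort)

def _smooth_field(shape, rng, sigma_vox):
    """Zero-mean unit-std smooth random field used to deform the liver surface."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _base_scene(params: PhantomParams, rng):
    """Label scene (0 air, 1 body, 2 liver, 3 tumor, 4 spleen) in base coords."""
    nz, nr, nc = params.shape
    sz, sy, sx = params.spacing
    zz, rr, cc = np.meshgrid(np.arange(nz), np.arange(nr), np.arange(nc),
                             indexing="ij")
    labels = np.full(params.shape, _AIR, dtype=np.uint8)

    # body: elliptic cylinder along z
    body_q = (((rr - 0.50 * nr) / (0.47 * nr)) ** 2
              + ((cc - 0.50 * nc) / (0.46 * nc)) ** 2)
    labels[body_q < 1.0] = _BODY

    # liver: deformed ellipsoid, centred right-of-midline (patient right)
    centre = np.array([0.50 * nz, 0.48 * nr, 0.40 * nc])
    axes_vox = np.array(params.liver_axes_mm) / np.array([sz, sy, sx])
    q = (((rr - centre[1]) / axes_vox[1]) ** 2
         + ((cc - centre[2]) / axes_vox[2]) ** 2)
    if nz > 1:
        q = q + ((zz - centre[0]) / axes_vox[0]) ** 2
    sigma = (0 if nz == 1 else 4, 10, 10)
    q = q + params.deform_amp * _smooth_field(params.shape, rng, sigma)
    liver = (q < 1.0) & (labels == _BODY)
    labels[liver] = _LIVER

    # spleen-like confounder on the opposite side, overlapping the liver window
    sp_centre = np.array([0.50 * nz, 0.40 * nr, 0.84 * nc])
    sp_axes = np.array(params.spleen_axes_mm) / np.array([sz, sy, sx])
    sq = (((rr - sp_centre[1]) / sp_axes[1]) ** 2
          + ((cc - sp_centre[2]) / sp_axes[2]) ** 2)
    if nz > 1:
        sq = sq + ((zz - sp_centre[0]) / sp_axes[0]) ** 2
    labels[(sq < 1.0) & (labels == _BODY)] = _SPLEEN

    _place_tumors(labels, params, rng)
    return labels


def _place_tumors(labels, params: PhantomParams, rng):
    if params.n_tumors == 0:
        return
    sz, sy, sx = params.spacing
    r_vox = params.tumor_radius_mm / min(sy, sx)
    liver = labels == _LIVER
    # centres must keep the whole blob inside the liver
    if params.shape[0] == 1:
        depth = ndimage.distance_transform_edt(liver[0], sampling=(sy, sx))[None]
    else:
        depth = ndimage.distance_transform_edt(liver, sampling=(sz, sy, sx))
    allowed = depth > params.tumor_radius_mm + 2.0 * min(sy, sx)
    zz, rr, cc = np.meshgrid(np.arange(params.shape[0]),
                             np.arange(params.shape[1]),
                             np.arange(params.shape[2]), indexing="ij")
    for _ in range(params.n_tumors):
        idx = np.argwhere(allowed)
        if idx.size == 0:
            raise PhantomParameterError(
                "requested tumor does not fit inside the liver")
        z0, r0, c0 = idx[rng.integers(idx.shape[0])]
        dist2 = (((zz - z0) * sz) ** 2 if params.shape[0] > 1 else 0) \
            + ((rr - r0) * sy) ** 2 + ((cc - c0) * sx) ** 2
        blob = (dist2 < params.tumor_radius_mm ** 2) & (labels == _LIVER)
        labels[blob] = _TUMOR
        # keep later tumors separated from this one
        allowed &= dist2 > (2.5 * params.tumor_radius_mm) ** 2


def _draw_affine(params: PhantomParams, rng):
    """Per-subject in-plane affine: (scale_r, scale_c, theta_rad, t_r, t_c) vox."""
    s = 1.0 + rng.uniform(-params.scale_range, params.scale_range, size=2)
    theta = np.deg2rad(rng.uniform(-params.rotation_range_deg,
                                   params.rotation_range_deg))
    t = rng.uniform(-params.translation_range_mm, params.translation_range_mm,
                    size=2) / np.array(params.spacing[1:])
    return s, theta, t


def _warp_labels(labels, params: PhantomParams, affine):
    """Apply the forward in-plane affine (about the grid centre) to the scene."""
    (sr, sc), theta, (tr, tc) = affine
    nr, nc = params.shape[1], params.shape[2]
    centre = np.array([0.5 * nr, 0.5 * nc])
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    fwd = rot @ np.diag([sr, sc])
    inv = np.linalg.inv(fwd)
    offset = centre - inv @ (centre + np.array([tr, tc]))
    out = np.empty_like(labels)
    for k in range(labels.shape[0]):
        out[k] = ndimage.affine_transform(labels[k], inv, offset=offset,
                                          order=0, mode="constant", cval=_AIR)
    return out


def _render_intensities(labels, params: PhantomParams, rng):
    vox = np.full(labels.shape, params.air_intensity, dtype=np.float64)
    vox[labels == _BODY] = params.body_intensity
    for lab, mean, sd in ((_LIVER, params.liver_mean, params.liver_sd),
                          (_TUMOR, params.tumor_mean, params.tumor_sd),
                          (_SPLEEN, 140.0 + params.organ_contrast, 4.0)):
        sel = labels == lab
        vox[sel] = rng.normal(mean, sd, size=int(sel.sum()))
    if params.noise_sd > 0:
        vox = vox + rng.normal(0.0, params.noise_sd, size=vox.shape)
    return vox


def _subject_from_scene(base_labels, params, affine, rng, subject_id):
    labels = _warp_labels(base_labels, params, affine)
    vox = _render_intensities(labels, params, rng)
    volume = Volume(vox, spacing=params.spacing, id=subject_id)
    liver = Mask(((labels == _LIVER) | (labels == _TUMOR)).astype(np.uint8),
                 label_name="liver", spacing=params.spacing)
    tumor = Mask((labels == _TUMOR).astype(np.uint8),
                 label_name="tumor", spacing=params.spacing)
    return volume, liver, tumor


def generate_phantom(params: PhantomParams = None, seed=None):
    """Generate one phantom subject: (Volume, liver Mask, tumor Mask).

    Deterministic given ``params.seed`` (or the ``seed`` override): the base
    anatomy, the subject affine and all intensity noise derive from it.
    """
    params = params if params is not None else PhantomParams()
    if seed is not None:
        params = replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)
    base = _base_scene(params, rng)
    affine = _draw_affine(params, rng)
    return _subject_from_scene(base, params, affine, rng, f"phantom-{params.seed}")


def generate_cohort(n_subjects: int, params: PhantomParams = None, seed=None):
    """Generate a cohort sharing one base anatomy with per-subject affines.

    Returns a list of (Volume, liver Mask, tumor Mask).  Each subject draws
    an independent affine (and intensity noise) from its own child generator,
    so liver volumes vary across the cohort; with zero affine ranges all
    masks are voxel-identical.
    """
    if n_subjects < 2:
        raise PhantomParameterError("a cohort needs at least 2 subjects")
    params = params if params is not None else PhantomParams()
    if seed is not None:
        params = replace(params, seed=seed)
    base_rng = np.random.default_rng(params.seed)
    base = _base_scene(params, base_rng)
    out = []
    seeds = np.random.SeedSequence(params.seed).spawn(n_subjects)
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        affine = _draw_affine(params, rng)
        out.append(_subject_from_scene(base, params, affine, rng,
                                       f"phantom-{params.seed}-s{i}"))
    return out


def liver_volume_cm3(mask: Mask) -> float:
    """Voxel-count liver volume in cm³ (count × voxel volume)."""
    return float(mask.count()) * np.prod(mask.spacing) / 1000.0
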