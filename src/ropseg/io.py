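"""Volume/mask I/O and the coordinate conventions used throughout the package.

Conventions
-----------
Arrays are indexed ``(slice, row, col)`` with z ascending; spacing is
``(z, y, x)`` in millimetres.  Bounding boxes are 0-based and half-open
``[min, max)`` so that ``image[r0:r1, c0:c1]`` is exactly the boxed region.
NIfTI is the canonical on-disk volume format; stacks of 8/16-bit grayscale
PNG slices are accepted for fixtures, with spacing supplied by the caller
(default (1.60, 0.78, 0.78) mm).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

DEFAULT_SPACING = (1.60, 0.78, 0.78)

VALID_MASK_LABELS = {"liver", "tumor", "coarse", "fcm", "elm", "fine"}


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


class GeometryError(ValueError):
    """A geometric precondition (bounds, degeneracy) was violated."""


@dataclass
class Volume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Intensities in scanner gray units.
    spacing : tuple of float
        (z, y, x) voxel size in mm; all components positive.
    id : str
        Subject identifier.
    """

    voxels: np.ndarray
    spacing: tuple = DEFAULT_SPACING
    id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise FormatError("Volume requires a non-empty 3D grid")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("Volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def n_slices(self):
        return self.voxels.shape[0]

    def slice(self, k: int) -> np.ndarray:
        return self.voxels[k]


@dataclass
class Mask:
    """A binary grid aligned to a Volume (or a single slice).

    ``voxels`` holds only {0, 1}; ``label_name`` records what the mask
    delineates (liver, tumor, or an intermediate pipeline stage).
    """

    voxels: np.ndarray
    label_name: str = "liver"
    spacing: tuple = DEFAULT_SPACING

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise FormatError(f"mask values must be in {{0,1}}, found {uniq[:10]}")
        self.voxels = arr.astype(np.uint8)
        if self.label_name not in VALID_MASK_LABELS:
            raise FormatError(f"unknown mask label {self.label_name!r}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class BBox2D:
    """Axis-aligned per-slice box, 0-based, half-open [min, max)."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise GeometryError(f"degenerate box {self}")
        if self.row_min < 0 or self.col_min < 0:
            raise GeometryError(f"negative box origin {self}")

    @property
    def height(self):
        return self.row_max - self.row_min

    @property
    def width(self):
        return self.col_max - self.col_min

    @property
    def area(self):
        return self.height * self.width

    def contains(self, other: "BBox2D") -> bool:
        return (self.row_min <= other.row_min and self.col_min <= other.col_min
                and self.row_max >= other.row_max and self.col_max >= other.col_max)

    def expand(self, margin: int, shape=None) -> "BBox2D":
        """Pad by `margin` pixels on every side, clipped to `shape` if given."""
        r0, c0 = self.row_min - margin, self.col_min - margin
        r1, c1 = self.row_max + margin, self.col_max + margin
        if shape is not None:
            r0, c0 = max(r0, 0), max(c0, 0)
            r1, c1 = min(r1, shape[0]), min(c1, shape[1])
        else:
            r0, c0 = max(r0, 0), max(c0, 0)
        return BBox2D(r0, c0, r1, c1)

    def to_dict(self, slice_index=None):
        d = {"row_min": self.row_min, "col_min": self.col_min,
             "row_max": self.row_max, "col_max": self.col_max}
        if slice_index is not None:
            d = {"slice": int(slice_index), **d}
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(d["row_min"], d["col_min"], d["row_max"], d["col_max"])


def tight_bbox(mask2d: np.ndarray) -> BBox2D:
    """Half-open tight box of the nonzero pixels of a 2D mask."""
    rows, cols = np.nonzero(np.asarray(mask2d))
    if rows.size == 0:
        raise GeometryError("empty mask has no bounding box")
    return BBox2D(int(rows.min()), int(cols.min()),
                  int(rows.max()) + 1, int(cols.max()) + 1)


def crop(image: np.ndarray, bbox: BBox2D) -> np.ndarray:
    """Copy the boxed region of a 2D grid."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise GeometryError("crop expects a 2D grid")
    if bbox.row_max > image.shape[0] or bbox.col_max > image.shape[1]:
        raise GeometryError(f"box {bbox} exceeds image shape {image.shape}")
    return image[bbox.row_min:bbox.row_max, bbox.col_min:bbox.col_max].copy()


# ---------------------------------------------------------------------------
# readers / writers

_PNG_EXTS = {".png", ".tif", ".tiff"}


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path, spacing=None, subject_id=None) -> Volume:
    """Read a Volume from a NIfTI file or a directory of grayscale slices.

    For NIfTI the spacing comes from the header (reordered to (z, y, x));
    for slice stacks it comes from `spacing` (default (1.60, 0.78, 0.78) mm).
    Slices sort ascending by filename.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        arr, n = _read_stack(path)
        return Volume(arr, spacing=spacing or DEFAULT_SPACING,
                      id=subject_id or path.name)
    if _is_nifti(path):
        import nibabel as nib
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"expected 3D NIfTI, got {data.ndim}D")
        # stored (x, y, z); package convention is (slice, row, col)
        vox = np.transpose(data, (2, 1, 0))
        zooms = img.header.get_zooms()[:3]
        sp = spacing or (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        return Volume(vox, spacing=sp, id=subject_id or path.stem.replace(".nii", ""))
    raise FormatError(f"unrecognised volume format: {path}")


def _read_stack(path: Path):
    import imageio.v3 as iio
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _PNG_EXTS)
    if not files:
        raise FormatError(f"no slice images in {path}")
    slices = [np.asarray(iio.imread(f)) for f in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent slice shapes {shapes}")
    if slices[0].ndim != 2:
        raise FormatError("slices must be single-channel grayscale")
    return np.stack(slices).astype(np.float64), len(files)


def write_volume(volume: Volume, path) -> None:
    """Write a Volume as NIfTI (.nii/.nii.gz) or a PNG slice directory."""
    path = Path(path)
    if path.suffix.lower() in _PNG_EXTS or (path.suffix == "" and not _is_nifti(path)):
        _write_stack(volume.voxels, path)
        return
    import nibabel as nib
    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    data = np.transpose(volume.voxels, (2, 1, 0))
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data), affine), str(path))


def _write_stack(voxels, path: Path):
    import imageio.v3 as iio
    path.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(voxels)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    for k in range(arr.shape[0]):
        iio.imwrite(path / f"slice_{k:04d}.png", arr[k].astype(np.uint16))


def read_mask(path, label_name="liver", spacing=None) -> Mask:
    vol = read_volume(path, spacing=spacing)
    vox = np.rint(vol.voxels).astype(np.int64)
    return Mask((vox > 0).astype(np.uint8) if set(np.unique(vox)) <= {0, 1}
                else _validate_binary(vox),
                label_name=label_name, spacing=vol.spacing)


def _validate_binary(arr):
    raise FormatError(f"mask file holds values outside {{0,1}}: {np.unique(arr)[:10]}")


def write_mask(mask: Mask, path) -> None:
    uniq = np.unique(mask.voxels)
    if not np.all(np.isin(uniq, (0, 1))):
        raise FormatError("refusing to write non-binary mask")
    write_volume(Volume(mask.voxels.astype(np.int16), spacing=mask.spacing,
                        id=mask.label_name), path)


def write_bboxes(boxes, path) -> None:
    """Serialize a per-slice box list ({slice_index: BBox2D or None}) as JSON."""
    records = [b.to_dict(k) for k, b in sorted(boxes.items()) if b is not None]
    Path(path).write_text(json.dumps(records, indent=1))


def read_bboxes(path) -> dict:
    records = json.loads(Path(path).read_text())
    return {int(r["slice"]): BBox2D.from_dict(r) for r in records}
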