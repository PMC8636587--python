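"""Canonical volume/mask containers, NIfTI/DICOM ingest, and preprocessing.

All downstream geometry assumes one fixed anatomical frame, referred to as
*canonical* throughout the package: arrays are indexed ``(x, y, z)`` with

* ``x`` increasing from the patient's right towards the left,
* ``y`` increasing from anterior towards posterior,
* ``z`` increasing from superior (proximal) towards inferior (distal).

Voxel spacing is carried in millimetres per axis.  Preprocessing follows the
usual segmentation recipe for anisotropic axial stacks: resample to a common
target spacing (default 0.6 x 0.6 x 6.5 mm), z-score the intensities over the
whole grid, and zero-pad each axis up to a multiple compatible with the
network's pooling plan, keeping an inverse record so predictions can be mapped
back onto the native grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import nibabel as nib
from scipy import ndimage

__all__ = [
    "BACKGROUND",
    "FEMUR",
    "TIBIA",
    "FIBULA",
    "CLASS_NAMES",
    "Volume",
    "LabelMask",
    "PreprocessSpec",
    "CropPadRecord",
    "LimbSplit",
    "resample",
    "normalize_intensity",
    "crop_or_pad",
    "restore_native",
    "split_limbs",
    "load_nifti_volume",
    "load_nifti_mask",
    "save_nifti",
    "load_dicom_series",
]

BACKGROUND, FEMUR, TIBIA, FIBULA = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", FEMUR: "femur", TIBIA: "tibia", FIBULA: "fibula"}

#: canonical axis codes in nibabel notation (x: right->left, y: anterior->
#: posterior, z: superior->inferior)
_CANONICAL_AXCODES = ("L", "P", "I")

Region = Literal["hip", "knee", "ankle"]


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be three positive numbers, got {spacing!r}")
    return spacing


@dataclass
class Volume:
    """A 3D intensity grid in the canonical anatomical frame."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    region: Region | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume grid must be 3D and nonempty, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """Integer class grid aligned to a :class:`Volume`.

    Class codes: 0 background, 1 femur, 2 tibia, 3 fibula.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    region: Region | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"mask grid must be 3D and nonempty, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("mask values must be integers")
            arr = arr.astype(np.uint8)
        if arr.min() < 0 or arr.max() > 3:
            raise ValueError("mask values must be in {0,1,2,3}")
        self.data = arr.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground(self) -> np.ndarray:
        return self.data > 0


@dataclass
class PreprocessSpec:
    """Resample / normalize / pad settings applied before the network."""

    target_spacing: tuple[float, float, float] = (0.6, 0.6, 6.5)
    normalize: bool = True
    pad_multiple: tuple[int, int, int] = (32, 32, 1)

    def __post_init__(self) -> None:
        self.target_spacing = _check_spacing(self.target_spacing)
        if any(int(m) < 1 for m in self.pad_multiple):
            raise ValueError("pad_multiple must be >= 1 per axis")
        self.pad_multiple = tuple(int(m) for m in self.pad_multiple)


def _resampled_shape(shape: Sequence[int], spacing: Sequence[float],
                     target: Sequence[float]) -> tuple[int, ...]:
    # round half away from zero, floor at one voxel
    out = []
    for n, s, t in zip(shape, spacing, target):
        x = n * s / t
        out.append(max(1, int(np.floor(x + 0.5))))
    return tuple(out)


def resample(obj: Volume | LabelMask, target_spacing: Sequence[float],
             mode: str | None = None):
    """Resample a volume (trilinear) or mask (nearest-neighbour) onto a new grid.

    The output shape is ``round(shape * spacing / target_spacing)`` per axis.
    Voxel centres are aligned so that the physical extent is preserved; the
    identity resample returns the grid unchanged.
    """
    target = _check_spacing(target_spacing)
    if mode is None:
        mode = "label" if isinstance(obj, LabelMask) else "intensity"
    if mode not in ("intensity", "label"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    in_shape = obj.shape
    out_shape = _resampled_shape(in_shape, obj.spacing, target)
    if out_shape == in_shape and all(abs(a - b) < 1e-12 for a, b in zip(obj.spacing, target)):
        return replace(obj, data=obj.data.copy())
    # map output voxel centres into input index space (centre-aligned grids)
    coords = np.meshgrid(
        *[( (np.arange(m) + 0.5) * (t / s) - 0.5 )
          for m, s, t in zip(out_shape, obj.spacing, target)],
        indexing="ij",
    )
    order = 1 if mode == "intensity" else 0
    out = ndimage.map_coordinates(
        obj.data.astype(np.float32 if mode == "intensity" else obj.data.dtype),
        np.stack([c.astype(np.float32) for c in coords]),
        order=order, mode="nearest",
    )
    return replace(obj, data=out, spacing=target)


def normalize_intensity(volume: Volume) -> Volume:
    """Z-score the whole grid to mean 0 / SD 1; a constant grid maps to zeros."""
    x = volume.data.astype(np.float64)
    sd = x.std()
    if sd == 0:
        out = np.zeros_like(x, dtype=np.float32)
    else:
        out = ((x - x.mean()) / sd).astype(np.float32)
    return replace(volume, data=out)


@dataclass(frozen=True)
class CropPadRecord:
    """Inverse record of a pad operation: slices selecting the native grid."""

    native_shape: tuple[int, int, int]
    padded_shape: tuple[int, int, int]
    lo: tuple[int, int, int]  # voxels prepended per axis

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, l + n) for l, n in zip(self.lo, self.native_shape))


def crop_or_pad(obj: Volume | LabelMask, pad_multiple: Sequence[int]):
    """Zero-pad each axis symmetrically up to the next multiple of ``pad_multiple``.

    Returns ``(padded, record)`` where ``record`` maps padded grids back to the
    native one via :func:`restore_native`.
    """
    mult = tuple(int(m) for m in pad_multiple)
    if any(m < 1 for m in mult):
        raise ValueError("pad_multiple must be >= 1 per axis")
    shape = obj.shape
    target = tuple(int(np.ceil(n / m)) * m for n, m in zip(shape, mult))
    lo = tuple((t - n) // 2 for t, n in zip(target, shape))
    pad = [(l, t - n - l) for l, t, n in zip(lo, target, shape)]
    out = np.pad(obj.data, pad, mode="constant", constant_values=0)
    record = CropPadRecord(native_shape=shape, padded_shape=target, lo=lo)
    return replace(obj, data=out), record


def restore_native(obj: Volume | LabelMask, record: CropPadRecord):
    """Undo :func:`crop_or_pad` using its inverse record."""
    if obj.shape != record.padded_shape:
        raise ValueError(
            f"grid shape {obj.shape} does not match pad record {record.padded_shape}")
    return replace(obj, data=obj.data[record.slices].copy())


@dataclass
class LimbSplit:
    left: LabelMask
    right: LabelMask
    warnings: list[str] = field(default_factory=list)


def split_limbs(mask: LabelMask) -> LimbSplit:
    """Assign foreground connected components to the left or right limb.

    In the canonical frame x increases right->left, so components whose
    centroid lies at x below the grid midline belong to the patient's right
    limb.  Each output keeps the full grid but only its side's voxels.
    """
    fg = mask.foreground()
    if not fg.any():
        raise ValueError("split_limbs requires at least one foreground voxel")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    mid = (mask.shape[0] - 1) / 2.0
    centroids = ndimage.center_of_mass(fg, labels, range(1, n + 1))
    left = np.zeros_like(mask.data)
    right = np.zeros_like(mask.data)
    for comp, (cx, _, _) in zip(range(1, n + 1), centroids):
        sel = labels == comp
        if cx > mid:
            left[sel] = mask.data[sel]
        else:
            right[sel] = mask.data[sel]
    warnings = []
    if not left.any():
        warnings.append("no components assigned to the left limb")
    if not right.any():
        warnings.append("no components assigned to the right limb")
    return LimbSplit(
        left=replace(mask, data=left),
        right=replace(mask, data=right),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# I/O


def _canonicalize_array(arr: np.ndarray, affine: np.ndarray):
    """Reorient an (i,j,k) array + affine into the canonical (L,P,I) frame."""
    current = nib.orientations.io_orientation(affine)
    target = nib.orientations.axcodes2ornt(_CANONICAL_AXCODES)
    xform = nib.orientations.ornt_transform(current, target)
    out = nib.orientations.apply_orientation(arr, xform)
    zooms = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    perm = xform[:, 0].astype(int)
    spacing = tuple(float(zooms[p]) for p in perm)
    return out, spacing


def load_nifti_volume(path: str | Path, region: Region | None = None) -> Volume:
    img = nib.load(str(path))
    arr, spacing = _canonicalize_array(np.asanyarray(img.dataobj), img.affine)
    return Volume(data=np.ascontiguousarray(arr, dtype=np.float32), spacing=spacing,
                  region=region)


def load_nifti_mask(path: str | Path, region: Region | None = None) -> LabelMask:
    img = nib.load(str(path))
    arr, spacing = _canonicalize_array(np.asanyarray(img.dataobj), img.affine)
    return LabelMask(data=np.ascontiguousarray(np.rint(arr)).astype(np.uint8),
                     spacing=spacing, region=region)


def save_nifti(obj: Volume | LabelMask, path: str | Path) -> None:
    """Write a canonical-frame grid as NIfTI (affine encodes the LPI axes)."""
    sx, sy, sz = obj.spacing
    affine = np.diag([-sx, -sy, -sz, 1.0])  # canonical axes in RAS world coords
    data = obj.data if isinstance(obj, LabelMask) else obj.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_dicom_series(directory: str | Path, region: Region | None = None) -> Volume:
    """Assemble one canonical Volume from an axial DICOM series directory.

    Slices are sorted by their position along the slice normal.  The series is
    assumed to share a single orientation and in-plane spacing.
    """
    import pydicom

    files = sorted(Path(directory).glob("*"))
    slices = []
    for f in files:
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array") and hasattr(ds, "ImagePositionPatient"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {directory}")
    iop = np.array(slices[0].ImageOrientationPatient, dtype=float)
    row, col = iop[:3], iop[3:]
    normal = np.cross(row, col)
    slices.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, float), normal)))
    stack = np.stack([ds.pixel_array.astype(np.float32) for ds in slices], axis=-1)
    # pixel_array is (row, col) == (j, i); reorder to (i, j, k)
    stack = np.transpose(stack, (1, 0, 2))
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        p0 = np.array(slices[0].ImagePositionPatient, float)
        p1 = np.array(slices[1].ImagePositionPatient, float)
        dz = float(abs(np.dot(p1 - p0, normal)))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    origin = np.array(slices[0].ImagePositionPatient, float)
    affine = np.eye(4)
    affine[:3, 0] = col * dx
    affine[:3, 1] = row * dy
    affine[:3, 2] = normal * dz
    affine[:3, 3] = origin
    # DICOM patient coords are LPS; nibabel orientations expect RAS
    affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine
    arr, spacing = _canonicalize_array(stack, affine)
    return Volume(data=np.ascontiguousarray(arr, dtype=np.float32), spacing=spacing,
                  region=region)


def preprocess(volume: Volume, spec: PreprocessSpec | None = None):
    """Resample -> normalize -> pad; returns ``(volume, record)``."""
    spec = spec or PreprocessSpec()
    out = resample(volume, spec.target_spacing, mode="intensity")
    if spec.normalize:
        out = normalize_intensity(out)
    return crop_or_pad(out, spec.pad_multiple)
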