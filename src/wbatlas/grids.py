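"""Grid-aligned volume containers, NIfTI I/O and basic image operations.

Conventions used throughout the package:

* array axes are ``(x, y, z)`` with z the cranio-caudal direction;
* world coordinates are in millimetres; ``origin`` is the world position of
  the centre of voxel ``(0, 0, 0)``;
* two grids are *compatible* iff shape, spacing and origin agree within
  1e-6 mm, and every voxel-wise operation requires compatibility;
* fraction-valued channels (fat/water fraction, p-maps) live in ``[0, 1]``
  and are clamped at load time.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.ndimage as ndi
import yaml

from .errors import DataError, FormatError, ParameterError

log = logging.getLogger("wbatlas")

#: conversion factor sigma = FWHM_TO_SIGMA * fwhm for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

GRID_ATOL = 1e-6


class ChannelKind(enum.Enum):
    """Semantic kind of a scalar channel; controls clamping at load."""

    FRACTION = "fraction"      # fat/water fraction, in [0, 1]
    ACTIVITY = "activity"      # PET activity concentration, Bq/ml
    SUV = "suv"                # standardised uptake value, g/ml
    NORMALIZED = "normalized"  # dimensionless uptake ratio
    PVALUE = "pvalue"          # probability map, in [0, 1]
    LOGJAC = "logjac"          # log Jacobian determinant, dimensionless
    OTHER = "other"

    @property
    def clamped(self) -> bool:
        return self in (ChannelKind.FRACTION, ChannelKind.PVALUE)


@dataclass
class VolumeGrid:
    """A 3D scalar image on a regular lattice.

    Parameters
    ----------
    data
        3D array of voxel values.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    kind
        Semantic channel kind (fraction, SUV, ...).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    kind: ChannelKind = ChannelKind.OTHER

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise FormatError(f"voxel spacing must be finite and positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def compatible_with(self, other: "VolumeGrid | DisplacementField | LabelMap") -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing, atol=GRID_ATOL)
            and np.allclose(self.origin, other.origin, atol=GRID_ATOL)
        )

    def require_compatible(self, other, what: str = "operands") -> None:
        if not self.compatible_with(other):
            raise DataError(f"incompatible grids for {what}")

    def with_data(self, data: np.ndarray, kind: ChannelKind | None = None) -> "VolumeGrid":
        return VolumeGrid(data, self.spacing.copy(), self.origin.copy(),
                          kind if kind is not None else self.kind)

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre world coordinates, one array per axis (broadcastable)."""
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)]
        return np.meshgrid(*axes, indexing="ij", sparse=True)


@dataclass
class DisplacementField:
    """A 3D field of mm displacement vectors on a reference-space lattice.

    The field maps a reference-space point ``x`` to the native-space point
    ``x + u(x)``; the zero field is the identity mapping.
    """

    vectors: np.ndarray  # shape (nx, ny, nz, 3), mm
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise FormatError("displacement field must have shape (nx, ny, nz, 3)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @classmethod
    def zero(cls, like: VolumeGrid) -> "DisplacementField":
        return cls(np.zeros(like.shape + (3,)), like.spacing.copy(), like.origin.copy())

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors ** 2, axis=-1))

    def magnitude_voxels(self) -> np.ndarray:
        return np.sqrt(np.sum((self.vectors / self.spacing) ** 2, axis=-1))

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.vectors.copy(), self.spacing.copy(), self.origin.copy())

    def grid_like(self) -> VolumeGrid:
        return VolumeGrid(np.zeros(self.shape, dtype=np.float32), self.spacing.copy(),
                          self.origin.copy())


@dataclass
class LabelMap:
    """Integer label volume plus a label-id -> name dictionary.

    Label 0 is background by convention.
    """

    labels: np.ndarray
    names: dict[int, str]
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.names = {int(k): str(v) for k, v in self.names.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def id_of(self, name: str) -> int:
        for k, v in self.names.items():
            if v == name:
                return k
        raise DataError(f"no VOI named {name!r} in label map")

    def mask(self, name: str, require_nonempty: bool = True) -> np.ndarray:
        m = self.labels == self.id_of(name)
        if require_nonempty and not m.any():
            raise DataError(f"VOI {name!r} is empty")
        return m

    def with_labels(self, labels: np.ndarray, names: dict[int, str] | None = None) -> "LabelMap":
        return LabelMap(labels, names if names is not None else dict(self.names),
                        self.spacing.copy(), self.origin.copy())

    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class SubjectDataset:
    """One subject's co-registered channels, metadata and (optional) truth.

    ``fat`` + ``water`` equals 1 (within float storage precision) at every
    body voxel; ``fdg`` is in Bq/ml in native space and in SUV (g/ml) after
    the pipeline converts it. Ground-truth members (``native_labels``,
    ``native_bones``, ``truth_lesions``) exist for synthetic subjects only.
    """

    subject_id: str
    fat: VolumeGrid
    water: VolumeGrid
    fdg: VolumeGrid
    weight_kg: float
    dose_MBq: float
    native_labels: LabelMap | None = None
    native_bones: LabelMap | None = None
    normalized_fdg: VolumeGrid | None = None
    space: str = "native"
    truth_lesions: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    # estimated reference->native displacement (set after registration);
    # declared last: the attribute name shadows dataclasses.field above it
    field: DisplacementField | None = None

    def __post_init__(self):
        if self.weight_kg <= 0:
            raise ParameterError("weight must be > 0 kg")
        if self.dose_MBq <= 0:
            raise ParameterError("dose must be > 0 MBq")
        self.fat.require_compatible(self.water, "fat/water channels")
        self.fat.require_compatible(self.fdg, "fat/FDG channels")

    def validate_fractions(self, body: np.ndarray, atol: float = 1e-5) -> None:
        s = self.fat.data.astype(np.float64) + self.water.data.astype(np.float64)
        bad = np.abs(s[body] - 1.0) > atol
        if bad.any():
            raise DataError(
                f"fat+water != 1 at {int(bad.sum())} body voxels (two-channel convention)")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _geometry_from(img) -> tuple[np.ndarray, np.ndarray]:
    aff = img.affine
    spacing = np.sqrt(np.sum(aff[:3, :3] ** 2, axis=0))
    origin = aff[:3, 3].copy()
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise FormatError(f"non-finite or non-positive voxel spacing in header: {spacing}")
    return spacing, origin


def read_volume(path: str | Path, kind: ChannelKind = ChannelKind.OTHER) -> VolumeGrid:
    """Read a scalar NIfTI-1 volume.

    Fraction-kind channels are clamped to ``[0, 1]``; the number of clamped
    voxels is recorded in the package log.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D scalar volume, got shape {data.shape}")
    spacing, origin = _geometry_from(img)
    data = np.asarray(data, dtype=np.float64)
    if kind.clamped:
        n_clamped = int(np.count_nonzero((data < 0) | (data > 1)))
        if n_clamped:
            log.info("read_volume(%s): clamped %d voxels to [0, 1]", path, n_clamped)
        data = np.clip(data, 0.0, 1.0)
    return VolumeGrid(data, spacing, origin, kind)


def write_volume(vol: VolumeGrid, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_field(path: str | Path) -> DisplacementField:
    """Read a displacement field stored as 4D NIfTI with last dim = 3 (mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: displacement field must be 4D with 3 components")
    spacing, origin = _geometry_from(img)
    return DisplacementField(np.asarray(data, dtype=np.float64), spacing, origin)


def write_field(fld: DisplacementField, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(fld.vectors, dtype=np.float32),
                          _affine(fld.spacing, fld.origin))
    nib.save(img, str(path))


def read_labels(path: str | Path, names_path: str | Path | None = None) -> LabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: label map must be 3D")
    spacing, origin = _geometry_from(img)
    names: dict[int, str] = {}
    npth = Path(names_path) if names_path else Path(str(path)).with_suffix("").with_suffix(".json")
    if npth.exists():
        names = {int(k): v for k, v in json.loads(npth.read_text()).items()}
    return LabelMap(np.rint(data).astype(np.int32), names, spacing, origin)


def write_labels(lm: LabelMap, path: str | Path, names_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(lm.labels.astype(np.int16), _affine(lm.spacing, lm.origin))
    nib.save(img, str(path))
    npth = Path(names_path) if names_path else Path(str(path)).with_suffix("").with_suffix(".json")
    npth.write_text(json.dumps({str(k): v for k, v in lm.names.items()}, indent=1))


def read_subject(directory: str | Path) -> SubjectDataset:
    """Read one subject from the on-disk layout written by :func:`write_subject`."""
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    fdg_kind = ChannelKind(meta.get("fdg_kind", "activity"))
    sub = SubjectDataset(
        subject_id=str(meta["id"]),
        fat=read_volume(d / "fat.nii.gz", ChannelKind.FRACTION),
        water=read_volume(d / "water.nii.gz", ChannelKind.FRACTION),
        fdg=read_volume(d / "fdg.nii.gz", fdg_kind),
        weight_kg=float(meta["weight_kg"]),
        dose_MBq=float(meta["dose_MBq"]),
        space=meta.get("space", "native"),
    )
    if (d / "labels.nii.gz").exists():
        sub.native_labels = read_labels(d / "labels.nii.gz")
    if (d / "bones.nii.gz").exists():
        sub.native_bones = read_labels(d / "bones.nii.gz")
    if (d / "field.nii.gz").exists():
        sub.field = read_field(d / "field.nii.gz")
    if (d / "normalized_fdg.nii.gz").exists():
        sub.normalized_fdg = read_volume(d / "normalized_fdg.nii.gz", ChannelKind.NORMALIZED)
    return sub


def write_subject(sub: SubjectDataset, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(sub.fat, d / "fat.nii.gz")
    write_volume(sub.water, d / "water.nii.gz")
    write_volume(sub.fdg, d / "fdg.nii.gz")
    if sub.native_labels is not None:
        write_labels(sub.native_labels, d / "labels.nii.gz")
    if sub.native_bones is not None:
        write_labels(sub.native_bones, d / "bones.nii.gz")
    if sub.field is not None:
        write_field(sub.field, d / "field.nii.gz")
    if sub.normalized_fdg is not None:
        write_volume(sub.normalized_fdg, d / "normalized_fdg.nii.gz")
    meta = {"id": sub.subject_id, "weight_kg": float(sub.weight_kg),
            "dose_MBq": float(sub.dose_MBq), "space": sub.space,
            "fdg_kind": sub.fdg.kind.value}
    (d / "meta.yaml").write_text(yaml.safe_dump(meta))


# ---------------------------------------------------------------------------
# Basic image operations
# ---------------------------------------------------------------------------

def gaussian_smooth(vol: VolumeGrid, fwhm_mm) -> VolumeGrid:
    """Gaussian smoothing with per-axis FWHM given in mm.

    Per-axis sigma is ``fwhm / (2 sqrt(2 ln 2))``. ``fwhm = 0`` returns the
    input unchanged. Values outside the array are treated as zero (constant
    padding); callers that need within-body statistics apply the body mask
    after smoothing.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ParameterError(f"FWHM must be >= 0 per axis, got {fwhm}")
    if np.all(fwhm == 0):
        return vol.with_data(vol.data.copy())
    sigma_vox = fwhm * FWHM_TO_SIGMA / vol.spacing
    out = ndi.gaussian_filter(np.asarray(vol.data, dtype=np.float64), sigma_vox,
                              mode="constant", cval=0.0)
    return vol.with_data(out)


def smooth_array(arr: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian filter an array with per-axis sigma in voxels (zero padded)."""
    sigma_vox = np.broadcast_to(np.asarray(sigma_vox, dtype=float), (arr.ndim,))
    if np.all(sigma_vox == 0):
        return arr.copy()
    return ndi.gaussian_filter(arr, sigma_vox, mode="constant", cval=0.0)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def body_mask(fat: VolumeGrid, water: VolumeGrid, threshold: float = 0.5) -> LabelMap:
    """Within-body mask from the fat and water channels.

    Tissue is where the summed fraction signal exceeds ``threshold`` (air
    carries ~zero signal in both channels). Internal holes are filled in 3D
    and only the largest 26-connected component is kept.
    """
    fat.require_compatible(water, "body_mask")
    tissue = (np.asarray(fat.data, dtype=np.float64)
              + np.asarray(water.data, dtype=np.float64)) > threshold
    if not tissue.any():
        raise DataError("body mask is empty: no tissue signal found")
    tissue = ndi.binary_fill_holes(tissue)
    lab, n = ndi.label(tissue, structure=_CONN26)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        tissue = lab == (1 + int(np.argmax(sizes)))
    return LabelMap(tissue.astype(np.int16), {1: "body"}, fat.spacing.copy(), fat.origin.copy())
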