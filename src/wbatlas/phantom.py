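"""Synthetic whole-body PET/MR phantom cohort generator.

The generator stands in for a PET/MR cohort acquisition: it builds a crisp
reference phantom (organ label map plus noise-free fat-fraction and FDG
templates), then derives subjects from it through

* a smooth, invertible synthesis deformation (per-organ volumetric scale
  factors blended by distance weighting, a global affine jitter and a
  band-limited random residual field),
* per-subject tissue-value jitter (each tissue's fat fraction and SUV drawn
  around the population mean),
* a global multiplicative PET intensity scale standing in for injected-dose
  and uptake-time variability,
* PET point-spread blurring plus Gaussian noise, MR fraction noise,
* optional implanted hypermetabolic lesions, a fatty-liver override and a
  regional uptake boost, all with ground truth recorded.

The TRUE synthesis field (reference -> subject, obtained by numerically
inverting the generative native -> reference map) is returned separately
from any registration estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import ParameterError, RecipeError, SpecError
from .fields import DisplacementField, invert_field, jacobian, resample_labels
from .grids import (ChannelKind, LabelMap, SubjectDataset, VolumeGrid, smooth_array,
                    write_field, write_subject)

MBQ_TO_BQ = 1.0e6


def suv_to_concentration_factor(weight_kg: float, dose_MBq: float) -> float:
    """Bq/ml per unit SUV: ``dose [Bq] / weight [g]``."""
    return dose_MBq * MBQ_TO_BQ / (weight_kg * 1000.0)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def contains(self, X, Y, Z):
        c, r = self.center, self.radii
        return (((X - c[0]) / r[0]) ** 2 + ((Y - c[1]) / r[1]) ** 2
                + ((Z - c[2]) / r[2]) ** 2) <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, X, Y, Z):
        c = self.center
        return ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) <= self.radius ** 2


@dataclass(frozen=True)
class ZCylinder:
    """Elliptic cylinder with axis along z."""

    center_xy: tuple[float, float]
    radii_xy: tuple[float, float]
    z_range: tuple[float, float]

    def contains(self, X, Y, Z):
        c, r = self.center_xy, self.radii_xy
        inside = (((X - c[0]) / r[0]) ** 2 + ((Y - c[1]) / r[1]) ** 2) <= 1.0
        return inside & (Z >= self.z_range[0]) & (Z <= self.z_range[1])


# ---------------------------------------------------------------------------
# Tissue table and phantom specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tissue:
    """Population tissue parameters: fat fraction (proportion), SUV (g/ml)."""

    name: str
    label: int
    fat_mean: float
    fat_sd: float
    suv_mean: float
    suv_sd: float


# Generator defaults: physiologically ordered (high fat fraction only in
# adipose tissue; low SUV in lungs, adipose and resting muscle; higher SUV in
# cerebellum, liver, spleen and kidney; blood pool in between). They are
# configurable, not measured values.
DEFAULT_TISSUES: tuple[Tissue, ...] = (
    Tissue("body", 1, 0.20, 0.025, 0.60, 0.07),
    Tissue("liver", 2, 0.03, 0.015, 2.20, 0.22),
    Tissue("spleen", 3, 0.03, 0.012, 1.80, 0.18),
    Tissue("lungs", 4, 0.10, 0.020, 0.40, 0.05),
    Tissue("kidneys", 5, 0.03, 0.012, 2.00, 0.20),
    Tissue("psoas", 6, 0.07, 0.020, 0.70, 0.08),
    Tissue("gluteal_adipose", 7, 0.85, 0.050, 0.30, 0.04),
    Tissue("cerebellum", 8, 0.05, 0.015, 4.00, 0.40),
    Tissue("aortic_arch_blood", 9, 0.02, 0.010, 1.70, 0.15),
    Tissue("bone", 10, 0.40, 0.040, 1.20, 0.12),
)


def _default_organs() -> dict[str, tuple]:
    """Organ geometry (mm) on a 256 x 256 x 640 mm whole-body field of view."""
    return {
        "liver": (Ellipsoid((95, 140, 325), (45, 30, 40)),),
        "spleen": (Ellipsoid((175, 140, 330), (20, 16, 22)),),
        "lungs": (Ellipsoid((88, 128, 430), (26, 32, 52)),
                  Ellipsoid((168, 128, 430), (26, 32, 52))),
        "kidneys": (Ellipsoid((90, 165, 255), (16, 14, 24)),
                    Ellipsoid((166, 165, 255), (16, 14, 24))),
        "psoas": (ZCylinder((110, 120), (13, 13), (175, 270)),
                  ZCylinder((146, 120), (13, 13), (175, 270))),
        "gluteal_adipose": (Ellipsoid((128, 185, 140), (42, 18, 38)),),
        "cerebellum": (Ellipsoid((128, 140, 545), (28, 22, 16)),),
        "aortic_arch_blood": (ZCylinder((128, 128), (9, 9), (430, 480)),),
    }


def _default_bone_segments() -> dict[str, tuple]:
    return {
        "spine": (ZCylinder((128, 95), (9, 9), (180, 500)),),
        "femur_left": (ZCylinder((100, 128), (10, 10), (40, 170)),),
        "femur_right": (ZCylinder((156, 128), (10, 10), (40, 170)),),
        "humeral_head_left": (Sphere((50, 128, 470), 11),),
        "humeral_head_right": (Sphere((206, 128, 470), 11),),
    }


def _default_body() -> tuple:
    return (ZCylinder((128, 128), (95, 80), (40, 520)),
            ZCylinder((128, 128), (22, 22), (505, 521)),   # neck
            Sphere((128, 128, 565), 52))                   # head


#: z-slab (mm) treated as the "legs" for regional uptake manipulations
LEG_Z_RANGE = (40.0, 160.0)


@dataclass
class PhantomSpec:
    """Whole-body phantom specification: grid, geometry and tissue table."""

    shape: tuple[int, int, int] = (64, 64, 160)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tissues: tuple[Tissue, ...] = DEFAULT_TISSUES
    body: tuple = field(default_factory=_default_body)
    organs: dict = field(default_factory=_default_organs)
    bone_segments: dict = field(default_factory=_default_bone_segments)
    psf_fwhm_mm: float = 6.0
    pet_noise_suv: float = 0.05
    mr_noise: float = 0.01
    ref_weight_kg: float = 75.0
    ref_dose_MBq: float = 150.0

    def __post_init__(self):
        for t in self.tissues:
            if t.fat_sd < 0 or t.suv_sd < 0:
                raise SpecError(f"tissue {t.name}: SDs must be >= 0")
            if not 0.0 <= t.fat_mean <= 1.0:
                raise SpecError(f"tissue {t.name}: fat fraction mean outside [0, 1]")
        if self.psf_fwhm_mm < 0 or self.pet_noise_suv < 0 or self.mr_noise < 0:
            raise SpecError("PSF/noise parameters must be >= 0")

    def tissue(self, name: str) -> Tissue:
        for t in self.tissues:
            if t.name == name:
                return t
        raise SpecError(f"unknown tissue {name!r}")

    def label_names(self) -> dict[int, str]:
        return {t.label: t.name for t in self.tissues}

    def world_coordinates(self):
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                for a in range(3)]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def grid(self, data: np.ndarray, kind=ChannelKind.OTHER) -> VolumeGrid:
        return VolumeGrid(data, self.spacing, self.origin, kind)

    # -- painting -----------------------------------------------------------

    def paint_at(self, X, Y, Z, check_overlap: bool = False
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate the continuous phantom geometry at arbitrary world
        coordinates; returns ``(labels, bone_segments)`` arrays.

        Painting at warped coordinates yields exact ground-truth native
        label maps for deformed subjects (the geometry is continuous, so
        sub-voxel boundary shifts are not quantised away).
        """
        out_shape = np.broadcast_shapes(np.shape(X), np.shape(Y), np.shape(Z))
        body = np.zeros(out_shape, dtype=bool)
        for shape in self.body:
            body |= shape.contains(X, Y, Z)
        labels = np.where(body, np.int16(1), np.int16(0))

        count = np.zeros(out_shape, dtype=np.int8) if check_overlap else None
        name_to_label = {t.name: t.label for t in self.tissues}
        for name, shapes in self.organs.items():
            m = np.zeros(out_shape, dtype=bool)
            for shape in shapes:
                m |= shape.contains(X, Y, Z)
            if check_overlap:
                if not m.any():
                    raise SpecError(f"organ {name!r} paints no voxels at this resolution")
                count += m
            labels[m] = name_to_label[name]

        bones = np.zeros(out_shape, dtype=np.int16)
        for i, (name, shapes) in enumerate(self.bone_segments.items(), start=1):
            m = np.zeros(out_shape, dtype=bool)
            for shape in shapes:
                m |= shape.contains(X, Y, Z)
            if check_overlap:
                if not m.any():
                    raise SpecError(f"bone segment {name!r} paints no voxels")
                count += m
            bones[m] = i
            labels[m] = name_to_label["bone"]

        if check_overlap and int(count.max(initial=0)) > 1:
            raise SpecError("overlapping organ definitions in phantom spec")
        return labels, bones

    def bone_names(self) -> dict[int, str]:
        return {i: name for i, name in enumerate(self.bone_segments, start=1)}

    def paint(self) -> tuple[LabelMap, LabelMap]:
        """Paint the organ label map and bone-segment map on the spec grid;
        validates that organ definitions are mutually disjoint."""
        X, Y, Z = self.world_coordinates()
        labels, bones = self.paint_at(X, Y, Z, check_overlap=True)
        lm = LabelMap(labels, self.label_names(), self.spacing, self.origin)
        bm = LabelMap(bones, self.bone_names(), self.spacing, self.origin)
        return lm, bm


def default_spec(**overrides) -> PhantomSpec:
    return PhantomSpec(**overrides)


def coarse_spec(**overrides) -> PhantomSpec:
    """Same anatomy on a 32 x 32 x 80 lattice (8 mm voxels); for fast tests."""
    overrides.setdefault("shape", (32, 32, 80))
    overrides.setdefault("spacing", (8.0, 8.0, 8.0))
    return PhantomSpec(**overrides)


def fine_torso_spec(**overrides) -> PhantomSpec:
    """Torso window (z = 280..478 mm) at 2 mm voxels.

    Sub-centimetre structures are under-resolved on the whole-body 4 mm
    lattice (an 8 mm sphere spans barely two voxels), so size-criterion
    behaviour near the 10 mm boundary is assessed on this finer window.
    Organs lying outside the window are dropped from the dictionary.
    """
    organs = _default_organs()
    for outside in ("kidneys", "psoas", "gluteal_adipose", "cerebellum"):
        organs.pop(outside)
    bones = _default_bone_segments()
    for outside in ("femur_left", "femur_right"):
        bones.pop(outside)
    overrides.setdefault("shape", (128, 128, 100))
    overrides.setdefault("spacing", (2.0, 2.0, 2.0))
    overrides.setdefault("origin", (0.0, 0.0, 280.0))
    overrides.setdefault("organs", organs)
    overrides.setdefault("bone_segments", bones)
    return PhantomSpec(**overrides)


# ---------------------------------------------------------------------------
# Subject recipes
# ---------------------------------------------------------------------------

@dataclass
class WarpParams:
    """Parameters of the smooth synthesis deformation (native -> reference
    map; the ground-truth reference -> native field is its inverse)."""

    organ_scales: dict = field(default_factory=dict)  # name -> volumetric factor
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    global_scale: float = 1.0
    residual_amp_mm: float = 0.0    # RMS magnitude of the random residual
    residual_corr_mm: float = 35.0  # correlation length of the residual
    organ_pad_mm: float = 8.0       # plateau margin around a scaled organ
    organ_tau_mm: float = 25.0      # distance-weight decay beyond the plateau

    @property
    def is_identity(self) -> bool:
        return (not any(abs(s - 1.0) > 0 for s in self.organ_scales.values())
                and all(t == 0 for t in self.translation_mm)
                and self.global_scale == 1.0
                and self.residual_amp_mm == 0.0)


@dataclass
class LesionSpec:
    """A spherical hypermetabolic lesion (native-space center, mm)."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    suv: float

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ParameterError("lesion diameter must be > 0 mm")


@dataclass
class SubjectRecipe:
    subject_id: str
    seed: int
    warp: WarpParams = field(default_factory=WarpParams)
    intensity_scale: float = 1.0
    lesions: tuple = ()
    liver_fat_override: float | None = None
    uptake_boost: tuple | None = None  # (z_min_mm, z_max_mm, delta_suv)
    weight_kg: float = 75.0
    dose_MBq: float = 150.0
    tissue_jitter: bool = True
    noise: bool = True


def uptake_boost_delta(spec: PhantomSpec, n_sd: float, with_jitter: bool = False) -> float:
    """SUV increment equal to ``n_sd`` voxel-wise atlas SDs in soft tissue."""
    var = spec.pet_noise_suv ** 2
    if with_jitter:
        var += spec.tissue("body").suv_sd ** 2
    return float(n_sd * np.sqrt(var))


# ---------------------------------------------------------------------------
# Reference phantom
# ---------------------------------------------------------------------------

def make_reference(spec: PhantomSpec, seed: int = 0) -> tuple[SubjectDataset, LabelMap]:
    """Noise-free template: per-voxel tissue means, full organ dictionary.

    FDG is stored in Bq/ml at the nominal reference weight/dose. The
    ``seed`` argument is part of the interface for symmetry with
    :func:`make_subject`; the template is deterministic.
    """
    labels, bones = spec.paint()
    fat_lut = np.zeros(max(t.label for t in spec.tissues) + 1)
    suv_lut = np.zeros_like(fat_lut)
    for t in spec.tissues:
        fat_lut[t.label] = t.fat_mean
        suv_lut[t.label] = t.suv_mean
    fat = fat_lut[labels.labels]
    suv = suv_lut[labels.labels]
    body = labels.labels > 0
    water = np.where(body, 1.0 - fat, 0.0)
    factor = suv_to_concentration_factor(spec.ref_weight_kg, spec.ref_dose_MBq)
    ref = SubjectDataset(
        subject_id="reference",
        fat=spec.grid(fat, ChannelKind.FRACTION),
        water=spec.grid(water, ChannelKind.FRACTION),
        fdg=spec.grid(suv * factor, ChannelKind.ACTIVITY),
        weight_kg=spec.ref_weight_kg,
        dose_MBq=spec.ref_dose_MBq,
        native_labels=labels,
        native_bones=bones,
        space="reference",
    )
    return ref, labels


# ---------------------------------------------------------------------------
# Synthesis deformation
# ---------------------------------------------------------------------------

def build_synthesis_map(spec: PhantomSpec, warp: WarpParams, labels: LabelMap,
                        rng: np.random.Generator) -> DisplacementField | None:
    """Native -> reference displacement ``v`` realising the recipe warp.

    The generative map is ``subject(y) = reference(y + v(y))``; a per-organ
    volumetric scale ``s`` therefore contributes the *inverse* linear scale
    ``s**(-1/3)`` around the organ centre, on a plateau covering the organ
    plus a margin, decaying smoothly with distance beyond it.
    """
    if warp.is_identity:
        return None
    X, Y, Z = spec.world_coordinates()
    v = np.zeros(spec.shape + (3,), dtype=np.float64)
    coords = (X, Y, Z)

    body = labels.labels > 0
    c_body = ndi.center_of_mass(body)
    c_body_mm = [spec.origin[a] + spec.spacing[a] * c_body[a] for a in range(3)]

    g = warp.global_scale
    t = warp.translation_mm
    if g != 1.0 or any(ti != 0 for ti in t):
        inv_g = 1.0 / g
        for a in range(3):
            v[..., a] += (inv_g - 1.0) * (coords[a] - c_body_mm[a]) - t[a] * inv_g

    for name, s in warp.organ_scales.items():
        if s <= 0:
            raise RecipeError(f"organ scale for {name!r} must be > 0")
        if abs(s - 1.0) < 1e-12:
            continue
        m = labels.mask(name)
        d = ndi.distance_transform_edt(~m, sampling=spec.spacing)
        w = np.exp(-np.maximum(d - warp.organ_pad_mm, 0.0) ** 2
                   / (2.0 * warp.organ_tau_mm ** 2))
        c_o = ndi.center_of_mass(m)
        c_o_mm = [spec.origin[a] + spec.spacing[a] * c_o[a] for a in range(3)]
        lin = s ** (-1.0 / 3.0) - 1.0
        for a in range(3):
            v[..., a] += w * lin * (coords[a] - c_o_mm[a])

    if warp.residual_amp_mm > 0:
        sigma_vox = warp.residual_corr_mm / np.asarray(spec.spacing)
        r = np.stack([smooth_array(rng.standard_normal(spec.shape), sigma_vox)
                      for _ in range(3)], axis=-1)
        rms = float(np.sqrt(np.mean(np.sum(r ** 2, axis=-1))))
        if rms > 0:
            v += r * (warp.residual_amp_mm / rms)

    return DisplacementField(v, np.asarray(spec.spacing), np.asarray(spec.origin))


# ---------------------------------------------------------------------------
# Subject synthesis
# ---------------------------------------------------------------------------

def _pullback(arr: np.ndarray, v: DisplacementField, order: int) -> np.ndarray:
    from .fields import resample_array
    return resample_array(arr, v, order=order)


def _sphere_mask(spec: PhantomSpec, center_mm, radius_mm) -> np.ndarray:
    X, Y, Z = spec.world_coordinates()
    return ((X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2
            + (Z - center_mm[2]) ** 2) <= radius_mm ** 2


_ERODE = ndi.generate_binary_structure(3, 1)


def make_subject(spec: PhantomSpec, recipe: SubjectRecipe,
                 reference: SubjectDataset) -> tuple[SubjectDataset, DisplacementField]:
    """Synthesise one subject; returns it with the TRUE reference -> native
    synthesis field (numerically inverted generative map) as ground truth.
    """
    rng = np.random.default_rng(recipe.seed)
    labels_ref = reference.native_labels
    v = build_synthesis_map(spec, recipe.warp, labels_ref, rng)

    if v is not None:
        jac = jacobian(v)
        if jac.min_det <= 0:
            raise RecipeError(
                f"recipe {recipe.subject_id!r}: synthesis map is not invertible "
                f"(min det {jac.min_det:.3f})")
        # exact ground-truth native anatomy: continuous geometry at y + v(y)
        X, Y, Z = spec.world_coordinates()
        lab_arr, bone_arr = spec.paint_at(X + v.vectors[..., 0],
                                          Y + v.vectors[..., 1],
                                          Z + v.vectors[..., 2])
        native_labels = LabelMap(lab_arr, spec.label_names(), spec.spacing, spec.origin)
        native_bones = LabelMap(bone_arr, spec.bone_names(), spec.spacing, spec.origin)
        fat = _pullback(reference.fat.data, v, order=1)
        ref_factor = suv_to_concentration_factor(spec.ref_weight_kg, spec.ref_dose_MBq)
        suv = _pullback(reference.fdg.data, v, order=1) / ref_factor
    else:
        native_labels = labels_ref.with_labels(labels_ref.labels.copy())
        native_bones = reference.native_bones.with_labels(reference.native_bones.labels.copy())
        fat = reference.fat.data.copy()
        suv = reference.fdg.data / suv_to_concentration_factor(
            spec.ref_weight_kg, spec.ref_dose_MBq)

    body = native_labels.labels > 0

    if recipe.tissue_jitter:
        max_label = max(t.label for t in spec.tissues)
        dfat = np.zeros(max_label + 1)
        dsuv = np.zeros(max_label + 1)
        for t in spec.tissues:
            dfat[t.label] = rng.normal(0.0, t.fat_sd) if t.fat_sd > 0 else 0.0
            dsuv[t.label] = rng.normal(0.0, t.suv_sd) if t.suv_sd > 0 else 0.0
        fat = fat + np.where(body, dfat[native_labels.labels], 0.0)
        suv = suv + np.where(body, dsuv[native_labels.labels], 0.0)

    if recipe.liver_fat_override is not None:
        fat = np.where(native_labels.labels == native_labels.id_of("liver"),
                       recipe.liver_fat_override, fat)

    lesion_masks: list[np.ndarray] = []
    for les in recipe.lesions:
        m = _sphere_mask(spec, les.center_mm, les.diameter_mm / 2.0)
        if not m.any():
            raise RecipeError(f"lesion at {les.center_mm} paints no voxels")
        suv = np.where(m, les.suv, suv)
        fat = np.where(m, 0.10, fat)   # lesions are water-dominant
        lesion_masks.append(m)

    if recipe.uptake_boost is not None:
        z_min, z_max, delta = recipe.uptake_boost
        _, _, Z = spec.world_coordinates()
        slab = body & (np.broadcast_to(Z, spec.shape) >= z_min) \
            & (np.broadcast_to(Z, spec.shape) <= z_max)
        suv = np.where(slab, suv + delta, suv)

    if recipe.noise and spec.mr_noise > 0:
        fat = fat + np.where(body, rng.normal(0.0, spec.mr_noise, spec.shape), 0.0)
    fat = np.clip(fat, 0.0, 1.0)
    fat = np.where(body, fat, 0.0)
    water = np.where(body, 1.0 - fat, 0.0)
    suv = np.where(body, np.maximum(suv, 0.0), 0.0)

    factor = suv_to_concentration_factor(recipe.weight_kg, recipe.dose_MBq)
    conc = suv * factor * recipe.intensity_scale
    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * (1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))) \
            / np.asarray(spec.spacing)
        conc = smooth_array(conc, sigma_vox)
    if recipe.noise and spec.pet_noise_suv > 0:
        conc = conc + rng.normal(0.0, spec.pet_noise_suv * factor, spec.shape)

    subject = SubjectDataset(
        subject_id=recipe.subject_id,
        fat=spec.grid(fat, ChannelKind.FRACTION),
        water=spec.grid(water, ChannelKind.FRACTION),
        fdg=spec.grid(conc, ChannelKind.ACTIVITY),
        weight_kg=recipe.weight_kg,
        dose_MBq=recipe.dose_MBq,
        native_labels=native_labels,
        native_bones=native_bones,
        space="native",
        meta={"intensity_scale": recipe.intensity_scale, "seed": recipe.seed},
    )

    # ground-truth lesion records, measured on the final image like a reader
    from .anomaly import LesionRecord
    suv_image = conc / factor
    liver = ndi.binary_erosion(native_labels.labels == native_labels.id_of("liver"),
                               _ERODE)
    liver_mean = float(suv_image[liver].mean()) if liver.any() else float("nan")
    vox_ml = spec.grid(conc).voxel_volume_ml
    for i, (les, m) in enumerate(zip(recipe.lesions, lesion_masks), start=1):
        vol_ml = float(m.sum()) * vox_ml
        rec = LesionRecord(
            lesion_id=f"{recipe.subject_id}-gt{i}",
            voxels=np.flatnonzero(m),
            volume_ml=vol_ml,
            equivalent_diameter_mm=float((6.0 * vol_ml * 1000.0 / np.pi) ** (1.0 / 3.0)),
            mean_normalized=float("nan"),
            suv_mean=float(suv_image[m].mean()),
            suv_max=float(suv_image[m].max()),
            passes_size=None,
            passes_uptake=None,
            source="ground_truth",
        )
        rec.passes_size = rec.equivalent_diameter_mm > 10.0
        rec.passes_uptake = rec.suv_mean > liver_mean
        subject.truth_lesions.append(rec)

    if v is not None:
        true_field, _ = invert_field(v, max_iters=80, tol_voxel=0.02)
    else:
        true_field = DisplacementField(np.zeros(spec.shape + (3,)),
                                       np.asarray(spec.spacing), np.asarray(spec.origin))
    return subject, true_field


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    spec: PhantomSpec
    reference: SubjectDataset
    labels: LabelMap
    bones: LabelMap
    subjects: list
    true_fields: list
    recipes: list
    manifest: pd.DataFrame


def make_cohort(spec: PhantomSpec, n_subjects: int, seed: int,
                lesion_plan: dict[int, list] | None = None,
                recipe_overrides: dict[int, dict] | None = None,
                warp: bool = True, tissue_jitter: bool = True, noise: bool = True,
                intensity_scale_range: tuple[float, float] = (0.7, 1.3),
                reference: tuple[SubjectDataset, LabelMap] | None = None) -> Cohort:
    """Generate a reproducible cohort of subjects plus a recipe manifest.

    Per-subject sub-seeds derive deterministically from ``seed``; running
    twice with the same arguments yields identical volumes and manifests.
    Healthy subjects draw their per-tissue values from the spec's tissue
    means/SDs (via ``tissue_jitter``); ``lesion_plan`` maps subject index to
    implanted lesions and ``recipe_overrides`` patches any recipe field.
    """
    if n_subjects < 2:
        raise ParameterError("a cohort needs at least 2 subjects")
    master = np.random.default_rng(seed)
    ref, labels = reference if reference is not None else make_reference(spec)
    bones = ref.native_bones
    lesion_plan = lesion_plan or {}
    recipe_overrides = recipe_overrides or {}

    subjects, fields_, recipes, rows = [], [], [], []
    for i in range(n_subjects):
        sub_seed = int(master.integers(0, 2 ** 31 - 1))
        weight = float(np.clip(master.normal(75.0, 9.0), 52.0, 105.0))
        dose = float(np.clip(master.normal(150.0, 15.0), 100.0, 200.0))
        scale = float(master.uniform(*intensity_scale_range))
        if warp:
            wp = WarpParams(
                organ_scales={"liver": float(np.exp(master.normal(0.0, 0.05))),
                              "spleen": float(np.exp(master.normal(0.0, 0.05)))},
                translation_mm=tuple(master.normal(0.0, 2.5, 3)),
                global_scale=float(np.exp(master.normal(0.0, 0.015))),
                residual_amp_mm=3.0,
                residual_corr_mm=35.0,
            )
        else:
            wp = WarpParams()
        recipe = SubjectRecipe(
            subject_id=f"s{i:02d}", seed=sub_seed, warp=wp, intensity_scale=scale,
            lesions=tuple(lesion_plan.get(i, ())), weight_kg=weight, dose_MBq=dose,
            tissue_jitter=tissue_jitter, noise=noise,
        )
        for k, val in recipe_overrides.get(i, {}).items():
            setattr(recipe, k, val)
        sub, tf = make_subject(spec, recipe, ref)
        subjects.append(sub)
        fields_.append(tf)
        recipes.append(recipe)
        rows.append({
            "subject_id": recipe.subject_id, "seed": recipe.seed,
            "weight_kg": recipe.weight_kg, "dose_MBq": recipe.dose_MBq,
            "intensity_scale": recipe.intensity_scale,
            "global_scale": recipe.warp.global_scale,
            "translation_mm": json.dumps(list(np.round(recipe.warp.translation_mm, 6))),
            "organ_scales": json.dumps({k: round(v, 6) for k, v in
                                        recipe.warp.organ_scales.items()}),
            "residual_amp_mm": recipe.warp.residual_amp_mm,
            "residual_corr_mm": recipe.warp.residual_corr_mm,
            "tissue_jitter": recipe.tissue_jitter, "noise": recipe.noise,
            "liver_fat_override": recipe.liver_fat_override,
            "uptake_boost": json.dumps(recipe.uptake_boost) if recipe.uptake_boost else None,
            "n_lesions": len(recipe.lesions),
            "lesions": json.dumps([{"center_mm": list(l.center_mm),
                                    "diameter_mm": l.diameter_mm, "suv": l.suv}
                                   for l in recipe.lesions]),
        })

    manifest = pd.DataFrame(rows)
    return Cohort(spec=spec, reference=ref, labels=labels, bones=bones,
                  subjects=subjects, true_fields=fields_, recipes=recipes,
                  manifest=manifest)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_subject(cohort.reference, out / "reference")
    for sub, fld in zip(cohort.subjects, cohort.true_fields):
        write_subject(sub, out / sub.subject_id)
        write_field(fld, out / sub.subject_id / "true_field.nii.gz")
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
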