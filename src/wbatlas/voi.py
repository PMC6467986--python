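"""VOI statistics, Jacobian-based organ volumetry and the native-vs-reference
bias test.

VOIs are fixed label maps shipped with the reference phantom; eroding a VOI
by one voxel emulates drawing volumes away from tissue borders and major
vessels. Organ volumes integrate the Jacobian determinant voxel-wise over
the reference VOI (native volume = sum of voxel volume x det), which reduces
to the mean-determinant formula and is strictly more general.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats

from .errors import DataError
from .fields import DisplacementField, JacobianMap, resample_labels
from .grids import LabelMap, SubjectDataset, VolumeGrid

_ERODE = ndi.generate_binary_structure(3, 1)


def erode_voi(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """One-voxel erosion keeping the VOI off tissue borders; returns the
    original mask when erosion would empty it."""
    if iterations <= 0:
        return mask
    er = ndi.binary_erosion(mask, _ERODE, iterations=iterations)
    return er if er.any() else mask


@dataclass
class VOIMeasurement:
    subject_id: str
    voi: str
    space: str                       # "reference" or "native"
    fat_mean: float
    fat_sd: float
    suv_mean: float
    suv_sd: float
    suv_max: float
    voxel_count: int
    volume_ml: float

    def __post_init__(self):
        if self.voxel_count <= 0:
            raise DataError("VOI measurement over an empty VOI")


def measure_voi(subject: SubjectDataset, voi: LabelMap | np.ndarray, name: str,
                space: str | None = None, erode: int = 0,
                z_slab: tuple[float, float] | None = None,
                suv_volume: VolumeGrid | None = None) -> VOIMeasurement:
    """Mean/SD (fat fraction) and mean/SD/max (SUV) over a VOI.

    ``suv_volume`` overrides the SUV channel (by default ``subject.fdg`` is
    used as-is, so callers pass SUV-converted data for SUV statistics).
    ``z_slab`` optionally restricts the VOI to a world-z interval (mm), the
    analogue of measuring on a fixed number of consecutive slices.
    """
    m = voi.mask(name) if isinstance(voi, LabelMap) else np.asarray(voi, bool)
    if erode:
        m = erode_voi(m, erode)
    if z_slab is not None:
        grid = subject.fat
        z = grid.origin[2] + grid.spacing[2] * np.arange(grid.shape[2])
        keep = (z >= z_slab[0]) & (z <= z_slab[1])
        m = m & keep[None, None, :]
    if not m.any():
        raise DataError(f"VOI {name!r} is empty after restriction")
    fat = np.asarray(subject.fat.data, dtype=np.float64)[m]
    suv_grid = suv_volume if suv_volume is not None else subject.fdg
    suv = np.asarray(suv_grid.data, dtype=np.float64)[m]
    return VOIMeasurement(
        subject_id=subject.subject_id, voi=name,
        space=space or subject.space,
        fat_mean=float(fat.mean()), fat_sd=float(fat.std(ddof=1)) if fat.size > 1 else 0.0,
        suv_mean=float(suv.mean()), suv_sd=float(suv.std(ddof=1)) if suv.size > 1 else 0.0,
        suv_max=float(suv.max()),
        voxel_count=int(m.sum()),
        volume_ml=float(m.sum()) * subject.fat.voxel_volume_ml,
    )


def organ_volume_jacobian(jac: JacobianMap, organ_voi: LabelMap | np.ndarray,
                          name: str | None = None) -> tuple[float, float]:
    """Native-space organ volume from the Jacobian determinant.

    ``volume = sum over reference organ voxels of voxel_volume * det``.
    Returns ``(volume_ml, nonpositive_fraction)``; a non-zero fraction of
    non-positive determinants inside the organ is reported rather than
    raised.
    """
    if isinstance(organ_voi, LabelMap):
        m = organ_voi.mask(name)
    else:
        m = np.asarray(organ_voi, bool)
        if not m.any():
            raise DataError("empty organ VOI")
    det = np.asarray(jac.det.data, dtype=np.float64)[m]
    nonpos = float(np.mean(det <= 0))
    return float(det.sum()) * jac.det.voxel_volume_ml, nonpos


def voi_to_native(voi: LabelMap, inverse_field: DisplacementField) -> LabelMap:
    """Transform reference-space VOIs to native space through the inverse of
    the subject's deformation field (nearest-neighbour)."""
    out = resample_labels(voi, inverse_field)
    if not (out.labels > 0).any():
        raise DataError("transformed VOI set is empty")
    return out


# ---------------------------------------------------------------------------
# Paired native-vs-reference bias test
# ---------------------------------------------------------------------------

def paired_t(differences: np.ndarray) -> tuple[float, float, bool]:
    """Classic paired t on a vector of differences.

    Returns ``(t, p_two_sided, degenerate)``. Zero-variance differences are
    degenerate: identical pairs give ``t = 0, p = 1``; a constant non-zero
    offset is reported as an exact-offset case (``p = 0``).
    """
    d = np.asarray(differences, dtype=np.float64)
    if d.size < 2:
        raise DataError("paired t-test needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0, True
        return float(np.inf * np.sign(d.mean())), 0.0, True
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), d.size - 1)
    return float(t), float(p), False


def native_reference_bias_test(measurements: pd.DataFrame, value_columns=("fat_mean", "suv_mean"),
                               alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-test per VOI and channel between reference- and native-space
    measurements (paired by subject).

    ``measurements`` is the tidy table produced by the pipeline (one row per
    subject x VOI x space). Returns one row per VOI x channel with the mean
    difference (native - reference), t, two-sided p and a significance flag.
    """
    rows = []
    for voi_name, grp in measurements.groupby("voi"):
        ref = grp[grp.space == "reference"].set_index("subject_id")
        nat = grp[grp.space == "native"].set_index("subject_id")
        common = ref.index.intersection(nat.index)
        if len(common) < 2:
            raise DataError(f"VOI {voi_name!r}: fewer than 2 paired subjects")
        for col in value_columns:
            d = (nat.loc[common, col] - ref.loc[common, col]).to_numpy(dtype=float)
            t, p, degenerate = paired_t(d)
            rows.append({"voi": voi_name, "channel": col,
                         "mean_difference": float(d.mean()), "t": t, "p": p,
                         "degenerate": degenerate,
                         "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def measure_cohort(subjects_ref: list[SubjectDataset],
                   subjects_native: list[SubjectDataset],
                   inverse_fields: list[DisplacementField],
                   labels: LabelMap, voi_names: list[str],
                   suv_ref: list[VolumeGrid] | None = None,
                   suv_native: list[VolumeGrid] | None = None,
                   erode: int = 1) -> pd.DataFrame:
    """Tidy measurement table over a cohort in both spaces.

    Reference-space rows use the atlas VOIs directly; native-space rows use
    the VOIs propagated through each subject's inverse field.
    """
    rows = []
    for i, (sr, sn, inv) in enumerate(zip(subjects_ref, subjects_native, inverse_fields)):
        native_voi = voi_to_native(labels, inv)
        for name in voi_names:
            m_ref = measure_voi(sr, labels, name, space="reference", erode=erode,
                                suv_volume=None if suv_ref is None else suv_ref[i])
            m_nat = measure_voi(sn, native_voi, name, space="native", erode=erode,
                                suv_volume=None if suv_native is None else suv_native[i])
            rows.extend([m_ref.__dict__, m_nat.__dict__])
    return pd.DataFrame(rows)
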