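"""SUV computation and mediastinal blood-pool intensity normalisation.

SUV (g/ml) divides the activity concentration by injected dose per body
weight. Blood-pool normalisation divides registered FDG data voxel-wise by
the mean uptake inside the aortic-arch blood VOI of the reference space,
removing global dose / uptake-time scale differences between subjects; the
result is a dimensionless uptake ratio whose blood-pool mean is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError, ParameterError
from .grids import ChannelKind, LabelMap, SubjectDataset, VolumeGrid

BLOOD_POOL_VOI = "aortic_arch_blood"


def to_suv(fdg: VolumeGrid, weight_kg: float, dose_MBq: float) -> VolumeGrid:
    """``SUV(x) = concentration(x) [Bq/ml] / (dose [Bq] / weight [g])``."""
    if weight_kg <= 0 or dose_MBq <= 0:
        raise ParameterError("weight and dose must be positive")
    factor = dose_MBq * 1.0e6 / (weight_kg * 1000.0)
    return fdg.with_data(np.asarray(fdg.data, dtype=np.float64) / factor,
                         ChannelKind.SUV)


@dataclass
class NormalizationResult:
    normalized_fdg: VolumeGrid
    blood_pool_mean: float
    voi_voxel_count: int


def normalize_blood_pool(fdg_reg: VolumeGrid, labels: LabelMap,
                         voi: str = BLOOD_POOL_VOI) -> NormalizationResult:
    """Divide registered FDG data by its mean over the blood-pool VOI.

    Operates on reference-space data (the VOI is defined there only); the
    input may be SUV or Bq/ml — the ratio is identical.
    """
    fdg_reg.require_compatible(
        VolumeGrid(np.empty(labels.shape, dtype=np.float32), labels.spacing, labels.origin),
        "normalize_blood_pool")
    m = labels.mask(voi)
    mean = float(np.asarray(fdg_reg.data, dtype=np.float64)[m].mean())
    if mean <= 0:
        raise NormalizationError(f"blood-pool VOI mean is non-positive ({mean:g})")
    out = fdg_reg.with_data(np.asarray(fdg_reg.data, dtype=np.float64) / mean,
                            ChannelKind.NORMALIZED)
    return NormalizationResult(normalized_fdg=out, blood_pool_mean=mean,
                               voi_voxel_count=int(m.sum()))


def normalize_subject(subject: SubjectDataset, labels: LabelMap) -> NormalizationResult:
    """Normalise a registered subject in place (sets ``normalized_fdg``)."""
    res = normalize_blood_pool(subject.fdg, labels)
    subject.normalized_fdg = res.normalized_fdg
    return res
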