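"""Single-subject voxel-wise anomaly detection against the normative atlas.

Two screening tasks are provided:

* FDG tumour screening — a two-sided single-case t-map of the subject's
  smoothed, blood-pool-normalised FDG data against the atlas, thresholded
  at ``p < alpha`` within the body, 26-connected components, and two
  classification criteria on each detected region: (i) equivalent-sphere
  diameter > 10 mm and (ii) mean FDG uptake above the subject's own mean
  liver uptake (reference liver VOI, eroded one voxel).
* Fat-infiltration screening — a two-sided single-case t-map on the fat
  fraction channel returning a probability map and the ``p < alpha``
  region map, with no further classification.

Detected regions live in reference space; evaluation against ground truth
matches regions by voxel overlap, recording merge events when one detected
region spans several true lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .errors import DataError, ParameterError
from .atlas import Atlas, loo_group_stats, single_case_tmap
from .grids import (ChannelKind, LabelMap, SubjectDataset, VolumeGrid,
                    gaussian_smooth)
from .voi import erode_voi

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def equivalent_diameter_mm(volume_ml: float) -> float:
    """Equivalent-sphere diameter ``(6 V / pi)^(1/3)`` for a volume in ml."""
    return float((6.0 * volume_ml * 1000.0 / np.pi) ** (1.0 / 3.0))


@dataclass
class LesionRecord:
    """One detected or ground-truth connected region (reference space)."""

    lesion_id: str
    voxels: np.ndarray            # flat voxel indices
    volume_ml: float
    equivalent_diameter_mm: float
    mean_normalized: float
    suv_mean: float
    suv_max: float
    passes_size: bool | None
    passes_uptake: bool | None
    source: str                   # "automatic" | "ground_truth"

    @property
    def classified(self) -> bool:
        return bool(self.passes_size) and bool(self.passes_uptake)

    def voxel_set(self) -> set[int]:
        return set(int(i) for i in self.voxels)


@dataclass
class DetectionConfig:
    alpha: float = 0.001
    min_diameter_mm: float = 10.0
    fwhm_voxel_factor: float = 2.0       # subject smoothing, FDG task only
    liver_voi: str = "liver"
    liver_erode: int = 1
    # criterion (ii) reference: the subject's own liver by default;
    # "atlas" switches to the atlas liver mean.
    liver_source: str = "subject"


def _liver_mean(cfg: DetectionConfig, labels: LabelMap, volume: np.ndarray,
                atlas_mean: np.ndarray | None = None) -> float:
    m = erode_voi(labels.mask(cfg.liver_voi), cfg.liver_erode)
    src = volume if cfg.liver_source == "subject" else atlas_mean
    return float(np.asarray(src, dtype=np.float64)[m].mean())


def detect_fdg_anomalies(subject: SubjectDataset, atlas: Atlas, labels: LabelMap,
                         cfg: DetectionConfig | None = None,
                         loo: bool = False) -> list[LesionRecord]:
    """FDG anomaly screening; returns every detected component with its
    classification flags (``classified`` regions pass both criteria).

    The subject must be registered and blood-pool normalised and must not
    be an atlas contributor unless ``loo=True``, in which case the atlas
    statistics are rebuilt with the subject removed.
    """
    cfg = cfg or DetectionConfig()
    if subject.normalized_fdg is None:
        raise DataError("subject is not intensity-normalised")
    if subject.subject_id in atlas.contributor_ids and not loo:
        raise DataError(
            f"subject {subject.subject_id} contributes to the atlas; "
            "use the leave-one-out variant (loo=True)")

    vol = subject.normalized_fdg
    mean, sd = atlas.channel("normalized_fdg")
    n = atlas.n_subjects
    mean_d, sd_d = mean.data, sd.data
    if loo and subject.subject_id in atlas.contributor_ids:
        mean_d, sd_d = loo_group_stats(mean.data, sd.data, n, vol.data)
        n = n - 1

    smoothed = gaussian_smooth(vol, cfg.fwhm_voxel_factor * vol.spacing)
    _, p = single_case_tmap(smoothed, mean.with_data(mean_d), sd.with_data(sd_d),
                            n, two_sided=True)
    body = labels.labels > 0
    sig = (p.data < cfg.alpha) & body
    lab, ncomp = ndi.label(sig, structure=_CONN26)

    liver_mean_norm = _liver_mean(cfg, labels, vol.data,
                                  atlas_mean=mean_d)
    vox_ml = vol.voxel_volume_ml
    norm_data = np.asarray(vol.data, dtype=np.float64)
    if subject.fdg.kind == ChannelKind.SUV:
        suv_data = np.asarray(subject.fdg.data, dtype=np.float64)
    else:  # raw activity: convert with the subject's own weight and dose
        factor = subject.dose_MBq * 1.0e6 / (subject.weight_kg * 1000.0)
        suv_data = np.asarray(subject.fdg.data, dtype=np.float64) / factor

    records: list[LesionRecord] = []
    for comp in range(1, ncomp + 1):
        m = lab == comp
        idx = np.flatnonzero(m)
        volume_ml = idx.size * vox_ml
        mean_norm = float(norm_data[m].mean())
        rec = LesionRecord(
            lesion_id=f"{subject.subject_id}-a{comp}",
            voxels=idx,
            volume_ml=volume_ml,
            equivalent_diameter_mm=equivalent_diameter_mm(volume_ml),
            mean_normalized=mean_norm,
            suv_mean=float(suv_data[m].mean()),
            suv_max=float(suv_data[m].max()),
            passes_size=None, passes_uptake=None,
            source="automatic",
        )
        rec.passes_size = rec.equivalent_diameter_mm > cfg.min_diameter_mm
        rec.passes_uptake = mean_norm > liver_mean_norm
        records.append(rec)
    return records


@dataclass
class FatDetectionConfig:
    alpha: float = 0.05


def detect_fat_anomalies(subject: SubjectDataset, atlas: Atlas, labels: LabelMap,
                         cfg: FatDetectionConfig | None = None
                         ) -> tuple[VolumeGrid, LabelMap]:
    """Fat-fraction anomaly screening: p-map plus ``p < alpha`` region map.

    No size or intensity classification is applied. If the subject is an
    atlas contributor its own volume is removed from the atlas statistics
    (leave-one-out) before testing. ``alpha = 0`` yields an empty region
    map (the p-map is still returned).
    """
    cfg = cfg or FatDetectionConfig()
    mean, sd = atlas.channel("fat_fraction")
    n = atlas.n_subjects
    mean_d, sd_d = mean.data, sd.data
    if subject.subject_id in atlas.contributor_ids:
        mean_d, sd_d = loo_group_stats(mean.data, sd.data, n, subject.fat.data)
        n = n - 1
    _, p = single_case_tmap(subject.fat, mean.with_data(mean_d), sd.with_data(sd_d),
                            n, two_sided=True)
    body = labels.labels > 0
    region = (p.data < cfg.alpha) & body if cfg.alpha > 0 else np.zeros(p.shape, bool)
    region_map = LabelMap(region.astype(np.int16), {1: "fat_anomaly"},
                          p.spacing.copy(), p.origin.copy())
    return p, region_map


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------

@dataclass
class DetectionEvaluation:
    matched_pairs: list[tuple[str, tuple[str, ...]]]
    true_positives: int
    false_positives: int
    false_negatives: int
    merge_events: int
    suvmax_pairs: list[tuple[float, float]]  # (auto, truth) per matched auto
    criteria_applied: bool


def evaluate_detection(auto: list[LesionRecord], truth: list[LesionRecord],
                       criteria_applied: bool = True) -> DetectionEvaluation:
    """Match automatic regions to ground truth by any-voxel overlap.

    One automatic region overlapping several true lesions is a merge event;
    the truth SUVmax of the merged pair is the max over the merged lesions.
    ``criteria_applied`` pre-filters both lists by the size and uptake
    criteria. True-positive counting is per true lesion (a merged detection
    still detects each of its lesions); false positives are unmatched
    automatic regions.
    """
    if criteria_applied:
        auto = [r for r in auto if r.classified]
        truth = [r for r in truth if r.classified]

    truth_sets = [(t, t.voxel_set()) for t in truth]
    matched_truth: set[str] = set()
    pairs: list[tuple[str, tuple[str, ...]]] = []
    suvmax_pairs: list[tuple[float, float]] = []
    merge_events = 0
    fp = 0
    for a in auto:
        a_set = a.voxel_set()
        hits = [t for t, ts in truth_sets if a_set & ts]
        if not hits:
            fp += 1
            continue
        if len(hits) > 1:
            merge_events += 1
        pairs.append((a.lesion_id, tuple(t.lesion_id for t in hits)))
        suvmax_pairs.append((a.suv_max, max(t.suv_max for t in hits)))
        matched_truth.update(t.lesion_id for t in hits)

    tp = len(matched_truth)
    fn = len(truth) - tp
    return DetectionEvaluation(
        matched_pairs=pairs, true_positives=tp, false_positives=fp,
        false_negatives=fn, merge_events=merge_events,
        suvmax_pairs=suvmax_pairs, criteria_applied=criteria_applied)
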