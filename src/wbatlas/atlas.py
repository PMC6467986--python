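"""Voxel-wise normative atlas construction and leave-one-out PET screening.

The atlas holds, for each of the four channels (fat fraction, water
fraction, blood-pool-normalised FDG, log Jacobian determinant), the
voxel-wise sample mean and sample SD (n-1 denominator) over the registered
contributors. The log of the Jacobian determinant is used so that the local
tissue volume channel is approximately normally distributed.

Single-subject comparisons use the singleton-group pooled-variance t
(Crawford-Howell): ``t = (x - mean) / (sd * sqrt(1 + 1/n))`` with ``n - 1``
degrees of freedom — the only well-defined two-sample t with one subject in
the first group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from scipy import stats

from .errors import DataError, ParameterError
from .fields import JacobianMap
from .grids import (ChannelKind, LabelMap, SubjectDataset, VolumeGrid,
                    gaussian_smooth, read_labels, read_volume, write_labels,
                    write_volume)

ATLAS_CHANNELS = ("fat_fraction", "water_fraction", "normalized_fdg", "log_jacobian")

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Atlas:
    """Per-channel voxel-wise mean/SD volumes plus the reference VOI set."""

    means: dict[str, VolumeGrid]
    sds: dict[str, VolumeGrid]
    n_subjects: int
    labels: LabelMap
    contributor_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_subjects < 2:
            raise DataError("an atlas needs at least 2 contributors")

    def channel(self, name: str) -> tuple[VolumeGrid, VolumeGrid]:
        return self.means[name], self.sds[name]

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for ch in self.means:
            write_volume(self.means[ch], d / f"{ch}_mean.nii.gz")
            write_volume(self.sds[ch], d / f"{ch}_sd.nii.gz")
        write_labels(self.labels, d / "labels.nii.gz")
        (d / "atlas.json").write_text(json.dumps(
            {"n_subjects": self.n_subjects, "contributor_ids": self.contributor_ids,
             "channels": list(self.means)}, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "Atlas":
        d = Path(directory)
        meta = json.loads((d / "atlas.json").read_text())
        means = {ch: read_volume(d / f"{ch}_mean.nii.gz") for ch in meta["channels"]}
        sds = {ch: read_volume(d / f"{ch}_sd.nii.gz") for ch in meta["channels"]}
        return cls(means=means, sds=sds, n_subjects=int(meta["n_subjects"]),
                   labels=read_labels(d / "labels.nii.gz"),
                   contributor_ids=list(meta["contributor_ids"]))


def _channel_stack(subjects: list[SubjectDataset], jacobians: list[JacobianMap],
                   channel: str) -> np.ndarray:
    if channel == "fat_fraction":
        vols = [s.fat.data for s in subjects]
    elif channel == "water_fraction":
        vols = [s.water.data for s in subjects]
    elif channel == "normalized_fdg":
        for s in subjects:
            if s.normalized_fdg is None:
                raise DataError(f"subject {s.subject_id}: not intensity-normalised")
        vols = [s.normalized_fdg.data for s in subjects]
    elif channel == "log_jacobian":
        vols = [j.log_det.data for j in jacobians]
    else:
        raise ParameterError(f"unknown atlas channel {channel!r}")
    return np.stack([np.asarray(v, dtype=np.float64) for v in vols])


def build_atlas(subjects: list[SubjectDataset], jacobians: list[JacobianMap],
                labels: LabelMap) -> Atlas:
    """Voxel-wise sample mean and SD per channel over registered, normalised
    contributors (all on the reference grid)."""
    if len(subjects) < 2:
        raise DataError("build_atlas requires at least 2 subjects")
    if len(jacobians) != len(subjects):
        raise DataError("one Jacobian map per subject is required")
    grid0 = subjects[0].fat
    for s in subjects[1:]:
        if not grid0.compatible_with(s.fat):
            raise DataError(f"subject {s.subject_id}: grid mismatch with reference")
    kinds = {"fat_fraction": ChannelKind.FRACTION,
             "water_fraction": ChannelKind.FRACTION,
             "normalized_fdg": ChannelKind.NORMALIZED,
             "log_jacobian": ChannelKind.LOGJAC}
    means, sds = {}, {}
    for ch in ATLAS_CHANNELS:
        stack = _channel_stack(subjects, jacobians, ch)
        means[ch] = grid0.with_data(stack.mean(axis=0), kinds[ch])
        sds[ch] = grid0.with_data(stack.std(axis=0, ddof=1), kinds[ch])
    return Atlas(means=means, sds=sds, n_subjects=len(subjects), labels=labels,
                 contributor_ids=[s.subject_id for s in subjects])


# ---------------------------------------------------------------------------
# Single-case statistics
# ---------------------------------------------------------------------------

def single_case_tmap(subject_vol: VolumeGrid, group_mean: VolumeGrid,
                     group_sd: VolumeGrid, n_group: int, two_sided: bool = True
                     ) -> tuple[VolumeGrid, VolumeGrid]:
    """Crawford-Howell single-case t and p maps against group mean/SD.

    Voxels with ``sd == 0`` get ``p = 1`` where the subject matches the
    group mean exactly and ``p = 0`` elsewhere (degenerate, flagged on the
    returned t-map object as ``n_zero_sd``).
    """
    if n_group < 2:
        raise ParameterError("group size must be >= 2")
    x = np.asarray(subject_vol.data, dtype=np.float64)
    mu = np.asarray(group_mean.data, dtype=np.float64)
    sd = np.asarray(group_sd.data, dtype=np.float64)
    if np.any(sd < 0):
        raise ParameterError("group SD must be >= 0")
    denom = sd * np.sqrt(1.0 + 1.0 / n_group)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (x - mu) / np.where(zero, 1.0, denom))
    df = n_group - 1
    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    p = np.clip(p, 0.0, 1.0)
    exact = np.isclose(x, mu)
    p = np.where(zero, np.where(exact, 1.0, 0.0), p)
    t = np.where(zero & ~exact, np.where(x > mu, np.inf, -np.inf), t)
    t_vol = subject_vol.with_data(t, ChannelKind.OTHER)
    p_vol = subject_vol.with_data(p, ChannelKind.PVALUE)
    t_vol.n_zero_sd = int(np.count_nonzero(zero))  # type: ignore[attr-defined]
    return t_vol, p_vol


def loo_group_stats(mean: np.ndarray, sd: np.ndarray, n: int, x: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out group mean/SD after removing contributor ``x``."""
    if n < 3:
        raise ParameterError("leave-one-out statistics need n >= 3")
    mean = np.asarray(mean, dtype=np.float64)
    sd = np.asarray(sd, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    loo_mean = (n * mean - x) / (n - 1)
    ss = (n - 1) * sd ** 2 + n * mean ** 2  # sum of squares of the full group
    loo_ss = ss - x ** 2 - (n - 1) * loo_mean ** 2
    loo_var = np.maximum(loo_ss, 0.0) / (n - 2)
    return loo_mean, np.sqrt(loo_var)


# ---------------------------------------------------------------------------
# Cluster-extent filter
# ---------------------------------------------------------------------------

def cluster_filter(p: VolumeGrid, alpha: float, min_voxels: int,
                   mask: np.ndarray | LabelMap) -> tuple[LabelMap, dict[int, int]]:
    """Binarise ``p < alpha`` within the mask, 26-connected labelling, and
    drop components smaller than ``min_voxels``; returns the relabelled
    cluster map and per-cluster sizes."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    m = mask.labels > 0 if isinstance(mask, LabelMap) else np.asarray(mask, dtype=bool)
    sig = (np.asarray(p.data) < alpha) & m
    lab, n = ndi.label(sig, structure=_CONN26)
    sizes: dict[int, int] = {}
    out = np.zeros_like(lab)
    next_id = 0
    if n:
        counts = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        for comp, cnt in enumerate(counts, start=1):
            if cnt >= min_voxels:
                next_id += 1
                out[lab == comp] = next_id
                sizes[next_id] = int(cnt)
    names = {i: f"cluster_{i}" for i in sizes}
    return LabelMap(out, names, p.spacing.copy(), p.origin.copy()), sizes


# ---------------------------------------------------------------------------
# Leave-one-out PET bias assessment
# ---------------------------------------------------------------------------

@dataclass
class QCConfig:
    alpha: float = 0.001
    min_voxels: int = 10
    fwhm_voxel_factor: float = 2.0   # subject smoothing FWHM = factor * voxel
    flag_mad_factor: float = 5.0
    flag_rel_factor: float = 2.0     # must also exceed rel_factor * median
    flag_abs_floor: int = 100        # counts below this never flag


@dataclass
class OutlierReport:
    counts: dict[str, int]
    clusters: dict[str, dict[int, int]]
    flagged: list[str]
    config: QCConfig

    def sorted_counts(self) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: kv[1], reverse=True)


def loo_bias_assessment(subjects: list[SubjectDataset], body: np.ndarray | LabelMap,
                        cfg: QCConfig | None = None) -> OutlierReport:
    """Leave-one-out outlier screening of normalised FDG contributors.

    Each subject's (Gaussian-smoothed) normalised FDG map is compared to
    the voxel-wise mean/SD of the remaining subjects with a single-case
    t-test; surviving ``p < alpha`` voxels are cluster-extent filtered and
    the per-subject total significant-voxel count is the outlier statistic.
    A subject is flagged when its count exceeds
    ``max(median + k * MAD, rel * median, abs_floor)`` over the cohort's
    counts: the MAD term adapts to the cohort spread, the relative term
    guards against MAD collapse when the null counts are tightly grouped,
    and the absolute floor suppresses flags in near-zero-count cohorts.
    """
    cfg = cfg or QCConfig()
    if len(subjects) < 3:
        raise DataError("leave-one-out assessment needs at least 3 subjects")
    body_m = body.labels > 0 if isinstance(body, LabelMap) else np.asarray(body, bool)

    vols = [np.asarray(s.normalized_fdg.data, dtype=np.float64) for s in subjects]
    n = len(vols)
    total = np.sum(vols, axis=0)
    total_sq = np.sum(np.square(vols), axis=0)
    grid0 = subjects[0].normalized_fdg
    fwhm = cfg.fwhm_voxel_factor * grid0.spacing

    counts: dict[str, int] = {}
    clusters: dict[str, dict[int, int]] = {}
    for s, x in zip(subjects, vols):
        loo_mean = (total - x) / (n - 1)
        loo_ss = total_sq - x ** 2 - (n - 1) * loo_mean ** 2
        loo_sd = np.sqrt(np.maximum(loo_ss, 0.0) / (n - 2))
        smoothed = gaussian_smooth(grid0.with_data(x), fwhm)
        _, p = single_case_tmap(smoothed, grid0.with_data(loo_mean),
                                grid0.with_data(loo_sd), n - 1, two_sided=True)
        cmap, sizes = cluster_filter(p, cfg.alpha, cfg.min_voxels, body_m)
        counts[s.subject_id] = int(sum(sizes.values()))
        clusters[s.subject_id] = sizes

    vals = np.array(list(counts.values()), dtype=float)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    threshold = max(med + cfg.flag_mad_factor * mad, cfg.flag_rel_factor * med,
                    float(cfg.flag_abs_floor))
    flagged = [sid for sid, c in counts.items() if c > threshold]
    return OutlierReport(counts=counts, clusters=clusters, flagged=flagged, config=cfg)
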