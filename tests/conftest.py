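"""Shared fixtures: phantom specs, references and expensive session-scoped
pipeline products (a registered known-warp subject, a normative atlas)."""

from __future__ import annotations

import numpy as np
import pytest

import wbatlas as wb

# background-tissue spots at least 20 mm away from every organ, used to
# plant lesions without touching organ boundaries
LESION_SPOTS = [(185, 110, 240), (60, 150, 200), (128, 160, 440),
                (128, 150, 70), (190, 170, 160)]

# (diameter mm, SUV multiple of liver): overtly hypermetabolic lesions,
# 12-20 mm, all >= 3x liver uptake
LESION_PLAN = [(12, 6.0), (14, 5.5), (16, 5.0), (18, 5.0), (20, 5.0),
               (12, 6.0), (14, 5.5), (16, 5.5), (18, 5.0), (20, 5.0)]


def promote_to_reference(sub: wb.SubjectDataset, labels: wb.LabelMap) -> wb.SubjectDataset:
    """Treat an undeformed subject as registered: convert FDG to SUV and
    blood-pool normalise (its anatomy already sits on the reference grid)."""
    sub.space = "reference"
    sub.fdg = wb.to_suv(sub.fdg, sub.weight_kg, sub.dose_MBq)
    wb.normalize_subject(sub, labels)
    return sub


@pytest.fixture(scope="session")
def coarse_ref():
    spec = wb.coarse_spec()
    ref, labels = wb.make_reference(spec)
    return spec, ref, labels


@pytest.fixture(scope="session")
def coarse_ref_nf():
    """Noise-free, PSF-free coarse phantom (null fixture)."""
    spec = wb.coarse_spec(psf_fwhm_mm=0.0, pet_noise_suv=0.0, mr_noise=0.0)
    ref, labels = wb.make_reference(spec)
    return spec, ref, labels


@pytest.fixture(scope="session")
def std_ref():
    spec = wb.default_spec()
    ref, labels = wb.make_reference(spec)
    return spec, ref, labels


@pytest.fixture(scope="session")
def std_ref_nf():
    spec = wb.default_spec(psf_fwhm_mm=0.0, pet_noise_suv=0.0, mr_noise=0.0)
    ref, labels = wb.make_reference(spec)
    return spec, ref, labels


KNOWN_WARP = wb.WarpParams(organ_scales={"liver": 1.2}, translation_mm=(4, 2, -3),
                           global_scale=1.02, residual_amp_mm=3.0,
                           residual_corr_mm=40.0)


@pytest.fixture(scope="session")
def warp_recovery(std_ref_nf):
    """Noise-free subject with a known smooth warp, registered to the
    reference; shared by registration-recovery and volumetry tests."""
    spec, ref, labels = std_ref_nf
    recipe = wb.SubjectRecipe("warped", seed=3, warp=KNOWN_WARP,
                              tissue_jitter=False, noise=False)
    subject, true_field = wb.make_subject(spec, recipe, ref)
    est_field, jac, report = wb.register_subject(subject, ref, labels)
    return {"spec": spec, "ref": ref, "labels": labels, "subject": subject,
            "true_field": true_field, "est_field": est_field, "jac": jac,
            "report": report}


@pytest.fixture(scope="session")
def fdg_atlas(std_ref):
    """Eight-contributor normative atlas (healthy jittered subjects, no
    anatomical warp, PSF and noise on) plus its contributor volumes."""
    spec, ref, labels = std_ref
    cohort = wb.make_cohort(spec, 8, seed=11, warp=False,
                            reference=(ref, labels))
    subs = [promote_to_reference(s, labels) for s in cohort.subjects]
    zero = wb.DisplacementField.zero(ref.fat)
    jacs = [wb.jacobian(zero)] * len(subs)
    atlas = wb.build_atlas(subs, jacs, labels)
    return {"spec": spec, "ref": ref, "labels": labels, "atlas": atlas,
            "subjects": subs}


@pytest.fixture(scope="session")
def fine_torso_atlas():
    """Atlas on the 2 mm torso window, where sub-centimetre lesions are
    properly resolved (size-criterion tests near the 10 mm boundary)."""
    spec = wb.phantom.fine_torso_spec()
    ref, labels = wb.make_reference(spec)
    cohort = wb.make_cohort(spec, 8, seed=11, warp=False,
                            reference=(ref, labels))
    subs = [promote_to_reference(s, labels) for s in cohort.subjects]
    zero = wb.DisplacementField.zero(ref.fat)
    atlas = wb.build_atlas(subs, [wb.jacobian(zero)] * len(subs), labels)
    return {"spec": spec, "ref": ref, "labels": labels, "atlas": atlas}


def make_small_lesion_subject(spec, ref, labels, seed: int) -> wb.SubjectDataset:
    """8 mm lesion at SUV 3.0 on the fine torso grid; noise-controlled
    (jitter-free) so the significant region tracks the lesion geometry."""
    les = wb.LesionSpec((128, 160, 440), 8.0, 3.0)
    recipe = wb.SubjectRecipe("small", seed=seed, lesions=(les,),
                              tissue_jitter=False, noise=True)
    sub, _ = wb.make_subject(spec, recipe, ref)
    return promote_to_reference(sub, labels)


def make_lesion_subject(spec, ref, labels, index: int, diameter: float,
                        suv_mult: float, seed: int) -> wb.SubjectDataset:
    liver_suv = spec.tissue("liver").suv_mean
    les = wb.LesionSpec(LESION_SPOTS[index % len(LESION_SPOTS)], diameter,
                        suv_mult * liver_suv)
    # noise-controlled test subject: tissue values at the population means,
    # so classification margins reflect the lesion rather than the
    # subject's whole-tissue draw
    recipe = wb.SubjectRecipe(f"lesion{index}", seed=seed, lesions=(les,),
                              tissue_jitter=False, noise=True)
    sub, _ = wb.make_subject(spec, recipe, ref)
    return promote_to_reference(sub, labels)
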