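# Methods

## Overview

`wbatlas` builds voxel-wise normative atlases of co-registered whole-body
PET/MR channels and screens single subjects against them. Everything is
exercised on synthetic phantom cohorts because the package's purpose is the
*pipeline* — registration, normalisation, atlas statistics, screening — not
any particular clinical dataset. The phantom generator is first-class code
with ground truth, so every pipeline stage can be validated as a
parameter-recovery problem.

## Coordinate and data conventions

Volumes are 3-D arrays in `(x, y, z)` order with z cranio-caudal, voxel
centres at `origin + index · spacing` (mm). Two grids are compatible when
shape, spacing and origin agree within 1e-6 mm; all voxel-wise operations
require compatibility. Fractions are proportions in `[0, 1]` (percent only
at reporting); fat + water = 1 at body voxels. A displacement field maps a
reference point `x` to the native point `x + u(x)`; the zero field is the
identity. All scalar volumes are NIfTI-1; displacement fields are 4-D NIfTI
with three mm components; subject metadata is one YAML per subject.

## Synthetic phantom cohort

The reference phantom is a 256 × 256 × 640 mm whole-body field of view
(default lattice 64 × 64 × 160 at 4 mm) containing a body envelope with
head and neck, paired lungs, an aortic-arch blood cylinder, liver, spleen,
paired kidneys, paired psoas muscles, gluteal subcutaneous adipose tissue,
cerebellum, and five bone segments (spine, femora, humeral heads), all as
analytic ellipsoids/cylinders validated to be mutually disjoint. Each
tissue has a population fat-fraction and SUV mean/SD; defaults are
physiologically ordered (adipose fat 0.85, liver fat 0.03; cerebellum SUV
4.0 > liver 2.2 > blood 1.7 > muscle 0.6-0.7 > lungs/adipose ≤ 0.4) with
~10 % between-subject SDs. They are configurable conventions, not measured
values.

Subjects derive from the reference through, in order:

1. **Synthesis deformation.** A smooth native→reference map `v` combines a
   global affine jitter (scale about the body centroid, translation),
   per-organ volumetric scale factors (`s` acts as linear factor
   `s^(-1/3)` on a plateau covering the organ plus an 8 mm margin, decaying
   with a 25 mm Gaussian distance weight), and a band-limited Gaussian
   random residual (RMS amplitude 3 mm, correlation length 35 mm in
   cohorts). Invertibility is checked numerically (`det(I+∇v) > 0`
   everywhere, else the recipe is rejected). Channels are linear pull-backs
   of the reference through `v`; ground-truth native labels are painted
   *analytically* at the warped coordinates, so sub-voxel boundary shifts
   are not quantised away — a liver scale of 1.2 changes the native label
   volume by 1.19-1.20 on the 4 mm lattice. The TRUE reference→native
   field is the numerical inverse of `v` and is stored separately from any
   registration estimate.
2. **Tissue-value jitter.** Per-subject per-tissue offsets drawn from the
   population SDs (switchable).
3. **Abnormalities.** Spherical hypermetabolic lesions (FDG set to the
   lesion SUV, water-dominant fractions), a liver fat override, and a
   regional z-slab uptake boost (used to emulate elevated leg-muscle
   uptake).
4. **Acquisition effects.** SUV → Bq/ml conversion with the subject's
   weight/dose, a global multiplicative PET intensity scale (uniform
   0.7-1.3 in cohorts, standing in for dose/uptake-time variability), PET
   point-spread blurring (6 mm FWHM), additive Gaussian PET noise
   (0.05 SUV) and MR fraction noise (0.01), clamped to `[0, 1]` with
   water = 1 − fat inside the body; air stays zero in all channels.

Ground-truth lesion records are measured on the final image (as a reader
would), so PSF suppression of small-lesion SUVmax is part of the truth.

What the generator does **not** emulate: MR physics and artefacts,
respiratory motion, arm-position variation, tracer kinetics, non-Gaussian
PET noise, and real anatomical topology (organs are smooth primitives).
Passing tests therefore demonstrate the pipeline's statistical and
geometric correctness under controlled conditions, not clinical
performance.

## Registration

Stage 1 aligns each reference bone segment to the subject by its centroid
shift (mask-driven; the synthesis model contains no rotational component,
so the centroid translation is the rigid fit; rotation estimation is
deliberately omitted) and blends per-segment displacements by
inverse-square-distance weighting, with segment voxels carrying exactly
their own displacement. Stages 2-3 refine the field with a demons scheme on
the water then the fat fraction channel: symmetric intensity-difference
forces `δu = (f−m∘u)·ḡ/(|ḡ|² + (f−m∘u)²/L²)` capped at 2 mm, Gaussian
smoothing of both update and field every iteration, multi-resolution
(decimation factors 4/2/1, anti-aliased strided sampling so lattices stay
aligned), and a hard-constraint reset of the field to the bone-stage values
on bone voxels after every iteration — the final field is bit-identical to
the bone field there. Water-stage field smoothing (8 mm sigma) is twice the
fat stage's (4 mm), encoding the assumption that lean tissue deforms more
homogeneously than adipose tissue; smoothing sigmas are floored at ~1 voxel
so that coarse lattices are never effectively unregularised. Heavy field
smoothing is what keeps the estimate diffeomorphic on these
piecewise-constant images; halving the sigmas produces negative Jacobians
(verified during development). Divergence (mean update > 10× the first)
sets a failure flag; a non-positive Jacobian inside the body flags the
subject for exclusion, the automated proxy of visual registration QC.

On a noise-free 4 mm phantom with a known smooth warp (liver ×1.2, 2 %
global scale, (4, 2, −3) mm translation, 3 mm RMS residual), the test
suite measures a mean endpoint error of ~0.5 voxel, liver volume recovered
by Jacobian integration within 1 %, and body volume conserved within 2 %.

Field calculus: Jacobians use spacing-aware central differences (one-sided
at borders; exact for the quadratic test fields used as oracles);
inversion solves `w = −u∘(id+w)` by fixed-point iteration to a 0.02-voxel
update tolerance and reports the round-trip residual map rather than
trusting convergence; resampling is pull-back interpolation (linear for
scalars, nearest for labels) with zero fill and a validity mask
out-of-domain.

## Normalisation, atlas, screening

Blood-pool normalisation divides registered FDG (SUV or Bq/ml — the ratio
is identical) by its mean over the reference-space aortic-arch VOI,
computed on unsmoothed data. The atlas holds voxel-wise sample mean and SD
(n−1) of fat fraction, water fraction, normalised FDG and the log Jacobian
determinant (logged to symmetrise compression/expansion).

Single-case comparisons use `t = (x−μ)/(σ√(1+1/n))` with df = n−1 — the
singleton-group pooled-variance reading of a two-sample t-test, identical
to the Crawford–Howell statistic. Zero-SD voxels (noise-free fixtures) are
handled explicitly: p = 1 where the subject matches the group mean, else
p = 0, with a count reported. The empirical null false-positive rate at
p < 0.001 sits inside its binomial 99 % CI over >1e5 voxel draws (measured
in the acceptance suite).

The leave-one-out QC screen smooths only the held-out subject (FWHM = 2 ×
voxel; the group maps stay unsmoothed), applies the t-test against the
remaining subjects, keeps p < 0.001 clusters of ≥10 voxels (26-connected)
inside the body mask, and uses the total surviving voxel count as the
outlier statistic. The flag rule is
`count > max(median + 5·MAD, 2·median, 100)`: the MAD term adapts to the
cohort, the 2×median guard protects against MAD collapse when null counts
are tightly grouped, and the floor suppresses flags in near-zero-count
cohorts. The constants are configurable; the source workflow never states
a numeric rule, so this is a documented package choice.

FDG anomaly screening smooths the subject's normalised map (FWHM = 2 ×
voxel), thresholds the two-sided p-map at 0.001 inside the body, takes
26-connected components and classifies each by (i) equivalent-sphere
diameter > 10 mm and (ii) mean uptake above the subject's own liver mean
(reference liver VOI eroded one voxel; an atlas-liver alternative is a
config switch). All components are returned with their flags. Evaluation
matches detections to ground truth by any-voxel overlap, recording merge
events (one detection spanning several true lesions) with the merged
truth SUVmax taken as their maximum. Fat screening returns the p-map and
the p < 0.05 region map with no classification, rebuilding leave-one-out
statistics if the subject contributes to the atlas, and does not smooth
the subject (subject smoothing is a PET-task convention).

## Validation fixture design

Fixture choices that were genuinely open, and why they are what they are:

* **Noise-controlled test subjects.** The planted-anomaly fixtures (lesion
  sensitivity, the 8 mm size-criterion case, fatty liver) draw the test
  subject's tissue values at the population means (PSF and voxel noise
  on). With full tissue jitter, a single whole-tissue draw — e.g. the
  subject's own liver uptake, which sets the classification threshold —
  dominates the margin of the planted effect, and at n = 8 contributors
  the singleton-t tissue-level tails are heavy enough that "100 %
  sensitivity" or "<5 % extra-hepatic voxels" would hold only for
  favourable seeds regardless of implementation. The noise-controlled
  subject isolates what the fixture is testing: recovery of the planted
  effect. Atlas contributors always keep full jitter.
* **Lesion intensities.** Planted classified lesions are 12-20 mm at 5-6×
  liver uptake (SUV 11-13), i.e. overt malignant-range lesions; measured
  over 80 phantoms across 16 atlas seeds: no misses, at most one
  classified false positive per phantom (a cerebellum physiological-uptake
  cluster — the same false-positive source whole-body screening is known
  for).
* **The 8 mm lesion** (detected but failing the size criterion) runs on a
  2 mm torso-window phantom (`fine_torso_spec`). On the 4 mm whole-body
  lattice an 8 mm sphere spans ~2 voxels and the 10 mm equivalent-diameter
  boundary falls between 8 and 9 significant voxels, so voxel-level
  variance in the group SD flips the verdict for a large fraction of seeds
  at every lesion intensity (measured by 40-seed sweeps). At 2 mm the
  significant region is 7.5-7.9 mm across 40 seeds at lesion SUV 3.
* **Outlier screening** uses a noise-only cohort (jitter off) with a
  +5 voxel-SD uptake boost over the leg slab of one subject: the planted
  subject's count (~10⁴ voxels) then separates from null counts (boundary
  shells of a few hundred voxels, systematic and exchangeable across
  subjects) by an order of magnitude, which no count-based rule can
  guarantee under whole-tissue jitter at n = 8.

## Numerical choices

Gaussian smoothing uses sigma = FWHM/(2√(2 ln 2)), zero padding, masks
applied after smoothing; FWHM 0 is the identity. Cluster labelling is
26-connected. Statistics are computed in float64; volumes are stored as
float32 on disk. Cohort sub-seeds derive deterministically from the master
seed; rerunning any pipeline with the same configuration is byte-identical
(timestamps are logged, never written into manifests). Degenerate paired
t-tests (zero-variance differences) return t = 0, p = 1 for identical
pairs and are reported as exact-offset cases otherwise.

## Limitations

The demons registration is a simplified stand-in with the same three-stage
structure, constraint contract and relative regularisation ordering as the
production whole-body method it emulates, not a reimplementation of it;
bone alignment is translation-only. Simulated cohorts share one grid and
one reference anatomy — there is no multi-scanner resampling, no arm
removal, and no groupwise template construction. PET intensities are not
Jacobian-modulated (count concentration, not total counts, is preserved);
the log-Jacobian channel is available for modulation but unused. No
multiple-comparison correction is applied anywhere, by design of the
screening recipe. Performance numbers quoted above are those computed by
the test suite and `scripts/acceptance.py` on synthetic cohorts; nothing
here claims clinical accuracy.
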