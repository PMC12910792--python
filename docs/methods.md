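# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic benchmark does and does not
emulate, and the numerical conventions that make runs reproducible.

## Synthetic tissue fields

The generator (`simgen`) draws, per field: circular nuclei at a chosen
density (nuclei per 100×100 µm), placed by rejection sampling without
overlap and fully inside the field; per nucleus, a condensate count from
a mean/dispersion family (dispersion 0 = deterministic, 1 = Poisson,
\>1 = negative binomial with that variance-to-mean ratio); per condensate,
an area from a log-normal in µm², rasterized as a disk inside its nucleus
without overlapping siblings (an optional `condensate_min_separation_um`
enforces an extra edge-to-edge gap; with the default 0, touching disks are
allowed and merge under blur — deliberately the harder case).  The ideal
scene (nuclei at `nucleus_intensity`, condensates adding
`condensate_peak_intensity`) is blurred by a Gaussian PSF, a linear
background plane is added, and noise is applied as Poisson shot noise at
`noise_gain` photons per intensity unit followed by Gaussian read noise.
Ground truth (32-bit label map plus an object table with id, true area,
centroid, host nucleus) always reflects the pre-blur disks, so "true
area" is unambiguous: label pixel count × pixel size².  Because pixel
centers form a lattice under a uniformly random sub-pixel offset, the
rasterized pixel count is an unbiased estimate of the continuous disk
area, which is what makes the log-normal-mean recovery test exact in
expectation.

Z-stacks reuse one in-focus scene; slice z is additionally blurred by
`defocus_sigma_per_slice_um × |z − z_focus(x,y)|`, where the focal
surface z_focus ramps linearly across the field width, so the left edge
is sharpest in the first slice and the right edge in the last.  The
spatially varying blur is realized by linear interpolation between a bank
of uniformly defocused scenes at integer defocus steps.  Noise is drawn
independently per slice; a 1-slice stack is bit-identical to the
corresponding single plane.

Defaults mirror the acquisition the pipeline targets: 0.173 µm/pixel,
512² fields, background 100 with a gentle gradient, condensate peak 300,
PSF σ 0.2 µm, read noise σ 5, unit photon gain.  The condensate size
distribution — log-mean ln 2 µm², log-sd 0.5 — is a calibration choice
that centers the population on the 1–5 µm² histogram range; no measured
size distribution for this protein is available to fit.  Two density
presets bracket the tissue regimes: sparse (12 nuclei / 100×100 µm,
cerebellum-like fields) and dense (40 nuclei / 100×100 µm,
hippocampus-like, the stress case for false-positive rejection).  The
knockout-like variant multiplies the per-nucleus count mean by 1.4 and
the area log-mean by 0.7 (a 30 % reduction), the "more and smaller"
phenotype the comparison stage is designed to detect.

What the generator does **not** emulate: non-circular or textured
condensates, nuclear heterochromatin texture, autofluorescence,
anisotropic or depth-dependent PSFs, tiled-scan stitching seams, and
chromatic channels.  Passing the recovery tests therefore certifies the
geometric and statistical machinery of the pipeline, not robustness to
every real-tissue artifact.

## Extended depth of field

Sharpness is local population variance in a (2r+1)² window (default
r = 4 px), computed with reflective padding; the per-pixel argmax over
slices selects the focus slice, ties resolving to the lowest index for
determinism.  The three vendor-style parameters are defined
operationally: `smoothing` s median-filters the index map with a
(2s+1)-wide kernel; `contrast_length` L and `reconstruction_factor` f
blend the selected slice with neighbours at |dz| ≤ L using weights f^|dz|
normalized to one (f = 0 is pure slice selection).  Defaults follow the
two acquisition regimes: (L 3, s 5, f 0.05) for sparse tissue and
(L 3, s 2, f 0.01) for dense tissue.  The vendor semantics of these
parameters are proprietary, so only qualitative parity is claimed; the
testable contract is agreement with the brute-force per-pixel variance
argmax and monotone fidelity (the EDF is never worse than the worst
slice against the in-focus ground truth).  Stack registration is out of
scope; `align_stack=True` raises.

A known limitation of variance-based selection: in featureless regions
there is no focus information and the argmax is arbitrary (that is what
the median smoothing is for), and near strong large-scale edges blur can
*increase* windowed variance, so slice selection is only guaranteed
meaningful near fine detail.

## Enhancement

Rolling-ball background subtraction is implemented literally as grayscale
opening with a spherical-cap structuring function of height
√(R² − d²) on the disk d ≤ R (the classical construction; R = 10 px
default), with nearest-edge padding, and the opening subtracted from the
image.  This choice, rather than a popular approximate variant, is pinned
by an exact test against a naive double-loop morphology oracle.  The
difference of Gaussians uses reflective boundaries and 4σ kernel
truncation, σ = 2 and 10 px by default; negative response is clipped at
zero since only bright foci are sought, and the two steps run
sequentially (subtract, then band-pass).

## Segmentation and measurement

The detector is deterministic: foreground = enhanced image above a
threshold (absolute, or median + k·1.4826·MAD inside the ROI, k = 3
default; when clipping has collapsed the MAD to zero the one-sided scale
quantile(0.8413) − median substitutes), seeds = regional maxima ≥ 3 px
apart within the foreground, objects = watershed of the negated enhanced
image from those seeds.  Each watershed object is then trimmed to the
connected pixels at or above 35 % of its enhanced peak.  This refinement
exists because a noise-level global threshold keeps the entire blurred
halo of a spot, inflating the area of a PSF-blurred disk by roughly 2×;
the 35 % fraction was calibrated on the forward optics model (disk → PSF
→ DoG) across 0.5–5 µm² and brings the mean measured area within a few
percent of truth (the plain 50 % FWHM rule under-measures DoG-reshaped
blobs by ~25 %).  Residual size-dependent bias remains at the extremes:
sub-µm² disks are still over-measured, the bound holding for the mean
over the population, not per object.

Objects touching the image border are always dropped (truncated areas);
optionally also objects touching the ROI boundary.  Measurements use
0-based pixel coordinates with centroids at pixel centers; areas are
pixel count × pixel size²; mean intensity is taken on the raw
(pre-enhancement) plane.

## False-positive rejection

In place of a trained object classifier, three auditable rules decide
acceptance; rejected records are retained with their failed rules listed
("area", "solidity", "contrast"):

- area within [0.1, 50] µm² (defaults);
- solidity ≥ 0.75;
- contrast ≥ 1.3, scaled up by `density / max_local_density` when the
  local object density exceeds 8 objects per 100 µm² (density = objects
  whose centroids fall within the circle of area 100 µm²).

Contrast is the object-to-annulus mean intensity ratio over a 3-px
annulus excluding all detected objects, measured on the **raw** plane
whenever it is supplied: on a zero-clipped band-passed image the annulus
of an isolated artifact averages ~0 and the ratio is vacuously infinite,
whereas physical intensities keep the background in the denominator.  On
synthetic fields this statistic separates cleanly — true condensates sit
at contrast ≥ 1.5 in both noise regimes while noise specks and
nucleus-edge artifacts stay ≤ 1.2 — which is what fixes the 1.3 default.

## Group statistics

Accepted areas are histogrammed per subject on half-open bins over fixed
µm² edges (default 1, 2, 3, 4, 5; last bin open; areas below the first
edge excluded from counts but tallied).  The subject — an animal or
field, not a condensate — is the statistical unit.  Per bin, the
subject-level counts of the two groups are compared with an unpaired
two-sided Student t-test (pooled variance; Welch optional by flag), and
the per-bin p-values are Holm–Šídák-adjusted: sort ascending, adjusted
p(i) = running max of 1 − (1 − p(j))^(m−j+1), capped at 1.  Total counts
are a single separate test, reported uncorrected.  Groups in which every
subject has the same count (common in sparse large-area bins) are
handled by convention: equal means give t = 0, p = 1; unequal constant
means give ±∞ and p = 0.

Monte-Carlo checks of this stage run on generator ground truth alone
(per-subject true-area tables, no image processing), which is what makes
100-replicate cohorts at n = 12 per group cheap: at the default sparse
preset the null configuration keeps the family-wise fraction of cohorts
with any adjusted p < 0.05 under 0.10, and the knockout-like alternative
is detected in the 1–2 µm² bin in ≈100 % of cohorts.

## Orchestration and reproducibility

A YAML config carries the image manifest (path, subject, group, optional
ROI mask) plus every stage's parameter block, the pixel size, bin edges,
and a seed.  `run_pipeline` processes each image (EDF only when the file
is multi-page), isolates per-image failures (logged, skipped, listed in
the summary, nonzero CLI exit), and writes records.csv, histograms.csv,
comparison.csv, summary.json and a provenance.json containing the full
config and package version — deliberately no timestamps, so reruns with
the same config and inputs are byte-identical.  All randomness lives in
the generator and is seed-derived (per-field seeds spawned from one
`SeedSequence`); the analysis path contains none.

## Problem sizes used in tests

The test suite and acceptance script use 512² fields for detector
benchmarks (12 fields, ~210–300 objects), 256² stacks for EDF checks,
ground-truth-only cohorts for the 100-replicate statistical studies, and
a 4-image cohort for the end-to-end determinism check; these sizes were
chosen as the smallest at which the measured proportions stabilize.
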