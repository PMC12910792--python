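# specklepipe

Quantification of bright sub-nuclear protein condensates (puncta /
speckles) in fluorescence images of brain tissue, for labs comparing
condensate number and size between two experimental groups — typically a
conditional knockout against wild-type littermates.  The package covers
the full chain from raw Z-stacks to per-bin group statistics, and ships a
synthetic-image generator with exact ground truth so every stage can be
benchmarked.

## The method

For each image the pipeline runs:

1. **Extended depth of field (EDF), variance method.**  A Z-stack is
   collapsed to one all-in-focus plane: per pixel the slice with maximal
   local intensity variance in a (2r+1)² window is selected (ties to the
   lowest slice), the slice-index map is median-smoothed, and the output
   is a normalized blend of the selected slice with its z-neighbours
   within ±`contrast_length` slices, weights decaying by the
   `reconstruction_factor` per step.
2. **Enhancement.**  Rolling-ball background subtraction (grayscale
   opening by a spherical-cap structuring element, radius 10 px) followed
   by a difference-of-Gaussians band-pass, σ = 2 and 10 px:
   `DoG = G₂∗I − G₁₀∗I`.
3. **Segmentation.**  Foreground by a robust threshold (median + k·MAD,
   k = 3, of the enhanced image inside the ROI), seeds from regional
   maxima ≥ 3 px apart, watershed of the inverted enhanced image, and a
   per-object support refinement at 35 % of each object's peak that
   compensates blur-induced area inflation.  Areas are physical:
   `area = pixel_count × p²` with p = 0.173 µm/pixel by default.
4. **False-positive rejection.**  Explicit rules replace a trained object
   classifier: area limits, minimum solidity, and a minimum
   object-to-annulus contrast on the raw plane whose requirement scales
   with local object density (for crowded, hippocampus-like tissue).
   Rejected objects are kept with their reason.
5. **Statistics.**  Accepted areas are binned per subject on fixed µm²
   edges (default 1–5 µm², open last bin).  Per bin, subject-level counts
   are compared between the two groups with an unpaired Student t-test
   (Welch optional) and Holm–Šídák step-down adjustment across bins,
   `p̃₍ᵢ₎ = maxⱼ≤ᵢ [1 − (1 − p₍ⱼ₎)^(m−j+1)]`; total counts are tested
   separately without correction.

A small behavioural utility scores Y-maze spontaneous alternation:
`SAR = alternations / (entries − 2) × 100`, an alternation being an
overlapping triplet of entries into three distinct arms.

## Worked example

```python
import specklepipe as sp

# a wild-type-like field and its knockout-like counterpart
spec_wt = sp.sparse_preset(seed=3)
spec_ko = sp.knockout_variant(spec_wt)   # count x1.4, smaller areas

plane, truth = sp.generate_plane(spec_wt)
enhanced = sp.enhance(plane)
roi = sp.RegionOfInterest.full_field(plane.shape, "cerebellum")
labels, records = sp.segment(enhanced, plane, roi)
records = sp.classify(records, sp.ClassifierRules(), labels, enhanced, raw=plane)
accepted = [r for r in records if r.accepted]
print(len(truth.objects), len(accepted))
print(round(sp.histogram_areas(records).total_count, 1))

# two-group comparison on ground-truth areas at the study sample size
table = sp.cohort_truth_areas(spec_wt, spec_ko, n_per_group=12, seed=3)
comp = sp.compare_groups(sp.histograms_from_table(table))
print(comp.per_bin[["bin_label", "t", "p_raw", "p_adj"]].round(4).to_string(index=False))
```

prints

```
43 42
42
bin_label       t  p_raw  p_adj
    [1,2)  5.3454 0.0000 0.0001
    [2,3) -0.4366 0.6667 0.6667
    [3,4) -1.8559 0.0769 0.2135
    [4,5) -2.7440 0.0118 0.0466
  [5,inf) -1.7353 0.0967 0.2135
```

42 of the 43 simulated condensates are detected and accepted, all with
areas of at least 1 µm².  In the cohort comparison (groups ordered
knockout first), the knockout-like group shows the expected strong excess
of small condensates — adjusted p ≈ 10⁻⁴ in the 1–2 µm² bin — together
with a mild deficit of large ones, the signature of a size shift.

The same stages are available as shell commands:

```bash
specklepipe simulate --n 12 --seed 7 --out cohort/
specklepipe edf --in stack.tif --contrast-length 3 --smoothing 5 \
    --reconstruction-factor 0.05 --out edf.tif
specklepipe enhance --in edf.tif --ball-radius 10 --dog 2 10 --out enhanced.tif
specklepipe segment --enhanced enhanced.tif --raw edf.tif --pixel-size 0.173 --out objects.csv
specklepipe quantify --records objects.csv --bins 1,2,3,4,5 --out hist.csv
specklepipe compare --hist hist.csv --out stats.csv
specklepipe sar --entries A,B,C,B,A
specklepipe run --config pipeline.yaml --seed 7 --out results/
```

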