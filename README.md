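# suvseg — threshold-based PET tumor volumetry on digital phantoms

`suvseg` is a toolkit for studying how well threshold-based PET delineation
recovers the true volume of a lesion.  The setting is PSMA-PET volumetry of
lymph-node metastases in prostate cancer: the PET-derived whole tumor volume
is an emerging imaging biomarker, but it depends entirely on the delineation
rule, and candidate rules disagree.  The package implements the five common
threshold families, an inverse per-lesion threshold solver, a synthetic
lesion-cohort generator with exactly known ground-truth volumes (the stand-in
for a morphological CT reference standard), and the statistics used to
compare the methods.

## The methods

All families segment the voxels inside an ellipsoidal lesion VOI whose SUV
is at least an absolute threshold *t* (inclusive rule, SUV ≥ *t*):

| family | threshold |
| --- | --- |
| fixed | *t* = an absolute SUV (grid 2.5 … 15.0) |
| isocontour | *t* = fraction × SUVmax in the VOI (grid 10% … 75%) |
| liver-relative | *t* = fraction × SUVmean of a 30 mm axial liver disc ROI (45% … 75%) |
| parotid-relative | *t* = fraction × SUVmean of a 10 mm parotid cube ROI (60% … 90%) |
| spleen-relative | *t* = fraction × SUVmean of a 30 mm spleen cube ROI (40% … 70%) |

The segmented volume is `n_voxels × voxel_volume_ml`.  Per family and grid
level, agreement with the reference volume over a cohort is summarized by a
correlation coefficient (Pearson if both samples pass a Shapiro–Wilk
normality test at α = 0.05, Spearman otherwise), r², a two-sided p-value and
Bland–Altman mean difference ± 1.96 SD limits of agreement.  *Backwards
thresholding* inverts the problem per lesion: over the finite set of voxel
SUVs in the VOI it picks the threshold whose volume is closest to the
reference volume; the cohort spread of these thresholds (CoV = 100·sd/mean)
measures how transferable a single cut-off would be.

Phantom images are built by painting an ellipsoidal lesion (homogeneous
uptake) and three background-tissue blocks into soft tissue, blurring with a
2 mm FWHM Gaussian PSF and adding truncated-Gaussian noise.  Ground truth is
the analytic ellipsoid volume, so convergence and recovery are exactly
testable.

## Worked example

```sh
python examples/02_threshold_families.py
```

```
true lesion volume: 4.52 ml

fixed SUV 4.0          ->  4.47 ml  (threshold 4.00)
isocontour 55% SUVmax  ->  4.47 ml  (threshold 8.12)
60% SUV_liver        ->  0.00 ml (threshold 17.33, SUVmean 28.88)
80% SUV_parotis      ->  4.47 ml (threshold 4.86, SUVmean 6.07)
60% SUV_spleen       ->  4.47 ml (threshold 4.56, SUVmean 7.61)
```

A 4.52 ml lesion with peak SUV 14 is recovered almost exactly by any
threshold between soft-tissue uptake and the blurred lesion surface; the
liver-relative rule fails here because this patient's liver SUVmean drew
high (28.9), pushing the threshold above the lesion maximum — exactly the
fragility that background-relative rules suffer when reference-tissue uptake
varies between patients.

`examples/04_full_evaluation.py` sweeps all 43 grid levels on the default
50-case cohort and prints the per-family ranking, e.g. the fixed-threshold
grid peaks strictly inside the grid (SUV 7.5, Spearman r = 0.992 on the
default seed): low thresholds over-segment blurred background, high
thresholds drop low-uptake lesions entirely.

## Command-line pipeline

```sh
suvseg simulate --out cohort/ --seed 1 --n-cases 50
suvseg delineate --cohort cohort/
suvseg evaluate --results cohort/results.csv --truth cohort/ground_truth.csv \
    --backwards cohort/backwards.csv --out eval/ --plots
```

writes NIfTI volumes, ground-truth/geometry CSVs, the long-form results
table, agreement summaries, a method ranking, the backwards-thresholding
summary and a markdown report; every CSV header records the seed and a
configuration hash, and identical configurations produce byte-identical
outputs.

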