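# Methods

## Image and geometry model

A PET image is a 3D array of body-weight SUV values on a regular grid with
per-axis spacing in mm; axis order is (x, y, z) with z axial.  World
coordinates are in mm, voxel indices 0-based, and the origin is the center
of voxel (0, 0, 0).  Regions (ellipsoid lesion VOI, cubic background ROIs,
single-slice circular liver ROI) are defined analytically in world space and
rasterized by voxel-center inclusion: a voxel belongs to a region iff its
center lies inside the closed analytic boundary.  This is deliberately
simpler than partial-volume weighting — membership is binary and exactly
enumerable, so every segmentation count can be checked against a brute-force
loop, and rasterized volume converges to the analytic volume as spacing
shrinks.  The circular liver ROI occupies exactly one axial slice (the slice
whose z center is nearest the ROI center); a planar ROI's thickness on a
voxel grid has to be fixed somehow, and one voxel is the thinnest honest
choice.

Volumes are stored as NIfTI-1 with a diagonal affine; I/O is lossless for
voxel values.  Resampling, registration and DICOM ingestion are out of
scope: each case lives on a single grid.

## Segmentation families

All five families reduce to counting VOI voxels with SUV ≥ t:

* fixed: t given in absolute SUV;
* isocontour: t = fraction × SUVmax inside the VOI;
* background-relative (liver / parotid / spleen): t = fraction × the
  tissue's SUVmean measured in its reference ROI.

The threshold rule is inclusive so that a 100% isocontour always contains
the maximum voxel and the inverse solver operates on a well-defined finite
candidate set.  No connectivity constraint is applied by default: the VOI is
assumed to have been placed to exclude other avid structures, so every
suprathreshold voxel inside it is lesion.  An optional connected-component
mode (26-connectivity, keeping the component that contains the VOI maximum)
is available for VOIs that cannot exclude neighbouring uptake.

The background-relative threshold is multiplicative (fraction × SUVmean),
e.g. "60% SUV_liver" means t = 0.6 × liver SUVmean.

### Backwards (inverse) thresholding

Given a target volume (the reference volume of the lesion), the candidate
thresholds are the unique voxel SUVs inside the VOI; volume(t) is a
non-increasing step function on that set.  The solver returns the candidate
minimizing |volume(t) − target|, breaking ties toward the larger threshold —
the conservative choice, never overshooting the target when two candidates
are equidistant.  Re-applying the returned threshold reproduces the achieved
volume exactly, which the tests assert against exhaustive enumeration.

## Phantom cohort

Each case paints, on a 160 × 160 × 80 mm grid at 2 mm isotropic spacing:
soft tissue everywhere, three cubic background blocks (liver, parotid,
spleen) carrying their reference ROIs, and one ellipsoidal lesion of
homogeneous uptake; then blurs with a Gaussian PSF and adds truncated
Gaussian noise (clipped at 0).  The lesion VOI is the lesion ellipsoid
dilated by 6 mm per axis; blocks are placed so VOI and ROIs never interact
through the blur.

Defaults, fixed once as the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| lesion volume | log-normal, median 3.2 ml, log-sd 0.6, resampled into [1.0, 23.8] ml | matches the reported cohort median and range |
| lesion shape | aspect ratios uniform [1.0, 1.6], min semi-axis ≥ 5 mm | lymph nodes with short-axis diameter ≥ 10 mm |
| lesion peak SUV | uniform [8, 40] | spans low- to high-avidity so fixed, isocontour and background-relative rules give non-identical segmentations |
| background SUVmean | log-normal; median (range): parotid 20.1 (5.8–36.3), liver 11.3 (4.2–25.5), spleen 9.9 (4.7–28.7); sigma set so the 2.5–97.5 percentile span matches the range | positive-valued and right-skewed, as the reported ranges suggest; tissues drawn independently, matching the reported absence of inter-tissue correlation |
| soft tissue SUV | log-normal, median 1.0, range 0.6–1.7 | typical soft-tissue background on PSMA PET |
| PSF | Gaussian, 2 mm FWHM | post-reconstruction smoothing of the emulated protocol |
| noise | additive Gaussian, sd 0.3 SUV, truncated at 0 | desk-scale surrogate for post-reconstruction noise, not a count-statistics model |

Ground truth is the *analytic* ellipsoid volume, not a voxelized mask: the
manual slice-by-slice morphological delineation it stands in for approximates
the true volume, and an analytic truth makes convergence testable.  Lesion
uptake is homogeneous before blurring; intra-lesional heterogeneity is not
modeled.  Seeding uses a named substream per case index, so case *i* is
identical in any cohort of any size with the same seed.

What the phantom does **not** emulate: attenuation, scatter and
reconstruction physics; respiratory motion; lesion shapes other than
ellipsoids; bone or visceral morphology; spill-over from adjacent avid
structures into the VOI.  Passing tests therefore show that the delineation
and evaluation machinery behaves correctly under controlled, known-truth
conditions — not that any particular threshold is clinically optimal.

## Evaluation harness

Per family × level, the PET volumes of all cases are compared with the
reference volumes: the correlation coefficient is Pearson's r if *both*
samples pass the Shapiro–Wilk test at α = 0.05, else Spearman's rho (one
non-normal variable forces the rank-based coefficient); r² is always the
square of the reported coefficient.  Bland–Altman analysis reports mean(d)
and mean(d) ∓ 1.96 sd(d) for d = PET − reference.  The coefficient of
variation is 100 × sample sd / mean; the sample (n−1) standard deviation is
used throughout.  Kruskal–Wallis (tie-corrected, chi-square p) serves for
group comparisons; all-identical input is reported as H = 0, p = 1 rather
than an error.  Ranking takes the argmax of r within each family, ties
toward the lower level.  Reports round r and r² to 3 decimals and volumes
to 1 decimal ml; p-values below 0.001 print as "p<0.001".

The backwards summary reports mean ± sd and CoV of the per-case inverse
thresholds, then re-applies the single cohort-mean threshold to every case
and correlates those volumes with the reference.  If the re-applied volumes
are degenerate (zero variance), the agreement is flagged as undefined rather
than fabricated.

## Pipeline and determinism

The CLI stages communicate only through files: NIfTI volumes plus
comma-separated, '.'-decimal, UTF-8 CSVs whose first line is a comment
recording the seed and a SHA-256 hash of the resolved configuration.  The
evaluation stage consumes only CSVs; because re-applying the cohort-mean
backwards threshold needs the images, the delineation stage performs that
second pass and stores the per-case volume at the mean threshold in
`backwards.csv`.  Identical configurations produce byte-identical CSVs.

## Problem sizes

The default cohort is 50 cases of 80 × 80 × 40 voxels; a full sweep (43 grid
levels × 50 cases) plus the backwards analysis completes in a few seconds.
Oracle-equivalence tests use ~200 randomized grids up to 20³ voxels against
a pure-Python triple-loop counter, and solver-optimality tests enumerate all
candidate thresholds exhaustively on 100 random cases.

## Known limitations

* The evaluation compares volumes only; overlap metrics (Dice, Hausdorff)
  are out of scope because the reference is a volume, not a contour.
* With a mild 2 mm PSF and 2 mm voxels, partial-volume bias is small for
  the ≥ 1 ml lesions generated; conclusions about sub-ml lesions cannot be
  drawn from this phantom.
* The correlation-type gate (Pearson vs Spearman) is a convention of this
  package; reported coefficients for skewed volume distributions are
  typically Spearman's rho.
* No multiple-testing correction is applied across grid levels, mirroring
  the descriptive character of the sweep.
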