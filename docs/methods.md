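# Methods

## The estimand and the paired-hip design

The quantity estimated is the *relative arterial contribution*: the fraction
of a bone region's perfusion supplied by the medial femoral circumflex
artery (MFCA), with the lateral femoral circumflex artery (LFCA) supplying
the complement. The design observes two hips of the same donor under
different infusion conditions:

- **control hip** — contrast infused into both arteries with equal doses,
  so its signal enhancement represents the *total* MFCA + LFCA supply;
- **experimental hip** — contrast infused into exactly one artery
  (randomized), so its enhancement represents that artery's territory alone.

Assuming (i) enhancement is linear in the amount of contrast reaching a
voxel, (ii) equal per-artery doses contribute with equal weight, and
(iii) the two hips of a donor share the same territory anatomy, the ratio of
experimental to control enhancement in a region is exactly the infused
artery's territory fraction. The ratio is clipped to [0, 1] before
conversion to percent: territory fractions are physical proportions, and
measurement noise can push the raw ratio slightly outside the unit interval
(observed cohort medians of exactly 0% and 100% are consistent with such
bounding).

## Signal quantification

Each scan is normalized **independently** by the mean intensity of its own
non-enhancing muscle reference region, using division rather than
subtraction: division makes the normalized volume invariant to a global
scanner gain applied to any single scan, which subtraction is not. The
enhancement of a region of interest is the difference of normalized ROI
means, post minus pre. ROI means are computed as count-weighted means of
per-coronal-slice means — algebraically identical to the plain voxel mean,
and asserted to be so in the tests — because the assessment is defined along
the coronal plane. Per-voxel normalized-difference histograms (bin width
0.01 normalized units) are descriptive output only and feed no downstream
number.

A control-hip enhancement at or below a configurable floor (default 0.05
normalized units) makes the ratio unreliable; the pipeline either raises
(strict QC, default) or flags the estimate `low_control_signal` and excludes
it from aggregation (lenient QC).

## Statistics

Per report cell, cohort MFCA percentages are compared with the LFCA
percentages by a two-sided Mann–Whitney U test with no multiplicity
adjustment, and Shapiro–Wilk (Royston approximation, via SciPy) is available
as a descriptive normality screen that gates nothing. Summary statistics are
mean, sample SD (n−1), median and 25th/75th percentiles with linear
interpolation; LFCA summary columns are exact complements of the MFCA
statistics, which is also what makes the pair sum to 100 without floating-
point slack.

For pooled sample sizes up to 20 the U test's p-value is **exact by complete
enumeration**: every C(n_a+n_b, n_a) assignment of the observed pooled
values is evaluated, two-sided p being the probability mass of assignments
with |U − n_a·n_b/2| at least the observed deviation. Enumeration was chosen
over the classical tie-free recursion because clipped percentages make ties
(0s and 100s) common, and enumeration handles them with no correction. The
implementation works on doubled mid-ranks (always integers), memoizes the
null deviation distribution per rank multiset, and falls back to the tie-
and continuity-corrected normal approximation for larger samples.

**Known property of the replicated design.** Because each specimen's LFCA%
is defined as 100 − MFCA%, the two "groups" entering the unpaired test are
exact mirror images rather than independent samples. Under a true fraction
of 0.5 this inflates the test's type-I error well above the nominal level
(simulation at n = 10 gives a rejection rate near 0.15 at α = 0.05; the
permutation variance n_a·n_b(N+1)/12 understates the mirror-design variance
of U). The package deliberately replicates this procedure rather than
substituting a one-sample/signed-rank analysis, because reproducing the
published analysis is the point; the inflation is surfaced here and in the
type-I-error acceptance test, which documents the behavior at the nominal
band and therefore fails by design under the mirrored procedure.

## The phantom generator

The generator emulates the study conditions so the pipeline is testable by
parameter recovery:

- **Geometry** is schematic: labeled rectangular blocks for GT
  (superolateral), LT (medial mid-level), IT (between them) and ST
  (inferior band), each split anterior/posterior at its y-midplane with
  equal halves, plus a disjoint muscle block. The analysis consumes only
  masks and intensities, so anatomical realism would add nothing testable.
  Axes are fixed as x = medial–lateral, y = anterior–posterior (coronal
  slice index), z = inferior–superior; default spacing (1, 2, 1) mm gives
  2 mm coronal slices.
- **Signals**: flat trabecular baseline 100 (fat suppression modeled as a
  low, flat marrow signal), muscle 100, enhancement amplitude 150 —
  i.e. a control-hip normalized enhancement of 1.5, the high-SNR regime of
  fat-suppressed post-contrast bone imaging. Additive Gaussian noise with
  SD 5 (SNR 20) is the default; a Rician option exists for low-SNR
  magnitude data but the analysis operates far from the Rician regime.
- **Territory truth**: each of the 8 subregions carries an MFCA fraction;
  a smooth random field (Gaussian-filtered white noise, σ = 2 voxels,
  default SD 0.05 fraction units) is added per voxel and clipped to [0, 1]
  to model within-region heterogeneity. Post-contrast bone voxels gain
  amplitude × (w·I_M + (1−w)·I_L) with 0/1 infusion indicators; muscle
  never enhances. Generator linearity (control = sum of the two
  single-artery infusions) is a tested invariant.
- **Cohorts**: default n = 10 specimens with balanced randomization of the
  experimental artery. Per-specimen subregion fractions are drawn from
  independent clipped normals whose default means/SDs are the published
  per-subregion cohort statistics (e.g. ST anterior 0.808 ± 0.212, GT
  anterior 0.503 ± 0.361); the implied region-level means are 0.685 (full
  trochanteric) and 0.525 (GT). The clipped normal is a modeling
  convention — the true between-specimen distribution shape is unknown.
  Note clipping shifts the realized mean of heavily clipped cells by up to
  ~2 percentage points from the nominal mean; the generator's draws are
  tested against the closed-form clipped-normal mean, and recovery is
  always judged against *realized* truth, so this bias cancels there.

What the phantom does **not** model: real vessel geometry, perfusion
kinetics over time (single post-contrast timepoint), registration error
between hips, bias fields, partial-volume effects at region boundaries, or
correlated subregion territories within a specimen. Passing recovery tests
therefore demonstrates correctness of the estimator under the design's
assumptions, not robustness to those real-data complications.

## Numerical and design choices

- Volumes are float64 in memory and float32 on disk (NIfTI-1); re-analyzing
  written volumes reproduces in-memory results to storage precision.
- Mask congruence is required per specimen; contralateral correspondence is
  handled at the region-label level, not by geometric mirroring.
- Percentile method is fixed (linear interpolation); tie-breaks in the U
  test are mid-ranks; all exact-test comparisons are integer arithmetic on
  doubled ranks.
- Degenerate inputs fail loudly: empty muscle or ROI masks, non-positive
  muscle baseline, constant samples in Shapiro–Wilk, grids too small to
  host the region layout, sub-2 cohorts in aggregation.
- Replicate simulation studies (noisy recovery, type-I error, significance
  pattern, and the acceptance script) use a 24×16×32 grid rather than the
  default 64×48×80: grid size only sets per-ROI voxel counts, and at either
  size per-ROI measurement noise (~0.2% of signal) is negligible against
  the between-specimen territory SD, so hundreds of cohorts run in seconds
  without changing what is being tested.
- All randomness flows from one root seed through per-specimen substreams;
  identical seeds give bitwise-identical cohorts.

## Limitations

No multiple-testing correction is applied (replicating the source
procedure) and the unpaired-test-on-complements issue above applies to all
reported p-values. Contributions are relative fractions only — absolute
perfusion (mL/min/100 g) is out of scope, as are inter-rater ROI
reliability, DICOM-series ingestion beyond NIfTI conversion convenience,
and registration/resampling between hips.
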