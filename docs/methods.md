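# Methods

## Scope and data model

`lcmri` quantifies the locus coeruleus (LC) on LC-sensitive brainstem MRI
that has already been brought onto a common 0.5 mm isotropic grid. Spatial
normalization itself (multi-resolution nonlinear registration, MNI warping)
and bias-field estimation are upstream of this package: any registration
tool can be applied before the volumes enter the pipeline, and the simulator
can add a smooth multiplicative bias field to check that the thresholding
stages tolerate one. All volumes are carried as `VolumeGrid` objects —
a 3D array in (x, y, z) order with x increasing toward the subject's left,
z the axial direction, voxel indices 0-based, and mm↔voxel conversions
rounding half away from zero (an 8.5 mm square at 0.5 mm spacing is exactly
17×17 voxels).

## Native-space quantification

The native-space (NS) route reproduces the semi-automatic protocol of
operator-guided LC segmentation with the human steps made deterministic:

1. An `RoiSpec` places the LC search box over the fourth-ventricle floor and
   two reference squares in the ventral pons, identical on every slice of an
   inclusive slice range (emulating software that drags a first-slice
   placement across slices).
2. The threshold is the minimum intensity within the 10 spatially
   interconnected maximum-intensity voxels. "Interconnected" is read as
   26-connectivity in 3D (the most permissive standard adjacency; a
   6-connectivity flag is provided to quantify sensitivity to this choice),
   and the set is built greedily: seed at the global maximum, repeatedly
   absorb the brightest voxel adjacent to the current set, ties broken
   toward the lowest C-order linear index. The greedy construction is a
   design decision — the protocol describes the set, not the algorithm — and
   is cross-checked against an independent oracle implementation in the
   test suite.
3. Voxels at or above the threshold become candidates. Selection is
   inclusive at the threshold because the threshold is itself the intensity
   of a member of the maximum set; a strict rule would discard the very
   voxels that defined it (and would select nothing on a flat plateau).
4. Candidates outside the anatomical-plausibility mask — the package's
   deterministic stand-in for operator vetoes — are permanently removed
   from eligibility and the threshold is recomputed. A round that vetoes
   nothing cannot change the next round's threshold, so the loop stops
   there (or at `max_iter = 50`, in which case the result is flagged as
   non-converged rather than silently truncated).
5. `LC_CR-NS` is the mean intensity of the accepted voxels over the mean
   intensity of both reference squares; `LC_VOX-NS` is the accepted count.
   Whether the original protocol used means, medians or peaks for the two
   intensities is not specified anywhere we know of; the mean is adopted
   and fixed. An empty selection reports a missing contrast ratio, never 0.

The NS count deliberately captures the bright LC core, not the full
nucleus: with a graded intensity profile the connected-maximum threshold
lands near the top of the distribution and only the plateau above it is
kept. Exact whole-structure recovery is therefore only expected (and only
tested) for flat-profile structures.

## Template-space quantification

The template-space (TS) route:

- **Template.** Voxelwise arithmetic mean of the aligned volumes (≥2,
  identical grids enforced; the offending volume is named otherwise).
- **LC mask.** Threshold μ_ROI + 4·σ_ROI, with μ and σ pooled over both
  reference squares across the whole slice span. σ is the population
  standard deviation (divisor N): on ~5000 reference voxels the difference
  from the sample formula is negligible, but the convention must be fixed
  for the threshold to be exactly reproducible. "Exceeding" the threshold
  is strict (>) here — a constant image yields an empty mask, not a full
  one. The supra-threshold set is intersected with the plausibility mask
  and split into left/right at the grid's x-center plane (configurable);
  voxels exactly on an odd-grid midline plane belong to neither side and
  are dropped from the split with a warning.
- **Extraction.** Per side, `LC_CR-TS = [max(LC) − max(Ref)]/max(Ref)` with
  maxima of the subject's intensities over that side's mask voxels and
  reference square; the combined value pools maxima over both sides.
  `LC_VOX-TS` counts side-mask voxels strictly above the subject's own
  μ+4σ threshold computed from the same (propagated) reference ROIs; the
  combined count is the sum of the sides. `LC_CR-TS` is scale-invariant,
  and because both the count's threshold and its intensities scale
  together, so is `LC_VOX-TS`.
- **Probabilistic map.** The per-voxel fraction of subjects whose
  supra-threshold binary map covers the voxel, with a strict cutoff
  (default: keep fractions > 0.10) and a per-slice, per-side table of
  peak-fraction coordinates.

## Mask compatibility

Overlap between a study mask A and a reference mask B uses the LC-atlas
convention: sensitivity |A∩B|/|B|, specificity |A∩B|/|A|, accuracy their
arithmetic mean. An empty mask makes its ratio (and the accuracy) missing
rather than 0/0. Percentages are formatted to one decimal with
round-half-even. Masks are compared on whatever shared grid they are
supplied in; if a caller resamples first, nearest-neighbor interpolation is
required so the masks stay binary.

## Agreement statistics

The statistics stage consumes a wide per-subject table and emits a fixed
set of comparisons: six NS–TS Pearson correlations (LC_CR and LC_VOX ×
combined/left/right — the single NS value is correlated against each TS
side to ask which side it tracks), paired t-tests for TS left-vs-right
differences in CR and VOX, and the left-vs-right reference-intensity test
as a negative control. Variables are Z-standardized (sample SD, divisor
N−1) before the parametric tests; this leaves r and t unchanged and is done
for parity with the descriptive outputs. Shapiro–Wilk statistics are
recorded per variable but not acted on: the pipeline intentionally applies
the check-then-parametric sequence as used in this literature. FDR
(Benjamini–Hochberg) is applied separately to the correlation family and
the paired-test family; the family partition is a design choice, fixed
here. All tests are two-sided at α = 0.05. Degenerate inputs error loudly
(constant vectors, zero-variance differences) with one resolved edge: an
identically-zero difference vector returns t = 0, p = 1 ("no difference
anywhere") instead of 0/0.

## Synthetic cohort generator

The generator emulates the *post-registration* state of an LC study — every
subject already on the common grid — because registration is out of scope.
Defaults, chosen once as the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| `grid_shape` | 64×64×53 | 32×32 mm in-plane, 26.5 mm axially (≈ 12 slices × 2.2 mm resampled to 0.5 mm) |
| `voxel_size_mm` | 0.5 | isotropic template grid |
| `background_mean` | 100 | ventral-pons intensity (arbitrary units) |
| `lc_contrast_true` | (1.30, 1.25) | left/right peak contrast; left > right by default |
| `lc_length_slices` | 17 | tube span (8.5 mm) |
| `lc_radius_mm` | 0.75 | per-slice disc radius → 153 voxels/side, 306 total |
| `rostrocaudal_profile` | 0.4 + 0.6·sin | middle-heavy slice weights in (0, 1], peak at the interior center |
| `radial_profile` | gaussian | taper σ = radius/2, truncated at the radius (a `tophat` option gives flat plateaus) |
| `subject_jitter_sd` | 0.05 | per-subject, per-side contrast jitter |
| `noise_sd` | 2.0 | additive iid Gaussian, i.e. 2% of background |
| `bias_field_amplitude` | 0.0 | optional smooth multiplicative ramp |

Tubes are Gaussian-profile discs around fixed para-midline centerlines
snapped onto voxel centers, so a noise-free subject's peak voxel is exactly
`contrast × background`. Truncating the radial taper at the radius makes
the true voxel set identical to the supra-background set, which is what
lets the noise-free recovery tests assert exact voxel counts. The
plausibility mask is a dilated box around the tubes minus a midline
"fourth ventricle" stripe, so the ventricle veto of the manual protocol has
a deterministic analogue. Everything is drawn from one seeded generator;
fixed seed means bit-identical volumes.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: acquisition physics (pulse sequence, k-space,
coil profiles), spatially correlated or Rician noise, inter-subject
anatomical variability and registration error, partial-volume effects at
the tube boundary, and real pons texture. Two measurement-level simulators
(`simulate_paired_measurements`, `simulate_agreement_table`) generate
biomarker tables directly for power/size studies of the statistics stage,
where the imaging chain would only add cost without adding information.

## Numerical choices

- Ties in the greedy set (seed and growth) break toward the lowest C-order
  linear index; results are exactly reproducible.
- mm→voxel conversions round half away from zero; percentage formatting
  rounds half to even at one decimal.
- NS candidate selection is inclusive (≥) at its threshold; both TS
  thresholds are strict (>). See the route descriptions for why.
- Population σ (divisor N) in the μ+4σ threshold; sample SD (N−1) in
  Z-standardization — each following its own convention.
- NIfTI volumes are written float64; files with missing or singular
  orientation metadata are refused rather than axis-guessed.

## Known limitations

- **Extreme-value bias of the max-based contrast ratio.** Because
  `LC_CR-TS` is built from maxima, iid voxel noise biases it: the reference
  maximum over the pooled 17×17×17-voxel squares sits ≈3.5 noise-SDs above
  the reference mean, while the LC maximum sits only ≈1 SD above the true
  peak (few voxels compete near a tapered peak). At 2% noise this deflates
  a true 0.30 contrast excess to ≈0.23–0.25 — a 15–25% relative shift that
  shrinks as noise decreases and vanishes without noise. It is a property
  of the max-based definition itself, not of this implementation; per-side
  comparisons and correlations, which is how the ratio is used, are
  unaffected in direction. The package reports the faithful quantity and
  documents the bias rather than redefining the estimator.
- The NS voxel count measures the bright LC core, not LC volume.
- Left/right assignment assumes the midline lies at the grid's x-center;
  supply `midline_x` when it does not.
- Operator judgment is modeled as a binary plausibility mask; graded or
  slice-wise expert edits have no analogue here.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run entirely on synthetic data:
cohorts of 30–53 subjects on the 64×64×53 grid for the imaging stages,
200–400 replicate measurement-level simulations at n = 53 for the power and
type-I-error studies, and 100–1000 randomized cases for the oracle
equivalence checks (greedy threshold, overlap counts, Benjamini–Hochberg).
These sizes make the whole suite run in seconds while keeping every
statistical assertion comfortably powered.
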