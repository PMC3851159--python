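# Methods

## The statistic

Regional homogeneity (ReHo) quantifies how synchronously a voxel's BOLD
time series fluctuates with its immediate neighbors. For each in-mask voxel
the package collects the K = 27 series of the voxel plus its 26 cube
neighbors (K = 19 and K = 7 neighborhoods are also supported), ranks each
series independently over the n retained time points (midranks on ties),
and computes Kendall's coefficient of concordance

    W = 12 Σ_i (R_i − R̄)² / (K² (n³ − n)),

where R_i is the sum of ranks at time point i across the K series and R̄
their mean. W ranges from 0 (no agreement) to 1 (identical rankings) and is
invariant under any strictly monotone transform of the series — the
property that makes it robust to scanner scaling. W is algebraically
equivalent to ((K−1) ρ̄ + 1)/K with ρ̄ the mean pairwise Spearman
correlation; the test suite uses that identity, computed independently via
`scipy.stats.spearmanr`, as an oracle.

An optional tie correction subtracts K Σ(t³ − t) over tie groups from the
denominator. It is off by default: the classical formula used throughout
the ReHo literature carries no tie term, and band-passed floating-point
BOLD series are effectively tie-free. Degenerate neighborhoods (all-constant
series, vanishing corrected denominator) are defined as W = 0 and flagged.

**n is the retained series length.** A 128-volume acquisition with 10
equilibration volumes discarded enters the ranking with n = 118. Quoting
the nominal acquisition length in the formula would be inconsistent with
the discard step; the map computation always uses the length of the data it
receives.

**Mask edges.** A voxel whose cubic neighborhood is clipped by the mask can
only be scored on the members present. By default (`min_neighbors = K`)
such partial-cube voxels emit 0, are flagged, and are excluded from the
whole-brain statistics used in standardization — partial cubes have a
different null distribution of W and would bias the normalizing mean. A
permissive mode (`min_neighbors = 14`, say) scores them on the members
available.

**Standardization.** Subject-level maps are standardized before group
comparison, either by dividing by the whole-brain mean W (the default;
in-mask mean becomes exactly 1) or by z-scoring (mean 0, SD 1), the variant
reported to improve normality. Statistics are taken over full-neighborhood
voxels only.

## Preprocessing

The pipeline consumes spatially aligned 4D volumes plus rigid-body motion
traces; realignment and template normalization are upstream concerns. The
default stage order is: discard the first 10 volumes → motion QC gate →
Gaussian smoothing → linear detrend → band-pass 0.01–0.08 Hz.

- **Motion QC**: a subject is rejected if any volume's displacement from
  the first retained volume exceeds 1 mm on any translation axis or 1° on
  any rotation axis. The rule is strict ("more than"): exactly 1.0 passes.
  Displacement is cumulative from reference, not frame-to-frame. Motion
  files use the SPM `rp_*.txt` dialect (rotations in radians on disk,
  converted to degrees on read and logged).
- **Smoothing**: separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in mm
  converted to voxels through the affine scales; zero-padded, with an
  optional in-mask renormalization (off by default) for mask-edge studies.
  Sheared affines are rejected rather than mis-smoothed. Because smoothing
  before the concordance computation inflates local synchrony, the stage is
  configurable: `before_reho` (default, the conventional order),
  `after_reho` (smooth the ReHo map instead), or `off`.
- **Detrend**: per-voxel least-squares line (intercept + slope) removed;
  idempotent.
- **Band-pass**: ideal rectangular filter in the discrete-Fourier domain —
  bins with low − ε ≤ f ≤ high + ε (ε = 1e−9 Hz, for deterministic edge
  behavior) are kept, all others including DC are zeroed. This matches the
  filter of the classical resting-state toolchain rather than an IIR
  design; it is idempotent by construction.

## Group inference

Voxel-wise contrasts use the pooled (equal-variance) two-sample t on
standardized maps, positive t meaning the first-listed group is higher.
Nuisance covariates (age, gender 0/1, education years, anxiety score) are
handled by one of:

- `residualize` (default): fit the covariate model with intercept across
  all subjects per voxel, t-test the residuals, df = n₁ + n₂ − 2. This
  mirrors "regress out the covariates, then compare" and leaves the
  familiar df (e.g. 2.042 at α = 0.05 for 16 + 16 subjects).
- `ancova`: test the group coefficient in the joint linear model,
  df = n₁ + n₂ − 2 − p. Closer to a full-factorial model with covariates.

The two coincide (exactly, up to the df-based variance rescaling) when the
covariates are orthogonal to the group indicator; a test asserts this.
Zero-variance voxels yield t = 0 with a count in the result rather than
NaNs. Demographic summary tables are reconstructed from per-group
(mean, SD, n) triples: one-way ANOVA from the between/within sum-of-squares
decomposition, pooled t, and Pearson chi-square without continuity
correction.

## Cluster-extent correction

Voxel-level thresholding alone does not control the family-wise error of a
whole-brain map; the package combines a per-voxel two-tailed level
(default p < 0.05) with a minimum cluster extent calibrated by Monte-Carlo
simulation. Per iteration: i.i.d. Gaussian noise on the mask grid, Gaussian
smoothing to the assumed spatial FWHM, re-standardization to unit variance
in-mask, two-tailed thresholding at the normal quantile, and recording of
the largest supra-threshold connected component (26-connectivity by
default, matching the 27-voxel neighborhood). The corrected extent at level
α is the smallest s with P(max null cluster ≥ s) ≤ α. Using the
max-cluster null makes this an FWE-style correction, slightly conservative
relative to a per-cluster frequency table.

Noise smoothness can be supplied directly or, by default in the pipeline,
estimated from the maps entering the contrast with a variance-of-gradients
estimator (per axis, FWHM = σ·2√(2 ln 2) with σ² = −1/(4 ln(1 − v_Δ/2v))).
Estimation matters: concordance maps are intrinsically smooth — adjacent
voxels share 18 of 27 member series — so a no-smoothness null would be
anticonservative even for unsmoothed data. Increases and decreases are
clustered and reported separately; each cluster record carries size in
voxels and mm³ (voxel count × |det| of the spatial affine), the signed peak
t, and the peak's voxel and world-mm coordinates.

## Synthetic cohorts

The generator produces the ground truth every downstream stage is tested
against. Each subject's in-mask series is

    y_v(t) = w·s_r(t) + (1 − w)·ε_v(t) + d(t),

with s_r one band-limited (0.01–0.08 Hz, built by frequency-domain
filtering of white noise, then standardized) signal per region, w the
region's per-group synchrony weight (0 outside regions), ε_v i.i.d.
Gaussian noise, and d a linear ramp. Mean regional W is monotone
nondecreasing in w (tested on a w ∈ {0, 0.3, 0.6, 0.9} ladder), so a
between-group difference in w is a recoverable regional effect. Motion
traces are small Gaussian random walks (step SD 0.02 mm / 0.02°,
overridable per subject to produce QC failures); covariates are drawn
independently of group — age U(20, 53) y, education U(9, 17) y, HAMA
U(2, 20), gender Bernoulli(1/2) — with an optional per-group HAMA shift to
exercise the adjustment path under confounding. Everything is reproducible
from (cohort seed, subject index).

Default conditions mirror the emulated acquisition: 128 volumes at TR = 3 s
(6 min 24 s), noise SD 1, drift amplitude 0.5 noise-SD units over the scan
(enough to exercise detrending without dominating the signal).

What the generator does **not** emulate: hemodynamic response shape,
physiological quasi-periodic noise structure, spatial noise correlations
from the scanner, susceptibility artifacts, or anatomical variation between
subjects. Passing the end-to-end suites therefore demonstrates that the
chain of statistics behaves correctly under its stated model — band-limited
synchrony mixed into white noise — not that effect sizes on real cohorts
will match.

## Problem sizes and numerical choices

The stochastic end-to-end suites run two-group cohorts (8 + 8 subjects,
128 acquired / 118 retained frames) on a 24³ grid of 3 mm voxels with a
5×5×5 ground-truth region, 300-iteration nulls per contrast; recovery is
checked over 20 seeds and false-positive control over 50 (the acceptance
script uses 10/20 seeds). At that grid an 8 mm kernel spans 2.7 voxels —
over half the region's width — so these suites run with time-series
smoothing off and rely on the unit-level impulse-response oracle to cover
the smoothing stage. Monte-Carlo calibration uses 1000 iterations on a 20³
mask.

Other choices: voxel indices are 0-based and world coordinates are whatever
the affine encodes (MNI mm for normalized data), with conversion only at
report time; masks must match the functional grid exactly (no silent
resampling); TR absent from a NIfTI header is an error unless supplied
explicitly; cluster records are ordered increases before decreases, then by
descending size with lexicographic peak-index tie-break, so reruns are
byte-identical; the global seed expands to per-stage seeds by a fixed
counter scheme, keeping results independent of subject processing order.

## Known limitations

- Both standardization modes scale or center by whole-brain statistics, so
  a genuinely elevated region slightly depresses the standardized
  background of the affected group — the familiar global-scaling coupling.
  With large focal effects on small masks this can surface as a diffuse
  opposite-signed cluster (examples/05 shows one); the effect shrinks as
  the region-to-brain volume ratio falls toward realistic values.
- The extent threshold is mask- and smoothness-specific; a published voxel
  count (e.g. 389 voxels for one study's intersection mask) is not portable
  to another mask and is treated as configuration output, not a constant.
- The max-cluster null is slightly conservative relative to AlphaSim's
  per-cluster tabulation.
- Welch-type unequal-variance contrasts, nonparametric voxel-wise tests,
  FDR and random-field corrections, and anatomical labeling of cluster
  peaks are out of scope.
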