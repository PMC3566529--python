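# Methods

## The model

`infoconn` quantifies *informational connectivity* (IC): the degree to
which two brain areas' multi-voxel condition information waxes and wanes
together over an fMRI session. The primitive is a per-time-point
**pattern discriminability** value for a voxel set (a seed region or a
roaming searchlight). With leave-one-run-out cross-validation, the
training runs yield one prototype per condition — the arithmetic mean of
that condition's training patterns. For a test time-point with pattern
**x** and correct condition *c*:

```
d = artanh(r_c) − artanh(max_{i≠c} r_i)
```

where `r_c`, `r_i` are Pearson correlations between **x** and the
prototypes. The artanh (Fisher) transform variance-stabilizes the
correlations; the subtraction yields a signed margin whose sign matches
the standard correlation classifier: `d > 0` exactly when the classifier
would label the time-point correctly (a property the test suite checks
over 10⁴ random time-points). Pearson's r is computed by the textbook
formula, which is algebraically identical to the normalized-row-vector dot
product over m−1 used in the correlation-classifier literature; the two
agree to < 1e−12 in tests, making the scaling convention (n vs n−1)
irrelevant.

An IC map correlates the seed's discriminability series against every
searchlight's series with Spearman's rank correlation (average ranks for
ties; a series without rank variation scores 0), placing each rₛ at the
searchlight's central voxel. Spearman is used because discriminability is
a nonlinear margin whose monotone transformations are not meaningful.

The matched **functional connectivity** (FC) baseline takes the seed's
mean activation series over the same time-points and relates it to every
voxel's series (or every searchlight's mean series) as the *partial
correlation* given the nuisance covariates. A GLM beta is the same fit on
a different scale; the partial correlation is stored because group maps of
correlations are Fisher-transformable on the same footing as IC maps.

## Preprocessing contract

Operations, each per voxel and per run: polynomial detrending (least
squares, the fitted component includes the mean), nuisance residualization
(OLS on intercept + regressors; all-zero and linearly dependent columns
dropped with a warning; residuals orthogonal to every retained column),
z-scoring over the run's task *and* rest TRs (sample SD, n−1), and a
condition-label shift (default 2 TRs) that compensates for hemodynamic
delay — shifted labels falling off a run's end are dropped, never wrapped,
so blocks cannot leak across runs. The canonical order is detrend →
residualize → z-score → shift: z-scoring comes last so the data entering
MVPA are exactly zero-mean/unit-variance per run. The steps are also
exposed individually. Zero-variance voxels are zeroed in place (never
dropped) to keep spatial geometry aligned. All TR indices are 0-based.

## Searchlight geometry

Radii are in voxel index units with the Euclidean norm on the index grid,
ignoring voxel anisotropy: a radius-3 sphere has exactly 123 lattice
points, the canonical searchlight volume (boundary inclusive: offsets at
squared norm exactly r² belong to the sphere). Spheres centered near mask
or volume edges are truncated rather than skipped, and the surviving
member count is carried for diagnostics. The whole-brain sweep is
implemented as a sparse membership matrix (searchlights × masked voxels);
all per-sphere Pearson correlations reduce to a handful of sparse-dense
products per cross-validation fold via running sums. The readable
per-voxel-set path is retained and the two implementations are
cross-checked to 1e−10 in the tests.

## Group inference

Per-subject maps are Fisher-transformed and smoothed with a mask-aware
Gaussian: per-axis sigma = (FWHM / voxel size) / (2√(2 ln 2)), computed by
convolving value·mask and mask separately (zero-padded) and dividing, so
out-of-mask voxels are neither read nor written and constant maps are
preserved at edges. Default FWHM is 8 mm.

A voxelwise one-sample t-test against zero (one-sided, positive) is
thresholded at p < 0.001 (configurable). The minimum significant cluster
size comes from a block-permutation null: the seed's series (only) is
shuffled by permuting whole stimulus blocks — within-block order intact,
equal-length blocks exchangeable, optionally only within runs — 100
permuted maps per subject, each passed through the identical
Fisher/smoothing pipeline; 1000 group maps are formed by sampling one
permuted map per subject with replacement; the maximum suprathreshold
cluster size of each forms the null, and the k-th largest (k = α·N, the
50th of 1000 at α = 0.05) is the threshold. Real clusters strictly larger
are significant, matching the "larger than" reading of the order
statistic. Cluster adjacency is face connectivity (6) by default, with
18/26 available; labeling is verified against a brute-force flood fill.
Voxels with zero across-subject variance get t = 0, p = 1.

Searchlights whose sphere shares voxels with the seed correlate with it
trivially (identically 1 at the seed's own center). They are excluded from
the analysis mask *before* smoothing: if they are only dropped at the
cluster stage, their self-correlation plateau leaks through the 8-mm
kernel and produces a spurious all-subjects-positive ring just beyond the
exclusion rim — we observed corrected false positives from exactly this
ring under a global-null simulation. For FC the seed's own voxels are
excluded on the same grounds.

## The synthetic generator

`default_block_design()` emulates a 12-run object-block session: four
conditions, one 9-TR block per condition per run in random order,
separated by 5 TRs of rest (TR 2.5 s; 24-s blocks and 12-s rests land on
9.6 and 4.8 TRs — the generator uses 9 and 5 so that, after the 2-TR label
shift, the bookkeeping is exactly 9 labeled TRs per block, 108 per
condition, 432 per session). Each region carries zero-mean unit-norm
condition patterns (orthogonalized by default; a pairwise-correlation
bound mode exists) and receives, during each block's TRs,

```
base_mean_amplitude · u_g(block)  +  base_snr · s_g(block) · pattern_c
```

plus i.i.d. Gaussian noise (SD 1). The block-wise fluctuation series `s`
(pattern SNR) and `u` (univariate mean) are log-normal with median 1
(log-SD 0.5); regions naming the same coupling group share the series —
the ground truth that IC (for `s`) and FC (for `u`) must recover.
Block-wise fluctuation encodes the assumption that information coupling
operates at block/attentional timescale. Defaults (base_snr 3, amplitude
1, noise 1) put single-searchlight 4-way accuracy near 0.6 and per-subject
seed–partner IC near 0.4 — strong but not ceiling effects at m = 123.

Signal is injected `hemodynamic_delay_trs` (default 2) after the stimulus
labels, so the analysis-side shift re-aligns labels with signal exactly as
the delay compensation intends. There is no HRF convolution and noise is
temporally white; what passing tests show is therefore recovery of
injected coupling under idealized temporal structure, not robustness to
autocorrelated noise or HRF blurring. Condition patterns are redrawn per
subject by default (`patterns_per_subject`): subjects share coarse
functional anatomy but not fine-grained pattern geometry, and fixing
patterns across subjects would turn subject-idiosyncratic stimulus-locked
structure into a consistent group-level pseudo-signal. Nuisance series are
smooth random walks orthogonalized, per run, to the task-support boxcar
(task-uncorrelated motion, the favorable case); they contribute nothing to
the data, and the manifest records every latent series. Generation is
byte-deterministic given (rng_seed, subject index).

The four standard regions instantiate the IC/FC dissociation quadrants:
`seed` (patterns + univariate response), `info_partner` (patterns coupled
to the seed's `s`, flat mean → IC only), `uni_partner` (no patterns, mean
coupled to the seed's `u` → FC only), `independent` (private series →
neither). `decoupled=True` makes every series private — the global-null
configuration used for type-I checks.

## Preprocessing interactions discovered on synthetic data (caveats)

Two pipeline steps, applied to drift-free block-design data, measurably
*create* informational coupling between regions that share nothing but the
stimulus timing:

1. **Polynomial detrending** (order ≥ 1): the per-run fit of each voxel's
   boxcar signal depends on the run's block arrangement, injecting a
   stimulus-locked pattern contamination common to all signal-bearing
   regions. Measured effect: ≈ +0.06 to +0.10 Spearman between otherwise
   independent regions' discriminability series, absent when comparing
   across subjects.
2. **Nuisance residualization** against shared regressors: projection onto
   a common random subspace modulates the per-TR magnitude of pattern
   contamination (projection leverage) identically everywhere; the
   nonlinear discriminability metric converts this into a shared temporal
   modulation worth ≈ +0.11 Spearman — even when the regressors are
   exactly task-orthogonal.

Because the block-permutation null destroys the temporal alignment that
carries both effects, they inflate corrected detections. On real data
these steps remove real artifacts (scanner drift, motion) and the
trade-off is unavoidable — users should know that IC between regions that
both respond to the task can be partly pipeline-induced. The synthetic
validation analyses (examples, recovery and type-I tests) therefore run
with detrend order 0 and without data residualization: the generator's
data contain no drift and its regressors carry no signal, so those steps
would remove nothing real while adding the biases above. Both operations
remain fully implemented, tested, and default-on for real data.

## Numerical choices

- Correlations are clipped to ±(1 − 1e−7) before artanh so a test pattern
  identical to a prototype stays finite.
- Degenerate (zero-variance) test patterns: discriminability 0, prediction
  counted incorrect, logged. Degenerate correlations (constant series,
  zero rank variance, zero residual variance) are defined as 0.
- Classifier ties break toward the condition earliest in sorted order —
  measure-zero on continuous data, deterministic on constructed inputs.
- The Fisher transform refuses to run twice on the same map.
- `corrected_min_cluster` requires round(α·N) ≥ 1 and is non-increasing
  in α.
- One integer seed drives everything: the generator derives per-subject
  streams via `SeedSequence([rng_seed, subject_index])`, and group
  inference threads a single `Generator` through permutation and
  resampling, making end-to-end runs bit-reproducible.

## Problem sizes used in validation

The validation suite runs the full design at a 20³-voxel volume with
123-voxel spherical regions: 10 subjects for recovery/dissociation, 100
block permutations per subject resampled into 200 null group maps, and 8
independent global-null replicates for the type-I check. Unit tests use a
12³ two-region session with radius-2 spheres and 4 runs. These sizes were
fixed as the package's standard validation conditions; the statistical
thresholds (p < 0.001 voxelwise, α = 0.05 cluster-corrected) are the
method's reference values.

## Known limitations

- No HRF model: the generator's delay-and-inject scheme matches the label
  shift by construction; real hemodynamics blur block boundaries.
- White noise only by default; temporally autocorrelated noise would widen
  the discriminability series' effective sampling interval and is not
  exercised by the shipped tests.
- The block permutation assumes equal-length exchangeable blocks; sessions
  with heterogeneous block lengths permute only within matching-length
  groups, which reduces the effective null space.
- Linear-trend-free validation data (see caveats above): the shipped
  validation evidence does not cover the detrend/residualization
  interactions it documents.
- Spherical searchlights on the index grid ignore voxel anisotropy (a
  "3-voxel radius" means grid units, not millimetres).
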