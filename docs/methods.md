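# Methods

## Model and procedure

The pipeline treats each preprocessed, masked BOLD run as a bag of
N-voxel frame vectors sampled every TR seconds. The working model is that
spontaneous activity visits a small set of recurring whole-brain states;
a frame expresses the spatial pattern of its current state plus noise.
Analysis proceeds per frequency band:

1. **Temporal preprocessing.** Per voxel: linear detrend, zero-phase
   bandpass into LFO (0.01–0.1 Hz), slow-5 (0.01–0.027 Hz) or slow-4
   (0.027–0.073 Hz), then optional regression of white-matter/CSF mean
   signals. At TR = 3 s the Nyquist frequency is ≈0.167 Hz, so all three
   bands are admissible.
2. **Frame matrix.** All subjects' frames are stacked (frames × voxels)
   and each frame is z-scored across voxels. For standardized rows,
   squared Euclidean distance is a monotone function of 1 − spatial
   Pearson correlation, so k-means on these rows clusters by pattern
   similarity rather than amplitude.
3. **Exemplar selection.** Per subject, the spatial variance of each
   frame is computed and frames at interior local maxima
   (`v[t−1] < v[t] ≥ v[t+1]`) are kept as exemplars — the moments where a
   coactivation event is most strongly expressed. Counts are clamped to
   10–15 per subject: surplus maxima are dropped lowest-variance-first;
   deficits are padded with the highest-variance non-maximum frames,
   flagged as padding.
4. **Two-stage clustering.** k-means with many random restarts
   (k-means++ seeding, Lloyd to convergence) on the pooled exemplars;
   the winning centroids initialize a single Lloyd pass over all frames.
   Centroids are recomputed as exact member means. The exemplar stage
   makes the full-data pass cheap and stable; restarts only need to pay
   the cost of the (much smaller) exemplar matrix.
5. **Model selection.** Mean Euclidean silhouette on the exemplar frames
   for each candidate k (default 2–20, configurable); maximal silhouette
   wins, ties to smaller k. Silhouette is computed on exemplars rather
   than all frames for tractability.
6. **Numbering and maps.** CAPs are renumbered by decreasing occurrence
   among control subjects (ties by internal cluster id), so CAP 1 is the
   most frequent control state. Each centroid is z-scored across voxels
   (sample SD) and thresholded at |z| > 1.5 into a +1/0/−1 map.
7. **Dynamics.** Occurrence, entry count (maximal runs), entry rate per
   minute (count·60/(T·TR)), mean duration in frames and seconds, and the
   row-normalized transition matrix, per subject × band × state. States
   never visited report missing (not zero) duration so group means are
   not biased toward zero; their occurrence is 0. The conservation
   identity occurrence·T = entries·duration holds exactly for visited
   states and is asserted in tests.
8. **Statistics.** Student pooled-variance t-tests per (band, CAP,
   metric) with Welch as an option; 2×2 Pearson chi-square without
   continuity correction for sex (the no-correction variant reproduces
   the cohort table's printed p from its own counts); one-way ANOVA
   reconstructed from (mean, SE, n) summaries for age — for two groups it
   equals the squared pooled t. Pearson correlation against the MMSE
   score. Uncorrected α = 0.05 by default with an optional
   Benjamini–Hochberg flag, off by default, matching common practice in
   this literature.
9. **Cross-band comparison.** Voxelwise Pearson correlations between the
   z-maps of two bands' CAPs, with the Hungarian algorithm providing the
   bijection maximizing total matched correlation. This formalizes the
   visual observation that similar CAPs in different bands need not share
   a number, since numbering follows band-specific occurrence.

## Synthetic cohort generator

The generator emulates only the structure the analysis assumes, with
known ground truth:

- **Latent dynamics**: per subject, a first-order Markov chain over K
  states; group G uses `P_G = λI + (1−λ)·1π_Gᵀ`, which has stationary
  distribution π_G for any persistence λ ∈ [0,1) and mean dwell
  `1/(1−P_kk)` frames.
- **Emission**: frame t equals the template of its state plus iid
  Gaussian voxel noise; templates are QR-orthogonalized Gaussian vectors
  standardized to mean 0, SD 1 across voxels (pairwise |r| ≲ 0.05 at
  2000 voxels). States are emitted directly per frame with no
  hemodynamic convolution: the downstream analysis operates on frames
  and models no hemodynamics either.
- **Phenotypes**: an MMSE-like score, `intercept + coefᵀ·(true
  occupancies) + N(0, σ²)` clipped to [0, 30]; uniform sex; age
  ~N(74, 7²) truncated to [55, 95]; CDR 0 for controls and 0.5–1.0 for
  patients.

Default study conditions: 20 subjects per group, T = 130 frames at
TR = 3 s, N = 2000 voxels, K = 7, noise SD 0.3, persistence λ = 0.3
(mean dwell ≈ 1.9 frames ≈ 5.7 s, a realistic CAP dwell time at this
TR). Control occupancies are (.25, .19, .16, .12, .11, .09, .08); the
patient chain shifts state 1 down by 0.15 with proportional
redistribution — a single transition-matrix change that alters
occupancy, entry rate and dwell time simultaneously. The score couples
to state-1 occupancy with coefficient +30, intercept 20 and residual
SD 1, putting patients near 23 and controls near 27.5 on the 0–30
scale. Labels are 1-based everywhere, matching the CAP 1..7 convention.

What the generator does **not** emulate: hemodynamic response and
autocorrelation, motion and physiological noise spectra, spatial
smoothness and anatomy, scanner drift. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated state-space
model, not performance on real scanner data.

## Numerical choices

- **Bandpass**: order-2 Butterworth applied forward-backward
  (`sosfiltfilt`; effective order 4, zero phase), per-voxel mean removed
  first; an FFT boxcar (`method="fft"`) with exact band edges is
  available. No frames are discarded for edge effects; dummy-volume
  removal is assumed upstream. Nuisance regression defaults to *after*
  filtering (`nuisance_stage` flag to move it before).
- **k-means**: squared Euclidean on frame-z-scored rows; restarts use
  k-means++ seeding, Lloyd with tol 1e-6 and ≤300 iterations; empty
  clusters re-seeded from farthest points. Tiny instances (k^n ≤ 2·10⁴
  assignments) are solved *exactly* by set-partition enumeration
  (restricted growth strings with SSE pruning): restarted local search
  can provably miss the global optimum even on 8 points, and at this
  scale exhaustive search is cheap and deterministic. The exemplar-stage
  default is 500 restarts; validation experiments on well-separated
  synthetic clusters use 10–50, which is already far past convergence
  there.
- **Degenerate inputs**: zero-variance frames, constant centroids,
  rank-deficient nuisance designs, zero chi-square margins, and
  zero-pooled-variance group cells are rejected or flagged `untestable`
  rather than returning infinities.
- **Determinism**: every stochastic step (generator, k-means restarts)
  is driven by an explicit seed; the full pipeline writes byte-identical
  TSVs across reruns with the same seed and refuses to overwrite an
  output directory produced under a different configuration hash.
- **Voxel order**: masked voxels are raveled x-fastest (Fortran order),
  recorded in NIfTI headers, so matrices round-trip exactly.

## Open design points resolved

- "Many iterations" of exemplar clustering is read as restart count, not
  Lloyd iteration count: restarts are what make the exemplar stage a
  robust initializer for the single full-data pass.
- The filter family/order and the filter-vs-regression order are not
  canonical in this literature; both are config-exposed
  (`filter_method`, `nuisance_stage`) with the defaults above.
- Whether frames are z-scored before clustering is exposed as
  `frame_norm: zscore|none` (default zscore).
- Silhouette on exemplars vs all frames is ambiguous in the source
  literature; exemplars are the default here (documented, and the
  validation suite shows the true K is recovered under the default).

## Problem sizes used in validation

Recovery experiments run at the default conditions above (40 subjects ×
130 frames × 2000 voxels); detection rates use 20 replicate seeds;
cross-band and determinism checks use reduced cohorts (12 subjects × 80
frames × 500 voxels, and 6 × 60 × 300 respectively), chosen so the whole
validation suite completes in minutes on a single CPU while leaving every
tested effect far from its decision threshold.

## Known limitations

- Exemplar silhouette can plateau when clusters are heavily overlapping;
  with real data the selected k should be inspected against the full
  silhouette curve (written to `silhouette_<band>.tsv`).
- Transition-probability group comparisons are computed but have no
  reference values to validate against beyond the generator.
- The pipeline consumes already registered, masked data; no motion
  correction, slice timing, smoothing or spatial normalization is
  provided.
- Temporal bandpass mixes adjacent frames, so on purely frame-wise
  synthetic state sequences filtering degrades state separability; the
  ground-truth recovery experiments therefore cluster unfiltered frames,
  while filter correctness is validated spectrally.
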