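# capdyn

Frequency-resolved whole-brain **coactivation-pattern (CAP)** analysis of
resting-state fMRI, with a synthetic Markov-state cohort generator for
validation.

## What it does

Resting brain activity is not stationary: single BOLD frames express
transient whole-brain states that recur across a scan. CAP analysis treats
every frame as an N-voxel vector and clusters the pooled frames of a
cohort with k-means; each centroid (the mean of its member frames) is a
CAP, a recurring spatial coactivation state. Because the BOLD
low-frequency range is itself composite — the LFO band (0.01–0.1 Hz)
splits into slow-5 (0.01–0.027 Hz) and slow-4 (0.027–0.073 Hz)
oscillations — the pipeline runs the whole analysis per band and then
matches CAPs across bands.

For a per-frame state sequence `s_1 … s_T` (labels 1..K) the pipeline
computes, per subject, band and state k:

- **occurrence** (fractional occupancy): `o_k = #{t : s_t = k} / T`
- **entry count / rate**: number of maximal runs of k (consecutive frames
  count once), also per minute of scan
- **mean duration** (dwell time): average run length, in frames and
  seconds (× TR); these satisfy `o_k · T = entries_k · duration_k` exactly
- **transition probabilities**: row-normalized one-step counts
  `P_ij = #{t : s_t = i, s_{t+1} = j} / #{t : s_t = i}`

Clustering is two-stage: per subject, *exemplar* frames are taken at
interior local maxima of the frame-wise spatial variance (10–15 per
subject); k-means with many restarts on the pooled exemplars seeds a
single k-means pass over all frames. The number of states is chosen by
maximal mean silhouette over k = 2…20 on the exemplar frames. CAPs are
numbered in decreasing order of control-group occurrence, each map is
z-scored across voxels, and |z| > 1.5 defines its activated/suppressed
voxels. Group differences use independent-samples t-tests (α = 0.05),
demographics use a 2×2 chi-square (sex) and a one-way ANOVA
reconstructable from printed mean ± SE summaries (age), and clinical
coupling uses Pearson correlation with the MMSE score. Cross-band CAP
similarity is a voxelwise Pearson matrix with Hungarian one-to-one
matching.

The synthetic generator emulates exactly the structure this analysis
assumes: hidden first-order Markov chains over K spatial templates,
group-specific transition matrices (so occupancy, entries and dwell time
all differ), white voxel noise, and an MMSE-like score linearly coupled to
true state occupancy.

## Worked example

```python
import numpy as np
import capdyn as cd
from capdyn.validation import fit_synthetic_cohort

# simulate a 2 x 10-subject cohort with 7 latent brain states
cfg = cd.default_cohort_config(seed=1, n_per_group=10, n_voxels=1000, n_frames=130)
cohort = cd.generate_cohort(cfg)

# cluster frames into 7 CAPs (exemplar-seeded k-means), order by controls
model, metrics, n_exemplars = fit_synthetic_cohort(cohort, k=7, n_restarts=50, seed=1)
print("exemplar frames pooled:", n_exemplars)
print("NC occurrence by CAP:  ", np.round(model.nc_occurrence_, 3))

# group comparison of occupancy
tests = cd.compare_groups(metrics, cohort.phenotypes)
hit = tests[tests.significant & (tests.metric == "occurrence")]
print(hit[["cap", "metric", "mean_AD", "mean_NC", "t", "p"]].to_string(index=False))

# MMSE coupling of the affected CAP's occupancy
occ = metrics[metrics.cap == int(hit.cap.iloc[0])].set_index("subject_id")["occurrence"]
r, p = cd.correlate_with_score(
    occ.reindex(cohort.phenotypes.subject_id), cohort.phenotypes.MMSE
)
print(f"occurrence-MMSE Pearson r = {r:.2f} (p = {p:.2g})")
```

prints

```
exemplar frames pooled: 300
NC occurrence by CAP:   [0.252 0.177 0.161 0.132 0.105 0.089 0.085]
 cap     metric  mean_AD  mean_NC         t        p
   1 occurrence 0.111538 0.251538 -5.818396 0.000016
   2 occurrence 0.232308 0.176923  3.068231 0.006624
occurrence-MMSE Pearson r = 0.94 (p = 7.5e-10)
```

CAP 1 — the state whose occupancy the generator suppressed in the patient
group — is detected (occupancy 0.11 vs 0.25, p ≈ 2·10⁻⁵; CAP 2 absorbs
part of the redistributed mass), and its occupancy correlates positively
with the MMSE-like score, matching the planted coupling.

The same analysis runs from the shell on NIfTI + TSV cohorts:

```bash
capdyn simulate --out cohort/ --seed 1
capdyn run --in cohort/ --out results/ --seed 1        # all three bands
capdyn report --out results/
```

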