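# Methods

This note documents the models, algorithms and numerical choices behind
`reinstate`, the defaults and their units, what the synthetic cohorts do and
do not emulate, and the package's known limitations.

## Experimental design model

A session comprises one **study run** and two **test runs**. Mini-blocks of
same-task trials alternate between a semantic and a phonological orienting
task; each semantic + phonological pair is followed by a fixation period.
Defaults (`default_design`):

| parameter | default | unit |
|---|---|---|
| TR | 1.2 | s |
| study blocks | 16 × 15 trials, SOA 3000 ms | — |
| test blocks (per session) | 18 × 10 trials, SOA 4400 ms | — |
| fixation after each pair | 21 | s |

A study block therefore spans exactly 37.5 volumes and a test block 44/1.2
≈ 36.67 volumes. Scans are assigned to the block whose half-open interval
[onset, onset + n_trials × SOA) contains the scan onset (0-based scan
indexing, seconds as the canonical unit); all other scans are fixation.
With this rule the 16 study blocks yield runs of 37 or 38 labeled scans
depending on where the 1.2 s grid falls. A design is serializable to JSON
and exportable as a BIDS-style events table. The brief distractor between
test sessions and the pre-block cue screens contain no scans of interest
and are not modeled.

The decoding target is the ±1 task boxcar sampled at TR, convolved with the
canonical double-gamma HRF (response delay 6 s, undershoot delay 16 s, unit
dispersions, response:undershoot ratio 6, 32 s support, peak-normalized)
and truncated to the run. The function is named by the literature; its
parameters are the standard canonical defaults since only the function, not
its parameterization, is conventionally reported. Fixation scans are kept
in the convolution (they shape the regressor) but excluded from decoder
training rows and from performance computation.

## Preprocessing

Per run, in fixed order:

1. **Outlier-scan repair** — a scan is an outlier if its mean absolute
   voxel value exceeds 5 SDs of that statistic's within-run distribution;
   it is replaced by the mean of its two neighbors (single neighbor at run
   ends). The classical rule is slice-based on raw volumes; after ROI
   extraction slices no longer exist, so an equivalent scan-level statistic
   is used while the neighbor-mean repair is preserved.
2. **Detrend / high-pass** — residualization against an intercept, a linear
   term, and a discrete-cosine basis of all frequencies below 1/180 Hz
   (SPM-style DCT projection rather than FIR filtering).
3. **Range scaling** — per voxel, per run, affine map to [−1, 1]
   (`scale_mode="per_voxel"`; a whole-matrix `"global"` mode is provided as
   a config switch since the toolbox convention is ambiguous — "varying
   ranges of voxel activity" argues for per-voxel, which is the default).
   Constant voxels map to 0 with a warning.

Runs are always conditioned separately; the chain is idempotent to ≈1e−6
per element. One measured caveat: a pure 1/300 Hz sinusoid is attenuated to
~1.3% residual RMS, not exactly 0, because a tone between DCT frequencies
leaks across the finite basis.

## Feature selection

Voxels are ranked by a two-group one-way ANOVA F (semantic vs. phonological
training scans; F = t² for two groups) and the top-N retained — selection
by rank, so no multiple-testing correction is involved. Candidate sizes
default to {500, 150, 50}. For task specificity, features are re-selected
inside each cross-validation fold (config `nested_selection`, default on)
so selection never sees held-out data; for memory specificity the feature
set is computed once on all encoding data, which is the training set.
Ties in F break by ascending voxel index; infinite F (zero within-group
variance) ranks first; N exceeding the voxel count clamps with a warning.

`choose_set_size` operationalizes "best performing without an age
confound": among sizes whose placebo task specificity shows no group
difference (two-sample t-test, α = 0.05), pick the size with the highest
grand-mean accuracy (ties to the smaller size); if every size is
confounded, pick the minimal |group difference| and flag. A frozen per-ROI
preset (prefrontal 500, hippocampus 50, posterior ROIs 150) ships as
`ROI_PRESET_SIZES`.

## Ridge decoding

`fit_ridge` centers the target by its training mean and solves the normal
equations (X'X + λI)w = X'(y − ȳ); at λ = 0 a rank-deficient system falls
back to the pseudo-inverse and is flagged. Predictions are X w + ȳ.
Performance is the Pearson correlation of predictions with the convolved
±1 targets of the test set — the same convention as training, since the
raw block labels are only defined up to hemodynamic lag. Degenerate
constant predictions map to performance 0 (the metric's chance level) with
a warning.

The penalty grid is (0, 0.01, 0.1, 1, 10, 100, 1000, 10000). λ is chosen
**once per subject** (per ROI × set size) by nested cross-validation on
placebo encoding data: for every (outer fold, inner fold) pair of the
8 block-pair folds, a decoder trained on the remaining 6 folds is scored on
the inner fold; scores are pooled into one subject-level mean per grid
value and the maximizer wins. Ties — including the exact ties that arise on
noise-free data, where correlation is invariant to shrinkage — resolve to
the smaller λ, with means within 1e−9 treated as tied. The chosen λ is
reused for the drug sessions and the memory analyses, avoiding leakage of
outer-fold information through per-fold hyperparameters. Internally the
nested search uses per-fold Gram matrices and one eigendecomposition per
split, so the whole grid costs little more than a single fit.

Task specificity: 8 folds, each holding out one semantic + phonological
block pair; the value is the mean fold performance. Memory specificity:
one decoder trained on all encoding scans, scored on each retrieval
session against that session's convolved targets, and the two sessions
averaged (a missing session yields the single-session value with a
warning).

## Correlation-distance metric

Per block, fixation scans and the first 7 block scans (0-based within-block
rank < 7) are discarded to allow for hemodynamic delay; remaining scans are
averaged per voxel, block means are averaged within phase × task (both
retrieval sessions pooled), and memory specificity is

    mean[r(sem_enc, sem_ret), r(phon_enc, phon_ret)]
  − mean[r(sem_enc, phon_ret), r(phon_enc, sem_ret)].

Correlations are averaged raw; a Fisher-z switch (`fisher_z`) exists but
defaults off. With the default timing, study blocks retain 30 or 31 scans
and test blocks 29 or 30 — the grid placement of 37.5- and 36.67-volume
blocks makes a single fixed count impossible, so actual retained counts are
reported per block rather than forced to a nominal value.

## Behavior

From old/new recognition counts (hits collapsed over Remember and Know):
Pr = hit rate − false-alarm rate, Br = false-alarm rate / (1 − Pr)
(undefined at Pr = 1; Br > 0.5 = liberal). The covariate for group analyses
is placebo Pr, mean-centered within age group. Covariate outliers are
flagged in a single pass at |z| > 2.5 within-group SDs; the within-group
(rather than whole-cohort) reference is a documented choice.
Recollection/familiarity estimation from Remember/Know proportions is not
implemented (no standard estimator is assumed).

## Group statistics

Rather than a full mixed-model RM-ANOVA, the 3-level within factor is
analyzed through contrast scores, which is statistically equivalent for
this design:

- **ANCOVA** (per ROI × metric × drug): OLS on [1, group, Pr_c,
  group × Pr_c] with effect-coded group (young +1, old −1); each term's F
  from a drop-one-column nested-model comparison (Type III-equivalent
  here). Verified against statsmodels' `compare_f_test` to 1e−8.
- **Drug trends**: per-subject linear (B − S) and quadratic (S − 2P + B)
  contrast scores tested by one-sample F (df 1, n−1); the omnibus drug
  effect uses orthonormal contrasts with Greenhouse–Geisser ε from Box's
  formula, ε = tr(M)²/((k−1)tr(M²)) with M the contrast-transformed
  covariance. Verified against pingouin's `rm_anova` (F, ε, corrected p) to
  1e−8. Drug coding is ordinal: sulpiride −1, placebo 0, bromocriptine +1.
- **Group × drug × Pr**: each subject's linear drug effect (B − S) on the
  metric is regressed on group, centered Pr and their product; the
  group × Pr term carries the three-way interaction. Its type-I error is
  calibrated (empirically 3–7% at α = 0.05 on null record tables).

Significance defaults to α = 0.05 two-sided with no multi-ROI correction.

## Synthetic cohorts

Each subject-session carries two unit-norm, exactly orthogonal
(Gram–Schmidt) spatial patterns on a shared random support of
`n_signal_voxels` voxels. Encoding signal is `encode_amp` × pattern ×
HRF-convolved task indicator; retrieval signal is additionally scaled by
the reinstatement strength ρ ∈ [0, 1] (ρ = −1 is available as an
adversarial debug mode). Noise is per-voxel AR(1) Gaussian (marginal SD
`noise_sd`), plus a sinusoidal drift below the high-pass cutoff, plus
rare amplitude-inflated outlier scans.

Defaults (`GenerativeParams`): 120 voxels, 24 signal voxels, encode_amp
1.0 a.u., noise_sd 1.0 a.u., ar1 0.3, drift amplitude 1.0 a.u. at period
240 s, outlier rate 0.005/scan. These place single-subject placebo task
specificity near 0.9 and make reinstatement recovery reliable without
being noise-free; the 120/24 voxel counts stand in for a small ROI (larger
regions would use the 500/150/50 selection regime), with set size 50 as
the default analysis choice.

Cohorts (`simulate_cohort`) cross two age groups with three within-subject
drug sessions. The default effect configuration (`EffectConfig`) plants the
qualitative structure under study, as a modeling choice rather than a
claim about mechanism:

- group mean ρ: young 0.6, old 0.3 (SD 0.15) — reduced reinstatement with
  age;
- encoding amplitude × 1.4 under both active drugs in both groups — an
  age-invariant task-specificity boost;
- old-group session ρ perturbed by δ × drug_code × (group mean Pr −
  baseline Pr) with δ = 1.2 — bromocriptine raises reinstatement in poorer
  performers and lowers it in better performers, sulpiride the reverse
  (the drug × Pr crossover);
- baseline Pr ~ cohort mean 0.47 with a positive link to ρ (slope 0.3,
  jitter SD 0.08), so memory performance correlates with reinstatement;
- recognition counts are binomial with P_hit = clamp(base + 0.25 ρ) and
  fixed P_fa = 0.2 over 120 old / 60 new items (2:1), with `base` placed
  so the expected Pr equals the subject's baseline Pr.

All draws descend from a single `master_seed` via `SeedSequence` spawning;
identical seeds give byte-identical datasets. Emitted formats: gzipped TSV
matrices with JSON annotation sidecars, truth and behavior tables as CSV,
optional NIfTI export (ROI voxels embedded in a dummy grid) for
interoperability.

What the generator does **not** emulate: spatial voxel structure and
smoothness, motion and physiological noise, trial-level item effects,
event-related variability within blocks, session-order effects, and any
nonlinearity of the BOLD response. Passing tests therefore show that the
pipeline recovers the planted block-level generative structure — they do
not certify performance on real recordings, where noise is richer and
effect sizes smaller.

## Calibration findings and problem sizes

- **Chance level.** Cross-phase memory specificity is unbiased under the
  null: on 200 no-signal subjects (pure AR(1) noise + drift) its mean is
  within 2 SE of 0 for both the ridge and the correlation metric. The
  within-run task-specificity estimate, however, carries a small positive
  offset (~+0.04): the run-wide DCT high-pass acts as a smoother whose
  width (~100 s at 1/180 Hz over an 888 s run) nearly matches the 111 s
  block-pair period, inducing a train→test correlation transfer inside the
  single study run that selection and ridge then harvest. Ablations
  localize the effect to the DCT columns (raw or linear-only detrended
  white noise decodes at chance; filtering the regressor does not remove
  it). This is inherent to cross-validating within one temporally filtered
  run, so absolute within-run decoding accuracies should be read against
  an empirical, not theoretical, baseline; cross-phase (between-run)
  measures are immune. `scripts/acceptance.py` reports the grand-mean
  empirical chance level of the full pipeline.
- **Parameter recovery.** Across ρ ∈ {0, 0.2, …, 1} × 20 seeds at default
  noise, measured memory specificity rank-correlates with generative ρ at
  Spearman ≈ 0.95–0.99.
- **Problem sizes.** The test suite uses 200 null subjects for chance
  calibration, 120 subjects for recovery, 500 record-level cohorts for the
  interaction test's type-I error (the test's distribution depends only on
  the record table, so records are simulated directly at this step), and
  20 full 16 + 16 cohorts for the qualitative effect-structure checks;
  unit tests run on a scaled design (4 study pairs of 5-trial blocks).
  These sizes are chosen to give stable Monte Carlo estimates at
  interactive runtimes.

## Known limitations

- Real-data ingestion is limited to the package's TSV/JSON container and
  the dummy-grid NIfTI export; masking arbitrary 4-D NIfTI volumes with
  ROI masks is out of scope here.
- The ANCOVA assumes one value per subject per slice; unbalanced designs
  beyond a missing drug session (which drops the subject from
  within-subject tests, with partial cohorts otherwise retained) are not
  handled.
- Only the two-task, two-group, three-session structure is supported; no
  multi-class decoders or alternative classifiers.
- Statistical machinery assumes Gaussian residuals; no permutation-based
  inference is exposed at the group level.
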