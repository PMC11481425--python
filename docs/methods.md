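# Methods

This note documents the models and numerical choices behind `hyperdifc`,
what the synthetic cohorts do and do not establish, and the defaults a
user may want to change.

## The measurement model

A hyperscanning session records two subjects simultaneously with
synchronized clocks. For electrodes *i* (male subject) and *j* (female
subject) the inter-brain connection at timepoint *w* is the Pearson
correlation of the two signals inside sliding window *w*:

    dIFC[i, j, w] = corr( male_i[t], female_j[t] ),  t in window w

The window axis is the object of interest: a whole-series correlation
("static" sFC) is the single-window special case and averages away any
temporal structure. All analyses run on the broadband 1–40 Hz signal; no
frequency-band decomposition is performed.

## Synthetic paired sessions

The generator produces the statistical structure the downstream stages
assume, without claiming biophysical realism.

**Signal model.** Each channel is unit-variance 1/f ("pink") noise scaled
to 10 µV RMS. The female subject's channel *i* is mixed from private
noise and the homologous male channel:

    female_i(t) = sqrt(1 - c(t)^2) * private_i(t) + c(t) * male_i(t)

with all components standardized before mixing, so the expected
within-window inter-brain correlation of a homologous pair equals `c(t)`
directly. Non-homologous pairs are uncorrelated in expectation.

**Two-stage coupling profile.** Hand-off blocks hold `c` at the baseline
throughout. Hand-on blocks draw a fresh `c` around the baseline every
coupling segment (2 s) during the first half of the block — the
"adaptation" stage — and settle deterministically at a group-specific
plateau in the second half. The stage boundary sits at 50 % of the block.
Defaults: baseline 0.2, lover plateau 0.5, stranger plateau 0.05,
stage-1 SD 0.1. The magnitudes are free parameters (no published estimate
of generative coupling exists for this design); they were chosen once to
give a moderate resting dependence with clearly separated late stages,
and they are configuration fields, not constants.

**Artifacts.** Blinks are 300 ms half-cosine deflections (80–160 µV) on
the EOG at 12 events/min, bleeding into EEG channels with gain
`0.5·exp(−d/0.6)` where `d` is the great-circle distance from the EOG
site — frontal channels receive most. With probability 0.05 per
recording, one channel is replaced by a near-duplicate of its nearest
neighbour (a "bridged" electrode) to exercise bad-channel detection.
Muscle artifacts, line noise, drifts, heartbeat and movement are *not*
modelled.

**Determinism.** Every pair's session is a pure function of
`(config.seed, pair_id)` via a seed sequence, so cohorts regenerate
bit-identically and pairs are independent streams.

**What this does not show.** Real inter-brain dependence is far weaker,
rides on volume-conducted within-subject structure, and shares
environmental noise between subjects. Passing tests on these cohorts
demonstrate that the estimator and statistics recover structure *of the
assumed form* at realistic SNR — not that any given laboratory dataset
contains such structure.

## Preprocessing

Fixed stage order: bad channels → interpolation → re-reference → filters
→ ICA → normalization → decimation → baseline removal.

- **Bad channels**: any EEG channel whose absolute correlation with
  another exceeds 0.95 marks the *lower-variance* member of the pair as
  bad (bridged/shorted channels lose signal power; ties break to the
  later montage position). Constant channels, whose correlation is
  undefined, are flagged unconditionally. The criterion is applied before
  re-referencing.
- **Slerp interpolation**: the bad electrode is rebuilt from its two
  nearest good electrodes (great-circle distance on the unit sphere) with
  spherical-linear weights `sin((1−t)Ω)/sinΩ`, `sin(tΩ)/sinΩ`; `t` is the
  bad electrode's normalized angular position along the donor arc
  (projection onto the donors' great circle, clipped to [0, 1]). For
  `sin Ω < 1e−6` the formula degenerates and the linear limit
  `(1−t, t)` is used, which equals the analytic Ω→0 limit.
- **Reference**: average of TP9/TP10, snapshot before subtraction so the
  mastoids themselves end up consistently re-referenced (making the
  operation idempotent). Mastoids stay in the data but never enter
  connectivity analysis.
- **Filtering**: zero-phase (forward–backward) Butterworth, order 4:
  band-stops 48–52, 148–152, 248–252 Hz, then band-pass 1–40 Hz. Notches
  at or above Nyquist are skipped with a warning. Edge transients are not
  trimmed (bookkeeping preservation was preferred); windows touching the
  block edges inherit slightly coloured noise.
- **Ocular/muscular removal**: FastICA over the EEG channels (fitted on
  an evenly subsampled ≤20 000-sample segment, applied to the full
  series). Components whose absolute correlation with the EOG exceeds
  0.7, or whose >20 Hz power fraction exceeds 0.7, are zeroed before
  reconstruction. The EOG channel itself is never altered; decomposition
  failure passes the recording through unchanged with a logged warning
  rather than dropping data.
- **Normalization**: per-channel min–max scaling to [0, 1]. A true
  z-scoring alternative sits behind `normalization="zscore"`. (The
  min–max formula is the documented default because it is the printed
  normalization rule for this pipeline family, even though such scaling
  is often *called* zero-mean-unit-variance in the applied literature.)
- **Decimation**: non-overlapping moving-average blocks, default factor
  100 (1000 Hz → 10 Hz), chosen so that a 4-minute block yields 2400
  samples and, with the default window, 29 timepoints. A length-preserving
  "smooth" mode exists. The window length of the moving average is the
  decimation factor itself.
- **Baseline**: subtract the mean of the first 500 ms (5 samples at
  10 Hz).

## Windowing

Window length 120 samples; step 80 samples (the step is a reconstruction:
only the window length is conventionally fixed, and 80 makes
2400 samples → 29 timepoints, matching the tp1..tp28-style indexing this
analysis family reports). The 120-sample window is applied *after*
decimation — i.e. each timepoint summarizes 12 s of data — which is the
only reading consistent with ~29 timepoints per 4-minute block; this is a
reconstruction and is prominently configurable. Trailing partial windows
are discarded. Raw r is carried into statistics (no Fisher z by default;
a flag exists). NaN windows (degenerate variance) propagate and are
excluded pairwise downstream rather than imputed.

## Group statistics

- **ROI selection**: per-channel mean absolute amplitude ("voltage
  magnitude"; RMS is a config alternative since the quantity is not
  standardized), averaged over both hand blocks per subject, compared
  between groups with Student's pooled two-sample t (Welch behind a
  flag; subjects, not dyads, are the unit here) and BH-FDR across
  channels.
- **Mixed ANOVA**: one between-dyad factor (relationship) and one
  within-dyad factor (hand). The interaction is computed from an explicit
  sums-of-squares decomposition (weighted cell means; the error term is
  the condition × dyad-within-group residual), giving
  `F((g−1)(m−1), (N−g)(m−1))` — `F(1, n_pairs−2)` for the 2×2 design —
  and partial η² = SS_int/(SS_int+SS_err). For two within levels this is
  algebraically the squared pooled t on per-dyad difference scores, which
  the tests exploit as an independent oracle (along with pingouin).
  Dyads missing a condition are excluded with a warning.
- **FDR**: Benjamini–Hochberg step-up, by default over the *entire*
  family of (channel pair × timepoint) tests; a per-channel-pair family
  is available. q-values are the standard monotone step-up adjustment.
- **Trend curves**: piecewise-cubic interpolation through all knots
  (scipy CubicSpline, not-a-knot ends). A natural spline was rejected
  because it cannot reproduce cubic trends exactly at the boundaries;
  knot-exactness is preserved either way. Interpolation is for
  visualization only and enters no test statistic.
- **Questionnaires**: Zung SDS/SAS totals (reverse-keyed items
  contribute `5 − x`; SDS reverses items 2,5,6,11,12,14,16,17,18,20 and
  SAS 5,9,13,17,19). Reliability: Cronbach's α from the variance formula
  and McDonald's ω from a one-factor decomposition
  `(Σλ)²/((Σλ)²+Σψ)`, both on recoded items.
- **Power**: noncentral-F power of the repeated-measures within-between
  interaction with the G*Power-style noncentrality
  `λ = f²·N·m·ε/(1−ρ)`, `df1=(g−1)(m−1)ε`, `df2=(N−g)(m−1)ε`; defaults
  ρ=0.5, ε=1. The implementation reproduces the standard benchmark
  (f=0.25, α=0.05, power=0.80, 2×2 → N=34). For f=0.20 and power 0.95 it
  yields N=84; a smaller published figure for this configuration would
  correspond to assuming a repeated-measures correlation near 2/3, which
  is why ρ is an explicit argument rather than a constant.

## Classification

Samples pool (dyad, hand, timepoint); features are the channel-pair r
values; labels are 0 = stranger, 1 = lover. Pipeline:
standardization (fitted on the training portion only) → SVC. Grid search
over kernel ∈ {rbf, linear}, C ∈ {0.1, 1, 10, 100},
γ ∈ {scale, 0.01, 0.1} by cross-validation on the training portion;
final refit on the full training set; metrics on the 30 % held-out set.

The default split is **group-aware**: a dyad's samples never straddle
train and test, and the CV inside the grid search uses stratified group
folds, because pooled splitting leaks a dyad's own timepoints into the
test set and inflates accuracy. `paper_split=True` restores the pooled
random shuffle with plain 10-fold CV for comparability with analyses
that used it. No class weighting is applied by default (supports are
reported unbalanced); a single-class draw is redrawn with a logged seed
bump. AUC is computed from the decision function; with ties, it equals
the concordant-pair probability with ties counted ½. Half-comparison
output is descriptive only — no significance is attached to the ordering
of first/second-half models.

## I/O and provenance

Recordings travel as BrainVision `.vhdr/.vmrk/.eeg` triplets
(IEEE float32, multiplexed, µV); the reader validates format, units and
file sizes and names the offending file on truncation. dIFC tensors
export to long-format CSV (pair, relationship, hand, ch_male, ch_female,
tp, r). Every pipeline run writes a single `provenance.json` with
versions, seeds, resolved parameters and flagged channels; reruns with
the same configuration are bit-identical. Internally all indices are
0-based half-open; user-facing timepoint labels are 1-based (tp1..tpN).

## Test problem sizes

The statistical acceptance checks run on synthetic cohorts of 12+12
dyads with 60 s blocks on a 16-electrode montage (14 analysis channels),
with artifact injection and the ICA stage disabled — those cohorts test
coupling recovery, effect localization and type-I control of the
statistics, while artifact handling has its own dedicated unit tests at
full rate. At the 10 Hz decimated rate a 60 s block yields 7 timepoints
(4 + 3 per half). Designed-effect checks use 10 seeds; null (type-I)
checks use 20 seeds for the ANOVA map and 10 for the classifier.

## Known limitations

- The generator couples only homologous electrode pairs and models no
  within-subject spatial covariance, so full-scalp dIFC patterns on real
  data will differ qualitatively from synthetic ones.
- The ICA criterion targets ocular templates and high-frequency
  components; slow muscle tone or electrode drift is untouched.
- The exact mapping from a 4-minute block to ~29 timepoints is a
  reconstruction (window step and pre/post-decimation placement are
  choices, both configurable).
- The mixed ANOVA assumes each channel-pair cell is analyzed
  independently; no spatial model links neighbouring electrodes beyond
  the FDR family choice.
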