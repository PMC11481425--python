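# hyperdifc

Dynamic interpersonal functional connectivity (dIFC) analysis for dual-EEG
hyperscanning experiments.

When two people are recorded simultaneously — say a dyad resting quietly
while holding hands or not — the statistical dependence between their
concurrent EEG signals ("brain-to-brain synchrony") can be tracked over
time. `hyperdifc` implements the full analysis chain for a two-group
(romantic lovers vs. opposite-sex strangers), two-condition (hand-off vs.
hand-on) resting-state design:

1. **Synthetic paired-EEG generator** — dual 31-EEG+1-EOG sessions at
   1000 Hz with a controllable, time-varying inter-brain coupling
   `c(t)`. Each female channel is mixed as
   `√(1−c²)·private + c·male_channel` (unit-variance components), so `c`
   *is* the expected inter-brain Pearson correlation. A two-stage profile
   (early fluctuation around a baseline, late group-specific plateau),
   blink artifacts and occasional bridged channels emulate the features the
   pipeline must handle.
2. **Preprocessing** — bad-channel detection (inter-channel |r| > 0.95,
   lower-variance member flagged) with spherical-linear (slerp)
   interpolation from the two nearest neighbours; average-mastoid
   (TP9/TP10) re-reference; zero-phase 50/150/250 Hz notches (±2 Hz) and
   1–40 Hz band-pass; ICA removal of EOG-correlated and high-frequency
   components; per-channel min–max normalization `x* = (x−min)/(max−min)`;
   moving-average decimation (default 1000 Hz → 10 Hz); 500 ms baseline
   removal.
3. **dIFC** — sliding-window Pearson correlation between every male
   electrode and every female electrode (window 120 samples, step 80): a
   4-minute block decimated to 2400 samples yields 29 timepoints
   tp1..tp29, split 15/14 into halves. A whole-series "static" snapshot
   (sFC) is the single-window special case.
4. **Group statistics** — per-channel voltage-magnitude t-tests for
   data-driven ROI selection; a 2 (relationship, between dyads) ×
   2 (hand, within dyads) mixed ANOVA at every (channel pair, timepoint),
   computed from an explicit sums-of-squares decomposition with
   `F(1, n_pairs−2)` and partial η²; Benjamini–Hochberg FDR over the whole
   family; cubic trend interpolation for visualization; Zung SDS/SAS
   questionnaire scoring (reverse-keyed items as `5−x`), Cronbach's α /
   McDonald's ω, and noncentral-F power analysis for the
   repeated-measures within-between interaction.
5. **Classification** — SVM (rbf/linear, grid-searched by 10-fold CV on
   the training portion) on pooled (dyad, hand, timepoint) samples with
   channel-pair r values as features; 70/30 held-out evaluation with
   per-class precision/recall/F1, accuracy, ROC and AUC, reported
   separately for the full series and for each half. The default split is
   group-aware by dyad; `paper_split=True` reproduces the pooled shuffle
   in which one dyad's timepoints may land on both sides.

## Worked example

```python
from hyperdifc import (SynthConfig, PreprocessConfig, WindowSpec,
                       generate_pair_session, preprocess_block,
                       compute_difc, split_halves)

cfg = SynthConfig(n_lover_pairs=1, n_stranger_pairs=0, block_s=240.0,
                  n_eeg=8, coupling_baseline=0.2,
                  coupling_lover_on_stage2=0.5, artifact_rate=0.0,
                  bad_channel_prob=0.0, seed=3)
_, hand_on = generate_pair_session(cfg, "L01", "lover")
block = preprocess_block(hand_on, PreprocessConfig(run_ica=False))
tensor = compute_difc(block, WindowSpec(length=120, step=80))
first, second = split_halves(tensor)
```

Running `python examples/difc_sliding_window.py` (this exact computation)
prints:

```
dIFC tensor: (6, 6, 29) (male x female x windows), labels tp1..tp29
homologous-pair mean r, first half:  0.172
homologous-pair mean r, second half: 0.488
static (whole-series) mean r:        0.322
```

The first half hovers near the generative baseline coupling (0.2), the
second half rises toward the lover hand-on plateau (0.5), and the static
snapshot averages the two stages away — which is exactly why the dynamic
window axis is the object of interest.

The other scripts in `examples/` walk through each capability: the
generator (`simulate_pair.py`), the preprocessing chain
(`preprocess_pipeline.py`), the timepoint-wise ANOVA map
(`group_statistics.py`), classification (`classify_relationship.py`) and
questionnaire scoring plus power analysis
(`questionnaires_and_power.py`). A thin CLI wraps the same calls:

```bash
hyperdifc run --out results/ --seed 1          # full pipeline
hyperdifc simulate --out raw/ --seed 1         # stage by stage
hyperdifc preprocess --in raw/ --out pre/
hyperdifc difc --in pre/ --out difc.csv
hyperdifc stats --difc difc.csv --out stats/
hyperdifc classify --difc difc.csv --out clf/ --half second
```

## Notes

- `docs/methods.md` documents the model, every default, and the known
  limitations of the synthetic cohorts.
- Results on real recordings depend on acquisition details the synthetic
  generator does not model (volume conduction, shared line noise,
  movement); see the methods note before interpreting pipeline output on
  laboratory data.
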