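"""Timepoint-wise mixed ANOVA with FDR on a small synthetic cohort.

Each (male electrode, female electrode, timepoint) cell gets a
2 (relationship, between dyads) x 2 (hand, within dyads) mixed ANOVA on the
inter-brain r; Benjamini-Hochberg FDR runs over the whole family of cells.
On a cohort whose lover hand-on coupling rises only in the second stage,
the significant cells should cluster in late timepoints.
"""

from hyperdifc import (PreprocessConfig, SynthConfig, anova_map,
                       compute_difc, generate_cohort, preprocess_block)

config = SynthConfig(n_lover_pairs=8, n_stranger_pairs=8, block_s=60.0,
                     n_eeg=8, coupling_baseline=0.2,
                     coupling_lover_on_stage2=0.55,
                     coupling_stranger_on_stage2=0.2, artifact_rate=0.0,
                     bad_channel_prob=0.0, seed=5)
blocks = generate_cohort(config)
processed = [preprocess_block(b, PreprocessConfig(run_ica=False))
             for b in blocks]
tensors = [compute_difc(b) for b in processed]

amap = anova_map(tensors, alpha=0.05)
print(f"ANOVA df = {amap.df} over {amap.n_pairs} dyads; "
      f"{len(amap.tp_labels)} timepoints per channel pair")
per_tp = amap.reject.sum(axis=(0, 1))
for tp, count in zip(amap.tp_labels, per_tp):
    print(f"  {tp}: {int(count):3d} significant channel pairs (q <= 0.05)")
print("heatmap row sums (per male electrode):",
      {ch: int(c) for ch, c in zip(amap.male_channels,
                                   amap.sig_count.sum(axis=1))})
print("\nSignificance concentrates in the timepoints after the stage")
print("boundary, where the groups' hand-on coupling actually diverges.")
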