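"""SVM classification of relationship type from dIFC features.

Samples are (dyad, hand, timepoint) triples, features the inter-brain r of
every channel pair.  The split is group-aware by dyad (no dyad straddles
train and test); pass ``paper_split=True`` to ``train_eval`` for the pooled
shuffle variant.  The second-half model should beat the first-half model
when the groups only diverge late in the block.
"""

from hyperdifc import (PreprocessConfig, SynthConfig, build_features,
                       compare_halves, compute_difc, generate_cohort,
                       preprocess_block, train_eval)

config = SynthConfig(n_lover_pairs=8, n_stranger_pairs=8, block_s=60.0,
                     n_eeg=8, coupling_baseline=0.2,
                     coupling_lover_on_stage2=0.55,
                     coupling_stranger_on_stage2=0.2, artifact_rate=0.0,
                     bad_channel_prob=0.0, seed=5)
tensors = [compute_difc(preprocess_block(b, PreprocessConfig(run_ica=False)))
           for b in generate_cohort(config)]

reports = []
for half in ("all", "first", "second"):
    fm = build_features(tensors, half=half)
    rep = train_eval(fm, test_frac=0.30, cv_folds=10, seed=0)
    reports.append(rep)
    print(f"--- {half} ({fm.X.shape[0]} samples x {fm.X.shape[1]} features, "
          f"best {rep.best_params}) ---")
    print(rep.to_table().to_string(index=False))
    print(f"AUC = {rep.auc:.3f}\n")

print(compare_halves(reports).to_string(index=False))
print("\nRows 0/1 are strangers/lovers; supports sum to the held-out size.")
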