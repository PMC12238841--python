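"""Balance positives, simulate negatives, and build peptide-holdout folds.

The dominant epitope is downsampled to the second most frequent epitope's
count; negatives are random TCR x peptide-HLA mispairings screened against
the positives; folds hold out every record of one peptide for unseen-peptide
evaluation.
"""

from collections import Counter

from tcrbind import synth
from tcrbind.negatives import MispairingConfig, downsample_top_epitope, simulate_negatives
from tcrbind.splits import make_folds, unseen_check

cfg = synth.SynthConfig(n_epitopes=5, tcrs_per_epitope=30,
                        dominant_epitope=True, seed=13)
positives, _ = synth.gen_binding_dataset(cfg)
counts = Counter(r.phla.peptide_aa for r in positives)
print("positive counts before downsampling:", dict(counts.most_common()))

balanced = downsample_top_epitope(positives, seed=13)
counts = Counter(r.phla.peptide_aa for r in balanced)
print("after downsampling:                 ", dict(counts.most_common()))

negatives = simulate_negatives(balanced, MispairingConfig(ratio=1.0, seed=13))
labelled = balanced + negatives
print(f"labelled set: {len(balanced)} binders + {len(negatives)} simulated nonbinders")

plan = make_folds(labelled, min_records=50)
print(f"peptide-holdout folds (>=50 records): {len(plan.folds)}")
for fold, clean in zip(plan.folds, unseen_check(plan, labelled)):
    print(f"  {fold.held_out_peptide}: {len(fold.test_ids)} test records, "
          f"holdout clean: {clean}")
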