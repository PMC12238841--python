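"""Why are some unseen peptides predictable and others not?

For each held-out peptide, three train/test relationship features are
computed: nearest-neighbour CDR3beta distance (TCRdist-style), the log count
of training records sharing the fold's HLA allele, and the best aligned
BLOSUM62 score to any training peptide.  With a noisy stand-in AUC per
peptide, the Pearson correlation of each feature with AUC is reported.
"""

import numpy as np

from tcrbind import synth
from tcrbind.splits import make_folds
from tcrbind.tractability import correlate, features_table

# features are computed over the positive records: mispairing negatives reuse
# the held-out fold's TCRs, which would pin every nearest-neighbour CDR3beta
# distance at zero
cfg = synth.SynthConfig(n_epitopes=6, tcrs_per_epitope=30,
                        cross_epitope_sharing=0.5, seed=17)
positives, _ = synth.gen_binding_dataset(cfg)
plan = make_folds(positives, min_records=25)

table = features_table(plan, positives)
print(table.round(2).to_string(index=False))

# stand-in per-peptide AUC: anti-correlated with CDR3beta distance plus noise
rng = np.random.default_rng(17)
dist = table["cdr3b_similarity"].to_numpy(dtype=float)
aucs = np.clip(0.95 - 0.004 * dist + rng.normal(0, 0.03, len(dist)), 0, 1)

per_feature, matrix = correlate(table, aucs)
print("\nPearson r against AUC:")
for name, stats in per_feature.items():
    print(f"  {name:>18}: r={stats['r']:+.2f} (p={stats['p']:.3f})")
# cdr3b_similarity is a distance, so its correlation with AUC is negative:
# folds whose test TCRs have close training neighbours are more tractable.
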