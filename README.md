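# tcrbind

Predicting whether an αβ T-cell receptor (TCR) recognises a peptide–HLA
class I complex, with the evaluation built around the hard case: **peptides
the model has never seen**. The package is aimed at computational
immunologists who work with curated TCR–pMHC binding data (VDJdb / McPAS /
IEDB-style tables and 10x single-cell screens) and want a complete,
desk-scale, fully reproducible version of the standard workflow:

* **standardize** — map heterogeneous source tables to one record layout and
  apply the curation rules (8–12-mer peptides, human HLA-A/B/C only, no
  ambiguous residues, allele-group imputation, label-aware deduplication);
* **germline** — reconstitute full variable-domain chains from
  (V, J, CDR3) as `V[:anchor] + CDR3 + J[anchor+1:]`, annotate CDR1/CDR2,
  and extract 34-residue HLA pseudosequences;
* **tenx** — pair single-cell chains (exactly one TRA + one TRB per
  barcode) and call binders where a peptide's UMI count exceeds the cell's
  negative-control count by more than 3 pooled standard deviations;
* **negatives** — downsample the dominant epitope and simulate nonbinders
  by screened random TCR × pHLA mispairing;
* **splits** — leave-one-peptide-out folds for peptides with ≥ 50 records;
* **model** — a small DeBERTa-style encoder (disentangled attention over
  relative positions, per-residue tokens with `[tra]/[trb]/[peptide]/[mhc]`
  prefixes), masked-LM pretraining and binary finetuning, implemented in
  pure numpy with its own reverse-mode autodiff;
* **evalstats** — Mann–Whitney AUC per held-out peptide, a 1000-replicate
  uniform-prediction null with 95% percentile intervals, and add-one
  empirical p-values;
* **tractability** — the three train/test relationship features that
  predict whether an unseen peptide is tractable (nearest CDR3β distance
  under a TCRdist-style metric, log HLA-allele support, best aligned
  BLOSUM62 peptide score), plus their Pearson correlations with AUC;
* **synth** — a generator for every input above (germline FASTA, binding
  tables, UMI matrices) with a controllable planted signal, so the entire
  pipeline is testable offline.

The core statistic: for a fold holding out peptide *p*,

    AUC = (#{score_pos > score_neg} + ½·#ties) / (n_pos · n_neg)

is compared against a null in which every record's score is drawn from
uniform[0, 1] (1000 replicates → mean ≈ 0.5 and a 95% interval), and the
model is significant for *p* when its AUC lands beyond the null's upper
tail, p = (1 + #{null ≥ AUC}) / (1 + 1000).

## Worked example

```python
import numpy as np
from tcrbind import synth, negatives, pipeline
from tcrbind.evalstats import auc, null_interval, random_null
from tcrbind.germline import packaged_pseudo_positions
from tcrbind.model import ModelConfig, finetune, pretrain_mlm

cfg = synth.SynthConfig(n_epitopes=4, tcrs_per_epitope=40, seed=5)
db = synth.gen_germline_db(cfg)
positives, _ = synth.gen_binding_dataset(cfg)
records = positives + negatives.simulate_negatives(
    positives, negatives.MispairingConfig(seed=5))
tokens = pipeline.prepare_tokens(records, db, synth.gen_hla_sequences(cfg),
                                 packaged_pseudo_positions(), max_len=96)
labels = np.array(pipeline.labels_array(records))
```

`examples/05_train_tiny_model.py` continues from here — masked-LM
pretraining on an independent synthetic cohort, finetuning, and evaluation
on records whose TCRs were never seen in training. A typical run prints:

```
masked-LM loss: 2.94 (start, ~ln20) -> 1.84
held-out TCRs: 62 records
model AUC: 0.804
random-model null: mean 0.501, 95% interval [0.363, 0.644]
p-value vs null: 0.0020 (significant: True)
```

Read: the untrained encoder is uniform over the 20 amino acids (loss ln 20 ≈
3.0); after pretraining and finetuning, the classifier separates binders
from mispaired nonbinders for unseen TCRs (AUC 0.80 at this reduced example
scale) far outside the random model's 95% interval, with an add-one
empirical p-value of 0.002. The other
`examples/` scripts demonstrate each stage the same way, one capability per
file.

A thin CLI chains the stages on files (`tcrbind synth | standardize |
stitch | tenx | negatives | split | pretrain | finetune | predict |
evaluate | features`), writing a JSON run manifest (config, seed, file
hashes, timings) next to every output.

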