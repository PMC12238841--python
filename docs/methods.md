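# Methods

`tcrbind` predicts whether an alpha/beta T-cell receptor (TCR) recognises a
peptide presented by a human class I HLA molecule, with the evaluation
centred on *unseen peptides*: peptides for which no cognate TCR exists in the
training data. This note records the models and procedures the package
implements, the assumptions behind them, and the choices made where the
design was genuinely open.

## Data model and curation

A binding record couples an alpha and/or beta chain — each described
minimally by its V gene call, J gene call and junction-inclusive CDR3
(conserved Cys through conserved Phe/Trp) — with a peptide, a two-field HLA
class I allele, a binary binder/nonbinder label, and a provenance tag.

Curation applies, in a fixed order, the inclusion rules used for public
binding databases: a valid TRA/TRB locus; at least one complete chain
(CDR3 + V + J); peptide length 8–12; only the 20 standard amino acids in
peptide and CDR3 (`X`, `B`, `Z`, `*` and lowercase are all rejected); a
human class I MHC label (mouse labels such as `H-2Kb` and class II codes
such as `DRB`/`DQ`/`DP` are rejected with distinct reasons). The first rule
that fires is the recorded rejection reason, and the per-reason counters
plus the retained count always sum to the input size.

Group-resolution HLA labels (e.g. `HLA-A*02`) are imputed to the most
frequent allele of the group using a small packaged frequency table of
common alleles, with lexicographic tie-breaks; V/J calls lacking an allele
suffix are completed to `*01`. Duplicate removal keys on (both chains'
V/J/CDR3, peptide, allele, **and label**): a binder and a nonbinder for the
same complex are contradictory evidence, not duplicates, and both survive.
When one source stores only a single chain and another stores the full pair
for the same complex, the single-chain record adopts the partner chain
before deduplication (an opt-in coalescing step).

## Chain reconstitution and HLA pseudosequences

Databases store TCRs minimally; the model wants full variable-domain
sequences. Reconstitution splices the junction between germline segments:

    full = V[0:anchor_V] + CDR3 + J[anchor_J + 1:]

where `anchor_V` indexes the conserved Cys of the V segment and `anchor_J`
the conserved Phe/Trp of the J segment's F/W-G-X-G motif. CDR3 residues
always override germline — somatic junctions legitimately differ. CDR1 and
CDR2 are read directly off the V germline annotation, since they are fully
determined by the V allele. Coordinates are 0-based half-open internally;
the pseudosequence position file is 1-based, converted exactly once on load.

The HLA molecule is represented by its pseudosequence: the heavy-chain
residues at a packaged list of 34 positions lining the peptide groove
(positions within 4 Å of a bound 9-mer), which compresses ~275 residues to
the 34 that matter for peptide binding. The position list is a parameter;
only the 34-position fixture ships. The packaged HLA FASTA contains
*synthetic* heavy-chain stand-ins (a shared scaffold with allele-specific
polymorphisms), sufficient for every structural contract here; real IPD-IMGT
sequences drop in without code changes.

## Single-cell binder calls

10x-style input arrives as per-chain rows keyed by cell barcode plus a
cell × peptide UMI count matrix with one negative-control column. A barcode
is kept only if it carries exactly two distinct chain sequences, one TRA and
one TRB (duplicated rows collapse first); everything else — empty GEMs,
single chains, multiplets, double-alpha cells — is dropped with a counted
reason. Binding is then called per (cell, peptide):

    binder  <=>  count(cell, peptide) > count(cell, negctrl) + 3 * s

with `s` the standard deviation of the negative-control counts pooled over
all cells (sample, n−1, by default; the population form is selectable).
The per-cell baseline plus pooled SD resolves an ambiguity in the rule's
usual phrasing: the SD is explicitly pooled "across all cells", implying the
baseline itself is not. Ties go to nonbinder (strict inequality). Only
positive calls enter the labelled set.

## Negatives and balancing

Public data contain essentially no experimental negatives, so nonbinders are
simulated by mispairing: a TCR and a peptide–HLA complex drawn independently
and uniformly from the positive set's *unique* entities (record-weighted
sampling is available), screened against the positive pairs (no accidental
true positive survives) and against the already-emitted output (sampling
without replacement). The default ratio is 1.0 — one negative per positive —
and the requested count is reached exactly or the operation fails loudly.
Unique-entity marginals were chosen over record-weighted ones so the
dominant epitope does not also dominate the negatives.

Because a single dominant epitope can hold half the positives, its records
are first downsampled (uniformly, seeded) to exactly the count of the
second most frequent epitope. "Approximately the same number" is
implemented as exactly equal.

## Peptide-holdout cross-validation

Each fold holds out *all* records of one peptide (exact string identity) as
the test set and trains on the rest; a peptide gets a fold only if it has at
least 50 records (binders plus simulated nonbinders), so that per-peptide
AUCs are reasonably stable. The threshold is inclusive (≥ 50) and
configurable. Folds are ordered by descending record count, then
lexicographically. A one-mismatch neighbour of the held-out peptide in
training does not violate the holdout — unseen means not identical.

## The sequence model

Input layout per record:

    [cls] [tra] alpha-chain [trb] beta-chain [peptide] peptide [mhc] 34-residue pseudosequence

one token per residue, with prefix tokens delimiting the components. If the
sequence exceeds the model's `max_len`, chain residues are trimmed from the
*start* of the longer chain (chain starts are germline framework; the
hypervariable CDR3 sits at the chain end); the peptide and pseudosequence
are never truncated.

The encoder is a small pre-norm transformer with disentangled attention:
unnormalised scores combine content→content, content→position and
position→content terms over relative distances clipped to a window
`[-k, k]`,

    score(i,j) = Qc_i·Kc_j + Qc_i·Kr[d(i,j)] + Qr[d(j,i)]·Kc_j,   d(i,j) = clip(i-j, -k, k),

scaled by sqrt(3·d_head) and row-softmaxed. `Kr`/`Qr` are the bias-free
key/query projections of a learned relative-position table, so zeroing that
table recovers standard scaled dot-product attention exactly (a test relies
on this). Because position enters only through relative distance, tokens
carry no notion of which input component they belong to; each token
therefore also receives a learned *segment embedding* (alpha / beta /
peptide / MHC), derived on the fly from the prefix tokens, following the
BERT segment-id convention.

The whole network — autodiff, Adam, attention, layer norm, losses — is
implemented in numpy; training a default-size model is a CPU job by design.
Weights are float32; initialisation is fan-in-scaled for linear maps and
unit-scale for embeddings, which the pre-norm stack needs to get off the
ground. All randomness (init, shuffling, masking, dropout) flows from the
config seed, so a fixed seed reproduces loss traces exactly.

**Pretraining** is masked-residue modelling: per sequence, each residue
token is selected with probability 0.15 (prefix/special tokens never; at
least one always), selected tokens go 80% to `[mask]`, 10% to a random
residue, 10% unchanged, and cross-entropy over the 20 residue classes is
computed at selected positions only. A fresh model scores ln 20 ≈ 3.0 per
masked position, a useful calibration check. Pretraining on sequences that
contain both the TCR and its cognate peptide is what teaches the encoder
the peptide↔CDR3β correspondence; pretraining on paired chains alone leaves
the finetuned model at chance on held-out TCRs (the package's small-scale
replication of the transfer-learning point).

**Finetuning** pools per-token states — by default the concatenation of the
mean and the feature-wise maximum over valid tokens — and feeds a one-hidden-
layer logistic head. Max pooling matters: "somewhere in the beta chain there
is a peptide-matching k-mer" is existence evidence that a mean over ~90
tokens dilutes. `[cls]` pooling and a purely linear head remain available
via config. The learning rate steps down (×0.3) at 70% of the epochs.

Default model: 2 layers, 2 heads, d_model 32, relative window 8,
max_len 192, dropout 0.1, lr 3e-3, batch 32 — a few tens of thousands of
parameters, deliberately desk-scale. Output projections (MLM head and
classifier logit) initialise near zero, so a fresh model is uniform over
the residue classes and the masked-LM loss starts at ln 20. No published architecture is claimed; every
hyperparameter is config and recorded in run metadata.

## Evaluation statistics

AUC uses the Mann–Whitney formulation, (#{pos>neg} + ½·ties)/(n₊·n₋),
computed via average ranks. The random-model null draws every record's
prediction from uniform[0,1] and recomputes the AUC, 1000 times per fold;
the null mean sits near 0.5 and the 2.5/97.5 linear-interpolation
percentiles give the 95% interval, which narrows as the fold grows. The
primary significance measure is the add-one empirical tail,
p = (1 + #{null ≥ AUC}) / (1 + n_null), one-sided (better than random), with
the lower tail also reported; a record-resampling bootstrap of the model
AUC (default 10,000 replicates) is a labelled secondary mode, since the
exact bootstrap the headline analysis used is under-specified.

## Tractability features

Per held-out peptide, three train/test relationship features:

1. **CDR3β similarity** — median over test records of the distance to the
   nearest training CDR3β under a TCRdist-style metric: trim 3 residues from
   the junction start and 2 from its end, centre-gap-pad the shorter core
   (gaps after the first ⌈len/2⌉ residues — a fixed convention), then sum
   per-position costs (0 identity, min(4, 4−BLOSUM62) substitution, 4 gap)
   weighted ×3 for the CDR3 loop. This follows the published CDR3 component
   of TCRdist restricted to the beta chain; it is not a bit-exact tcrdist3
   port, and centre-gap alignment means the triangle inequality is not
   guaranteed (identity, symmetry and non-negativity are).
2. **HLA support** — ln(1 + number of training records with the fold's modal
   test allele); log1p handles absent alleles.
3. **Peptide proximity** — best aligned BLOSUM62 score between the held-out
   peptide and any training peptide (global alignment, linear gap −4 per gap
   position, via Bio.Align).

The per-fold summary statistics (median of minima; modal test allele) are
fixed conventions chosen for determinism. Pearson r (two-sided p) of each
feature against per-peptide AUC is reported, plus the full symmetric
correlation matrix; zero-variance features come back as missing, not zero.

## The synthetic study

The generator emulates the statistical structure of curated binding data at
desk scale, and its defaults are the package's study conditions:

* germline: 8 V and 4 J genes per locus; V segments 80–100 aa ending in the
  conserved Cys with annotated CDR1/CDR2 spans; J segments 12–18 aa whose
  F-G-X-G anchor sits 9–12 residues from the end, as in real TRAJ/TRBJ;
* 8 epitopes × 75 TCRs; peptide lengths over 8–12 (mode at 9-mers:
  0.05/0.50/0.25/0.15/0.05); 4 HLA alleles with skewed usage
  (0.40/0.30/0.18/0.12), mirroring the real dominance of a few alleles;
* binding signal: each epitope's CDR3β motif is its peptide's N-terminal
  4-mer, planted uncorrupted in a binder's CDR3β core with probability
  `motif_strength` (default 1.0). Deriving the motif from the peptide makes
  similar peptides attract similar motifs — the structure that makes some
  unseen peptides tractable. `cross_epitope_sharing` lets epitopes adopt a
  common motif instead; a dominant-epitope mode gives epitope 0 half of all
  positives to exercise downsampling;
* UMI tables: background (and negative-control) counts Poisson(20); a true
  binder's cognate count is Poisson(20 + effect·√20), i.e. the excess is
  `effect` background SDs.

What the generator does **not** emulate: real V(D)J recombination statistics,
biophysical TCR–pMHC energetics, cross-reactivity, batch effects, or
experimentally mislabelled records. Passing tests show the pipeline's logic
and the model's ability to extract a planted compositional signal; they say
nothing about accuracy on real repertoires.

## Problem sizes and numerical choices

The heavy test trains at the default study size (8×75 positives, equal
negatives, max_len 96 tokens — enough for both trimmed chains, any 8–12-mer
peptide and the full pseudosequence), with masked-LM pretraining on an
independently seeded synthetic cohort followed by finetuning; the evaluation
split holds out 20% of TCRs with all their records. Pretraining and
finetuning epoch counts at this scale are set so the whole learning check
runs in minutes on one CPU. Degenerate inputs fail loudly rather than
silently: single-class finetuning labels, a corpus smaller than one batch,
mask rate outside (0,1), a single-cell UMI table (SD undefined), infeasible
negative requests. Ties break deterministically everywhere (lexicographic
alleles, first-occurrence dedup, strict-inequality binder calls).

## Known limitations

* The numpy training loop is single-threaded and unsuitable beyond
  desk-scale corpora; the architecture, not the throughput, is the point.
* The packaged HLA sequences are synthetic stand-ins; real analyses must
  supply real heavy chains (the loaders accept any FASTA keyed by allele).
* The CDR3 metric approximates tcrdist3's CDR3β component only; V-gene CDR1/
  CDR2 contributions to TCR distance are out of scope.
* Simulated negatives inherit the known biases of mispairing (presumed
  non-cross-reactivity); the package reproduces the procedure, not a fix.
* With training from scratch (no pretraining) the model memorises TCR
  identities instead of learning the binding rule; this is a finding, and
  the default pipeline therefore pretrains first.
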