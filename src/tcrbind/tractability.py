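"""Train/test relationship features that make an unseen peptide tractable,
and their correlation with per-peptide AUC.

Three features are computed per held-out peptide:

1. CDR3beta similarity — for each test TCR, the distance to its nearest
   training CDR3beta under a TCRdist-style metric (trimmed cores, BLOSUM62
   substitution penalties capped at 4, CDR3 weight 3); summarised as the
   median over test records.  Lower = a more similar TCR exists in training.
2. HLA support — ln(1 + number of training records carrying the fold's
   modal test HLA allele).
3. Peptide proximity — the best aligned BLOSUM62 score between the held-out
   peptide and any training peptide (global alignment, linear gap -4).
   Higher = a more similar peptide exists in training.

The TCRdist-style metric here follows the published CDR3 component
restricted to the beta chain; it is an approximation, not a bit-exact port
of the tcrdist3 package.  Note the centre-gap alignment means the triangle
inequality is not guaranteed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import pearsonr

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

_GAP = "-"
_MISMATCH_CAP = 4.0
_GAP_COST = 4.0
_CDR3_WEIGHT = 3.0
_TRIM_START = 3
_TRIM_END = 2


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -4.0   # linear gap: -4 per gap position
    aligner.extend_gap_score = -4.0
    return aligner


_PEPTIDE_ALIGNER = _aligner()


def _centre_pad(core: str, target_len: int) -> str:
    """Insert gaps at the centre of ``core`` until it reaches ``target_len``
    (gaps go after the first ceil(len/2) residues; a fixed convention)."""
    gaps = target_len - len(core)
    split = (len(core) + 1) // 2
    return core[:split] + _GAP * gaps + core[split:]


def cdr3_distance(a: str, b: str) -> float:
    """TCRdist-style distance between two junction-inclusive CDR3 strings.

    Both are trimmed (3 from the start, 2 from the end), the shorter core is
    centre-gap padded to the longer, and per-position costs are summed:
    0 for identity, min(4, 4 - blosum62) for a substitution, 4 for a gap
    against a residue.  The sum is weighted by 3 (the CDR3 loop weight).
    """
    cores = []
    for cdr3 in (a, b):
        core = cdr3[_TRIM_START: len(cdr3) - _TRIM_END]
        if not core:
            raise ValueError(f"CDR3 {cdr3!r} too short to trim (need length > 5)")
        cores.append(core)
    n = max(len(c) for c in cores)
    x, y = (_centre_pad(c, n) for c in cores)
    total = 0.0
    for ca, cb in zip(x, y):
        if ca == cb:
            continue
        if ca == _GAP or cb == _GAP:
            total += _GAP_COST
        else:
            total += min(_MISMATCH_CAP, _MISMATCH_CAP - _BLOSUM62[ca, cb])
    return _CDR3_WEIGHT * total


def peptide_blosum_score(p1: str, p2: str) -> float:
    """Aligned BLOSUM62 score between two peptides: optimal global alignment
    score with a linear gap penalty of -4 per gap position."""
    if not p1 or not p2:
        raise ValueError("peptides must be non-empty")
    return float(_PEPTIDE_ALIGNER.score(p1, p2))


@dataclass
class PeptideFeatures:
    peptide: str
    cdr3b_similarity: Optional[float]  # median nearest-neighbour CDR3beta distance
    hla_log_count: float               # ln(1 + training records with the fold's HLA)
    peptide_distance: Optional[float]  # best aligned BLOSUM62 score to training


def fold_features(fold, train_records, test_records) -> PeptideFeatures:
    """The three tractability features for one held-out-peptide fold.

    ``cdr3b_similarity`` is the median over test records of the minimum
    CDR3beta distance to any training record; marked missing (None) when a
    side has no beta chains.  The fold's HLA allele is the modal allele of
    the test records."""
    train_cdr3b = [r.beta.cdr3_aa for r in train_records if r.beta is not None]
    test_cdr3b = [r.beta.cdr3_aa for r in test_records if r.beta is not None]
    if train_cdr3b and test_cdr3b:
        nn = [min(cdr3_distance(t, s) for s in train_cdr3b) for t in test_cdr3b]
        cdr3b_similarity = float(np.median(nn))
    else:
        cdr3b_similarity = None

    alleles = [r.phla.hla_allele for r in test_records]
    modal_allele = max(sorted(set(alleles)), key=alleles.count)
    n_same = sum(1 for r in train_records if r.phla.hla_allele == modal_allele)
    hla_log_count = math.log1p(n_same)

    held_out = test_records[0].phla.peptide_aa
    train_peptides = {r.phla.peptide_aa for r in train_records}
    if train_peptides:
        peptide_distance = max(peptide_blosum_score(held_out, p) for p in train_peptides)
    else:
        peptide_distance = None

    return PeptideFeatures(peptide=held_out, cdr3b_similarity=cdr3b_similarity,
                           hla_log_count=hla_log_count,
                           peptide_distance=peptide_distance)


def features_table(plan, records) -> pd.DataFrame:
    rows = []
    for fold in plan.folds:
        train = [records[i] for i in fold.train_ids]
        test = [records[i] for i in fold.test_ids]
        rows.append(asdict(fold_features(fold, train, test)))
    return pd.DataFrame(rows)


def correlate(features: pd.DataFrame, auc_per_peptide: Sequence[float]):
    """Pearson r (and two-sided p) of each feature against AUC, plus the full
    symmetric correlation matrix over {AUC, features}.  Zero-variance
    columns are reported as missing (NaN)."""
    feats = features.drop(columns=[c for c in ("peptide",) if c in features.columns])
    table = feats.astype(float).copy()
    table.insert(0, "auc", np.asarray(auc_per_peptide, dtype=float))
    if len(table) < 3:
        raise ValueError("need at least three peptides to correlate")

    per_feature = {}
    for col in table.columns:
        if col == "auc":
            continue
        sub = table[["auc", col]].dropna()
        if len(sub) < 3 or sub[col].std() == 0 or sub["auc"].std() == 0:
            per_feature[col] = {"r": float("nan"), "p": float("nan")}
            continue
        r, p = pearsonr(sub["auc"], sub[col])
        per_feature[col] = {"r": float(r), "p": float(p)}

    cols = list(table.columns)
    matrix = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            if ci == cj:
                col = table[ci].dropna()
                val = 1.0 if col.std() > 0 else float("nan")
            else:
                sub = table[[ci, cj]].dropna()
                if len(sub) < 3 or sub[ci].std() == 0 or sub[cj].std() == 0:
                    val = float("nan")
                else:
                    val = float(pearsonr(sub[ci], sub[cj])[0])
            matrix.loc[ci, cj] = matrix.loc[cj, ci] = val
    return per_feature, matrix
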