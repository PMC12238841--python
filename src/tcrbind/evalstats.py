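"""Per-peptide evaluation: AUC, random-model null distribution, and
empirical significance.

The AUC is the Mann-Whitney statistic: the probability that a randomly
chosen positive is scored above a randomly chosen negative, with ties
counted half.  The null model draws every record's prediction independently
from uniform[0,1]; repeating this (default 1000 times) gives a per-fold null
AUC distribution whose mean sits near 0.5 and whose 2.5/97.5 percentiles
form a 95% interval.  A predictor is significantly better than random when
its AUC lands in the extreme upper tail of that null (add-one empirical
p-value); a record-resampling bootstrap of the model AUC is available as a
secondary view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: (#{pos>neg} + 0.5 * #{ties}) / (n_pos * n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def random_null(labels: Sequence[int], n_reps: int = 1000,
                seed: int = 0) -> np.ndarray:
    """Null AUC distribution: each replicate scores every record with an
    independent uniform[0,1] draw and computes the AUC against ``labels``."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    return np.array([auc(rng.random(len(labels)), labels) for _ in range(n_reps)])


def null_interval(null_aucs: Sequence[float]) -> tuple[float, float, float]:
    """Mean and 2.5/97.5 linear-interpolation percentiles of a null AUC
    vector: ``(mean, lo, hi)``."""
    null_aucs = np.asarray(null_aucs, dtype=float)
    if null_aucs.size < 2:
        raise ValueError("need at least two null AUC values")
    lo, hi = np.percentile(null_aucs, [2.5, 97.5])
    return float(null_aucs.mean()), float(lo), float(hi)


@dataclass
class SignificanceResult:
    p_value: float            # one-sided, better-than-random (add-one)
    p_lower: float            # one-sided lower tail (worse-than-random)
    significant: bool         # p_value < alpha
    bootstrap_overlap: Optional[float] = None  # fraction of bootstrap AUCs <= null 97.5 pct


def significance(model_auc: float, null_aucs: Sequence[float],
                 alpha: float = 0.05,
                 scores: Optional[Sequence[float]] = None,
                 labels: Optional[Sequence[int]] = None,
                 n_boot: int = 10_000, seed: int = 0) -> SignificanceResult:
    """Empirical significance of a model AUC against the random null.

    Primary p-value: ``(1 + #{null >= model_auc}) / (1 + n_null)``.  When
    ``scores``/``labels`` are given, a record-resampling bootstrap (``n_boot``
    replicates) additionally reports how much of the bootstrap model-AUC
    distribution overlaps the null's upper bound.
    """
    null_aucs = np.asarray(null_aucs, dtype=float)
    if null_aucs.size == 0:
        raise ValueError("null distribution is empty")
    p = (1 + int((null_aucs >= model_auc).sum())) / (1 + null_aucs.size)
    p_lo = (1 + int((null_aucs <= model_auc).sum())) / (1 + null_aucs.size)
    overlap = None
    if scores is not None and labels is not None:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        rng = np.random.default_rng(seed)
        _, _, hi = null_interval(null_aucs)
        boot = np.empty(n_boot)
        n = len(labels)
        for b in range(n_boot):
            while True:
                idx = rng.integers(n, size=n)
                if 0 < labels[idx].sum() < n:
                    break
            boot[b] = auc(scores[idx], labels[idx])
        overlap = float((boot <= hi).mean())
    return SignificanceResult(p_value=float(p), p_lower=float(p_lo),
                              significant=bool(p < alpha),
                              bootstrap_overlap=overlap)


@dataclass
class PeptideEval:
    peptide: str
    n_records: int
    model_auc: float
    null_mean: float
    null_lo: float
    null_hi: float
    p_value: float
    significant: bool


@dataclass
class EvalReport:
    rows: list[PeptideEval]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def to_json(self, path=None) -> str:
        text = json.dumps([asdict(r) for r in self.rows], indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def evaluate_folds(plan, scores: Sequence[float], labels: Sequence[int],
                   n_reps: int = 1000, seed: int = 0,
                   alpha: float = 0.05) -> EvalReport:
    """Per held-out peptide: model AUC on the fold's test records, the
    random-model null (mean and 95% interval), and the empirical p-value.

    ``scores`` and ``labels`` are aligned with the record indexing that
    ``plan`` refers to."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rows = []
    for k, fold in enumerate(plan.folds):
        idx = np.asarray(fold.test_ids, dtype=int)
        fold_auc = auc(scores[idx], labels[idx])
        nulls = random_null(labels[idx], n_reps=n_reps, seed=seed + k)
        mean, lo, hi = null_interval(nulls)
        sig = significance(fold_auc, nulls, alpha=alpha)
        rows.append(PeptideEval(
            peptide=fold.held_out_peptide, n_records=len(idx),
            model_auc=fold_auc, null_mean=mean, null_lo=lo, null_hi=hi,
            p_value=sig.p_value, significant=sig.significant,
        ))
    return EvalReport(rows=rows)
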