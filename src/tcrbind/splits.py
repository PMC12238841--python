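"""Peptide-holdout (leave-one-group-out) cross-validation folds.

Unseen-peptide evaluation holds out all records of one peptide as the test
set and trains on everything else.  Only peptides with enough associated
records (default >= 50, binders plus simulated nonbinders) get a fold, so
that per-peptide performance estimates are reasonably stable.  Identity is
exact string match on the peptide — a one-mismatch neighbour in training
does not violate the holdout.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from .records import BindingRecord


@dataclass
class Fold:
    held_out_peptide: str
    test_ids: list[int]
    train_ids: list[int]


@dataclass
class SplitPlan:
    folds: list[Fold] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {"folds": [
            {"held_out_peptide": f.held_out_peptide,
             "test_ids": f.test_ids, "train_ids": f.train_ids}
            for f in self.folds
        ]}
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(folds=[Fold(f["held_out_peptide"], f["test_ids"], f["train_ids"])
                          for f in payload["folds"]])


def make_folds(records: list[BindingRecord], min_records: int = 50) -> SplitPlan:
    """One fold per peptide with >= ``min_records`` total records.  Each
    fold's test set is every record with that exact peptide; the train set is
    everything else.  Folds ordered by descending record count, ties broken
    lexicographically by peptide."""
    counts = Counter(r.phla.peptide_aa for r in records)
    qualifying = sorted(
        (p for p, n in counts.items() if n >= min_records),
        key=lambda p: (-counts[p], p),
    )
    plan = SplitPlan()
    for peptide in qualifying:
        test = [i for i, r in enumerate(records) if r.phla.peptide_aa == peptide]
        train = [i for i, r in enumerate(records) if r.phla.peptide_aa != peptide]
        plan.folds.append(Fold(peptide, test, train))
    return plan


def unseen_check(plan: SplitPlan, records: list[BindingRecord]) -> list[bool]:
    """Per fold: True iff the held-out peptide string occurs nowhere among
    the fold's training records (exact identity, not similarity)."""
    results = []
    for fold in plan.folds:
        leaked = any(records[i].phla.peptide_aa == fold.held_out_peptide
                     for i in fold.train_ids)
        results.append(not leaked)
    return results
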