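"""Positive-set balancing and simulated negatives by random mispairing.

Public binding data contain essentially no experimentally confirmed
non-binders, so negatives are simulated: a TCR and a peptide-HLA complex are
drawn independently from the positive set's marginals and paired, and the
pair is kept only if it does not occur among the positives (screening out
true positives generated at random) and has not been emitted before
(sampling without replacement).

Because a single dominant epitope can hold half the positives, its records
are first downsampled to the count of the second most frequent epitope so
that an equally sized negative pool can be drawn without replacement.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .records import BindingRecord


@dataclass
class MispairingConfig:
    ratio: float = 1.0          # negatives per positive
    seed: int = 0
    max_attempts: int = 0       # 0 -> auto (100x the requested count)
    weighted: bool = False      # record-weighted marginals instead of unique-entity

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def peptide_counts(records: list[BindingRecord]) -> Counter:
    return Counter(r.phla.peptide_aa for r in records)


def downsample_top_epitope(positives: list[BindingRecord], seed: int) -> list[BindingRecord]:
    """Subsample the single most frequent peptide's records (uniformly,
    without replacement, seeded) down to the count of the second most
    frequent peptide.  No-op when the top two counts are already equal."""
    counts = peptide_counts(positives)
    if len(counts) < 2:
        raise ValueError("need at least two distinct peptides to downsample")
    (top_pep, top_n), (_, second_n) = counts.most_common(2)
    if top_n <= second_n:
        return list(positives)
    rng = np.random.default_rng(seed)
    top_idx = [i for i, r in enumerate(positives) if r.phla.peptide_aa == top_pep]
    keep = set(rng.choice(top_idx, size=second_n, replace=False).tolist())
    return [r for i, r in enumerate(positives)
            if r.phla.peptide_aa != top_pep or i in keep]


def simulate_negatives(positives: list[BindingRecord],
                       cfg: MispairingConfig | None = None) -> list[BindingRecord]:
    """Generate ``floor(ratio * len(positives))`` nonbinder records by
    mispairing, screened against the positive pairs and internally unique.

    TCRs and peptide-HLA complexes are sampled uniformly over the unique
    entities of the positive set (record-weighted with ``cfg.weighted``).
    Raises if the requested count cannot be reached (small bipartite
    complement or attempt cap hit) — never a silent shortfall.
    """
    cfg = cfg or MispairingConfig()
    n_out = math.floor(cfg.ratio * len(positives))
    if n_out == 0:
        return []

    tcr_map: dict[tuple, BindingRecord] = {}
    phla_map: dict[tuple, BindingRecord] = {}
    for r in positives:
        tcr_map.setdefault(r.tcr_key(), r)
        phla_map.setdefault(r.phla_key(), r)
    if len(tcr_map) < 2 or len(phla_map) < 2:
        raise ValueError("need at least two distinct TCRs and two distinct pHLA")
    if cfg.weighted:
        tcr_keys = [r.tcr_key() for r in positives]
        phla_keys = [r.phla_key() for r in positives]
    else:
        tcr_keys = list(tcr_map)
        phla_keys = list(phla_map)

    positive_pairs = {(r.tcr_key(), r.phla_key()) for r in positives}
    complement_size = len(tcr_map) * len(phla_map) - len(positive_pairs)
    if n_out > complement_size:
        raise ValueError(
            f"cannot draw {n_out} unique negatives: only {complement_size} "
            f"non-positive (TCR, pHLA) pairs exist"
        )

    max_attempts = cfg.max_attempts or max(100 * n_out, 10_000)
    rng = np.random.default_rng(cfg.seed)
    emitted: set[tuple] = set()
    out: list[BindingRecord] = []
    attempts = 0
    while len(out) < n_out:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"mispairing exhausted {attempts} attempts with "
                f"{len(out)}/{n_out} negatives generated"
            )
        attempts += 1
        tk = tcr_keys[rng.integers(len(tcr_keys))]
        pk = phla_keys[rng.integers(len(phla_keys))]
        if (tk, pk) in positive_pairs or (tk, pk) in emitted:
            continue
        emitted.add((tk, pk))
        donor_tcr = tcr_map[tk]
        donor_phla = phla_map[pk]
        out.append(BindingRecord(
            alpha=donor_tcr.alpha, beta=donor_tcr.beta,
            phla=donor_phla.phla, label="nonbinder", source="mispairing",
        ))
    return out
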