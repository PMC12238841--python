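"""Glue between standardized records and the sequence model: stitching both
chains against a germline reference, extracting HLA pseudosequences, and
tokenizing everything for training and prediction."""

from __future__ import annotations

from .germline import GermlineDb, pseudosequence, stitch_chain
from .model.vocab import Vocabulary, tokenize
from .records import BindingRecord


def prepare_tokens(records: list[BindingRecord], db: GermlineDb,
                   hla_sequences: dict[str, str], pseudo_positions: list[int],
                   vocab: Vocabulary | None = None,
                   max_len: int | None = None) -> list[list[int]]:
    """Token id sequences for a list of records, order-aligned.

    Each record's chains are reconstituted from (V, J, CDR3) against the
    germline reference, and the HLA allele is mapped to its 34-residue
    pseudosequence.  Records must carry both chains.
    """
    vocab = vocab or Vocabulary.default()
    pseudo_cache: dict[str, str] = {}
    stitch_cache: dict[tuple, str] = {}
    out = []
    for i, r in enumerate(records):
        if r.alpha is None or r.beta is None:
            raise ValueError(f"record {i}: both chains required for the model")
        chains = {}
        for name, chain in (("alpha", r.alpha), ("beta", r.beta)):
            key = (chain.v_call, chain.j_call, chain.cdr3_aa)
            if key not in stitch_cache:
                stitch_cache[key] = stitch_chain(*key, db)
            chains[name] = stitch_cache[key]
        allele = r.phla.hla_allele
        if allele not in pseudo_cache:
            try:
                full = hla_sequences[allele]
            except KeyError:
                raise KeyError(f"record {i}: no heavy-chain sequence for {allele}") from None
            pseudo_cache[allele] = pseudosequence(full, pseudo_positions)
        out.append(tokenize(chains["alpha"], chains["beta"], r.phla.peptide_aa,
                            pseudo_cache[allele], vocab, max_len=max_len))
    return out


def labels_array(records: list[BindingRecord]) -> list[int]:
    return [1 if r.label == "binder" else 0 for r in records]
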