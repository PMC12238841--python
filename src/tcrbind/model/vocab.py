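"""Token vocabulary: the 20 standard amino acids plus special tokens.

The input layout for one binding record is

    [cls] [tra] a-chain residues [trb] b-chain residues
          [peptide] peptide residues [mhc] 34 pseudosequence residues

Prefix tokens delimit the four sequence components; [cls] pools the record
for classification; [pad]/[mask] serve batching and masked-LM pretraining.
Special tokens are never targets of the MLM head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SPECIAL_TOKENS = ["[pad]", "[cls]", "[mask]", "[tra]", "[trb]", "[peptide]", "[mhc]"]


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple[str, ...]

    @classmethod
    def default(cls) -> "Vocabulary":
        return cls(tokens=tuple(SPECIAL_TOKENS) + tuple(AMINO_ACIDS))

    def __len__(self) -> int:
        return len(self.tokens)

    def id(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    @property
    def pad_id(self) -> int:
        return self.id("[pad]")

    @property
    def mask_id(self) -> int:
        return self.id("[mask]")

    @property
    def residue_offset(self) -> int:
        return len(SPECIAL_TOKENS)

    @property
    def n_residues(self) -> int:
        return len(AMINO_ACIDS)

    def is_residue(self, token_id: int) -> bool:
        return token_id >= self.residue_offset

    def residue_id(self, aa: str) -> int:
        idx = AMINO_ACIDS.find(aa)
        if idx < 0:
            raise ValueError(f"residue {aa!r} outside the 20-letter alphabet")
        return self.residue_offset + idx

    def residue_class(self, token_id: int) -> int:
        """Map an amino-acid token id to its 0..19 class for the MLM head."""
        if not self.is_residue(token_id):
            raise ValueError(f"token id {token_id} is not a residue")
        return token_id - self.residue_offset

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"tokens": list(self.tokens)}, fh)

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            return cls(tokens=tuple(json.load(fh)["tokens"]))


def tokenize_pair(alpha_aa: str, beta_aa: str,
                  vocab: Vocabulary | None = None) -> list[int]:
    """Token ids for an unlabelled paired repertoire sequence (pretraining):
    [cls][tra]alpha[trb]beta."""
    vocab = vocab or Vocabulary.default()
    if not alpha_aa or not beta_aa:
        raise ValueError("both chains required for a paired sequence")
    ids = [vocab.id("[cls]"), vocab.id("[tra]")]
    ids += [vocab.residue_id(c) for c in alpha_aa]
    ids.append(vocab.id("[trb]"))
    ids += [vocab.residue_id(c) for c in beta_aa]
    return ids


def tokenize(alpha_aa: str, beta_aa: str, peptide_aa: str, pseudo_aa: str,
             vocab: Vocabulary | None = None,
             max_len: int | None = None) -> list[int]:
    """Token ids for one record: [cls][tra]a[trb]b[peptide]p[mhc]pseudo.

    All four components must be present.  If the result exceeds ``max_len``,
    chain residues are trimmed from the *start* of the longer chain first —
    chain starts are germline framework, while the hypervariable CDR3 sits
    near the chain end.  The peptide and pseudosequence components (the tail
    of the layout) are never truncated.
    """
    vocab = vocab or Vocabulary.default()
    for name, seq in [("alpha", alpha_aa), ("beta", beta_aa),
                      ("peptide", peptide_aa), ("pseudosequence", pseudo_aa)]:
        if not seq:
            raise ValueError(f"missing {name} sequence")

    if max_len is not None:
        fixed = 5 + len(peptide_aa) + len(pseudo_aa)
        budget = max_len - fixed
        if budget < 2:
            raise ValueError(f"max_len {max_len} cannot fit peptide and pseudosequence")
        overflow = len(alpha_aa) + len(beta_aa) - budget
        while overflow > 0:
            if len(beta_aa) >= len(alpha_aa):
                beta_aa = beta_aa[1:]
            else:
                alpha_aa = alpha_aa[1:]
            overflow -= 1

    ids = [vocab.id("[cls]"), vocab.id("[tra]")]
    ids += [vocab.residue_id(c) for c in alpha_aa]
    ids.append(vocab.id("[trb]"))
    ids += [vocab.residue_id(c) for c in beta_aa]
    ids.append(vocab.id("[peptide]"))
    ids += [vocab.residue_id(c) for c in peptide_aa]
    ids.append(vocab.id("[mhc]"))
    ids += [vocab.residue_id(c) for c in pseudo_aa]
    return ids
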