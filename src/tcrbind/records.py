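"""Core domain types for alpha/beta TCR - peptide-HLA-I binding records.

A binding record couples an alpha/beta T-cell receptor (at least one chain,
each described by its V and J gene calls and junction-inclusive CDR3) with a
peptide presented by an HLA class I molecule, plus a binary binder/nonbinder
label and a provenance tag.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_HLA_FULL_RE = re.compile(r"^HLA-[ABC]\*\d+:\d+$")
_HLA_GROUP_RE = re.compile(r"^HLA-[ABC]\*\d+$")


def is_standard_aa(seq: str) -> bool:
    """True iff every character is one of the 20 standard amino acids (uppercase)."""
    return bool(seq) and all(c in STANDARD_AA for c in seq)


@dataclass(frozen=True)
class TcrChain:
    """One TCR chain in minimal description: locus, V/J gene calls, CDR3.

    ``cdr3_aa`` is junction-inclusive (conserved Cys through conserved
    Phe/Trp).  ``full_aa`` holds the reconstituted variable domain when a
    germline reference has been applied.
    """

    locus: str  # "TRA" or "TRB"
    v_call: str
    j_call: str
    cdr3_aa: str
    full_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise ValueError(f"invalid locus {self.locus!r}")
        if not is_standard_aa(self.cdr3_aa):
            raise ValueError(f"CDR3 {self.cdr3_aa!r} contains non-standard residues")
        if not self.v_call.startswith(self.locus + "V"):
            raise ValueError(f"v_call {self.v_call!r} inconsistent with locus {self.locus}")
        if not self.j_call.startswith(self.locus + "J"):
            raise ValueError(f"j_call {self.j_call!r} inconsistent with locus {self.locus}")


@dataclass(frozen=True)
class PeptideHla:
    """A peptide together with the presenting HLA class I allele.

    ``pseudo_aa`` optionally carries the 34-residue heavy-chain
    pseudosequence used as the compact HLA representation.
    """

    peptide_aa: str
    hla_allele: str
    pseudo_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if not is_standard_aa(self.peptide_aa):
            raise ValueError(f"peptide {self.peptide_aa!r} contains non-standard residues")


@dataclass(frozen=True)
class BindingRecord:
    """One alpha/beta TCR - peptide-HLA-I observation with a binary label."""

    phla: PeptideHla
    label: str  # "binder" or "nonbinder"
    alpha: Optional[TcrChain] = None
    beta: Optional[TcrChain] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.alpha is None and self.beta is None:
            raise ValueError("record must carry an alpha and/or beta chain")
        if self.label not in ("binder", "nonbinder"):
            raise ValueError(f"invalid label {self.label!r}")

    def dedup_key(self) -> tuple:
        """Identity used for duplicate removal (label included: a binder and a
        nonbinder for the same complex are distinct records)."""
        a = (self.alpha.v_call, self.alpha.j_call, self.alpha.cdr3_aa) if self.alpha else (None,) * 3
        b = (self.beta.v_call, self.beta.j_call, self.beta.cdr3_aa) if self.beta else (None,) * 3
        return a + b + (self.phla.peptide_aa, self.phla.hla_allele, self.label)

    def tcr_key(self) -> tuple:
        """TCR identity only (both chains, no peptide/HLA/label)."""
        a = (self.alpha.v_call, self.alpha.j_call, self.alpha.cdr3_aa) if self.alpha else (None,) * 3
        b = (self.beta.v_call, self.beta.j_call, self.beta.cdr3_aa) if self.beta else (None,) * 3
        return a + b

    def phla_key(self) -> tuple:
        return (self.phla.peptide_aa, self.phla.hla_allele)


@dataclass
class FilterReport:
    """Per-reason rejection counters; ``rejections`` + ``retained`` partitions
    the input (conservation is asserted by :meth:`check`)."""

    rejections: Counter = field(default_factory=Counter)
    retained: int = 0

    def reject(self, reason: str) -> None:
        self.rejections[reason] += 1

    def accept(self) -> None:
        self.retained += 1

    @property
    def total(self) -> int:
        return self.retained + sum(self.rejections.values())

    def check(self, n_input: int) -> None:
        if self.total != n_input:
            raise AssertionError(
                f"filter report not conserved: {self.total} counted vs {n_input} input rows"
            )

    def to_dict(self) -> dict:
        return {"retained": self.retained, "rejections": dict(self.rejections)}


def hla_resolution(label: str) -> str:
    """Classify an HLA label: 'full' (2-field), 'group' (1-field), or 'other'."""
    if _HLA_FULL_RE.match(label):
        return "full"
    if _HLA_GROUP_RE.match(label):
        return "group"
    return "other"
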