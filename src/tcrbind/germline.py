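"""Chain reconstitution against a germline reference, CDR1/CDR2 annotation,
and HLA pseudosequence extraction.

Binding databases usually store a TCR chain as (V call, J call, CDR3) only.
The full variable-domain amino-acid sequence is reconstituted by splicing the
junction-inclusive CDR3 between the germline V prefix (everything before the
conserved Cys) and the germline J suffix (everything after the conserved
Phe/Trp of the F/W-G-X-G motif):

    full = V[0:anchor_V] + CDR3 + J[anchor_J+1:]

CDR3 residues always win over germline where they disagree — somatic
junctions legitimately differ from the reference.

The HLA class I molecule is compactly represented by a pseudosequence: the
heavy-chain residues at a fixed list of 34 positions lining the peptide
groove (positions within 4 A of a bound 9-mer), 1-based on the mature chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import is_standard_aa


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V or J amino-acid segment with its junction anchor.

    anchor: 0-based index of the conserved Cys (V) or the conserved Phe/Trp
    of the F/W-G-X-G motif (J).  V segments carry half-open CDR1/CDR2 spans.
    """

    name: str
    segment_type: str  # "V" or "J"
    aa: str
    anchor: int
    cdr1_span: Optional[tuple[int, int]] = None
    cdr2_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.segment_type not in ("V", "J"):
            raise ValueError(f"segment_type must be V or J, got {self.segment_type!r}")
        if not (0 <= self.anchor < len(self.aa)):
            raise ValueError(f"anchor {self.anchor} out of range for {self.name}")
        if self.segment_type == "V" and self.aa[self.anchor] != "C":
            raise ValueError(f"V segment {self.name}: anchor residue is not Cys")
        if self.segment_type == "J":
            if self.aa[self.anchor] not in "FW":
                raise ValueError(f"J segment {self.name}: anchor residue is not Phe/Trp")
            if self.anchor + 1 < len(self.aa) and self.aa[self.anchor + 1] != "G":
                raise ValueError(f"J segment {self.name}: F/W not followed by G")
        for span in (self.cdr1_span, self.cdr2_span):
            if span is not None and not (0 <= span[0] <= span[1] <= len(self.aa)):
                raise ValueError(f"CDR span {span} outside segment {self.name}")


class GermlineDb:
    """Allele-name -> segment lookup with gene-name fallback to the ``*01``
    allele (the canonical first allele of a gene)."""

    def __init__(self, segments: list[GermlineSegment]):
        self._by_name = {s.name: s for s in segments}

    def get(self, name: str) -> GermlineSegment:
        seg = self._by_name.get(name)
        if seg is None and "*" not in name:
            seg = self._by_name.get(name + "*01")
        if seg is None:
            raise KeyError(f"allele {name!r} not found in germline reference")
        return seg

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
            return True
        except KeyError:
            return False

    def segments(self) -> list[GermlineSegment]:
        return list(self._by_name.values())


def stitch_chain(v_call: str, j_call: str, cdr3_aa: str, db: GermlineDb) -> str:
    """Reconstitute the full variable-domain amino-acid sequence.

    ``cdr3_aa`` must follow the junction convention (starts with Cys, ends
    with Phe or Trp).  The CDR3 appears verbatim in the output at offset
    ``V.anchor``; a first residue differing from the germline Cys is not an
    error at this level (the junction convention check covers it).
    """
    if not cdr3_aa or cdr3_aa[0] != "C" or cdr3_aa[-1] not in "FW":
        raise ValueError(f"non-canonical junction {cdr3_aa!r} (must be C...F/W)")
    if not is_standard_aa(cdr3_aa):
        raise ValueError(f"CDR3 {cdr3_aa!r} contains non-standard residues")
    v = db.get(v_call)
    j = db.get(j_call)
    if v.segment_type != "V":
        raise ValueError(f"{v_call} is not a V segment")
    if j.segment_type != "J":
        raise ValueError(f"{j_call} is not a J segment")
    return v.aa[: v.anchor] + cdr3_aa + j.aa[j.anchor + 1 :]


def annotate_cdrs(v_call: str, db: GermlineDb) -> tuple[str, str]:
    """CDR1 and CDR2 of a V allele — fully determined by the germline."""
    v = db.get(v_call)
    if v.cdr1_span is None or v.cdr2_span is None:
        raise ValueError(f"V allele {v_call} lacks CDR1/CDR2 annotations")
    return (v.aa[v.cdr1_span[0] : v.cdr1_span[1]],
            v.aa[v.cdr2_span[0] : v.cdr2_span[1]])


def pseudosequence(hla_full_aa: str, positions: list[int]) -> str:
    """Extract the residues at the given 1-based positions of a mature HLA
    heavy chain, in the listed order."""
    if positions and max(positions) > len(hla_full_aa):
        raise ValueError(
            f"sequence too short: position {max(positions)} beyond length {len(hla_full_aa)}"
        )
    return "".join(hla_full_aa[p - 1] for p in positions)


# ---------------------------------------------------------------------------
# file formats: FASTA with structured headers (name|type|anchor|cdr1|cdr2),
# TSV sidecar mirroring the header fields, one-position-per-line text file.

def _span_str(span) -> str:
    return f"{span[0]}-{span[1]}" if span else "-"


def _parse_span(text: str):
    if text in ("-", ""):
        return None
    a, b = text.split("-")
    return (int(a), int(b))


def save_germline_fasta(db: GermlineDb, fasta_path, sidecar_path=None) -> None:
    recs = []
    for s in db.segments():
        header = "|".join([s.name, s.segment_type, str(s.anchor),
                           _span_str(s.cdr1_span), _span_str(s.cdr2_span)])
        recs.append(SeqRecord(Seq(s.aa), id=header, description=""))
    SeqIO.write(recs, fasta_path, "fasta")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            fh.write("name\tsegment_type\tanchor\tcdr1_span\tcdr2_span\n")
            for s in db.segments():
                fh.write("\t".join([s.name, s.segment_type, str(s.anchor),
                                    _span_str(s.cdr1_span), _span_str(s.cdr2_span)]) + "\n")


def load_germline_fasta(fasta_path) -> GermlineDb:
    segments = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name, seg_type, anchor, cdr1, cdr2 = rec.id.split("|")
        segments.append(GermlineSegment(
            name=name, segment_type=seg_type, aa=str(rec.seq), anchor=int(anchor),
            cdr1_span=_parse_span(cdr1), cdr2_span=_parse_span(cdr2),
        ))
    return GermlineDb(segments)


def load_pseudo_positions(path) -> list[int]:
    """One 1-based position per line; must be strictly increasing."""
    with open(path) as fh:
        positions = [int(line.strip()) for line in fh if line.strip()]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("pseudosequence positions must be strictly increasing")
    return positions


def load_hla_fasta(path) -> dict[str, str]:
    """Allele name -> mature heavy-chain amino-acid sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def packaged_pseudo_positions() -> list[int]:
    """The packaged 34-position pseudosequence definition (groove residues
    within 4 A of a bound 9-mer, 1-based on the mature heavy chain)."""
    ref = resources.files("tcrbind.data") / "pseudo_positions_34.txt"
    with resources.as_file(ref) as path:
        return load_pseudo_positions(path)


def packaged_hla_sequences() -> dict[str, str]:
    """Packaged synthetic HLA heavy-chain stand-ins (for tests and demos; not
    real IMGT/IPD sequences)."""
    ref = resources.files("tcrbind.data") / "hla_synthetic.fasta"
    with resources.as_file(ref) as path:
        return load_hla_fasta(path)


def packaged_hla_frequencies() -> dict[str, float]:
    """Packaged global HLA-I allele frequency fixture used for allele-group
    imputation (two-field allele -> approximate population frequency)."""
    ref = resources.files("tcrbind.data") / "hla_frequencies.tsv"
    freqs = {}
    with resources.as_file(ref) as path, open(path) as fh:
        next(fh)  # header
        for line in fh:
            name, freq = line.split("\t")
            freqs[name.strip()] = float(freq)
    return freqs
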