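"""Reconstitute a full TCR chain from its minimal description.

A binding database usually stores only (V call, J call, CDR3).  The full
variable domain is germline V up to its conserved Cys, then the junction,
then germline J after its conserved Phe — printed here together with the
germline-determined CDR1/CDR2 loops and an HLA pseudosequence.
"""

from tcrbind import synth
from tcrbind.germline import (annotate_cdrs, packaged_hla_sequences,
                              packaged_pseudo_positions, pseudosequence,
                              stitch_chain)

cfg = synth.SynthConfig(seed=7)
db = synth.gen_germline_db(cfg)

v_call, j_call, cdr3 = "TRBV1*01", "TRBJ1*01", "CASSLGQAYEQYF"
full = stitch_chain(v_call, j_call, cdr3, db)
cdr1, cdr2 = annotate_cdrs(v_call, db)

print(f"V={v_call} J={j_call} CDR3={cdr3}")
print(f"full beta chain ({len(full)} aa): {full}")
print(f"CDR3 found at offset {full.find(cdr3)} (the V anchor)")
print(f"CDR1={cdr1}  CDR2={cdr2}  (fixed by the V allele)")

positions = packaged_pseudo_positions()
allele, seq = next(iter(packaged_hla_sequences().items()))
print(f"{allele} pseudosequence ({len(positions)} groove residues): "
      f"{pseudosequence(seq, positions)}")
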